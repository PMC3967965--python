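"""End-to-end replay of the study's computational analyses on the packaged
synthetic fixture.

Composes the module-level operations into one report: the miR-224 /
miR-224_SNP x C/G-allele seed truth table, the moving-window ensemble
summary, per-allele duplex/accessibility ddG, probing concordance against
the packaged cleavage table, k_obs recovery from simulated annealing
courses, and synthetic-cohort allelic-imbalance statistics.
"""

from __future__ import annotations

from typing import Optional

from . import aei, fixtures, kinetics
from .core import apply_allele
from .energy import site_ddG
from .ensemble import (
    DEFAULT_SCHEME,
    WindowScheme,
    fold_ensemble,
    mfe_fold,
    probing_concordance,
    snp_context_summary,
)
from .fold import EnergyModel
from .seeds import allelic_site_effect
from .simulate import synth_aei_cohort

#: Published observed annealing rate constants used as simulation ground
#: truth: C-variant and G-variant complexes with miR-224, M^-1 s^-1.
KOBS_C = 2.2e6
KOBS_G = 1.4e6
#: Annealing assay concentrations: 0.5 nM labeled miRNA, 5 nM target.
A0_MOLAR = 0.5e-9
B0_MOLAR = 5e-9

DEFAULT_TIMES = (10, 30, 60, 120, 300, 600, 1200)

#: Reduced scheme for quick smoke runs (window counts scale, folding stays cheap).
QUICK_SCHEME = WindowScheme(sizes=(60, 100), steps=(20, 20), description="quick 60/100 nt grid")


def seed_truth_table(toy=None) -> dict:
    """4-cell truth table: {miR-224, miR-224_SNP} x {C allele, G allele}."""
    t, v, _ = toy if toy is not None else fixtures.tcf21_toy()
    cells = {}
    for m in (fixtures.MIR224, fixtures.MIR224_SNP):
        eff = allelic_site_effect(m, t, v)
        cells[m.id] = {
            "C_allele_match": eff.ref_match,
            "G_allele_match": eff.alt_match,
            "verdict": eff.verdict.value,
        }
    return cells


def ensemble_report(toy=None, scheme: WindowScheme = DEFAULT_SCHEME, model: Optional[EnergyModel] = None) -> dict:
    t, v, _ = toy if toy is not None else fixtures.tcf21_toy()
    folded = fold_ensemble(t, v, scheme, model)
    summary = snp_context_summary(folded)
    return {
        "n_structures": len(folded),
        "per_allele": {
            allele: {
                "allele_base": s.allele_base,
                "n_windows": s.n_windows,
                "n_loop": s.n_loop,
                "n_stem": s.n_stem,
                "fraction_loop": s.fraction_loop,
            }
            for allele, s in summary.items()
        },
    }


def ddg_report(toy=None, window: int = 200, model: Optional[EnergyModel] = None) -> dict:
    """Per-allele ddG over a window centered on the planted site."""
    t, v, m = toy if toy is not None else fixtures.tcf21_toy()
    start = max(1, v.pos - window // 2)
    end = min(len(t), start + window - 1)
    site_start = fixtures.SEED_SITE_START - start + 1
    site_end = fixtures.SEED_SITE_END - start + 1
    out = {}
    for which, base in (("ref", v.ref), ("alt", v.alt)):
        seq = apply_allele(t, v, which).seq[start - 1 : end]
        res = site_ddG(seq, m, site_start, site_end, allele=base, model=model)
        out[base] = {"dG_duplex": res.dG_duplex, "dG_open": res.dG_open, "ddG": res.ddG}
    return out


def probing_report(toy=None, window: int = 100, model: Optional[EnergyModel] = None) -> dict:
    """Concordance of each allele's folded window with its cleavage records."""
    t, v, _ = toy if toy is not None else fixtures.tcf21_toy()
    start = max(1, v.pos - window // 2)
    end = min(len(t), start + window - 1)
    records = fixtures.fig5_cleavage_records()
    out = {}
    for which, base in (("ref", v.ref), ("alt", v.alt)):
        seq = apply_allele(t, v, which).seq[start - 1 : end]
        s = mfe_fold(seq, model)
        recs = [r for r in records if r.allele == base]
        rep = probing_concordance(s, recs, window_start=start)
        out[base] = {
            "n_concordant": rep.n_concordant,
            "n_total": rep.n_total,
            "fraction": rep.fraction,
            "n_invalid_t1": sum(1 for _, status in rep.verdicts if status == "invalid_t1"),
        }
    return out


def kinetics_report(seed: int = 0, noise_cv: float = 0.0) -> dict:
    out = {}
    for label, k_true in (("C", KOBS_C), ("G", KOBS_G)):
        tc = kinetics.simulate_timecourse(
            k_true, A0_MOLAR, B0_MOLAR, DEFAULT_TIMES, noise_cv=noise_cv, seed=seed
        )
        est = kinetics.estimate_kobs(tc)
        out[label] = {
            "k_true": k_true,
            "k_obs": est.k_obs,
            "rel_error": abs(est.k_obs - k_true) / k_true,
            "converged": est.converged,
        }
    return out


def aei_report(seed: int = 0, n: int = 22, fold: float = 2.0, noise_cv: float = 0.10) -> dict:
    cohort = synth_aei_cohort(n=n, fold=fold, noise_cv=noise_cv, seed=seed)
    res = aei.aei_cohort_test(cohort)
    return {
        "n": res.n,
        "planted_fold": fold,
        "mean_ratio": res.mean_ratio,
        "mean_log2_ratio": res.mean_log2_ratio,
        "p_paired": res.p_paired,
        "p_vs_one": res.p_vs_one,
    }


def replay(
    seed: int = 0,
    scheme: WindowScheme = DEFAULT_SCHEME,
    model: Optional[EnergyModel] = None,
) -> dict:
    """Full fixture replay; deterministic for fixed seed and scheme."""
    toy = fixtures.tcf21_toy()
    return {
        "fixture": {"transcript": toy[0].id, "variant": toy[1].rsid, "length": len(toy[0])},
        "seed_truth_table": seed_truth_table(toy),
        "ensemble": ensemble_report(toy, scheme, model),
        "ddG": ddg_report(toy, model=model),
        "probing": probing_report(toy, model=model),
        "kinetics": kinetics_report(seed=seed),
        "aei": aei_report(seed=seed),
    }
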