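"""Seeded synthetic-data generators for every pipeline stage.

All generators draw from independent substreams of a single root seed via
``numpy``'s SeedSequence spawning: ``default_rng([root_seed, stream_id])``
with a fixed stream id per generator, so adding a generator never perturbs
the output of another.  Identical configuration implies bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aei import AeiSample
from .core import GenomicInterval, Mirna, MirsnpError, Transcript, Variant, revcomp
from .overlap import LdPair, SnpRecord

__all__ = [
    "STREAMS",
    "synth_transcript_with_site",
    "synth_aei_cohort",
    "synth_tracks",
    "synth_correlated_series",
    "SyntheticTracks",
]

#: Fixed substream ids; never renumber, only append.
STREAMS = {
    "transcript": 1,
    "aei": 2,
    "tracks": 3,
    "series": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), STREAMS[stream]])


def _random_rna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=p)])


def synth_transcript_with_site(
    utr_len: int = 2000,
    seed_heptamer: str = "GUGACUU",
    site_start: int | None = None,
    snp_offset_in_site: int = 5,
    alt_base: str = "G",
    seed: int = 0,
    gc: float = 0.5,
    forced_bases: dict | None = None,
    transcript_id: str = "synthUTR",
    rsid: str = "rsSYNTH",
    max_tries: int = 200,
) -> tuple[Transcript, Variant, Mirna]:
    """A random-background UTR with one planted seed site and a site-internal SNP.

    The heptamer (the target match to guide nt 2-8) is planted at
    ``site_start`` (1-based; default: centered), the variant substitutes
    ``alt_base`` at offset ``snp_offset_in_site`` (1-7) within the heptamer,
    and the returned guide's nt 2-8 are the reverse complement of the
    heptamer.  Backgrounds are rejection-sampled until the heptamer's 6-nt
    core occurs nowhere else on either allele, so a scanner finds exactly
    the planted site on the reference allele and nothing on the alternate.
    """
    if len(seed_heptamer) != 7:
        raise MirsnpError("seed heptamer must be 7 nt")
    if not 1 <= snp_offset_in_site <= 7:
        raise MirsnpError(f"snp_offset_in_site {snp_offset_in_site} outside 1-7")
    if snp_offset_in_site == 1:
        # the heptamer's first base only pairs guide nt 8; substituting it
        # leaves the 6-nt core intact, so the alternate allele would keep a
        # detectable 6mer/7mer-A1 site
        raise MirsnpError("snp_offset_in_site 1 cannot fully disrupt the site; use 2-7")
    if site_start is None:
        site_start = utr_len // 2 - 3
    if site_start < 1 or site_start + 6 > utr_len:
        raise MirsnpError(f"site at {site_start} does not fit in a {utr_len}-nt UTR")
    ref_base = seed_heptamer[snp_offset_in_site - 1]
    if alt_base == ref_base:
        raise MirsnpError(f"alt base {alt_base} equals the planted reference base")
    pos = site_start + snp_offset_in_site - 1

    # core whose uniqueness guarantees exactly one detectable site
    core6 = seed_heptamer[1:]

    rng = _rng(seed, "transcript")
    for _ in range(max_tries):
        bases = list(_random_rna(rng, utr_len, gc))
        bases[site_start - 1 : site_start + 6] = list(seed_heptamer)
        for p, b in (forced_bases or {}).items():
            if site_start <= p <= site_start + 6 and bases[p - 1] != b:
                raise MirsnpError(f"forced base at {p} conflicts with the planted site")
            bases[p - 1] = b
        ref_seq = "".join(bases)
        alt_seq = ref_seq[: pos - 1] + alt_base + ref_seq[pos:]
        if ref_seq.count(core6) == 1 and alt_seq.count(core6) == 0:
            t = Transcript(transcript_id, ref_seq)
            v = Variant(transcript_id, pos, ref_base, alt_base, rsid)
            guide = "C" + revcomp(seed_heptamer)  # nt 1 arbitrary non-A-pairing
            guide = guide + _random_rna(rng, 13, gc)  # pad to a 21-nt guide
            m = Mirna("synth-miR", guide)
            return t, v, m
    raise MirsnpError("could not place a unique site in the requested geometry")


def synth_aei_cohort(
    n: int = 22,
    fold: float = 2.0,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> list[AeiSample]:
    """Heterozygous cohort with a planted fold-imbalance.

    gDNA allelic ratios are lognormal around 1 and cDNA ratios lognormal
    around ``fold``, both with coefficient of variation ``noise_cv``
    (noise_cv = 0 gives every normalized ratio exactly ``fold``).
    """
    if n < 1:
        raise MirsnpError("n must be >= 1")
    if fold <= 0:
        raise MirsnpError("fold must be positive")
    if noise_cv < 0:
        raise MirsnpError("noise_cv must be non-negative")
    rng = _rng(seed, "aei")
    sigma = math.sqrt(math.log1p(noise_cv**2))
    out = []
    for i in range(n):
        g_ratio = float(rng.lognormal(mean=0.0, sigma=sigma)) if sigma else 1.0
        c_ratio = float(rng.lognormal(mean=math.log(fold), sigma=sigma)) if sigma else fold
        out.append(
            AeiSample(
                sample_id=f"S{i + 1:02d}",
                signal_a_cdna=c_ratio,
                signal_b_cdna=1.0,
                signal_a_gdna=g_ratio,
                signal_b_gdna=1.0,
            )
        )
    return out


@dataclass(frozen=True)
class SyntheticTracks:
    tf_track: tuple
    mir_track: tuple
    snps: tuple
    ld_pairs: tuple
    config: dict


def synth_tracks(
    genome_len: int = 1_000_000,
    n_tf: int = 200,
    n_mir: int = 100,
    n_snps: int = 2000,
    tf_len: int = 300,
    mir_len: int = 20,
    co_occurrence: float = 0.05,
    p_tf_only: float = 0.15,
    p_mir_only: float = 0.05,
    n_ld_pairs: int = 100,
    seed: int = 0,
    chrom: str = "chr1",
) -> SyntheticTracks:
    """Toy single-chromosome genome with configurable SNP/track co-occurrence.

    SNP categories are drawn multinomially: a fraction ``co_occurrence``
    is placed inside engineered TF+miR double-overlap regions, ``p_tf_only``
    inside TF-only regions, ``p_mir_only`` inside miR-only regions, and the
    rest rejection-sampled outside both tracks, so recovered Venn fractions
    converge to the configuration as n_snps grows.
    """
    probs = (co_occurrence, p_tf_only, p_mir_only)
    if any(p < 0 for p in probs) or sum(probs) > 1:
        raise MirsnpError("category probabilities must be non-negative and sum <= 1")
    n_both_regions = max(1, n_tf // 10)
    if (n_tf + n_mir) * max(tf_len, mir_len) > genome_len // 2:
        raise MirsnpError("track density infeasible for the genome length")
    rng = _rng(seed, "tracks")

    tf, mir = [], []
    # engineered double-overlap regions: a miR site inside a TF region
    for i in range(n_both_regions):
        start = int(rng.integers(0, genome_len - tf_len))
        tf.append(GenomicInterval(chrom, start, start + tf_len, f"tf_both_{i}"))
        moff = int(rng.integers(0, tf_len - mir_len))
        mir.append(GenomicInterval(chrom, start + moff, start + moff + mir_len, f"mir_both_{i}"))
    for i in range(n_tf - n_both_regions):
        start = int(rng.integers(0, genome_len - tf_len))
        tf.append(GenomicInterval(chrom, start, start + tf_len, f"tf_{i}"))
    for i in range(n_mir - n_both_regions):
        start = int(rng.integers(0, genome_len - mir_len))
        mir.append(GenomicInterval(chrom, start, start + mir_len, f"mir_{i}"))

    def covered(pos: int, track: list[GenomicInterval]) -> bool:
        return any(iv.start <= pos < iv.end for iv in track)

    both_regions = [
        (m.start, m.end) for m in mir if m.name.startswith("mir_both_")
    ]
    cats = rng.choice(4, size=n_snps, p=[*probs, 1.0 - sum(probs)])
    snps = []
    for i, cat in enumerate(cats):
        if cat == 0:  # both
            lo, hi = both_regions[int(rng.integers(0, len(both_regions)))]
            pos = int(rng.integers(lo, hi))
        elif cat == 1:  # TF only
            while True:
                iv = tf[int(rng.integers(0, len(tf)))]
                pos = int(rng.integers(iv.start, iv.end))
                if not covered(pos, mir):
                    break
        elif cat == 2:  # miR only
            while True:
                iv = mir[int(rng.integers(0, len(mir)))]
                pos = int(rng.integers(iv.start, iv.end))
                if not covered(pos, tf):
                    break
        else:  # neither
            while True:
                pos = int(rng.integers(0, genome_len))
                if not covered(pos, tf) and not covered(pos, mir):
                    break
        snps.append(SnpRecord(f"rs{i:06d}", chrom, pos))

    ld = []
    for _ in range(n_ld_pairs):
        a, b = rng.choice(n_snps, size=2, replace=False)
        ld.append(LdPair(snps[a].snp_id, snps[b].snp_id, float(rng.uniform(0.5, 1.0))))

    return SyntheticTracks(
        tf_track=tuple(tf),
        mir_track=tuple(mir),
        snps=tuple(snps),
        ld_pairs=tuple(ld),
        config={
            "genome_len": genome_len,
            "co_occurrence": co_occurrence,
            "p_tf_only": p_tf_only,
            "p_mir_only": p_mir_only,
            "seed": seed,
        },
    )


def synth_correlated_series(n: int = 16, target_r: float = -0.7, seed: int = 0) -> tuple:
    """Bivariate normal pair (x, y) with population correlation ``target_r``.

    target_r = +/-1 degenerates to an exact linear relation.
    """
    if n < 3:
        raise MirsnpError("n must be >= 3")
    if not -1.0 <= target_r <= 1.0:
        raise MirsnpError(f"target_r {target_r} outside [-1, 1]")
    rng = _rng(seed, "series")
    x = rng.standard_normal(n)
    if abs(target_r) == 1.0:
        y = math.copysign(1.0, target_r) * x
    else:
        z = rng.standard_normal(n)
        y = target_r * x + math.sqrt(1.0 - target_r**2) * z
    return x, y
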