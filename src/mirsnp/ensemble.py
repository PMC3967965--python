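"""Moving-window structure ensembles around a SNP, and probing concordance.

The ensemble procedure slides fixed-size windows across the variant so the
SNP occupies a grid of internal offsets, folds every window for both
alleles, and classifies the SNP's structural context (paired = stem,
any unpaired context = loop) per allele.  Predicted structures can be
scored against chemical/enzymatic probing records: Pb2+ cleaves any
unpaired residue, RNase T1 only unpaired G residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import MirsnpError, Transcript, Variant, apply_allele
from .fold import EnergyModel, SecondaryStructure, mfe_fold, pair_context

__all__ = [
    "WindowScheme",
    "WindowSpec",
    "FoldedWindow",
    "EnsembleSummary",
    "CleavageRecord",
    "ConcordanceReport",
    "DEFAULT_SCHEME",
    "enumerate_windows",
    "fold_ensemble",
    "snp_context_summary",
    "site_accessibility",
    "probing_concordance",
]


@dataclass(frozen=True)
class WindowScheme:
    """Window sizes with one step per size; the SNP offsets within a window
    of size s with step d are d, 2d, ..., <= s (floor(s/d) windows)."""

    sizes: tuple
    steps: tuple
    description: str = ""

    def __post_init__(self):
        if len(self.sizes) != len(self.steps):
            raise MirsnpError("scheme needs one step per window size")
        for s, d in zip(self.sizes, self.steps):
            if s <= 0:
                raise MirsnpError(f"window size {s} must be positive")
            if not 10 <= d <= 25:
                raise MirsnpError(f"step {d} outside the 10-25 nt range")

    def n_windows(self) -> int:
        return sum(s // d for s, d in zip(self.sizes, self.steps))


#: Sizes 100/200/400/800 with steps 10/10/20/20: 10+20+20+40 = 90 windows per
#: allele, 180 over both alleles.
DEFAULT_SCHEME = WindowScheme(
    sizes=(100, 200, 400, 800),
    steps=(10, 10, 20, 20),
    description="default 100-800 nt grid, 90 windows per allele",
)


@dataclass(frozen=True)
class WindowSpec:
    """One window: transcript interval [start, end] (1-based inclusive) with
    the SNP at 1-based offset ``snp_offset`` inside it."""

    size: int
    snp_offset: int
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.snp_offset <= self.size:
            raise MirsnpError(f"snp_offset {self.snp_offset} outside window of size {self.size}")
        if self.end - self.start + 1 != self.size:
            raise MirsnpError("window interval inconsistent with size")


def enumerate_windows(t: Transcript, v: Variant, scheme: WindowScheme = DEFAULT_SCHEME) -> list[WindowSpec]:
    """All window specs of the scheme mapped to transcript coordinates.

    A window that would extend past either transcript end is an error, not
    clipped: unequal windows would break the paired allele comparison.
    """
    n = len(t)
    out = []
    for size, step in zip(scheme.sizes, scheme.steps):
        for k in range(1, size // step + 1):
            offset = k * step
            start = v.pos - offset + 1
            end = start + size - 1
            if start < 1 or end > n:
                raise MirsnpError(
                    f"window size {size} with SNP offset {offset} spans "
                    f"[{start},{end}] outside transcript of length {n}"
                )
            out.append(WindowSpec(size=size, snp_offset=offset, start=start, end=end))
    return out


@dataclass(frozen=True)
class FoldedWindow:
    allele: str  # "ref" or "alt"
    allele_base: str
    spec: WindowSpec
    structure: SecondaryStructure

    @property
    def snp_context(self) -> str:
        return pair_context(self.structure, self.spec.snp_offset)


def fold_ensemble(
    t: Transcript,
    v: Variant,
    scheme: WindowScheme = DEFAULT_SCHEME,
    model: Optional[EnergyModel] = None,
) -> list[FoldedWindow]:
    """Fold every window of the scheme for both alleles (ref first).

    Both alleles are folded over identical coordinate windows, so the output
    is a paired comparison of 2 x n_windows structures.
    """
    windows = enumerate_windows(t, v, scheme)
    out = []
    for which, base in (("ref", v.ref), ("alt", v.alt)):
        allele_t = apply_allele(t, v, which)
        for spec in windows:
            seq = allele_t.seq[spec.start - 1 : spec.end]
            out.append(
                FoldedWindow(
                    allele=which,
                    allele_base=base,
                    spec=spec,
                    structure=mfe_fold(seq, model),
                )
            )
    return out


@dataclass(frozen=True)
class EnsembleSummary:
    """Binary loop/stem tally of the SNP position over one allele's windows."""

    allele: str
    allele_base: str
    n_windows: int
    n_loop: int
    n_stem: int

    @property
    def fraction_loop(self) -> float:
        return self.n_loop / self.n_windows if self.n_windows else float("nan")

    def __post_init__(self):
        if self.n_loop + self.n_stem != self.n_windows:
            raise MirsnpError("loop + stem counts must equal window count")


def snp_context_summary(folded: list[FoldedWindow]) -> dict[str, EnsembleSummary]:
    """Per-allele loop/stem counts: paired -> stem, any unpaired context -> loop."""
    tallies: dict[str, dict] = {}
    for fw in folded:
        tal = tallies.setdefault(fw.allele, {"base": fw.allele_base, "loop": 0, "stem": 0})
        if fw.snp_context == "stem":
            tal["stem"] += 1
        else:
            tal["loop"] += 1
    return {
        allele: EnsembleSummary(
            allele=allele,
            allele_base=tal["base"],
            n_windows=tal["loop"] + tal["stem"],
            n_loop=tal["loop"],
            n_stem=tal["stem"],
        )
        for allele, tal in tallies.items()
    }


def site_accessibility(s: SecondaryStructure, start: int, end: int) -> float:
    """Fraction of site nucleotides unpaired; interval 1-based inclusive."""
    n = len(s.seq)
    if not (1 <= start <= end <= n):
        raise MirsnpError(f"site [{start},{end}] outside structure of length {n}")
    ptab = s.partner_table()
    free = sum(1 for p in range(start - 1, end) if ptab[p] == -1)
    return free / (end - start + 1)


@dataclass(frozen=True)
class CleavageRecord:
    """One probing cleavage: reagent Pb (any unpaired) or T1 (unpaired G)."""

    position: int  # 1-based transcript coordinate
    reagent: str  # "Pb" or "T1"
    strength: str  # "weak" or "strong"
    allele: str = ""

    def __post_init__(self):
        if self.reagent not in ("Pb", "T1"):
            raise MirsnpError(f"unknown probing reagent {self.reagent!r}")
        if self.strength not in ("weak", "strong"):
            raise MirsnpError(f"unknown cleavage strength {self.strength!r}")


@dataclass(frozen=True)
class ConcordanceReport:
    n_concordant: int
    n_total: int
    verdicts: tuple  # (record, status) with status concordant|discordant|invalid_t1

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_total if self.n_total else float("nan")


def probing_concordance(
    s: SecondaryStructure,
    cleavages: list[CleavageRecord],
    window_start: int = 1,
) -> ConcordanceReport:
    """Score predicted structure against cleavage records.

    ``window_start`` maps transcript coordinates onto the folded window.  A
    Pb record is concordant iff the residue is predicted unpaired; a T1
    record additionally requires a G residue — T1 records on non-G residues
    are flagged invalid and excluded from the total.
    """
    n = len(s.seq)
    ptab = s.partner_table()
    verdicts = []
    n_conc = n_total = 0
    for rec in cleavages:
        local = rec.position - window_start + 1
        if not 1 <= local <= n:
            raise MirsnpError(
                f"cleavage position {rec.position} outside window starting at {window_start}"
            )
        if rec.reagent == "T1" and s.seq[local - 1] != "G":
            verdicts.append((rec, "invalid_t1"))
            continue
        unpaired = ptab[local - 1] == -1
        n_total += 1
        if unpaired:
            n_conc += 1
            verdicts.append((rec, "concordant"))
        else:
            verdicts.append((rec, "discordant"))
    return ConcordanceReport(n_concordant=n_conc, n_total=n_total, verdicts=tuple(verdicts))
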