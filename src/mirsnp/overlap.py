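"""SNP x track overlap analysis: LD expansion, interval membership, Venn
counts and binomial enrichment.

Mirrors the desk-scale structure of a genome-wide analysis intersecting a
disease-SNP catalog (LD-expanded at an r-squared threshold) with TF-binding
and miRNA-site tracks, then asking whether the number of SNPs hitting an
annotation exceeds the binomial expectation given the fraction of the
background genome the annotation covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .core import GenomicInterval, MirsnpError

__all__ = [
    "LdPair",
    "SnpRecord",
    "OverlapSummary",
    "EnrichmentResult",
    "expand_ld",
    "snps_in_track",
    "overlap_venn",
    "binomial_enrichment",
    "track_overlap_fraction",
]


@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise MirsnpError(f"r2 {self.r2} outside [0, 1]")


@dataclass(frozen=True)
class SnpRecord:
    """A SNP as a width-1 genomic interval (0-based position)."""

    snp_id: str
    chrom: str
    pos: int  # 0-based

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, self.snp_id)


def expand_ld(snps: set, ld_pairs: Iterable[LdPair], r2_min: float = 0.8) -> set:
    """Input set plus all single-hop LD partners with r2 strictly > r2_min.

    Symmetric on load (a-b implies b-a), monotone (output is a superset) and
    idempotent for a fixed table.
    """
    if not 0.0 <= r2_min <= 1.0:
        raise MirsnpError(f"r2_min {r2_min} outside [0, 1]")
    out = set(snps)
    for pair in ld_pairs:
        if pair.r2 > r2_min:
            if pair.snp_a in snps:
                out.add(pair.snp_b)
            if pair.snp_b in snps:
                out.add(pair.snp_a)
    return out


def _build_trees(track: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def snps_in_track(snps: Sequence[SnpRecord], track: Sequence[GenomicInterval]) -> list[bool]:
    """Per-SNP membership flags: True iff the SNP base overlaps any interval
    (half-open semantics; a SNP at position p hits [p, p+1) overlaps)."""
    trees = _build_trees(track)
    flags = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        flags.append(bool(tree is not None and tree.overlaps(snp.pos, snp.pos + 1)))
    return flags


@dataclass(frozen=True)
class OverlapSummary:
    """Venn counts of a SNP set against two tracks; n_in_tf and n_in_mir each
    include the SNPs hitting both."""

    n_snps: int
    n_in_tf: int
    n_in_mir: int
    n_in_both: int

    def __post_init__(self):
        if self.n_in_both > min(self.n_in_tf, self.n_in_mir):
            raise MirsnpError("both-count exceeds a marginal count")

    def fraction(self, count: int) -> float:
        return count / self.n_snps if self.n_snps else 0.0

    @property
    def fractions(self) -> dict:
        return {
            "tf": self.fraction(self.n_in_tf),
            "mir": self.fraction(self.n_in_mir),
            "both": self.fraction(self.n_in_both),
        }


def overlap_venn(
    snps: Sequence[SnpRecord],
    tf_track: Sequence[GenomicInterval],
    mir_track: Sequence[GenomicInterval],
) -> OverlapSummary:
    in_tf = snps_in_track(snps, tf_track)
    in_mir = snps_in_track(snps, mir_track)
    return OverlapSummary(
        n_snps=len(snps),
        n_in_tf=sum(in_tf),
        n_in_mir=sum(in_mir),
        n_in_both=sum(a and b for a, b in zip(in_tf, in_mir)),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    n_regions: int
    n_hits: int
    background_fraction: float
    p_binomial: float


def binomial_enrichment(n_regions: int, n_hits: int, background_fraction: float) -> EnrichmentResult:
    """Upper-tail binomial test: P(X >= n_hits), X ~ Binom(n_regions, f).

    f is the fraction of the background genome covered by the annotation.
    p = 1 when n_hits = 0 by construction.
    """
    if not 0 <= n_hits <= n_regions:
        raise MirsnpError(f"n_hits {n_hits} outside [0, {n_regions}]")
    if not 0.0 <= background_fraction <= 1.0:
        raise MirsnpError(f"background fraction {background_fraction} outside [0, 1]")
    p = float(stats.binom.sf(n_hits - 1, n_regions, background_fraction))
    return EnrichmentResult(
        n_regions=n_regions,
        n_hits=n_hits,
        background_fraction=background_fraction,
        p_binomial=min(max(p, 0.0), 1.0),
    )


def track_overlap_fraction(
    query: Sequence[GenomicInterval], other: Sequence[GenomicInterval]
) -> float:
    """Fraction of query intervals overlapping the other track by >= 1 bp.

    Secondary statistic mirroring "fraction of miRNA sites inside TF regions".
    """
    if not query:
        return 0.0
    trees = _build_trees(other)
    hits = 0
    for iv in query:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            hits += 1
    return hits / len(query)
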