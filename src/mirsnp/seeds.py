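"""Canonical miRNA seed-site detection and allele-aware site classification.

Site taxonomy follows the canonical hierarchy: a perfect Watson-Crick match
of the target to guide nucleotides 2-8 with an A opposite guide nt 1 is an
8mer; without the A it is a 7mer-m8; a match to nt 2-7 plus the A is a
7mer-A1; a bare 2-7 match is a 6mer.  No G:U wobble is allowed in the seed,
so a C:G pair counts as a match and G:G as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import Mirna, Transcript, Variant, apply_allele, revcomp

__all__ = [
    "SiteType",
    "SeedSite",
    "AllelicSiteEffect",
    "Verdict",
    "find_seed_sites",
    "classify_site_type",
    "allelic_site_effect",
    "ALL_SITE_TYPES",
]


class SiteType(str, Enum):
    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"
    SIXMER = "6mer"


ALL_SITE_TYPES = frozenset(SiteType)


class Verdict(str, Enum):
    DISRUPTED_BY_ALT = "disrupted_by_alt"
    CREATED_BY_ALT = "created_by_alt"
    UNAFFECTED = "unaffected"
    ABSENT = "absent"


@dataclass(frozen=True)
class SeedSite:
    """A detected site; seed_interval is 1-based inclusive on the transcript.

    The interval covers the target bases pairing guide nt 2-8 (length 7 for
    8mer/7mer-m8) or nt 2-7 (length 6 for 7mer-A1/6mer).  ``t1_pos`` is the
    transcript position opposite guide nt 1, or None at the transcript 3' end.
    """

    mirna_id: str
    transcript_id: str
    site_type: SiteType
    seed_start: int
    seed_end: int
    t1_pos: Optional[int]

    @property
    def seed_interval(self) -> tuple[int, int]:
        return (self.seed_start, self.seed_end)

    def contains(self, pos: int) -> bool:
        return self.seed_start <= pos <= self.seed_end


def classify_site_type(
    match28: bool, match27: bool, a_at_t1: bool, match_m8: bool
) -> Optional[SiteType]:
    """Map the four canonical match flags onto a site type (or None).

    match28: target matches guide nt 2-8; match27: nt 2-7; a_at_t1: the
    transcript base opposite guide nt 1 is an A; match_m8: the single base
    opposite guide nt 8 matches.
    """
    if match28 and not match27:
        raise ValueError("inconsistent flags: match28 implies match27")
    if match28 and not match_m8:
        raise ValueError("inconsistent flags: match28 implies match_m8")
    if match28:
        return SiteType.EIGHTMER if a_at_t1 else SiteType.SEVENMER_M8
    if match27:
        if a_at_t1 and not match_m8:
            return SiteType.SEVENMER_A1
        if not a_at_t1:
            return SiteType.SIXMER
        # a_at_t1 and match_m8 but not match28 cannot happen
        raise ValueError("inconsistent flags: match27, a_at_t1 and match_m8 without match28")
    return None


def find_seed_sites(
    m: Mirna,
    t: Transcript,
    types: frozenset = ALL_SITE_TYPES,
) -> list[SeedSite]:
    """Scan a transcript for canonical seed sites of one miRNA.

    The target site is the exact reverse complement (Watson-Crick only) of
    the guide seed.  Each locus reports its single best type under the
    hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer; only types listed in
    ``types`` are reported.  Sites are sorted by seed start.
    """
    seq = t.seq
    n = len(seq)
    site27 = revcomp(m.guide[1:7])  # 6-nt match to guide nt 2-7
    m8_base = revcomp(m.guide[7])  # target base opposite guide nt 8
    out = []
    # s = 1-based start of the 6-nt core pairing guide nt 2-7
    for s in range(1, n - 6 + 2):
        if seq[s - 1 : s + 5] != site27:
            continue
        match_m8 = s >= 2 and seq[s - 2] == m8_base
        match28 = match_m8
        t1 = s + 6  # position opposite guide nt 1, just 3' of the core
        a_at_t1 = t1 <= n and seq[t1 - 1] == "A"
        stype = classify_site_type(match28, True, a_at_t1, match_m8)
        if stype is None or stype not in types:
            continue
        if stype in (SiteType.EIGHTMER, SiteType.SEVENMER_M8):
            start, end = s - 1, s + 5
        else:
            start, end = s, s + 5
        out.append(
            SeedSite(
                mirna_id=m.id,
                transcript_id=t.id,
                site_type=stype,
                seed_start=start,
                seed_end=end,
                t1_pos=t1 if t1 <= n else None,
            )
        )
    out.sort(key=lambda site: site.seed_start)
    return out


@dataclass(frozen=True)
class AllelicSiteEffect:
    """How a variant changes seed matching of one miRNA at its locus."""

    variant: Variant
    mirna_id: str
    ref_match: bool
    alt_match: bool
    verdict: Verdict
    ref_sites: tuple
    alt_sites: tuple


def _verdict(ref_match: bool, alt_match: bool, any_site: bool) -> Verdict:
    """Truth table over the variant-containing matches.

    When neither allele carries a site through the variant, the verdict is
    "unaffected" if the miRNA has sites elsewhere on the transcript and
    "absent" if it has none at all.
    """
    if ref_match and not alt_match:
        return Verdict.DISRUPTED_BY_ALT
    if alt_match and not ref_match:
        return Verdict.CREATED_BY_ALT
    if ref_match and alt_match:
        return Verdict.UNAFFECTED
    return Verdict.UNAFFECTED if any_site else Verdict.ABSENT


def allelic_site_effect(
    m: Mirna,
    t: Transcript,
    v: Variant,
    types: frozenset = ALL_SITE_TYPES,
) -> AllelicSiteEffect:
    """Scan both allele sequences and compare sites whose seed spans the variant."""
    ref_t = apply_allele(t, v, "ref")
    alt_t = apply_allele(t, v, "alt")
    ref_all = find_seed_sites(m, ref_t, types)
    alt_all = find_seed_sites(m, alt_t, types)
    ref_sites = tuple(s for s in ref_all if s.contains(v.pos))
    alt_sites = tuple(s for s in alt_all if s.contains(v.pos))
    ref_match = bool(ref_sites)
    alt_match = bool(alt_sites)
    return AllelicSiteEffect(
        variant=v,
        mirna_id=m.id,
        ref_match=ref_match,
        alt_match=alt_match,
        verdict=_verdict(ref_match, alt_match, bool(ref_all or alt_all)),
        ref_sites=ref_sites,
        alt_sites=alt_sites,
    )
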