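"""Core domain types: transcripts, variants, miRNAs and genomic intervals.

Coordinate conventions
----------------------
Transcript positions are 1-based inclusive, counted from the 5' end of the
transcript (the convention used when a variant is reported as sitting at,
say, "position 1058" of a 3'-UTR).  Genomic intervals follow the BED
convention: 0-based start, half-open end.  All sequences are stored as RNA
(alphabet ACGU, 5'->3'); DNA input is converted T->U on normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MirsnpError",
    "InvalidAlphabetError",
    "ReferenceMismatchError",
    "Transcript",
    "Variant",
    "Mirna",
    "GenomicInterval",
    "normalize_to_rna",
    "apply_allele",
    "revcomp",
    "RNA_COMPLEMENT",
]


class MirsnpError(ValueError):
    """Base class for all validation errors raised by this package."""


class InvalidAlphabetError(MirsnpError):
    """A sequence contains a character outside ACGTUacgtu/whitespace."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} "
            f"(allowed: ACGTU, case-insensitive, and whitespace)"
        )


class ReferenceMismatchError(MirsnpError):
    """A variant's stated reference base does not match the transcript."""


_ALLOWED = set("ACGTUacgtu")
_WS = set(" \t\r\n")

RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


def normalize_to_rna(raw: str) -> str:
    """Uppercase, strip whitespace and convert T->U.

    Positions in the error refer to the raw input, 1-based, so the offending
    character can be located in the file it came from.
    """
    out = []
    for i, ch in enumerate(raw, start=1):
        if ch in _WS:
            continue
        if ch not in _ALLOWED:
            raise InvalidAlphabetError(ch, i)
        out.append("U" if ch in "Tt" else ch.upper())
    return "".join(out)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (Watson-Crick, A<->U, C<->G)."""
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Transcript:
    """An RNA sequence with an identifier; positions are 1-based from 5'."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise MirsnpError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGU")
        if bad:
            raise MirsnpError(
                f"transcript {self.id!r}: non-RNA characters {sorted(bad)}; "
                "normalize with normalize_to_rna() first"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= pos <= len(self.seq):
            raise MirsnpError(
                f"position {pos} outside transcript {self.id!r} (length {len(self.seq)})"
            )
        return self.seq[pos - 1]


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution on a transcript (1-based position)."""

    transcript_id: str
    pos: int
    ref: str
    alt: str
    rsid: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise MirsnpError(f"variant {self.rsid or self.pos}: ref == alt ({self.ref})")
        for label, b in (("ref", self.ref), ("alt", self.alt)):
            if b not in "ACGU":
                raise MirsnpError(f"variant {self.rsid or self.pos}: {label} allele {b!r} not in ACGU")
        if self.pos < 1:
            raise MirsnpError(f"variant {self.rsid or self.pos}: position must be >= 1")

    def swapped(self) -> "Variant":
        """The same site with ref and alt exchanged."""
        return Variant(self.transcript_id, self.pos, self.alt, self.ref, self.rsid)


@dataclass(frozen=True)
class Mirna:
    """A miRNA guide strand (5'->3'); the seed is guide nt 2-8."""

    id: str
    guide: str
    passenger: Optional[str] = None

    def __post_init__(self):
        if len(self.guide) < 8:
            raise MirsnpError(
                f"miRNA {self.id!r}: guide length {len(self.guide)} < 8 "
                "(seed positions 2-8 must exist)"
            )
        bad = set(self.guide) - set("ACGU")
        if bad:
            raise MirsnpError(f"miRNA {self.id!r}: non-RNA characters {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Guide nucleotides 2-8 (the canonical seed heptamer)."""
        return self.guide[1:8]


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-style interval: 0-based start, half-open end."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise MirsnpError(
                f"interval {self.chrom}:{self.start}-{self.end}: requires 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def apply_allele(t: Transcript, v: Variant, which: str) -> Transcript:
    """Return the transcript carrying the requested allele of ``v``.

    ``which`` is "ref" or "alt".  The stated reference base must match the
    transcript at ``v.pos``; this check runs for both alleles so a mismatched
    variant record never silently produces a sequence.
    """
    if which not in ("ref", "alt"):
        raise MirsnpError(f"which must be 'ref' or 'alt', got {which!r}")
    actual = t.base(v.pos)
    if actual != v.ref:
        raise ReferenceMismatchError(
            f"variant {v.rsid or v.pos}: transcript {t.id!r} has {actual} at "
            f"position {v.pos}, expected ref {v.ref}"
        )
    if which == "ref":
        return t
    seq = t.seq[: v.pos - 1] + v.alt + t.seq[v.pos :]
    return Transcript(t.id, seq)
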