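"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Bio.SeqIO; BED and the TSV tables are simple enough that
they are parsed directly, with strict validation (malformed lines raise with
a line number rather than being coerced).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GenomicInterval,
    MirsnpError,
    Transcript,
    Variant,
    normalize_to_rna,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_table",
    "write_table",
    "read_variants",
    "read_timecourse_table",
]


def read_fasta(path) -> list[Transcript]:
    """Read a FASTA file into normalized transcripts (DNA auto-converted to RNA)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MirsnpError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise MirsnpError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(Transcript(rec.id, normalize_to_rna(str(rec.seq))))
    return out


def write_fasta(transcripts: Iterable[Transcript], path) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (chrom, start, end[, name[, score]]); empty file -> empty list."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MirsnpError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise MirsnpError(f"{path}:{lineno}: non-integer BED coordinates") from None
            name = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise MirsnpError(f"{path}:{lineno}: non-numeric BED score") from None
            try:
                out.append(GenomicInterval(chrom, start, end, name, score))
            except MirsnpError as e:
                raise MirsnpError(f"{path}:{lineno}: {e}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.score is not None:
                fields.append(iv.name or ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_table(path, required: Sequence[str]) -> list[dict]:
    """Read a header-bearing TSV, checking that the required columns exist."""
    path = Path(path)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise MirsnpError(f"{path}: empty table (no header)")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise MirsnpError(f"{path}: missing required columns {missing}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) in (None, "") for c in required):
                raise MirsnpError(f"{path}:{lineno}: missing value in required column")
            rows.append(dict(row))
    return rows


def write_table(rows: Iterable[dict], path, columns: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t", extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_variants(path) -> list[Variant]:
    """TSV with columns transcript_id, pos, ref, alt, rsid."""
    rows = read_table(path, ["transcript_id", "pos", "ref", "alt"])
    out = []
    for row in rows:
        try:
            pos = int(row["pos"])
        except ValueError:
            raise MirsnpError(f"{path}: non-integer variant position {row['pos']!r}") from None
        out.append(
            Variant(
                transcript_id=row["transcript_id"],
                pos=pos,
                ref=normalize_to_rna(row["ref"]),
                alt=normalize_to_rna(row["alt"]),
                rsid=row.get("rsid", "") or "",
            )
        )
    return out


def read_timecourse_table(path) -> tuple[list[float], list[float]]:
    """TSV with columns t_seconds, fraction -> (times, fractions)."""
    rows = read_table(path, ["t_seconds", "fraction"])
    try:
        times = [float(r["t_seconds"]) for r in rows]
        fracs = [float(r["fraction"]) for r in rows]
    except ValueError:
        raise MirsnpError(f"{path}: non-numeric time-course value") from None
    return times, fracs
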