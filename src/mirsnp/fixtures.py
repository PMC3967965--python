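"""Packaged study fixtures: miR-224 sequences, the Fig-5-style cleavage
table, and a synthetic TCF21-like toy transcript.

The toy transcript is SYNTHETIC: the real TCF21 3'-UTR sequence is not
bundled.  The toy reproduces the published coordinate geometry — the seed
heptamer GUGACUU at positions 1054-1060 so the C of the heptamer falls at
position 1058 (the rs12190287-like C>G site, pairing miRNA nt 4, inside a
miR-224 site ending at position 1061) — on a random background, with a G
forced at position 1070 so every RNase-T1 record in the cleavage table sits
on a G residue of the allele it probes.
"""

from __future__ import annotations

import csv
from importlib import resources

from .core import Mirna, Transcript, Variant
from .ensemble import CleavageRecord
from .simulate import synth_transcript_with_site

__all__ = [
    "MIR224",
    "MIR224_SNP",
    "SNP_POSITION",
    "SEED_SITE_START",
    "SEED_SITE_END",
    "SEED_HEPTAMER_C",
    "tcf21_toy",
    "fig5_cleavage_records",
]

#: Mature miR-224 guide and the seed-swapped control guide (G>C at nt 4),
#: plus the passenger strand, as used for annealing and reporter work.
MIR224 = Mirna(
    "miR-224",
    guide="CAAGUCACUAGUGGUUCCGUU",
    passenger="AAAAUGGUGCCCUAGUGACUACA",
)
MIR224_SNP = Mirna("miR-224_SNP", guide="CAACUCACUAGUGGUUCCGUU")

SEED_HEPTAMER_C = "GUGACUU"  # target match to miR-224 nt 2-8, C allele
SNP_POSITION = 1058
SEED_SITE_START = 1054
SEED_SITE_END = 1060


def tcf21_toy(seed: int = 12190287, utr_len: int = 2000) -> tuple[Transcript, Variant, Mirna]:
    """Synthetic TCF21-like transcript, its C>G variant at 1058, and miR-224.

    Deterministic for a fixed seed.  The returned miRNA is the real mature
    miR-224 guide, not the generator's synthetic guide.
    """
    t, v, _ = synth_transcript_with_site(
        utr_len=utr_len,
        seed_heptamer=SEED_HEPTAMER_C,
        site_start=SEED_SITE_START,
        snp_offset_in_site=SNP_POSITION - SEED_SITE_START + 1,
        alt_base="G",
        seed=seed,
        forced_bases={1070: "G"},
        transcript_id="TCF21-toy",
        rsid="rs12190287",
    )
    return t, v, MIR224


def fig5_cleavage_records() -> list[CleavageRecord]:
    """The packaged probing summary (per-allele Pb2+/RNase-T1 cleavages)."""
    text = resources.files("mirsnp.data").joinpath("tcf21_fig5_cleavage.tsv").read_text()
    out = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.append(
            CleavageRecord(
                position=int(row["position"]),
                reagent=row["reagent"],
                strength=row["strength"],
                allele=row["allele"],
            )
        )
    return out
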