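"""miRNA:target duplex energetics with a structure-accessibility penalty.

ddG for a site is defined as dG_duplex + dG_open: the nearest-neighbor
hybridization energy of the guide:site duplex plus the (non-negative) cost
of forcing the site single-stranded in the target's own MFE structure.  A
matched allele therefore scores more favorably (more negative) than an
allele carrying a seed mismatch, both through weaker pairing and, when the
mismatch reshapes local structure, through a larger opening cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import Mirna, MirsnpError
from .fold import EnergyModel, _PAIR_IDX, default_model, mfe_fold

__all__ = ["DuplexResult", "duplex_energy", "site_open_penalty", "site_ddG"]


@dataclass(frozen=True)
class DuplexResult:
    allele: str
    dG_duplex: float
    dG_open: float

    @property
    def ddG(self) -> float:
        return self.dG_duplex + self.dG_open

    def __post_init__(self):
        if self.dG_open < -1e-9:
            raise MirsnpError("dG_open must be non-negative")


def duplex_energy(m: Mirna, site_seq: str, model: Optional[EnergyModel] = None) -> float:
    """Nearest-neighbor energy (kcal/mol) of the antiparallel guide:site hybrid.

    Guide nucleotide 2 is aligned opposite the site 3' end (the geometry of
    a seed site, whose target interval pairs guide nt 2 onward; the base
    opposite guide nt 1 is not part of the site), ungapped and antiparallel.
    Paired positions (WC + G:U) contribute stack terms; a run of m
    mismatched positions flanked by pairs is scored as an interior loop of
    2m unpaired nucleotides (m on each strand); unpaired overhangs at either
    end are free.  The bimolecular initiation penalty applies once.  If no
    position can pair at all there is no duplex and the energy is 0.
    """
    model = model or default_model()
    if not site_seq:
        raise MirsnpError("empty site sequence")
    guide = m.guide
    n_site = len(site_seq)
    L = min(len(guide) - 1, n_site)
    # alignment: guide[k] (0-based, from nt 2) opposite site[n_site - k]
    paired = []
    for k in range(1, L + 1):
        g, s = guide[k], site_seq[n_site - k]
        paired.append(_PAIR_IDX.get(g + s))
    idx = [k for k, p in enumerate(paired) if p is not None]
    if not idx:
        return 0.0
    itab = model.interior(2 * L + 2)
    total = model.duplex_init
    for a, b in zip(idx, idx[1:]):
        if b == a + 1:
            total += int(model.stack[paired[a], paired[b]])
        else:
            total += int(itab[2 * (b - a - 1)])
    return total / 100.0


def site_open_penalty(
    window_seq: str,
    site_start: int,
    site_end: int,
    model: Optional[EnergyModel] = None,
) -> float:
    """Cost (>= 0) of freeing the site: constrained minus unconstrained MFE.

    ``site_start``/``site_end`` are 1-based inclusive within the window.
    """
    n = len(window_seq)
    if not (1 <= site_start <= site_end <= n):
        raise MirsnpError(f"site [{site_start},{site_end}] outside window of length {n}")
    model = model or default_model()
    free = mfe_fold(window_seq, model)
    constrained = mfe_fold(window_seq, model, constraints=range(site_start, site_end + 1))
    return round(constrained.energy - free.energy, 10)


def site_ddG(
    window_seq: str,
    m: Mirna,
    site_start: int,
    site_end: int,
    allele: str = "",
    model: Optional[EnergyModel] = None,
) -> DuplexResult:
    """ddG = duplex energy of the site sequence + opening penalty of the site."""
    model = model or default_model()
    site_seq = window_seq[site_start - 1 : site_end]
    return DuplexResult(
        allele=allele,
        dG_duplex=duplex_energy(m, site_seq, model),
        dG_open=site_open_penalty(window_seq, site_start, site_end, model),
    )
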