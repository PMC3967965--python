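"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over a compact nearest-neighbor model
(Watson-Crick + G:U stacks, tabulated hairpin/bulge/interior loop penalties
with logarithmic extrapolation, affine multiloops, no pseudoknots, no
dangling ends, lonely pairs allowed).  The same loop-decomposition scorer
(`energy_of_structure`) evaluates arbitrary structures, so the DP can be
checked against exhaustive enumeration on short sequences.

Energies are handled internally as integer centi-kcal/mol so that the DP,
the traceback and the scorer agree exactly, with no floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from numba import njit

from .core import MirsnpError

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "InvalidStructureError",
    "default_model",
    "energy_of_structure",
    "mfe_fold",
    "pair_context",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
]

INF = 1 << 28  # sentinel "impossible" energy in centi-kcal

_BASES = "ACGU"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_PAIR_ORDER = ["CG", "GC", "GU", "UG", "AU", "UA"]
_PAIR_IDX = {p: i for i, p in enumerate(_PAIR_ORDER)}


class InvalidStructureError(MirsnpError):
    """Pairs are crossing, clashing, non-canonical, or violate the hairpin minimum."""


def _ci(x: float) -> int:
    """kcal/mol -> integer centi-kcal."""
    return int(round(100.0 * x))


def _interp_table(tab: dict[int, float], lo: int) -> np.ndarray:
    """Expand a sparse {size: dG} table into a dense array, linear between anchors.

    Entries below ``lo`` are INF (loop size not allowed).
    """
    sizes = sorted(tab)
    if sizes[0] != lo:
        raise MirsnpError(f"loop table must start at size {lo}, starts at {sizes[0]}")
    hi = sizes[-1]
    arr = np.full(hi + 1, INF, dtype=np.int64)
    for a, b in zip(sizes, sizes[1:]):
        for n in range(a, b + 1):
            frac = (n - a) / (b - a) if b > a else 0.0
            arr[n] = _ci(tab[a] + frac * (tab[b] - tab[a]))
    arr[hi] = _ci(tab[hi])
    return arr


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set, integer centi-kcal/mol internally."""

    version: int
    stack: np.ndarray        # (6, 6) int64, indexed by _PAIR_ORDER
    hairpin_tab: np.ndarray  # dense through the last tabulated size
    bulge_tab: np.ndarray
    interior_tab: np.ndarray
    ml_a: int
    ml_b: int
    ml_c: int
    duplex_init: int
    min_hairpin: int
    max_interior: int
    rt_kcal: float
    lxc: float

    def _extend(self, tab: np.ndarray, upto: int) -> np.ndarray:
        """Log-extrapolate a loop table out to size ``upto``."""
        if upto < len(tab):
            return tab
        nmax = len(tab) - 1
        out = np.full(upto + 1, INF, dtype=np.int64)
        out[: nmax + 1] = tab
        ns = np.arange(nmax + 1, upto + 1)
        out[nmax + 1 :] = tab[nmax] + np.round(
            100.0 * self.lxc * self.rt_kcal * np.log(ns / nmax)
        ).astype(np.int64)
        return out

    def hairpin(self, upto: int) -> np.ndarray:
        return self._extend(self.hairpin_tab, upto)

    def bulge(self, upto: int) -> np.ndarray:
        return self._extend(self.bulge_tab, upto)

    def interior(self, upto: int) -> np.ndarray:
        return self._extend(self.interior_tab, upto)

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stack term in kcal/mol for outer/inner pairs given as e.g. "CG"."""
        return self.stack[_PAIR_IDX[outer], _PAIR_IDX[inner]] / 100.0


def _rev(p: str) -> str:
    return p[::-1]


@lru_cache(maxsize=4)
def default_model(name: str = "rna_params.yaml") -> EnergyModel:
    """Load the packaged parameter file."""
    text = resources.files("mirsnp.data").joinpath(name).read_text()
    raw = yaml.safe_load(text)

    stack = np.full((6, 6), INF, dtype=np.int64)
    for key, dg in raw["stacks"].items():
        p1, p2 = key.split(".")
        for a, b in ((p1, p2), (_rev(p2), _rev(p1))):
            i, j = _PAIR_IDX[a], _PAIR_IDX[b]
            val = _ci(dg)
            if stack[i, j] != INF and stack[i, j] != val:
                raise MirsnpError(f"stack table conflict at {a}.{b}")
            stack[i, j] = val
    if (stack == INF).any():
        raise MirsnpError("stack table incomplete after symmetry expansion")

    ml = raw["multiloop"]
    return EnergyModel(
        version=int(raw["version"]),
        stack=stack,
        hairpin_tab=_interp_table({int(k): float(v) for k, v in raw["hairpin"].items()}, 3),
        bulge_tab=_interp_table({int(k): float(v) for k, v in raw["bulge"].items()}, 1),
        interior_tab=_interp_table({int(k): float(v) for k, v in raw["interior"].items()}, 2),
        ml_a=_ci(ml["a"]),
        ml_b=_ci(ml["b"]),
        ml_c=_ci(ml["c"]),
        duplex_init=_ci(raw["duplex_init"]),
        min_hairpin=int(raw["min_hairpin"]),
        max_interior=int(raw["max_interior"]),
        rt_kcal=float(raw["rt_kcal"]),
        lxc=float(raw["lxc"]),
    )


def _pair_index_matrix() -> np.ndarray:
    m = np.full((4, 4), -1, dtype=np.int64)
    for p, idx in _PAIR_IDX.items():
        m[_BASE_CODE[p[0]], _BASE_CODE[p[1]]] = idx
    return m


_PIDX = _pair_index_matrix()


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int64)
    except KeyError as e:
        raise MirsnpError(f"non-RNA base {e.args[0]!r} in sequence") from None


# ---------------------------------------------------------------------------
# structure representation


def pairs_to_dotbracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise InvalidStructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise InvalidStructureError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise InvalidStructureError("unbalanced '(' in dot-bracket")
    return frozenset(pairs)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free structure with its free energy in kcal/mol."""

    seq: str
    pairs: frozenset  # of (i, j), 1-based, i < j
    energy: float

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(len(self.seq), self.pairs)

    def partner_table(self) -> list[int]:
        """0-based partner array, -1 for unpaired (index 0 .. n-1)."""
        ptab = [-1] * len(self.seq)
        for i, j in self.pairs:
            ptab[i - 1] = j - 1
            ptab[j - 1] = i - 1
        return ptab


def _validated_partner(seq: str, pairs: Iterable[tuple[int, int]], model: EnergyModel) -> list[int]:
    n = len(seq)
    ptab = [-1] * n
    plist = sorted(pairs)
    for i, j in plist:
        if not (1 <= i < j <= n):
            raise InvalidStructureError(f"pair ({i},{j}) out of range or unordered")
        if j - i < model.min_hairpin + 1:
            raise InvalidStructureError(
                f"pair ({i},{j}) closes a hairpin loop shorter than {model.min_hairpin} nt"
            )
        if _PIDX[_BASE_CODE[seq[i - 1]], _BASE_CODE[seq[j - 1]]] < 0:
            raise InvalidStructureError(
                f"non-canonical pair {seq[i - 1]}-{seq[j - 1]} at ({i},{j})"
            )
        if ptab[i - 1] != -1 or ptab[j - 1] != -1:
            raise InvalidStructureError(f"position in more than one pair near ({i},{j})")
        ptab[i - 1] = j - 1
        ptab[j - 1] = i - 1
    # crossing check on the sorted pair list
    open_stack: list[int] = []
    for i, j in plist:
        while open_stack and open_stack[-1] < i:
            open_stack.pop()
        if open_stack and j > open_stack[-1]:
            raise InvalidStructureError(f"crossing pairs (pseudoknot) at ({i},{j})")
        open_stack.append(j)
    return ptab


def _loop_children(ptab: Sequence[int], i: int, j: int) -> tuple[list[tuple[int, int]], int]:
    """Direct child helices and unpaired count inside the loop closed by (i,j), 0-based."""
    children = []
    unpaired = 0
    k = i + 1
    while k < j:
        if ptab[k] == -1:
            unpaired += 1
            k += 1
        else:
            children.append((k, ptab[k]))
            k = ptab[k] + 1
    return children, unpaired


def _pair_code(codes: np.ndarray, i: int, j: int) -> int:
    return int(_PIDX[codes[i], codes[j]])


def energy_of_structure(
    seq: str,
    pairs: Iterable[tuple[int, int]],
    model: Optional[EnergyModel] = None,
) -> float:
    """Score a structure by loop decomposition; kcal/mol.

    The empty structure scores 0 (the unfolded reference).  Raises
    InvalidStructureError for crossing pairs, clashes, non-canonical pairs,
    or hairpin loops shorter than the model minimum.
    """
    model = model or default_model()
    pairs = list(pairs)
    ptab = _validated_partner(seq, pairs, model)
    if not pairs:
        return 0.0
    codes = encode(seq)
    n = len(seq)
    hp = model.hairpin(n)
    bl = model.bulge(n)
    itab = model.interior(n)
    total = 0
    for i1, j1 in pairs:
        i, j = i1 - 1, j1 - 1
        children, unpaired = _loop_children(ptab, i, j)
        if not children:
            total += int(hp[unpaired])
        elif len(children) == 1:
            (ci, cj) = children[0]
            lu, ru = ci - i - 1, j - cj - 1
            if lu == 0 and ru == 0:
                total += int(model.stack[_pair_code(codes, i, j), _pair_code(codes, ci, cj)])
            elif lu == 0 or ru == 0:
                total += int(bl[lu + ru])
            else:
                total += int(itab[lu + ru])
        else:
            total += model.ml_a + model.ml_b * (1 + len(children)) + model.ml_c * unpaired
    return total / 100.0


# ---------------------------------------------------------------------------
# the dynamic program


@njit(cache=True)
def _fill(codes, blocked, pidx, stack, hp, bl, itab, ml_a, ml_b, ml_c, maxloop, minhp):
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    W = np.zeros((n + 1, n), dtype=np.int64)  # W[i, j]; W[j+1, j] == 0 row padding
    for l in range(1, n):
        for i in range(0, n - l):
            j = i + l
            # --- V: energy given (i, j) paired
            if (
                j - i > minhp
                and not blocked[i]
                and not blocked[j]
                and pidx[codes[i], codes[j]] >= 0
            ):
                pij = pidx[codes[i], codes[j]]
                best = hp[j - i - 1]
                # interior loops (stack when 0 unpaired), capped at maxloop unpaired
                ip_hi = min(i + maxloop + 1, j - minhp - 1)
                for ip in range(i + 1, ip_hi + 1):
                    lu = ip - i - 1
                    jp_lo = max(ip + minhp + 1, j - 1 - (maxloop - lu))
                    for jp in range(jp_lo, j):
                        v = V[ip, jp]
                        if v >= INF:
                            continue
                        ru = j - jp - 1
                        if lu == 0 and ru == 0:
                            e = stack[pij, pidx[codes[ip], codes[jp]]]
                        elif lu == 0 or ru == 0:
                            e = bl[lu + ru]
                        else:
                            e = itab[lu + ru]
                        cand = e + v
                        if cand < best:
                            best = cand
                # multiloop: closing pair + >= 2 branches inside
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # --- WM: multiloop component, >= 1 branch in [i, j]
            best = INF
            if WM[i + 1, j] < INF:
                best = WM[i + 1, j] + ml_c
            for k in range(i + minhp + 1, j + 1):
                v = V[i, k]
                if v >= INF:
                    continue
                if k == j:
                    rest = 0
                else:
                    rest = ml_c * (j - k)
                    if WM[k + 1, j] < rest:
                        rest = WM[k + 1, j]
                cand = v + ml_b + rest
                if cand < best:
                    best = cand
            WM[i, j] = best
            # --- W: exterior segment
            best = W[i + 1, j]
            for k in range(i + minhp + 1, j + 1):
                v = V[i, k]
                if v >= INF:
                    continue
                cand = v + W[k + 1, j] if k < j else v
                if cand < best:
                    best = cand
            W[i, j] = best
    return V, WM, W


def _traceback(codes, blocked, V, WM, W, model: EnergyModel, hp, bl, itab) -> set:
    """Recover one optimal structure deterministically.

    At every choice point, decompositions are tried in a fixed order that
    prefers pairing the leftmost position with the smallest possible partner,
    so equal-energy ties always resolve the same way.
    """
    n = codes.shape[0]
    minhp = model.min_hairpin
    maxloop = model.max_interior
    pairs: set[tuple[int, int]] = set()
    agenda: list[tuple[str, int, int]] = [("W", 0, n - 1)] if n else []
    while agenda:
        mode, i, j = agenda.pop()
        if i > j:
            continue
        if mode == "W":
            target = W[i, j]
            placed = False
            for k in range(i + minhp + 1, j + 1):
                v = V[i, k]
                if v >= INF:
                    continue
                rest = W[k + 1, j] if k < j else 0
                if v + rest == target:
                    agenda.append(("V", i, k))
                    if k < j:
                        agenda.append(("W", k + 1, j))
                    placed = True
                    break
            if not placed:
                assert target == W[i + 1, j], "traceback failure in W"
                agenda.append(("W", i + 1, j))
        elif mode == "V":
            pairs.add((i + 1, j + 1))
            target = V[i, j]
            pij = int(_PIDX[codes[i], codes[j]])
            found = False
            ip_hi = min(i + maxloop + 1, j - minhp - 1)
            for ip in range(i + 1, ip_hi + 1):
                lu = ip - i - 1
                jp_lo = max(ip + minhp + 1, j - 1 - (maxloop - lu))
                for jp in range(jp_lo, j):
                    v = V[ip, jp]
                    if v >= INF:
                        continue
                    ru = j - jp - 1
                    if lu == 0 and ru == 0:
                        e = int(model.stack[pij, int(_PIDX[codes[ip], codes[jp]])])
                    elif lu == 0 or ru == 0:
                        e = int(bl[lu + ru])
                    else:
                        e = int(itab[lu + ru])
                    if e + v == target:
                        agenda.append(("V", ip, jp))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                    if model.ml_a + model.ml_b + WM[i + 1, k] + WM[k + 1, j - 1] == target:
                        agenda.append(("M", i + 1, k))
                        agenda.append(("M", k + 1, j - 1))
                        found = True
                        break
            if not found:
                assert target == hp[j - i - 1], "traceback failure in V"
        else:  # mode == "M": multiloop component
            target = WM[i, j]
            placed = False
            for k in range(i + minhp + 1, j + 1):
                v = V[i, k]
                if v >= INF:
                    continue
                if k == j and v + model.ml_b == target:
                    agenda.append(("V", i, k))
                    placed = True
                    break
                if k < j:
                    if v + model.ml_b + model.ml_c * (j - k) == target:
                        agenda.append(("V", i, k))
                        placed = True
                        break
                    if WM[k + 1, j] < INF and v + model.ml_b + WM[k + 1, j] == target:
                        agenda.append(("V", i, k))
                        agenda.append(("M", k + 1, j))
                        placed = True
                        break
            if not placed:
                assert target == WM[i + 1, j] + model.ml_c, "traceback failure in WM"
                agenda.append(("M", i + 1, j))
    return pairs


def mfe_fold(
    seq: str,
    model: Optional[EnergyModel] = None,
    constraints: Optional[Iterable[int]] = None,
) -> SecondaryStructure:
    """Fold a sequence to its minimum-free-energy structure.

    ``constraints`` is an optional set of 1-based positions forced to stay
    unpaired.  Sequences too short to pair return the all-unpaired structure
    at 0 kcal/mol.  Among equal-energy optima the traceback is deterministic.
    """
    model = model or default_model()
    n = len(seq)
    codes = encode(seq)
    blocked = np.zeros(n, dtype=np.bool_)
    if constraints:
        for pos in constraints:
            if not 1 <= pos <= n:
                raise MirsnpError(f"constraint position {pos} outside sequence (length {n})")
            blocked[pos - 1] = True
    if n <= model.min_hairpin + 1:
        return SecondaryStructure(seq, frozenset(), 0.0)
    hp = model.hairpin(n)
    bl = model.bulge(n)
    itab = model.interior(n)
    V, WM, W = _fill(
        codes,
        blocked,
        _PIDX,
        model.stack,
        hp,
        bl,
        itab,
        model.ml_a,
        model.ml_b,
        model.ml_c,
        model.max_interior,
        model.min_hairpin,
    )
    energy_ci = int(W[0, n - 1])
    pairs = _traceback(codes, blocked, V, WM, W, model, hp, bl, itab)
    return SecondaryStructure(seq, frozenset(pairs), energy_ci / 100.0)


# ---------------------------------------------------------------------------
# structural context


def pair_context(s: SecondaryStructure, pos: int) -> str:
    """Classify a 1-based position: stem if paired, else by its enclosing loop.

    Returns one of "stem", "hairpin_loop", "internal_or_bulge", "multiloop",
    "exterior".
    """
    n = len(s.seq)
    if not 1 <= pos <= n:
        raise MirsnpError(f"position {pos} outside structure (length {n})")
    ptab = s.partner_table()
    p = pos - 1
    if ptab[p] != -1:
        return "stem"
    # innermost enclosing pair
    best = None
    for i1, j1 in s.pairs:
        if i1 < pos < j1 and (best is None or i1 > best[0]):
            best = (i1, j1)
    if best is None:
        return "exterior"
    children, _ = _loop_children(ptab, best[0] - 1, best[1] - 1)
    if not children:
        return "hairpin_loop"
    if len(children) == 1:
        return "internal_or_bulge"
    return "multiloop"
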