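"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: structure enumeration
is recursive substring decomposition, seed search is naive substring
scanning, interval overlap is all-pairs comparison, the kinetics reference
integrates the rate ODE numerically, and the binomial tail is exact
rational summation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All non-crossing canonical-pair structures (frozensets of 1-based pairs)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i + 1 <= 0:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if seq[i] + seq[k] in CANONICAL:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(frozenset({(i + 1, k + 1)}) | left | right)
        return tuple(out)

    return rec(0, n - 1)


def brute_min_energy(seq, scorer, constraints=frozenset()):
    """Minimum over all enumerated structures avoiding constrained positions."""
    best = math.inf
    best_pairs = frozenset()
    for pairs in enumerate_structures(seq):
        if any(i in constraints or j in constraints for i, j in pairs):
            continue
        e = scorer(seq, pairs)
        if e < best:
            best, best_pairs = e, pairs
    return best, best_pairs


def naive_seed_hits(guide: str, seq: str):
    """1-based start positions where the 6-nt reverse complement of guide
    nt 2-7 occurs, by checking every offset."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    core = "".join(comp[b] for b in reversed(guide[1:7]))
    return [s for s in range(1, len(seq) - 5 + 1) if seq[s - 1 : s + 5] == core]


def brute_overlap_flags(snp_positions, snp_chroms, intervals):
    """All-pairs point-in-interval membership (half-open)."""
    flags = []
    for pos, chrom in zip(snp_positions, snp_chroms):
        flags.append(
            any(c == chrom and s <= pos < e for c, s, e in intervals)
        )
    return flags


def ode_fraction(k, A0, B0, times):
    """Numerical integration of dx/dt = k (A0 - x)(B0 - x), x(0) = 0."""
    times = np.asarray(times, dtype=float)

    def rhs(_t, x):
        return [k * (A0 - x[0]) * (B0 - x[0])]

    sol = solve_ivp(
        rhs,
        (0.0, float(times.max())),
        [0.0],
        t_eval=times,
        rtol=1e-10,
        atol=1e-16 * A0,
        method="LSODA",
    )
    return sol.y[0] / A0


def exact_binom_upper_tail(n: int, k: int, f: float) -> float:
    """P(X >= k) by exact rational summation of the binomial mass."""
    ff = Fraction(f).limit_denominator(10**12)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * ff**i * (1 - ff) ** (n - i)
    return float(total)
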