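"""Allelic-expression-imbalance quantification and cohort statistics.

A heterozygous sample's cDNA allelic ratio is normalized by its own gDNA
allelic ratio (the gDNA of a heterozygote carries exactly one copy of each
allele, so its ratio calibrates the assay); the expected normalized ratio
under balanced expression is 1.0.  Cohort inference runs on log2 ratios:
ratios are multiplicative, and the paired design (cDNA vs gDNA within
sample) becomes a paired t-test on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MirsnpError

__all__ = [
    "AeiSample",
    "CohortResult",
    "StandardCurve",
    "normalized_allelic_ratio",
    "pyro_allelic_ratio",
    "aei_cohort_test",
    "fit_standard_curve",
    "quantify",
    "pearson_correlation",
]


@dataclass(frozen=True)
class AeiSample:
    """Allele signals (fluorescence, quantity or peak area) for one sample."""

    sample_id: str
    signal_a_cdna: float
    signal_b_cdna: float
    signal_a_gdna: float
    signal_b_gdna: float

    def __post_init__(self):
        for name in ("signal_a_cdna", "signal_b_cdna", "signal_a_gdna", "signal_b_gdna"):
            if getattr(self, name) <= 0:
                raise MirsnpError(
                    f"sample {self.sample_id!r}: {name} must be positive for a valid "
                    "heterozygous measurement"
                )

    @property
    def ratio_cdna(self) -> float:
        return self.signal_a_cdna / self.signal_b_cdna

    @property
    def ratio_gdna(self) -> float:
        return self.signal_a_gdna / self.signal_b_gdna

    def swapped(self) -> "AeiSample":
        """Allele labels exchanged; the normalized ratio inverts exactly."""
        return AeiSample(
            self.sample_id,
            self.signal_b_cdna,
            self.signal_a_cdna,
            self.signal_b_gdna,
            self.signal_a_gdna,
        )


def normalized_allelic_ratio(s: AeiSample) -> float:
    """(a_cdna / b_cdna) / (a_gdna / b_gdna); 1.0 means balanced expression."""
    return s.ratio_cdna / s.ratio_gdna


def pyro_allelic_ratio(peak_area_a: float, peak_area_b: float) -> dict:
    """Allelic ratio and percent-A from pyrosequencing peak areas.

    ``ratio`` is None (undefined) when the B-allele area is zero.
    """
    if peak_area_a < 0 or peak_area_b < 0:
        raise MirsnpError("peak areas must be non-negative")
    if peak_area_a == 0 and peak_area_b == 0:
        raise MirsnpError("both peak areas are zero")
    ratio = peak_area_a / peak_area_b if peak_area_b > 0 else None
    return {"ratio": ratio, "percent_a": 100.0 * peak_area_a / (peak_area_a + peak_area_b)}


@dataclass(frozen=True)
class CohortResult:
    n: int
    mean_log2_ratio: float
    ci_low: float
    ci_high: float
    p_paired: float
    p_vs_one: float

    @property
    def mean_ratio(self) -> float:
        """Geometric-mean normalized allelic ratio."""
        return 2.0 ** self.mean_log2_ratio


def aei_cohort_test(samples: list[AeiSample], ci: float = 0.95) -> CohortResult:
    """Cohort-level imbalance statistics on log2-normalized ratios.

    p_paired: paired t-test of log2 cDNA ratio vs log2 gDNA ratio across
    samples.  p_vs_one: one-sample t-test of log2 normalized ratio against 0
    (i.e. ratio 1.0).  Both two-sided.
    """
    if len(samples) < 3:
        raise MirsnpError(f"need >= 3 samples, got {len(samples)}")
    log_c = np.log2([s.ratio_cdna for s in samples])
    log_g = np.log2([s.ratio_gdna for s in samples])
    diffs = log_c - log_g
    n = len(diffs)
    mean = float(np.mean(diffs))
    if np.allclose(diffs, diffs[0]):
        # zero variance: degenerate t; p = 1 iff exactly no imbalance
        p_one = 1.0 if math.isclose(diffs[0], 0.0, abs_tol=1e-12) else 0.0
        p_paired = p_one
        half = 0.0
    else:
        t_paired = stats.ttest_rel(log_c, log_g)
        t_one = stats.ttest_1samp(diffs, 0.0)
        p_paired = float(t_paired.pvalue)
        p_one = float(t_one.pvalue)
        sem = stats.sem(diffs)
        half = float(sem * stats.t.ppf(0.5 + ci / 2.0, n - 1))
    return CohortResult(
        n=n,
        mean_log2_ratio=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        p_paired=p_paired,
        p_vs_one=p_one,
    )


@dataclass(frozen=True)
class StandardCurve:
    """Ct = slope * log10(quantity) + intercept; slope < 0 for a valid series."""

    slope: float
    intercept: float
    r2: float

    @property
    def degenerate(self) -> bool:
        return self.slope >= 0

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (2.0 for -1/log10(2))."""
        return 10.0 ** (-1.0 / self.slope) if self.slope < 0 else float("nan")


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """OLS of Ct on log10(quantity) over a dilution series (>= 3 points)."""
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cts, dtype=float)
    if len(q) != len(c) or len(q) < 3:
        raise MirsnpError("need >= 3 matched dilution points")
    if np.any(q <= 0):
        raise MirsnpError("quantities must be positive")
    if np.ptp(c) == 0:
        # flat Ct series: slope 0, degenerate
        return StandardCurve(slope=0.0, intercept=float(c[0]), r2=0.0)
    res = stats.linregress(np.log10(q), c)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2))


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity for an observed Ct."""
    if curve.degenerate:
        raise MirsnpError("cannot quantify from a degenerate (non-negative slope) curve")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def pearson_correlation(x, y) -> dict:
    """Pearson r with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MirsnpError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise MirsnpError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MirsnpError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}
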