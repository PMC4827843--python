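"""Statistical comparisons for derived gait and EMG metrics.

Paired two-tailed t-tests compare conditions on per-subject metrics;
Cohen's d grades effect size (0.2-0.5 small, 0.5-0.8 medium, >0.8
large); a one-way ANOVA compares the four reconstruction modes on VAF;
Bonferroni correction accounts for the 11-muscle multiplicity; and
Shapiro-Wilk screens normality (as a warning gate, not a test switch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst


@dataclass
class PairedComparison:
    t_statistic: float
    p_value: float
    cohens_d: float
    n: int


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedComparison:
    """Two-tailed paired t-test on a - b, df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return PairedComparison(0.0, 1.0, 0.0, len(a))
        raise ValueError("zero variance of nonzero differences; t undefined")
    t, p = sst.ttest_rel(a, b)
    return PairedComparison(
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=cohens_d(a, b),
        n=len(a),
    )


def cohens_d(a: np.ndarray, b: np.ndarray, mode: str = "pooled") -> float:
    """Cohen's d: pooled-SD standardized mean difference (default).

    ``mode='paired'`` standardizes the mean difference by the SD of the
    paired differences instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each sample")
    if mode == "pooled":
        na, nb = len(a), len(b)
        sp = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        if sp == 0:
            if np.isclose(a.mean(), b.mean()):
                return 0.0
            raise ValueError("zero pooled SD with unequal means")
        return float((a.mean() - b.mean()) / sp)
    if mode == "paired":
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            if np.isclose(d.mean(), 0):
                return 0.0
            raise ValueError("zero SD of nonzero differences")
        return float(d.mean() / sd)
    raise ValueError("mode must be 'pooled' or 'paired'")


def effect_size_label(d: float) -> str:
    """Conventional magnitude label for |d|."""
    m = abs(d)
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p over two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    f, p = sst.f_oneway(*groups)
    return float(f), float(p)


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return np.minimum(1.0, p * m)


def normality_check(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000.

    Used as a screening gate (warn on non-normality) rather than to
    switch tests.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.allclose(x, x[0]):
        raise ValueError("constant sample; normality test undefined")
    w, p = sst.shapiro(x)
    return float(w), float(p)
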