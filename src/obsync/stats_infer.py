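"""Inferential statistics the pipeline computes itself.

2x2 chi-squared prevalence comparisons (no continuity correction),
circular statistics (Rayleigh uniformity test, Watson-Williams two-sample
test of mean directions) and Benjamini-Hochberg false-discovery-rate
adjustment.  Standard group comparisons (rank-sum, KS, t-tests, ANOVA)
are delegated to scipy/statsmodels by callers and are not re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ContingencyTable2x2", "chi2_2x2", "rayleigh_test",
           "watson_williams_test", "bh_adjust"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d), e.g. (with ridge, without) x (TC, MC)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi2_2x2(table: ContingencyTable2x2) -> tuple:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    Returns ``(statistic, p)`` with p from the chi-squared(df=1) upper
    tail.  Raises on zero marginals (expected counts must be positive).
    """
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts must be positive")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def rayleigh_test(angles) -> dict:
    """Rayleigh test of circular uniformity.

    R is the mean resultant length, Z = n R^2, and p uses the standard
    small-sample-corrected approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n)).
    """
    a = np.asarray(getattr(angles, "angles", angles), dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    C, S = np.cos(a).sum(), np.sin(a).sum()
    Rn = np.hypot(C, S)
    R = Rn / n
    Z = n * R ** 2
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - Rn ** 2))
                     - (1.0 + 2.0 * n)))
    return {"R": float(R), "Z": float(Z), "p": min(p, 1.0), "n": n,
            "mean_angle": float(np.arctan2(S, C))}


def _resultant(a: np.ndarray) -> float:
    return float(np.hypot(np.cos(a).sum(), np.sin(a).sum()))


def watson_williams_test(angles_a, angles_b) -> dict:
    """Watson-Williams circular one-way test of equal mean directions.

    F = K * (N - 2) * (R1 + R2 - R) / (N - R1 - R2) with the standard
    concentration correction K = 1 + 3/(8 kappa_hat) (Berens/Zar), kappa
    estimated from the pooled mean resultant length; p from
    F(1, N - 2).  The test assumes adequately concentrated von Mises
    samples; the result is flagged (``"warning"``) when the pooled mean
    resultant length is < 0.45.
    """
    a = np.asarray(getattr(angles_a, "angles", angles_a), dtype=float)
    b = np.asarray(getattr(angles_b, "angles", angles_b), dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("Watson-Williams requires n >= 5 per sample")
    n1, n2 = a.size, b.size
    N = n1 + n2
    R1, R2 = _resultant(a), _resultant(b)
    R = _resultant(np.concatenate([a, b]))
    rbar = (R1 + R2) / N
    warning = None
    if rbar < 0.45:
        warning = "concentration inadequate (pooled mean resultant < 0.45)"
    kappa = _kappa_mle(rbar)
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - R1 - R2
    if denom <= 0:
        return {"F": float("inf"), "p": 0.0, "warning": "degenerate concentration"}
    F = K * (N - 2) * (R1 + R2 - R) / denom
    F = max(F, 0.0)
    p = float(sps.f.sf(F, 1, N - 2))
    return {"F": float(F), "p": p, "n": (n1, n2), "warning": warning}


def _kappa_mle(rbar: float) -> float:
    """Approximate von Mises concentration from mean resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (p_BH), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
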