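"""Paired agreement statistics.

Wilcoxon signed-rank testing (exact for small n, normal approximation with
continuity correction otherwise), Pearson correlation, and Bland-Altman
limits of agreement with a nonparametric spread (median +/- k * IQR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from cpcmra.errors import ValidationError

EXACT_N_MAX = 25


@dataclass
class PairedSeries:
    """Two same-length measurement series of the same quantity."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValidationError("paired series must be equal-length 1D arrays")
        if len(self.values_a) < 1:
            raise ValidationError("paired series must be non-empty")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValidationError("paired series must be finite")

    @property
    def n(self) -> int:
        return len(self.values_a)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class BlandAltmanResult:
    means: np.ndarray
    differences: np.ndarray
    center: float
    limit_low: float
    limit_high: float
    k: float


def _exact_signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` are the midranks doubled to integers; returns counts indexed
    by the doubled statistic value.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(pairs: PairedSeries, zero_policy: str = "drop") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties get midranks.  Returns
    ``(W, p)`` with ``W = min(W+, W-)``.  For n <= 25 the p-value is exact
    (full sign-assignment distribution); beyond that a normal
    approximation with continuity and tie correction is used.
    """
    if zero_policy != "drop":
        raise ValidationError("only the 'drop' zero policy is implemented")
    d = pairs.differences
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("degenerate: no nonzero pairs")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = w_plus + w_minus
    w = min(w_plus, w_minus)

    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        dist = _exact_signed_rank_distribution(ranks2)
        n_assign = dist.sum()
        w2 = int(round(2 * w))
        total2 = int(round(2 * total))
        p = (dist[: w2 + 1].sum() + dist[total2 - w2 :].sum()) / n_assign
        p = min(float(p), 1.0)
    else:
        mean = total / 2.0
        # variance with tie correction on midranks
        var = float(np.sum(ranks**2)) / 4.0
        z = (w - mean + 0.5) / np.sqrt(var)
        p = min(2.0 * norm.cdf(z), 1.0)
    return w, p


def pearson_r(pairs: PairedSeries) -> float:
    """Product-moment correlation coefficient."""
    if pairs.n < 2:
        raise ValidationError("pearson_r needs at least 2 pairs")
    a = pairs.values_a
    b = pairs.values_b
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("pearson_r undefined for zero-variance series")
    a = a - a.mean()
    b = b - b.mean()
    r = float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
    return float(np.clip(r, -1.0, 1.0))


def bland_altman(
    pairs: PairedSeries, k: float = 1.45, center: str = "median"
) -> BlandAltmanResult:
    """Agreement limits ``center +/- k * IQR`` of the paired differences.

    The nonparametric default (median centre, IQR spread) suits skewed
    data; ``center='mean'`` gives the classical mean-centred variant (the
    spread term stays IQR-based).
    """
    if pairs.n < 2:
        raise ValidationError("bland_altman needs at least 2 pairs")
    d = pairs.differences
    m = (pairs.values_a + pairs.values_b) / 2.0
    if center == "median":
        c = float(np.median(d))
    elif center == "mean":
        c = float(np.mean(d))
    else:
        raise ValidationError("center must be 'median' or 'mean'")
    q1, q3 = np.quantile(d, [0.25, 0.75])  # linear interpolation
    iqr = float(q3 - q1)
    return BlandAltmanResult(
        means=m,
        differences=d,
        center=c,
        limit_low=c - k * iqr,
        limit_high=c + k * iqr,
        k=k,
    )
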