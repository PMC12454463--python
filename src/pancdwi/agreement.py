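"""Test-retest repeatability and inter-reader agreement statistics.

Repeatability of paired acquisitions is summarised two ways:

* the coefficient of repeatability r = 1.96 * sqrt(sum(d^2)/n) over the
  per-subject differences d (RMS form, no mean-centering) — the headline
  coefficient;
* Bland-Altman mean difference and limits of agreement
  mean(d) +/- 1.96 * SD(d) with the sample SD (n-1 denominator), plus a
  proportional-bias slope of d against the pair mean.

Both are reported so the difference between the RMS and mean-centred
conventions stays visible.

Inter-reader agreement of continuous ROI measurements uses the two-way
random-effects, absolute-agreement, single-measurement intraclass
correlation ICC(2,1), banded poor/moderate/good/excellent at
0.5/0.75/0.9. Ordinal (Likert) ratings use quadratically weighted kappa
with Landis-Koch bands. Kappa requires integer categories: averaged
half-step scores are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ValidationError


@dataclass
class RepeatabilityResult:
    """Paired-difference statistics for one metric."""

    d: np.ndarray
    n: int
    mean_diff: float
    loa_low: float
    loa_high: float
    r: float
    bias_slope: float | None = None


@dataclass
class AgreementResult:
    icc: float | None = None
    icc_band: str | None = None
    kappa_w: float | None = None
    kappa_band: str | None = None


def icc_band(icc: float) -> str:
    """Koo-Li interpretation bands (exactly 0.5 is moderate, 0.75 and 0.9
    are good, above 0.9 excellent)."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def kappa_band(kappa: float) -> str:
    """Landis-Koch interpretation bands."""
    if kappa <= 0.0:
        return "less than chance"
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost perfect"


def repeatability_coefficient(d: Sequence[float], n: int | None = None) -> float:
    """r = 1.96 * sqrt(sum(d_i^2) / n) over test-retest differences."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValidationError("need at least one difference")
    if n is None:
        n = d.size
    return float(1.96 * np.sqrt(np.sum(d**2) / n))


def bland_altman(pairs: np.ndarray) -> RepeatabilityResult:
    """Bland-Altman analysis of (first, second) measurement pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValidationError("need >= 2 (first, second) pairs")
    d = pairs[:, 0] - pairs[:, 1]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    means = pairs.mean(axis=1)
    # proportional-bias slope of d against the pair mean
    if np.ptp(means) > 0:
        slope = float(np.polyfit(means, d, 1)[0])
    else:
        slope = 0.0
    return RepeatabilityResult(
        d=d,
        n=len(d),
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        r=repeatability_coefficient(d),
        bias_slope=slope,
    )


def _icc_mean_squares(ratings: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_absolute_agreement(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random, absolute agreement, single measurement.

    ``ratings``: complete (subjects x raters) table, >= 3 subjects and
    >= 2 raters.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 3 or ratings.shape[1] < 2:
        raise ValidationError("need a complete table of >= 3 subjects x >= 2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValidationError("ratings table is incomplete (non-finite entries)")
    msr, msc, mse, n, k = _icc_mean_squares(ratings)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return AgreementResult(icc=icc, icc_band=icc_band(icc))


def icc_consistency(ratings: np.ndarray) -> float:
    """ICC(3,1) consistency form (rater bias ignored); for comparison only."""
    ratings = np.asarray(ratings, dtype=float)
    msr, _, mse, n, k = _icc_mean_squares(ratings)
    return float((msr - mse) / (msr + (k - 1) * mse))


def weighted_kappa(
    rater_a: Sequence,
    rater_b: Sequence,
    categories: Sequence | None = None,
) -> AgreementResult:
    """Quadratically weighted Cohen's kappa on ordinal ratings.

    Disagreement weights w_ij = (i - j)^2 / (k - 1)^2 on the declared
    ordered category set (defaults to the union of observed values), so
    categories one rater never used still shape the weights.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("raters must supply equal-length rating vectors")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = np.asarray(categories)
    k = len(categories)
    if k < 2:
        raise ValidationError("need >= 2 ordered categories")
    index = {c: i for i, c in enumerate(categories.tolist())}
    try:
        ia = np.array([index[v] for v in a.tolist()])
        ib = np.array([index[v] for v in b.tolist()])
    except KeyError as e:  # rating outside declared set
        raise ValidationError(f"rating {e} not in declared categories") from e

    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0)
    obs /= obs.sum()
    exp = obs.sum(axis=1)[:, None] * obs.sum(axis=0)[None, :]
    w = (np.arange(k)[:, None] - np.arange(k)[None, :]) ** 2 / (k - 1) ** 2
    denom = np.sum(w * exp)
    kap = 1.0 if denom == 0 else float(1.0 - np.sum(w * obs) / denom)
    return AgreementResult(kappa_w=kap, kappa_band=kappa_band(kap))
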