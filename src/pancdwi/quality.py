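"""Plausibility masking, excluded-voxel accounting and ROI statistics.

Diffusion and kurtosis estimates in magnitude MR data can be driven to
physically impossible values by noise, motion and ringing. Voxels are
excluded per map when they violate that map's plausibility rule:
negative diffusivity or kurtosis, MK above 2.5, FA outside [0, 1], or
diffusivity above a free-water ceiling. The default ceiling is
3.0e-3 mm^2/s (free water at body temperature); it is configurable
because published exclusion rules are often stated in reporting units of
x1e-3 mm^2/s without saying so.

ROI statistics (median, IQR, 10th/90th percentiles) use
linear-interpolation percentiles over the retained voxels only, and the
excluded fraction is reported as a percentage of ROI voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RoiLabelMap, ScalarMapSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlausibilityRules:
    """Per-map exclusion thresholds."""

    mk_max: float = 2.5
    mk_min: float = 0.0
    diffusivity_min: float = 0.0
    diffusivity_max: float = 3.0e-3  # mm^2/s, free-water ceiling
    fa_min: float = 0.0
    fa_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mk_max > self.mk_min):
            raise ValidationError("mk_max must exceed mk_min")
        if not (self.diffusivity_max > self.diffusivity_min):
            raise ValidationError("diffusivity_max must exceed diffusivity_min")


@dataclass
class RoiSummary:
    """Summary statistics of one map over one ROI label."""

    map_name: str
    roi_label: int
    median: float
    iqr: float
    p10: float
    p90: float
    excluded_fraction: float  # percent of ROI voxels failing plausibility
    n_voxels: int


def plausibility_mask(
    maps: ScalarMapSet, rules: PlausibilityRules = PlausibilityRules()
) -> dict[str, np.ndarray]:
    """Per-map boolean exclusion masks (True = excluded).

    NaN voxels count as excluded. Masks are independent per map: a voxel
    may be excluded in MK yet retained in MD.
    """
    masks: dict[str, np.ndarray] = {}
    for name, m in maps.items():
        nan = ~np.isfinite(m)
        with np.errstate(invalid="ignore"):
            if name in ScalarMapSet._DIFFUSIVITY:
                bad = (m < rules.diffusivity_min) | (m > rules.diffusivity_max)
            elif name == "fa":
                bad = (m < rules.fa_min) | (m > rules.fa_max)
            elif name == "mk":
                bad = (m < rules.mk_min) | (m > rules.mk_max)
            else:
                bad = np.zeros_like(m, dtype=bool)
        masks[name] = bad | nan
        logger.debug("map %s: %d voxels excluded", name, int(masks[name].sum()))
    return masks


def excluded_fraction(mask: np.ndarray, roi: RoiLabelMap, label: int = 1) -> float:
    """Percent of ROI voxels excluded by a plausibility mask."""
    sel = roi.mask(label)
    n = int(sel.sum())
    if n == 0:
        raise ValidationError(f"ROI label {label} is empty")
    return 100.0 * float(np.sum(mask & sel)) / n


def roi_statistics(
    map_data: np.ndarray,
    roi: RoiLabelMap,
    label: int = 1,
    mask: np.ndarray | None = None,
    map_name: str = "",
) -> RoiSummary:
    """Median/IQR/p10/p90 over retained ROI voxels.

    ``mask`` is the exclusion mask (True = drop). With zero retained
    voxels the statistics are NaN and excluded_fraction is 100.
    """
    sel = roi.mask(label)
    n_roi = int(sel.sum())
    if n_roi == 0:
        raise ValidationError(f"ROI label {label} is empty")
    excl = ~np.isfinite(map_data) if mask is None else (mask | ~np.isfinite(map_data))
    vals = map_data[sel & ~excl]
    frac = 100.0 * (n_roi - vals.size) / n_roi
    if vals.size == 0:
        return RoiSummary(map_name, label, np.nan, np.nan, np.nan, np.nan, 100.0, 0)
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    return RoiSummary(
        map_name=map_name,
        roi_label=label,
        median=float(p50),
        iqr=float(p75 - p25),
        p10=float(p10),
        p90=float(p90),
        excluded_fraction=float(frac),
        n_voxels=int(vals.size),
    )


def summaries_to_frame(summaries: list[RoiSummary], **extra) -> pd.DataFrame:
    """Long-format table of ROI summaries; ``extra`` adds constant columns
    (subject, repeat, protocol...). Diffusivity maps are additionally
    reported in x1e-3 mm^2/s in a ``units`` column convention."""
    rows = []
    for s in summaries:
        scale = 1e3 if s.map_name in ScalarMapSet._DIFFUSIVITY else 1.0
        unit = "x1e-3 mm^2/s" if scale == 1e3 else "dimensionless"
        rows.append(
            dict(
                map=s.map_name,
                roi_label=s.roi_label,
                median=s.median * scale,
                iqr=s.iqr * scale,
                p10=s.p10 * scale,
                p90=s.p90 * scale,
                excluded_fraction=s.excluded_fraction,
                n_voxels=s.n_voxels,
                units=unit,
                **extra,
            )
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    table: pd.DataFrame,
    value_col: str = "median",
    subject_col: str = "subject",
    repeat_col: str = "repeat",
) -> pd.DataFrame:
    """Cohort summary: average repeats within subject, then median/IQR/range.

    ``table`` is long-format with at least (map, subject, repeat, value)
    columns; grouping keys other than subject/repeat/value are preserved
    (e.g. protocol). Subjects missing a metric are dropped from that
    metric with a warning.
    """
    keys = list(dict.fromkeys(
        ["map"] + [c for c in ("protocol", "units") if c in table.columns]
    ))
    n_expected = table.groupby("map")[subject_col].nunique().max()
    per_subject = (
        table.dropna(subset=[value_col])
        .groupby(keys + [subject_col], as_index=False)[value_col]
        .mean()
    )
    out = []
    for key_vals, grp in per_subject.groupby(keys):
        if grp[subject_col].nunique() < (n_expected or 0):
            logger.warning("metric %s missing for some subjects", key_vals)
        v = grp[value_col].to_numpy()
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(
            cohort_median=float(q50),
            cohort_iqr=float(q75 - q25),
            cohort_min=float(v.min()),
            cohort_max=float(v.max()),
            n_subjects=int(grp[subject_col].nunique()),
        )
        out.append(rec)
    return pd.DataFrame(out)
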