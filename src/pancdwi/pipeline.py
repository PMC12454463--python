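"""End-to-end study workflow: simulate/load -> preprocess -> fit -> QC -> stats.

Per subject and repeat the stages are: MP-PCA denoising and Gibbs
unringing; weighted-least-squares DTI on b = 200/1000; three-shell
mean-signal DKI and two-point ADC; plausibility masking; whole-pancreas
ROI statistics. Across the cohort: per-subject repeat averaging, cohort
medians/IQRs, Bland-Altman and the coefficient of repeatability per
metric, and (when several reader ROI variants are supplied) ICC across
readers. Every stage is a pure function of (inputs, config, seed); a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement
from .core import DwiDataset, RoiLabelMap, ScalarMapSet, ValidationError, read_dwi, read_roi_labels
from .dti import DiffusionTensorModel
from .msdki import MeanSignalDKIModel
from .phantom import PANCREAS_LABEL, PhantomSpec, iter_study
from .preprocess import preprocess
from .quality import (
    PlausibilityRules,
    plausibility_mask,
    roi_statistics,
    summaries_to_frame,
    summarize_cohort,
)

logger = logging.getLogger(__name__)

MAP_NAMES = ("md", "ad", "rd", "fa", "mk", "adc")


@dataclass
class PipelineConfig:
    """Configuration for a full run; every default is written to the log."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    input_dir: str | None = None  # if set, read a simulated/real file tree
    dti_shells: tuple[float, float] = (200.0, 1000.0)
    msdki_shells: tuple[float, float, float] = (200.0, 1000.0, 1700.0)
    adc_direction_index: int = 0
    run_preprocess: bool = True
    mppca_window: tuple[int, int, int] = (5, 5, 3)
    gibbs_neighborhood: int = 3
    gibbs_n_shifts: int = 20
    rules: PlausibilityRules = field(default_factory=PlausibilityRules)
    roi_label: int = PANCREAS_LABEL

    def __post_init__(self) -> None:
        if len(self.msdki_shells) < 3:
            raise ValidationError("mean-signal kurtosis fitting needs 3 shells")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclass
class SubjectResult:
    subject: int
    repeat: int
    maps: ScalarMapSet
    masks: dict[str, np.ndarray]
    roi: RoiLabelMap
    summaries: pd.DataFrame


@dataclass
class PipelineResult:
    """Cohort outputs: per-acquisition maps and the statistics tables."""

    config: PipelineConfig
    per_acquisition: list[SubjectResult]
    roi_table: pd.DataFrame
    cohort_table: pd.DataFrame
    repeatability_table: pd.DataFrame

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.roi_table.to_csv(out / "roi_statistics.csv", index=False)
        self.cohort_table.to_csv(out / "cohort_summary.csv", index=False)
        self.repeatability_table.to_csv(out / "repeatability.csv", index=False)
        (out / "config.json").write_text(self.config.to_json())
        return out


def process_acquisition(
    dataset: DwiDataset, roi: RoiLabelMap, config: PipelineConfig
) -> SubjectResult:
    """Run preprocessing, both fits, QC and ROI statistics for one scan."""
    subject = int(dataset.meta.get("subject", 0))
    repeat = int(dataset.meta.get("repeat", 0))
    if config.run_preprocess:
        dataset, _ = preprocess(
            dataset,
            window=config.mppca_window,
            neighborhood=config.gibbs_neighborhood,
            n_shifts=config.gibbs_n_shifts,
        )
    dti_res = DiffusionTensorModel(dataset, shells=config.dti_shells).fit()
    dki_res = MeanSignalDKIModel(
        dataset,
        shells=config.msdki_shells,
        adc_direction_index=config.adc_direction_index,
    ).fit()
    maps = dti_res.maps.update(dki_res.maps)
    masks = plausibility_mask(maps, config.rules)
    summaries = []
    for name, m in maps.items():
        s = roi_statistics(m, roi, config.roi_label, masks[name], map_name=name)
        summaries.append(s)
    table = summaries_to_frame(
        summaries, subject=subject, repeat=repeat,
        protocol=dataset.meta.get("protocol", ""),
    )
    logger.info("subject %d repeat %d processed", subject, repeat)
    return SubjectResult(subject, repeat, maps, masks, roi, table)


def _repeatability_tables(roi_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (map_name,), grp in roi_table.groupby(["map"]):
        wide = grp.pivot_table(index="subject", columns="repeat", values="median")
        if wide.shape[1] < 2:
            continue
        pairs = wide.iloc[:, :2].dropna().to_numpy()
        if len(pairs) < 2:
            continue
        res = agreement.bland_altman(pairs)
        rows.append(
            dict(
                map=map_name,
                n=res.n,
                mean_diff=res.mean_diff,
                loa_low=res.loa_low,
                loa_high=res.loa_high,
                r=res.r,
                bias_slope=res.bias_slope,
                r_relative_to_median_pct=100.0 * res.r
                / abs(np.median(pairs.mean(axis=1))),
            )
        )
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole study workflow on a phantom cohort or a file tree."""
    logger.info("pipeline config:\n%s", config.to_json())
    results: list[SubjectResult] = []
    if config.input_dir is not None:
        results.extend(_run_from_tree(config))
    else:
        for subject, repeat, ds, roi, _ in iter_study(config.phantom):
            results.append(process_acquisition(ds, roi, config))
    if not results:
        raise ValidationError("no acquisitions found to process")
    roi_table = pd.concat([r.summaries for r in results], ignore_index=True)
    cohort = summarize_cohort(roi_table)
    repeatability = _repeatability_tables(roi_table)
    return PipelineResult(config, results, roi_table, cohort, repeatability)


def _run_from_tree(config: PipelineConfig) -> list[SubjectResult]:
    root = Path(config.input_dir)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise ValidationError(f"missing manifest.csv under {root}")
    rows = pd.read_csv(manifest)
    out = []
    for _, row in rows.iterrows():
        d = root / row["path"]
        for f in ("dwi.nii.gz", "dwi.bval", "dwi.bvec", "roi.nii.gz"):
            if not (d / f).exists():
                raise ValidationError(f"stage input missing: {d / f}")
        ds = read_dwi(d / "dwi.nii.gz", d / "dwi.bval", d / "dwi.bvec",
                      meta=dict(subject=int(row["subject"]),
                                repeat=int(row["repeat"]),
                                protocol=str(row.get("protocol", ""))))
        roi = read_roi_labels(d / "roi.nii.gz")
        out.append(process_acquisition(ds, roi, config))
    return out


def reader_agreement(
    roi_tables: dict[str, pd.DataFrame], value_col: str = "median"
) -> pd.DataFrame:
    """ICC(2,1) across reader ROI variants, per map.

    ``roi_tables`` maps reader name -> long-format ROI table (as produced
    by the pipeline with that reader's segmentation).
    """
    readers = sorted(roi_tables)
    if len(readers) < 2:
        raise ValidationError("need >= 2 readers")
    rows = []
    maps = sorted(set.intersection(*[set(t["map"]) for t in roi_tables.values()]))
    for map_name in maps:
        cols = []
        for reader in readers:
            t = roi_tables[reader]
            sel = (
                t[t["map"] == map_name]
                .groupby("subject")[value_col]
                .mean()  # average repeats, as in the study
                .sort_index()
            )
            cols.append(sel)
        table = pd.concat(cols, axis=1).dropna().to_numpy()
        res = agreement.icc_absolute_agreement(table)
        rows.append(dict(map=map_name, icc=res.icc, band=res.icc_band,
                         n_subjects=table.shape[0], n_readers=len(readers)))
    return pd.DataFrame(rows)
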