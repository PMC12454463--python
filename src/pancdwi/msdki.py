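"""Mean-signal diffusion kurtosis fit and the two-point clinical ADC.

Mean-signal DKI avoids estimating the full kurtosis tensor: signals are
first averaged over all diffusion directions of each shell, and the
direction-averaged signal MS is fitted with

    MS(b) ~= S0 * exp(-b*MD + (1/6) * b^2 * MD^2 * MK)

over b = 200/1000/1700 s/mm^2 by weighted linear least squares on
ln MS with regressors [1, -b, b^2]; the quadratic coefficient maps to
MK = 6*theta2/MD^2. With exactly three shells the fit is the exact
interpolant regardless of weights; the weighting (direction count times
squared predicted signal, two passes) matters only for four or more
shells. Acquired b = 0 volumes are excluded, paralleling the DTI
perfusion-suppression choice; S0 is a free extrapolated baseline.

The clinical-style ADC uses a single diffusion direction and two shells:
ADC = ln(S(200)/S(1000)) / (1000 - 200).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import DwiDataset, ScalarMapSet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MSDKI_SHELLS = (200.0, 1000.0, 1700.0)
DEFAULT_ADC_SHELLS = (200.0, 1000.0)


def directional_average(dataset: DwiDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel mean signal per nonzero shell.

    Returns ``(bvals, ms, counts)`` where ``ms`` has shape
    (x, y, z, n_shells) and ``counts[k]`` is the number of contributing
    measurements of shell k (directions weighted by their scanner
    averages), used as fit weights.
    """
    shells = dataset.scheme.shells
    if not shells:
        raise ValidationError("dataset has no nonzero shells")
    ms = np.empty(dataset.spatial_shape + (len(shells),))
    counts = np.empty(len(shells))
    for k, b in enumerate(shells):
        idx = dataset.scheme.shell_indices(b)
        if idx.size == 0:
            raise ValidationError(f"empty shell b={b}")
        ms[..., k] = dataset.signal[..., idx].mean(axis=-1)
        counts[k] = dataset.scheme.averages[idx].sum()
    return np.asarray(shells), ms, counts


def fit_msdki_signals(
    bvals: np.ndarray,
    ms: np.ndarray,
    counts: np.ndarray | None = None,
    n_reweight: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the mean-signal kurtosis model to shell-averaged signals.

    ``ms``: (..., n_shells) positive mean signals. Returns ``(md, mk, s0)``
    with NaN at voxels where any shell signal is non-positive, and NaN MK
    where the fitted MD is non-positive (flagged for QC exclusion).
    """
    bvals = np.asarray(bvals, dtype=float)
    if len(bvals) < 3:
        raise ValidationError("mean-signal kurtosis fit needs >= 3 shells")
    ms = np.asarray(ms, dtype=float)
    lead = ms.shape[:-1]
    flat = ms.reshape(-1, len(bvals))
    X = np.column_stack([np.ones_like(bvals), -bvals, bvals**2])
    if counts is None:
        counts = np.ones_like(bvals)

    md = np.full(flat.shape[0], np.nan)
    mk = np.full(flat.shape[0], np.nan)
    s0 = np.full(flat.shape[0], np.nan)
    valid = np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)
    if valid.any():
        y = np.log(flat[valid])
        w = np.broadcast_to(counts, y.shape).astype(float).copy()
        theta = _wls(X, y, w)
        for _ in range(n_reweight):
            w = counts[None, :] * np.exp(2.0 * (theta @ X.T))
            theta = _wls(X, y, w)
        md_v = theta[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            mk_v = 6.0 * theta[:, 2] / md_v**2
        n_bad = int(np.sum(md_v <= 0))
        if n_bad:
            logger.info("%d voxels with non-positive mean diffusivity; MK flagged NaN",
                        n_bad)
        mk_v[md_v <= 0] = np.nan
        md[valid] = md_v
        mk[valid] = mk_v
        s0[valid] = np.exp(theta[:, 0])
    return md.reshape(lead), mk.reshape(lead), s0.reshape(lead)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted LS solve: X (N,3), y/w (V,N) -> theta (V,3)."""
    XtW = X.T[None, :, :] * w[:, None, :]
    A = XtW @ X
    rhs = np.einsum("vpn,vn->vp", XtW, y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def compute_adc(
    dataset: DwiDataset,
    direction_index: int = 0,
    shells: tuple[float, float] = DEFAULT_ADC_SHELLS,
) -> np.ndarray:
    """Two-point monoexponential ADC on one diffusion direction.

    ``direction_index`` selects among the volumes of each shell in
    acquisition order (default: the first listed direction, the clinical
    convention this pipeline mirrors). Non-positive signals give NaN.
    """
    b_lo, b_hi = shells
    idx_lo = dataset.scheme.shell_indices(b_lo)
    idx_hi = dataset.scheme.shell_indices(b_hi)
    if direction_index >= len(idx_lo) or direction_index >= len(idx_hi):
        raise ValidationError(
            f"direction index {direction_index} missing on shells {shells}"
        )
    s_lo = dataset.signal[..., idx_lo[direction_index]]
    s_hi = dataset.signal[..., idx_hi[direction_index]]
    with np.errstate(invalid="ignore", divide="ignore"):
        adc = np.log(s_lo / s_hi) / (b_hi - b_lo)
    adc[(s_lo <= 0) | (s_hi <= 0)] = np.nan
    return adc


class MeanSignalDKIModel:
    """Mean-signal DKI over b = 200/1000/1700 plus the two-point ADC."""

    def __init__(
        self,
        dataset: DwiDataset,
        shells: tuple[float, ...] = DEFAULT_MSDKI_SHELLS,
        adc_direction_index: int = 0,
    ):
        from .core import select_shells

        missing = [
            b for b in shells if dataset.scheme.shell_indices(b).size == 0
        ]
        if missing or len(shells) < 3:
            raise ValidationError(
                f"mean-signal kurtosis fit needs shells {shells}; missing {missing}"
            )
        self.dataset = select_shells(dataset, shells)
        self.shells = shells
        self.adc_direction_index = adc_direction_index

    def fit(self, mask: np.ndarray | None = None) -> "MeanSignalDKIResults":
        bvals, ms, counts = directional_average(self.dataset)
        if mask is not None:
            ms = np.where(mask[..., None], ms, np.nan)
        md, mk, s0 = fit_msdki_signals(bvals, ms, counts)
        adc = compute_adc(self.dataset, self.adc_direction_index)
        if mask is not None:
            adc = np.where(mask, adc, np.nan)
        return MeanSignalDKIResults(self, md, mk, s0, adc)


class MeanSignalDKIResults:
    """Fitted MD/MK/S0 of the mean-signal model and the companion ADC map."""

    def __init__(self, model: MeanSignalDKIModel, md: np.ndarray, mk: np.ndarray,
                 s0: np.ndarray, adc: np.ndarray):
        self.model = model
        self.md = md
        self.mk = mk
        self.s0 = s0
        self.adc = adc

    @property
    def maps(self) -> ScalarMapSet:
        return ScalarMapSet(mk=self.mk, adc=self.adc, md_msdki=self.md,
                            s0_msdki=self.s0)

    def summary(self, roi_mask: np.ndarray | None = None) -> str:
        def med(m):
            v = m if roi_mask is None else m[roi_mask]
            v = v[np.isfinite(v)]
            return float(np.median(v)) if v.size else float("nan")

        return (
            "Mean-signal DKI fit (shells "
            f"{tuple(int(s) for s in self.model.shells)} s/mm^2)\n"
            f"  MD  median {med(self.md) * 1e3:.3f} x1e-3 mm^2/s\n"
            f"  MK  median {med(self.mk):.3f}\n"
            f"  ADC median {med(self.adc) * 1e3:.3f} x1e-3 mm^2/s"
        )
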