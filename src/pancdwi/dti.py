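"""Diffusion tensor estimation by iteratively re-weighted linear least squares.

The model for the perfusion-suppressed signal at b-value b along unit
direction g is

    S(b, g) = S0' * exp(-b * g^T D g)

fitted on the b = 200 and 1000 s/mm^2 shells only; acquired b = 0 volumes
are deliberately excluded so that IVIM-like perfusion does not bias the
tensor, and the intercept S0' is a perfusion-suppressed extrapolated
baseline. Taking logs gives a linear system with the 7-column design
matrix of :func:`build_design_matrix`. Ordinary least squares on the log
signal initialises the fit; subsequent passes re-weight each row by the
squared predicted signal (the optimal weights for log-transformed Rician
data at moderate SNR), which is the standard weighted-least-squares DTI
scheme.

From the eigen-decomposition (eigenvalues sorted descending,
lambda1 >= lambda2 >= lambda3) the scalar maps are

    MD = (l1 + l2 + l3)/3,  AD = l1,  RD = (l2 + l3)/2,
    FA = sqrt(3/2 * ((l1-MD)^2 + (l2-MD)^2 + (l3-MD)^2)
              / (l1^2 + l2^2 + l3^2)).

Negative eigenvalues are preserved (not clamped) so the plausibility mask
can detect and exclude them downstream.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    DwiDataset,
    GradientScheme,
    ScalarMapSet,
    TensorField,
    ValidationError,
    select_shells,
)

logger = logging.getLogger(__name__)

DEFAULT_DTI_SHELLS = (200.0, 1000.0)

#: floor applied before taking logs of the measured signal
_LOG_EPS = 1e-12


def build_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """N x 7 log-linear DTI design matrix.

    Row i = [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    mapping (log S0', Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to the log signal.
    """
    b = scheme.bvals
    g = scheme.bvecs
    if np.any(b <= 0):
        raise ValidationError("design matrix requires all volumes on nonzero shells")
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise ValidationError(
            "insufficient directions: design matrix rank "
            f"{np.linalg.matrix_rank(X)} < 7 from {X.shape[0]} volumes"
        )
    return X


def eigendecompose(field: TensorField) -> TensorField:
    """Populate eigvals (descending) / eigvecs of a tensor field in place.

    Non-finite tensors yield NaN eigen-systems. Negative eigenvalues are
    preserved for downstream QC.
    """
    M = field.as_matrices()
    flat = M.reshape(-1, 3, 3)
    finite = np.all(np.isfinite(flat), axis=(1, 2))
    vals = np.full((flat.shape[0], 3), np.nan)
    vecs = np.full((flat.shape[0], 3, 3), np.nan)
    if finite.any():
        w, v = np.linalg.eigh(flat[finite])  # ascending
        vals[finite] = w[:, ::-1]
        vecs[finite] = v[:, :, ::-1]
    field.eigvals = vals.reshape(M.shape[:-2] + (3,))
    field.eigvecs = vecs.reshape(M.shape[:-2] + (3, 3))
    return field


def compute_dti_maps(field: TensorField) -> ScalarMapSet:
    """MD/AD/RD/FA maps from a tensor field with populated eigenvalues."""
    if field.eigvals is None:
        raise ValidationError("eigendecompose the tensor field first")
    lam = field.eigvals
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    norm2 = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(
            1.5 * ((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
            / np.where(norm2 > 0, norm2, np.nan)
        )
    return ScalarMapSet(md=md, ad=ad, rd=rd, fa=fa)


def fractional_anisotropy(eigvals: np.ndarray) -> np.ndarray:
    """FA from (..., 3) eigenvalues (NaN where all eigenvalues are zero)."""
    field = TensorField(log_s0=np.zeros(eigvals.shape[:-1]),
                        D=np.zeros(eigvals.shape[:-1] + (6,)),
                        eigvals=np.asarray(eigvals, dtype=float))
    return compute_dti_maps(field).fa


class DiffusionTensorModel:
    """Weighted-least-squares DTI on a perfusion-suppressed b-range.

    Parameters
    ----------
    dataset:
        Any DWI dataset; volumes outside ``shells`` are dropped before the
        fit (default shells 200 and 1000 s/mm^2).
    shells:
        b-values used for the fit. Must give a full-rank design matrix.
    n_reweight:
        Number of re-weighted passes after the OLS initialisation.
    """

    def __init__(
        self,
        dataset: DwiDataset,
        shells: tuple[float, ...] = DEFAULT_DTI_SHELLS,
        n_reweight: int = 2,
    ):
        self.dataset = select_shells(dataset, shells)
        self.shells = shells
        self.n_reweight = int(n_reweight)
        self.design = build_design_matrix(self.dataset.scheme)

    def fit(self, mask: np.ndarray | None = None) -> "DiffusionTensorResults":
        ds = self.dataset
        shape = ds.spatial_shape
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        S = ds.signal[mask]  # (V, N)
        V, N = S.shape
        X = self.design

        valid = S.max(axis=1) > 0
        n_clipped = int(np.sum((S <= 0) & valid[:, None]))
        if n_clipped:
            logger.warning("clipped %d non-positive signals before log", n_clipped)
        y = np.log(np.clip(S, _LOG_EPS, None))

        beta = np.full((V, 7), np.nan)
        if valid.any():
            yv = y[valid]
            # OLS initialisation
            b = np.linalg.lstsq(X, yv.T, rcond=None)[0].T
            for _ in range(self.n_reweight):
                w = np.exp(2.0 * (b @ X.T))  # squared predicted signals
                XtW = X.T[None, :, :] * w[:, None, :]
                A = XtW @ X
                rhs = np.einsum("vpn,vn->vp", XtW, yv)
                b = np.linalg.solve(A, rhs[..., None])[..., 0]
            beta[valid] = b

        log_s0 = np.full(shape, np.nan)
        D = np.full(shape + (6,), np.nan)
        log_s0[mask] = beta[:, 0]
        D[mask] = beta[:, 1:]
        field = eigendecompose(TensorField(log_s0=log_s0, D=D))
        return DiffusionTensorResults(self, field, mask)


class DiffusionTensorResults:
    """Fitted tensor field plus derived scalar maps and diagnostics."""

    def __init__(self, model: DiffusionTensorModel, tensor_field: TensorField,
                 mask: np.ndarray):
        self.model = model
        self.tensor_field = tensor_field
        self.mask = mask
        self.maps = compute_dti_maps(tensor_field)

    @property
    def md(self) -> np.ndarray:
        return self.maps.md

    @property
    def ad(self) -> np.ndarray:
        return self.maps.ad

    @property
    def rd(self) -> np.ndarray:
        return self.maps.rd

    @property
    def fa(self) -> np.ndarray:
        return self.maps.fa

    def predict(self) -> np.ndarray:
        """Model-predicted signals on the fitted shells (NaN where unfit)."""
        X = self.model.design
        shape = self.model.dataset.spatial_shape
        beta = np.concatenate(
            [self.tensor_field.log_s0[..., None], self.tensor_field.D], axis=-1
        )
        return np.exp(beta.reshape(-1, 7) @ X.T).reshape(shape + (X.shape[0],))

    def summary(self, roi_mask: np.ndarray | None = None) -> str:
        """Human-readable median map values (x1e-3 mm^2/s for diffusivities)."""
        sel = roi_mask if roi_mask is not None else self.mask
        lines = ["Diffusion tensor fit (WLS, shells "
                 f"{tuple(int(s) for s in self.model.shells)} s/mm^2)"]
        for name, m in self.maps.items():
            vals = m[sel]
            vals = vals[np.isfinite(vals)]
            med = np.median(vals) if vals.size else np.nan
            if name in ScalarMapSet._DIFFUSIVITY:
                lines.append(f"  {name.upper():<3} median {med * 1e3:.3f} x1e-3 mm^2/s")
            else:
                lines.append(f"  {name.upper():<3} median {med:.3f}")
        return "\n".join(lines)
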