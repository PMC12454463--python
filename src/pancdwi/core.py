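"""Core domain types and I/O for diffusion-weighted MRI datasets.

Gradient tables use the FSL dialect (``.bval``/``.bvec``: whitespace
separated, bvec as 3 rows x N columns). Volumes and scalar maps are
NIfTI-1, read and written through nibabel. Voxel coordinates are 0-based
grid indices; the world affine is carried opaquely and never interpreted
beyond the voxel size. Excluded or invalid voxels are encoded as NaN in
all scalar maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: b-values within this distance (s/mm^2) belong to the same shell;
#: scanners jitter nominal b-values.
SHELL_TOLERANCE = 25.0


class ValidationError(ValueError):
    """Raised when a dataset or argument violates a documented contract."""


class FormatError(ValidationError):
    """Raised when on-disk files are structurally inconsistent."""


# ---------------------------------------------------------------------------
# Gradient scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """Diffusion weighting b (s/mm^2) and unit direction g per volume.

    ``averages`` records how many scanner signal averages each delivered
    volume represents (NEX/NSA); it weights shell means downstream.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    averages: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (len(bvals), 3):
            raise ValidationError(
                f"bvecs shape {bvecs.shape} does not match {len(bvals)} b-values"
            )
        averages = np.asarray(self.averages, dtype=int).ravel()
        if len(averages) != len(bvals):
            raise ValidationError("averages length does not match bvals")
        if np.any(bvals < 0):
            raise ValidationError("negative b-value in gradient scheme")
        if np.any(averages < 1):
            raise ValidationError("averages must be >= 1")

        bvecs = bvecs.copy()
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero_b = bvals > 0
        bad = nonzero_b & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad & (norms == 0)):
            raise ValidationError("zero direction vector on a nonzero shell")
        if np.any(bad):
            logger.warning(
                "normalizing %d direction vectors with non-unit norm", int(bad.sum())
            )
            bvecs[bad] /= norms[bad, None]
        bvecs[~nonzero_b] = 0.0

        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "averages", averages)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def shells(self) -> tuple[float, ...]:
        """Distinct nonzero shells (cluster centers, tolerance ±25 s/mm^2)."""
        centers: list[float] = []
        for b in sorted(self.bvals[self.bvals > 0]):
            if not centers or abs(b - centers[-1]) > SHELL_TOLERANCE:
                centers.append(float(b))
        return tuple(centers)

    def shell_indices(self, b: float, tol: float = SHELL_TOLERANCE) -> np.ndarray:
        """Volume indices whose b-value lies within ``tol`` of ``b``."""
        return np.flatnonzero(np.abs(self.bvals - b) <= tol)

    def subset(self, idx: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.bvals[idx], self.bvecs[idx], self.averages[idx])


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class DwiDataset:
    """4-D magnitude DWI grid (x, y, z, volume) with its gradient scheme."""

    signal: np.ndarray
    scheme: GradientScheme
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        if signal.ndim != 4:
            raise ValidationError(f"signal must be 4-D, got {signal.ndim}-D")
        if not np.all(np.isfinite(signal)):
            raise ValidationError("signal contains non-finite values")
        if np.any(signal < 0):
            raise ValidationError("magnitude signal must be >= 0")
        if signal.shape[3] != len(self.scheme):
            raise ValidationError(
                f"{signal.shape[3]} volumes but {len(self.scheme)} scheme entries"
            )
        self.signal = signal
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def slice_count(self) -> int:
        return self.signal.shape[2]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]


@dataclass
class RoiLabelMap:
    """Integer label grid aligned to a dataset (0 = background, 1 = pancreas)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError("labels must be a 3-D grid")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValidationError("labels must be integers")
            labels = np.round(labels).astype(np.int32)
        if np.any(labels < 0):
            raise ValidationError("labels must be non-negative")
        self.labels = labels

    def mask(self, label: int = 1) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# Fit products
# ---------------------------------------------------------------------------

@dataclass
class TensorField:
    """Per-voxel diffusion tensor with eigen-decomposition.

    ``D`` stores the six unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s; ``log_s0`` is the perfusion-suppressed log baseline
    (intercept of the b=200/1000 fit, not an acquired b=0). Eigenvalues are
    sorted descending; negative eigenvalues are preserved for QC.
    """

    log_s0: np.ndarray
    D: np.ndarray
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None

    def as_matrices(self) -> np.ndarray:
        """(..., 3, 3) symmetric matrices from the 6-component storage."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.D, -1, 0)
        M = np.empty(self.D.shape[:-1] + (3, 3), dtype=float)
        M[..., 0, 0] = dxx
        M[..., 1, 1] = dyy
        M[..., 2, 2] = dzz
        M[..., 0, 1] = M[..., 1, 0] = dxy
        M[..., 0, 2] = M[..., 2, 0] = dxz
        M[..., 1, 2] = M[..., 2, 1] = dyz
        return M


@dataclass
class ScalarMapSet:
    """Per-voxel scalar maps. Diffusivities in mm^2/s, FA/MK dimensionless.

    Reporting convention downstream is x10^-3 mm^2/s for diffusivities;
    the maps themselves stay in plain mm^2/s.
    """

    md: np.ndarray | None = None
    ad: np.ndarray | None = None
    rd: np.ndarray | None = None
    fa: np.ndarray | None = None
    mk: np.ndarray | None = None
    adc: np.ndarray | None = None
    md_msdki: np.ndarray | None = None  # kurtosis-corrected MD of the MS fit
    s0_msdki: np.ndarray | None = None
    units_note: str = "diffusivities reported as x1e-3 mm^2/s"

    _DIFFUSIVITY = ("md", "ad", "rd", "adc", "md_msdki")

    def items(self):
        for name in ("md", "ad", "rd", "fa", "mk", "adc", "md_msdki"):
            m = getattr(self, name)
            if m is not None:
                yield name, m

    def update(self, other: "ScalarMapSet") -> "ScalarMapSet":
        for name in ("md", "ad", "rd", "fa", "mk", "adc", "md_msdki", "s0_msdki"):
            m = getattr(other, name)
            if m is not None:
                setattr(self, name, m)
        return self


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dwi(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    averages: Sequence[int] | None = None,
    meta: Mapping | None = None,
) -> DwiDataset:
    """Read a 4-D NIfTI volume plus FSL ``.bval``/``.bvec`` files.

    Direction vectors are normalized (with a warning) if needed; shell
    structure is detected with the ±25 s/mm^2 tolerance.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # FSL convention: rows are components
        bvecs = bvecs.T
    n_vol = data.shape[3]
    if len(bvals) != n_vol or bvecs.shape[0] != n_vol:
        raise FormatError(
            f"volume count mismatch: NIfTI has {n_vol} volumes, "
            f"bval has {len(bvals)}, bvec has {bvecs.shape[0]}"
        )
    if averages is None:
        averages = np.ones(n_vol, dtype=int)
    zooms = img.header.get_zooms()[:3]
    scheme = GradientScheme(bvals, bvecs, averages)
    return DwiDataset(
        signal=np.clip(data, 0, None),
        scheme=scheme,
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
        meta=dict(meta or {}),
    )


def write_dwi(dataset: DwiDataset, nifti_path: str | Path,
              bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a dataset back to NIfTI + FSL gradient files (32-bit float)."""
    img = nib.Nifti1Image(dataset.signal.astype(np.float32), dataset.affine)
    img.header.set_zooms(tuple(dataset.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    np.savetxt(str(bval_path), dataset.scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), dataset.scheme.bvecs.T, fmt="%.8f")


def write_scalar_map(map_data: np.ndarray, voxel_size: Sequence[float],
                     out_path: str | Path,
                     affine: np.ndarray | None = None) -> None:
    """Write a scalar map as 32-bit float NIfTI-1; NaN marks excluded voxels."""
    map_data = np.asarray(map_data)
    if map_data.size == 0:
        raise ValidationError("cannot write an empty map")
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(map_data.astype(np.float32), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, str(out_path))


def read_scalar_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def write_roi_labels(roi: RoiLabelMap, voxel_size: Sequence[float],
                     out_path: str | Path,
                     affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(roi.labels.astype(np.int16), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, str(out_path))


def read_roi_labels(path: str | Path) -> RoiLabelMap:
    return RoiLabelMap(np.asarray(nib.load(str(path)).dataobj).astype(np.int32))


# ---------------------------------------------------------------------------
# Shell selection
# ---------------------------------------------------------------------------

def select_shells(dataset: DwiDataset, shells: Sequence[float],
                  tol: float = SHELL_TOLERANCE) -> DwiDataset:
    """Sub-dataset containing only volumes on the requested shells.

    b=0 counts as a shell and may be requested explicitly. Used to
    restrict the tensor fit to b=200/1000 (perfusion suppression).
    """
    available = (0.0,) + dataset.scheme.shells
    keep = np.zeros(dataset.n_volumes, dtype=bool)
    for b in shells:
        idx = dataset.scheme.shell_indices(b, tol)
        if idx.size == 0:
            raise ValidationError(
                f"shell b={b} not present; available shells: {available}"
            )
        keep[idx] = True
    idx = np.flatnonzero(keep)
    return DwiDataset(
        signal=dataset.signal[..., idx],
        scheme=dataset.scheme.subset(idx),
        voxel_size=dataset.voxel_size,
        affine=dataset.affine,
        meta=dict(dataset.meta),
    )
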