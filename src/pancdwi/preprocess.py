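"""Denoising and Gibbs-ringing removal applied before model fitting.

Two stages, applied in this order:

1. ``mppca_denoise`` — random-matrix (Marchenko–Pastur) principal component
   analysis denoising. For every voxel, the patch-by-volume signal matrix
   centred on it is eigen-decomposed; eigenvalues inside the
   Marchenko–Pastur noise bulk are suppressed and only the centre voxel's
   reconstructed series is kept. The bulk edge also yields a per-voxel
   noise-level estimate sigma.

2. ``gibbs_unring`` — sub-voxel shift ringing removal. Each axial slice is
   resampled at a set of sub-voxel shifts via Fourier interpolation; per
   voxel the shift minimising a local finite-difference oscillation
   measure is selected and the value is linearly interpolated back to the
   grid. The two in-plane axes are handled on complementary k-space
   weighted images and summed.

Motion/eddy-current and susceptibility correction are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DwiDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NoiseMap:
    """Per-voxel noise SD estimate and number of retained PCA components."""

    sigma: np.ndarray
    retained_components: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sigma[np.isfinite(self.sigma)] < 0):
            raise ValidationError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# MP-PCA
# ---------------------------------------------------------------------------

def _mp_classify_batch(vals_desc: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Split sample-covariance eigenvalues into signal and MP noise bulk.

    ``vals_desc``: (V, n) eigenvalues of (1/m) X^T X, descending, for V
    voxels. Returns (p, sigma^2) per voxel where p is the number of signal
    components: the smallest p for which the spread of the remaining
    eigenvalues fits inside the Marchenko-Pastur bulk width
    4*sigma^2*sqrt(gamma), gamma = (n-p)/m, with sigma^2 estimated as the
    mean of those same eigenvalues (the standard iterative criterion).
    """
    V, n = vals_desc.shape
    # tail means for every candidate p: mean of vals_desc[:, p:]
    rev_cumsum = np.cumsum(vals_desc[:, ::-1], axis=1)[:, ::-1]
    counts = n - np.arange(n)
    tail_mean = rev_cumsum / counts  # (V, n), column p -> sigma^2 candidate
    spread = vals_desc - vals_desc[:, -1][:, None]  # tail[0] - tail[-1]
    gamma = counts / m
    # the 1e-10*lambda_max slack classifies numerically-zero tails
    # (noiseless low-rank data) as noise instead of looping to p = n
    tol = 1e-10 * vals_desc[:, :1]
    ok = spread <= 4.0 * tail_mean * np.sqrt(gamma)[None, :] + tol
    p = np.argmax(ok, axis=1)
    # no p satisfies the test -> all components are signal
    p = np.where(ok.any(axis=1), p, n)
    inside = np.clip(p, 0, n - 1)
    sigma2 = np.where(p < n, tail_mean[np.arange(V), inside], 0.0)
    return p, sigma2


def mppca_denoise(
    dataset: DwiDataset,
    window: tuple[int, int, int] = (5, 5, 3),
    chunk_size: int = 4096,
) -> tuple[DwiDataset, NoiseMap]:
    """MP-PCA denoising with centre-voxel assignment.

    ``window`` is the local patch size (3 odd integers). Near the grid
    edges the window is shifted inward so it always fits; the output value
    is still assigned to the centre voxel only. Voxels are processed in
    chunks of ``chunk_size`` with batched eigendecompositions.
    """
    win = tuple(int(w) for w in window)
    if any(w < 1 or w % 2 == 0 for w in win):
        raise ValidationError("window must be 3 odd positive integers")
    shape = dataset.spatial_shape
    if any(w > s for w, s in zip(win, shape)):
        raise ValidationError(f"window {win} larger than grid {shape}")
    n_vol = dataset.n_volumes
    m = int(np.prod(win))
    if m < n_vol:
        logger.warning(
            "window has %d voxels < %d volumes; MP classification is weak", m, n_vol
        )
    if m < 2:
        # a single-voxel patch carries no spatial redundancy to separate
        # noise from signal: pass the data through unchanged
        shape = dataset.spatial_shape
        return dataset, NoiseMap(
            sigma=np.zeros(shape),
            retained_components=np.full(shape, n_vol, dtype=np.int32),
        )

    sig = dataset.signal

    # window start per coordinate, shifted inward at the edges
    starts = [
        np.clip(np.arange(s) - w // 2, 0, s - w) for s, w in zip(shape, win)
    ]
    offs = [np.arange(w) for w in win]

    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    coords = grid.reshape(-1, 3)  # voxel order = C order of the grid
    n_voxels = coords.shape[0]

    denoised_flat = np.empty((n_voxels, n_vol))
    sigma_flat = np.empty(n_voxels)
    ncomp_flat = np.empty(n_voxels, dtype=np.int32)

    for lo in range(0, n_voxels, chunk_size):
        c = coords[lo:lo + chunk_size]
        x0 = starts[0][c[:, 0]]
        y0 = starts[1][c[:, 1]]
        z0 = starts[2][c[:, 2]]
        # gather (V, wx, wy, wz, n_vol) patches then flatten the window
        X = sig[
            (x0[:, None, None, None] + offs[0][None, :, None, None]),
            (y0[:, None, None, None] + offs[1][None, None, :, None]),
            (z0[:, None, None, None] + offs[2][None, None, None, :]),
            :,
        ].reshape(len(c), m, n_vol)
        C = np.einsum("vmi,vmj->vij", X, X) / m
        vals, vecs = np.linalg.eigh(C)  # ascending eigenvalues
        p, sigma2 = _mp_classify_batch(vals[:, ::-1], m)
        # keep the top-p components (last p columns of ascending order)
        comp_rank = np.arange(n_vol - 1, -1, -1)[None, :]  # rank 0 = largest
        keep_mask = comp_rank < p[:, None]
        center_idx = np.ravel_multi_index(
            (c[:, 0] - x0, c[:, 1] - y0, c[:, 2] - z0), win
        )
        rows = X[np.arange(len(c)), center_idx, :]
        coeff = np.einsum("vi,vij->vj", rows, vecs) * keep_mask
        denoised_flat[lo:lo + len(c)] = np.einsum("vj,vij->vi", coeff, vecs)
        sigma_flat[lo:lo + len(c)] = np.sqrt(np.clip(sigma2, 0.0, None))
        ncomp_flat[lo:lo + len(c)] = p

    denoised = denoised_flat.reshape(shape + (n_vol,))
    sigma = sigma_flat.reshape(shape)
    ncomp = ncomp_flat.reshape(shape)

    out = DwiDataset(
        signal=np.clip(denoised, 0, None),
        scheme=dataset.scheme,
        voxel_size=dataset.voxel_size,
        affine=dataset.affine,
        meta={**dataset.meta, "denoised": "mppca"},
    )
    return out, NoiseMap(sigma=sigma, retained_components=ncomp)


# ---------------------------------------------------------------------------
# Gibbs unringing
# ---------------------------------------------------------------------------

def _shift_1d(spec: np.ndarray, freqs: np.ndarray, s: float) -> np.ndarray:
    """Sample f(x + s) from the FFT along the last axis (periodic sinc)."""
    return np.fft.ifft(spec * np.exp(2j * np.pi * freqs * s), axis=-1).real


def _oscillation(img: np.ndarray, neighborhood: int) -> np.ndarray:
    """Local oscillation measure along the last axis.

    Sum of absolute first differences over ``neighborhood`` points on the
    left and on the right of each voxel; the smaller side is used, so a
    single genuine edge does not masquerade as ringing.
    """
    d = np.abs(np.diff(img, axis=-1, append=img[..., -1:]))
    left = np.zeros_like(img)
    right = np.zeros_like(img)
    for j in range(1, neighborhood + 1):
        left += np.roll(d, j, axis=-1)
        right += np.roll(d, 1 - j, axis=-1)
    return np.minimum(left, right)


def _unring_1d(img: np.ndarray, neighborhood: int, n_shifts: int) -> np.ndarray:
    """Sub-voxel-shift unringing along the last axis of a 2-D slice."""
    n = img.shape[-1]
    spec = np.fft.fft(img, axis=-1)
    freqs = np.fft.fftfreq(n)
    shifts = np.array(
        [k / (2.0 * n_shifts) for k in range(-n_shifts, n_shifts + 1)]
    )
    best_osc = np.full(img.shape, np.inf)
    best_val = img.copy()
    for s in shifts:
        shifted = _shift_1d(spec, freqs, s)
        osc = _oscillation(shifted, neighborhood)
        better = osc < best_osc
        if s == 0.0:
            unshifted = shifted
        elif s > 0:
            # shifted[x] = f(x + s); interpolate back to x
            unshifted = (1 - s) * shifted + s * np.roll(shifted, 1, axis=-1)
        else:
            unshifted = (1 + s) * shifted - s * np.roll(shifted, -1, axis=-1)
        best_val = np.where(better, unshifted, best_val)
        best_osc = np.where(better, osc, best_osc)
    return best_val


def _axis_weights(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Complementary k-space weights for combining the two axis results.

    The image is split into a part dominated by variation along x (unrung
    along x) and one along y; weights follow the standard cosine form and
    sum to 1 everywhere.
    """
    nx, ny = shape
    kx = 2 * np.pi * np.fft.fftfreq(nx)[:, None]
    ky = 2 * np.pi * np.fft.fftfreq(ny)[None, :]
    cx = 1.0 + np.cos(kx)
    cy = 1.0 + np.cos(ky)
    denom = cx + cy
    with np.errstate(invalid="ignore", divide="ignore"):
        gx = np.where(denom > 1e-12, cy / denom, 0.5)  # smooth along y -> unring x
        gy = np.where(denom > 1e-12, cx / denom, 0.5)
    return gx, gy


def _unring_slice(sl: np.ndarray, neighborhood: int, n_shifts: int) -> np.ndarray:
    gx, gy = _axis_weights(sl.shape)
    spec = np.fft.fft2(sl)
    part_x = np.fft.ifft2(spec * gx).real
    part_y = np.fft.ifft2(spec * gy).real
    out_x = np.swapaxes(
        _unring_1d(np.swapaxes(part_x, 0, 1), neighborhood, n_shifts), 0, 1
    )
    out_y = _unring_1d(part_y, neighborhood, n_shifts)
    return out_x + out_y


def gibbs_unring(
    dataset: DwiDataset, neighborhood: int = 3, n_shifts: int = 20
) -> DwiDataset:
    """Remove Gibbs ringing slice-by-slice (axial) for every volume."""
    if neighborhood < 1 or n_shifts < 1:
        raise ValidationError("neighborhood and n_shifts must be positive")
    if dataset.signal.shape[0] < 2 or dataset.signal.shape[1] < 2:
        raise ValidationError("in-plane grid too small for 2-D unringing")
    out = np.empty_like(dataset.signal)
    for iz in range(dataset.slice_count):
        for iv in range(dataset.n_volumes):
            out[:, :, iz, iv] = _unring_slice(
                dataset.signal[:, :, iz, iv], neighborhood, n_shifts
            )
    return DwiDataset(
        signal=np.clip(out, 0, None),
        scheme=dataset.scheme,
        voxel_size=dataset.voxel_size,
        affine=dataset.affine,
        meta={**dataset.meta, "unrung": "subvoxel-shift"},
    )


def preprocess(
    dataset: DwiDataset,
    window: tuple[int, int, int] = (5, 5, 3),
    neighborhood: int = 3,
    n_shifts: int = 20,
) -> tuple[DwiDataset, NoiseMap]:
    """MP-PCA denoising followed by Gibbs unringing (study processing order)."""
    denoised, noise = mppca_denoise(dataset, window=window)
    unrung = gibbs_unring(denoised, neighborhood=neighborhood, n_shifts=n_shifts)
    return unrung, noise
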