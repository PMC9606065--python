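"""Body-masked image-quality metrics: MAE (SUV), PSNR, SSIM.

All metrics restrict the comparison to voxels inside a patient-specific
body mask, so scores reflect the body and not the empty space around it.
Volumes are zeroed outside the mask before any windowed computation.

PSNR uses a fixed data range of 50 SUV — the cohort-wide normalization
ceiling — rather than a per-image maximum, so scores are comparable across
patients. SSIM is computed in 3D over the volume with a uniform 7x7x7
window by default; a per-slice 2D mode is available for comparability with
slice-based evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import VolumeGrid

__all__ = [
    "BodyMask",
    "derive_body_mask",
    "masked_mae_suv",
    "masked_psnr",
    "masked_ssim",
]


@dataclass
class BodyMask:
    """Binary mask of the patient body, aligned to the PET grid."""

    mask: VolumeGrid
    provenance: str = "from-ct-threshold"  # or "from-phantom-truth"

    def __post_init__(self) -> None:
        if not np.any(self.mask.values):
            raise ValueError("body mask is empty")

    @property
    def values(self) -> np.ndarray:
        return self.mask.values.astype(bool)

    @classmethod
    def from_truth(cls, body_mask: VolumeGrid) -> "BodyMask":
        return cls(body_mask, provenance="from-phantom-truth")


def derive_body_mask(ct: VolumeGrid, hu_threshold: float = -500.0) -> BodyMask:
    """Body mask from a CT volume on the PET grid.

    Recipe: threshold HU above ``hu_threshold``, morphological closing with
    a 3-voxel-radius ball, keep the largest 3D connected component, and fill
    internal holes slice by slice (recovering air-like interior tissue such
    as lung). Raises on an empty result (e.g. an all-air volume).
    """
    raw = ct.values > hu_threshold
    if not raw.any():
        raise ValueError("body mask is empty: no voxels above the HU threshold")
    r = 3
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    ball = zz**2 + yy**2 + xx**2 <= r**2
    # edge-replicating pad: the body may span the full axial field of view,
    # and closing against a zero border would erode those end slices
    padded = np.pad(raw, r, mode="edge")
    closed = ndi.binary_erosion(ndi.binary_dilation(padded, structure=ball), structure=ball)
    closed = closed[r:-r, r:-r, r:-r]
    labels, n = ndi.label(closed)
    if n == 0:
        raise ValueError("body mask is empty after morphology")
    largest = np.argmax(ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))) + 1
    body = labels == largest
    filled = np.stack([ndi.binary_fill_holes(sl) for sl in body])
    return BodyMask(ct.with_values(filled.astype(np.int32), is_label=True))


def _check(pred: VolumeGrid, ref: VolumeGrid, mask: BodyMask) -> np.ndarray:
    pred.require_same_geometry(ref, "pred and ref")
    pred.require_same_geometry(mask.mask, "volumes and mask")
    m = mask.values
    if not m.any():
        raise ValueError("body mask is empty")
    return m


def masked_mae_suv(pred: VolumeGrid, ref: VolumeGrid, mask: BodyMask) -> float:
    """Mean absolute error in SUV over in-mask voxels."""
    m = _check(pred, ref, mask)
    return float(np.mean(np.abs(pred.values[m] - ref.values[m])))


def masked_psnr(
    pred: VolumeGrid, ref: VolumeGrid, mask: BodyMask, data_range: float = 50.0
) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(R^2 / MSE)`` over the mask.

    Identical volumes (zero MSE) return ``inf``.
    """
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    m = _check(pred, ref, mask)
    mse = float(np.mean((pred.values[m].astype(np.float64) - ref.values[m]) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def masked_ssim(
    pred: VolumeGrid,
    ref: VolumeGrid,
    mask: BodyMask,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 50.0,
    per_slice: bool = False,
) -> float:
    """Structural similarity averaged over window centers inside the mask.

    Volumes are zeroed outside the mask before windowing, and the SSIM map
    (uniform window, standard constants) is averaged only over voxels whose
    window center lies in the mask. ``per_slice=True`` computes 2D SSIM per
    axial slice and averages in-mask centers across slices instead.
    """
    m = _check(pred, ref, mask)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if per_slice:
        if window > min(pred.shape[1:]):
            raise ValueError("window larger than slice extent")
    elif window > min(pred.shape):
        raise ValueError("window larger than volume extent")
    x = np.where(m, pred.values, 0.0).astype(np.float64)
    y = np.where(m, ref.values, 0.0).astype(np.float64)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def ssim_map(a: np.ndarray, b: np.ndarray, size) -> np.ndarray:
        mu_a = ndi.uniform_filter(a, size=size)
        mu_b = ndi.uniform_filter(b, size=size)
        # sample (unbiased) moments, matching the reference implementation
        n_win = int(np.prod(size)) if np.iterable(size) else size ** a.ndim
        cov_norm = n_win / (n_win - 1)
        var_a = cov_norm * (ndi.uniform_filter(a * a, size=size) - mu_a**2)
        var_b = cov_norm * (ndi.uniform_filter(b * b, size=size) - mu_b**2)
        cov = cov_norm * (ndi.uniform_filter(a * b, size=size) - mu_a * mu_b)
        return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
        )

    if per_slice:
        smap = np.stack([ssim_map(x[i], y[i], window) for i in range(x.shape[0])])
    else:
        smap = ssim_map(x, y, window)
    return float(smap[m].mean())
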