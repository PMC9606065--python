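"""PET/CT preprocessing into normalized 2.5D network samples, and its inverse.

The network consumes 2D samples built from three consecutive axial slices
stacked on the channel axis (a "2.5D" representation): channels 0-2 are the
previous/center/next PET slices; when CT is used, channels 3-5 carry the
matching CT slices. Intensities are normalized to (0, 1) with fixed clinical
ceilings — SUV 50 for PET, (-1000, 3000) HU for CT — padded to the network
resolution, and rescaled to (-1, 1).

Every step of the chain has an exact inverse on its non-saturated range, so
network outputs can be mapped back to SUV volumes for quantitative
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .grid import VolumeGrid

__all__ = [
    "NormSpec",
    "Sample25D",
    "bq_to_suv",
    "normalize_suv",
    "denormalize_suv",
    "normalize_hu",
    "resample_ct_to_pet",
    "stack_25d",
    "fuse_channels",
    "split_channels",
    "pad_and_rescale",
    "unpad_and_unscale",
    "volume_to_samples",
    "postprocess_prediction",
]


@dataclass(frozen=True)
class NormSpec:
    """Fixed normalization ceilings shared by the whole cohort.

    A constant SUV ceiling (rather than a per-patient max) keeps intensities
    comparable across patients; uptake above the ceiling saturates, so
    information for lesions beyond SUV ``suv_max`` is lost by design.
    """

    suv_max: float = 50.0
    hu_min: float = -1000.0
    hu_max: float = 3000.0

    def __post_init__(self) -> None:
        if self.suv_max <= 0:
            raise ValueError("suv_max must be > 0")
        if self.hu_max <= self.hu_min:
            raise ValueError("hu_max must exceed hu_min")


@dataclass
class Sample25D:
    """One network sample: (C, H, W) image in [-1, 1], C in {3, 6}.

    Channels 0-2 are PET (previous, center, next axial slice); channels 3-5,
    when present, the matching CT slices. ``center_index`` is the axial slice
    this sample predicts.
    """

    image: np.ndarray
    center_index: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 3 or self.image.shape[0] not in (3, 6):
            raise ValueError(f"expected (C,H,W) with C in {{3,6}}, got {self.image.shape}")
        if self.image.shape[1] != self.image.shape[2]:
            raise ValueError("sample must be spatially square")
        lo, hi = float(self.image.min()), float(self.image.max())
        if lo < -1.0 - 1e-5 or hi > 1.0 + 1e-5:
            raise ValueError(f"sample values outside [-1, 1]: [{lo}, {hi}]")

    @property
    def n_channels(self) -> int:
        return self.image.shape[0]


def bq_to_suv(conc_bq_ml, weight_kg: float, injected_MBq: float):
    """Body-weight standardized uptake value from activity concentration.

    SUV = concentration [Bq/ml] x body weight [g] / injected activity [Bq];
    with ~1 g/ml tissue density this is dimensionless and equals 1 for a
    uniform whole-body distribution.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    if injected_MBq <= 0:
        raise ValueError("injected_MBq must be > 0")
    conc = np.asarray(conc_bq_ml, dtype=np.float64)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be >= 0")
    suv = conc * (weight_kg * 1000.0) / (injected_MBq * 1e6)
    return suv if suv.ndim else float(suv)


def normalize_suv(suv_volume: VolumeGrid, norm: NormSpec = NormSpec()) -> VolumeGrid:
    """Map SUV to (0, 1): ``clip(suv, 0, suv_max) / suv_max``."""
    v = np.asarray(suv_volume.values, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("SUV volume must be non-negative")
    return suv_volume.with_values(np.clip(v, 0.0, norm.suv_max) / norm.suv_max)


def denormalize_suv(volume: VolumeGrid, norm: NormSpec = NormSpec()) -> VolumeGrid:
    """Exact inverse of :func:`normalize_suv` on [0, suv_max]."""
    return volume.with_values(np.asarray(volume.values, dtype=np.float64) * norm.suv_max)


def normalize_hu(ct: VolumeGrid, norm: NormSpec = NormSpec()) -> VolumeGrid:
    """Map HU to (0, 1): ``clip((hu - hu_min) / (hu_max - hu_min), 0, 1)``."""
    v = np.asarray(ct.values, dtype=np.float64)
    out = np.clip((v - norm.hu_min) / (norm.hu_max - norm.hu_min), 0.0, 1.0)
    return ct.with_values(out)


def resample_ct_to_pet(ct: VolumeGrid, pet: VolumeGrid) -> VolumeGrid:
    """Resample CT onto the PET grid (trilinear, air fill -1000 HU)."""
    def to_sitk(g: VolumeGrid) -> sitk.Image:
        img = sitk.GetImageFromArray(np.asarray(g.values, dtype=np.float64))
        img.SetSpacing((g.spacing[2], g.spacing[1], g.spacing[0]))
        img.SetOrigin((g.origin[2], g.origin[1], g.origin[0]))
        return img

    out = sitk.Resample(
        to_sitk(ct),
        to_sitk(pet),
        sitk.Transform(),
        sitk.sitkLinear,
        -1000.0,
        sitk.sitkFloat64,
    )
    return VolumeGrid(sitk.GetArrayFromImage(out), spacing=pet.spacing, origin=pet.origin)


def stack_25d(volume: VolumeGrid, center_index: int) -> np.ndarray:
    """Three consecutive axial slices as a (3, H, W) channel stack.

    Valid centers are 1..N-2: the first and last slices of a volume are
    never predicted (in real acquisitions they are noise-dominated) and are
    used only to complete the neighbour channels of the second and
    penultimate slices. Each volume therefore yields exactly N-2 samples.
    """
    n = volume.n_slices
    if n < 3:
        raise ValueError(f"need at least 3 axial slices, got {n}")
    if not (1 <= center_index <= n - 2):
        raise ValueError(f"center_index must be in [1, {n - 2}], got {center_index}")
    v = volume.values
    return np.stack([v[center_index - 1], v[center_index], v[center_index + 1]], axis=0)


def fuse_channels(pet25d: np.ndarray, ct25d: np.ndarray | None = None) -> np.ndarray:
    """Concatenate PET (channels 0-2) and optional CT (channels 3-5)."""
    pet25d = np.asarray(pet25d)
    if pet25d.shape[0] != 3:
        raise ValueError(f"PET stack must have 3 channels, got {pet25d.shape[0]}")
    if ct25d is None:
        return pet25d
    ct25d = np.asarray(ct25d)
    if ct25d.shape != pet25d.shape:
        raise ValueError(f"shape mismatch: PET {pet25d.shape} vs CT {ct25d.shape}")
    return np.concatenate([pet25d, ct25d], axis=0)


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Inverse of :func:`fuse_channels`."""
    if image.shape[0] == 3:
        return image, None
    if image.shape[0] == 6:
        return image[:3], image[3:]
    raise ValueError(f"expected 3 or 6 channels, got {image.shape[0]}")


def pad_and_rescale(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Zero-pad a (0,1) channel stack to ``size`` and rescale to (-1, 1).

    Padding is symmetric with constant 0 in (0,1) space — the air/background
    value — which maps to -1 after ``x -> 2x - 1``. A 220-pixel slice gains a
    2-pixel border on each side.
    """
    image = np.asarray(image, dtype=np.float64)
    c, h, w = image.shape
    if h != w:
        raise ValueError("input must be square")
    if h > size:
        raise ValueError(f"input size {h} exceeds target {size}")
    lo = (size - h) // 2
    hi = size - h - lo
    padded = np.pad(image, ((0, 0), (lo, hi), (lo, hi)), constant_values=0.0)
    return 2.0 * padded - 1.0


def unpad_and_unscale(image: np.ndarray, original_size: int) -> np.ndarray:
    """Exact inverse of :func:`pad_and_rescale`: crop the center, map to (0,1)."""
    c, h, w = np.asarray(image).shape
    if original_size > h:
        raise ValueError("original size exceeds padded size")
    lo = (h - original_size) // 2
    cropped = np.asarray(image)[:, lo : lo + original_size, lo : lo + original_size]
    return (cropped + 1.0) / 2.0


def volume_to_samples(
    pet: VolumeGrid,
    ct: VolumeGrid | None = None,
    norm: NormSpec = NormSpec(),
    pad_to: int = 224,
    patient_id: str = "",
    target: VolumeGrid | None = None,
) -> list[Sample25D] | tuple[list[Sample25D], np.ndarray]:
    """Full preprocessing chain for one volume (pair).

    Normalizes PET (and CT, which must already be on the PET grid), stacks
    2.5D neighbours for every valid center slice, fuses modalities, pads and
    rescales to (-1, 1). When ``target`` (the reference PET) is given, also
    returns the matching (N-2, 1, pad_to, pad_to) target center slices.
    """
    pet_n = normalize_suv(pet, norm)
    ct_n = None
    if ct is not None:
        pet.require_same_geometry(ct, "PET and CT")
        ct_n = normalize_hu(ct, norm)
    samples = []
    targets = []
    if target is not None:
        pet.require_same_geometry(target, "input and target PET")
        tgt_n = normalize_suv(target, norm)
    for c in range(1, pet.n_slices - 1):
        stack = stack_25d(pet_n, c)
        if ct_n is not None:
            stack = fuse_channels(stack, stack_25d(ct_n, c))
        samples.append(Sample25D(pad_and_rescale(stack, pad_to), c, patient_id))
        if target is not None:
            t = tgt_n.values[c][None]
            targets.append(pad_and_rescale(t, pad_to))
    if target is not None:
        return samples, np.stack(targets).astype(np.float32)
    return samples


def postprocess_prediction(
    pred: np.ndarray, template: VolumeGrid, norm: NormSpec = NormSpec()
) -> VolumeGrid:
    """Map a stack of network outputs back to an SUV volume on ``template``.

    ``pred`` holds one (-1,1) output per valid center slice, i.e. N-2 slices
    for an N-slice template, each padded to the network resolution. The
    center crop is taken, intensities map back through (0,1) to SUV, and
    negatives are clamped to 0. The first and last axial slices, which have
    no prediction, are filled by replicating the nearest predicted slice.
    """
    pred = np.asarray(pred)
    if pred.ndim == 4:  # (N-2, 1, H, W)
        pred = pred[:, 0]
    n = template.n_slices
    if pred.shape[0] != n - 2:
        raise ValueError(f"expected {n - 2} predicted slices, got {pred.shape[0]}")
    size = template.shape[1]
    if template.shape[1] != template.shape[2]:
        raise ValueError("template must be square in-plane")
    out = np.empty(template.shape, dtype=np.float64)
    for i in range(pred.shape[0]):
        sl = unpad_and_unscale(pred[i][None], size)[0]
        out[i + 1] = np.clip(sl, 0.0, 1.0) * norm.suv_max
    out[0] = out[1]
    out[-1] = out[-2]
    return template.with_values(out, is_label=False)
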