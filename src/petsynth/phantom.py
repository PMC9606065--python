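"""Whole-body software phantom with paired full/ultra-short acquisition PET.

Emulates the statistical structure of a whole-body FDG-PET/CT study: a body
with organ compartments (bones, liver, lung, lymph nodes, other soft tissue),
focal lesions of configurable volume and uptake, a matched CT volume in
Hounsfield units, and PET acquisitions simulated at any fraction of the full
acquisition time.

The acquisition surrogate is voxelwise Poisson thinning: the expected count
in a voxel is ``SUV x counts_per_suv_fulltime x time_ratio``; a Poisson draw
is scaled back to SUV and blurred with a Gaussian reconstruction PSF. This
preserves the property the enhancement network must learn — voxel noise
variance scales as ``1/time_ratio`` — without modelling scanner physics
(continuous bed motion, attenuation, scatter, or iterative reconstruction).

The default time ratio 1.5/50 matches a table speed of 50 mm/s for the
ultra-short scan against 1.5 mm/s for the reference scan, i.e. a ~33.3-fold
reduction in acquisition time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .grid import VolumeGrid

__all__ = [
    "ORGAN_CATEGORIES",
    "ORGAN_LABELS",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "simulate_pet",
    "make_pair",
    "random_spec",
]

#: Anatomical categories a lesion can belong to. Label 0 is outside the body.
ORGAN_CATEGORIES = ("bones", "liver", "lung", "lymph nodes", "other")
ORGAN_LABELS = {name: i + 1 for i, name in enumerate(ORGAN_CATEGORIES)}

_DEFAULT_ORGAN_SUV = {
    "other": 1.0,
    "liver": 2.5,
    "lung": 0.4,
    "bones": 1.4,
    "lymph nodes": 1.0,
}
_DEFAULT_ORGAN_HU = {
    "other": 40.0,
    "liver": 60.0,
    "lung": -700.0,
    "bones": 700.0,
    "lymph nodes": 40.0,
}
_AIR_HU = -1000.0

#: 33.3-fold acquisition-time reduction (50 mm/s vs 1.5 mm/s table speed).
DEFAULT_TIME_RATIO = 1.5 / 50.0


@dataclass
class LesionSpec:
    """One focal lesion: a sphere of elevated uptake inside an organ."""

    organ: str
    center_mm: tuple[float, float, float]  # (z, y, x) world coordinates
    volume_ml: float
    suv: float

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_CATEGORIES:
            raise ValueError(f"unknown organ category {self.organ!r}")
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be > 0")
        if self.suv < 0:
            raise ValueError("lesion SUV must be >= 0")

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient and its acquisition.

    ``counts_per_suv_fulltime`` is the calibration constant of the Poisson
    surrogate: expected full-acquisition-time counts per voxel per unit SUV.
    It has no physically derivable value here and is exposed as a knob; the
    default of 100 makes the full-time scan low-noise and the ultra-short
    scan (time ratio 0.03, ~3 counts per soft-tissue voxel) noise-dominated.
    """

    shape: tuple[int, int, int] = (40, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.3, 3.3)
    lesions: list[LesionSpec] = field(default_factory=list)
    organ_suv: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ORGAN_SUV))
    organ_hu: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ORGAN_HU))
    weight_kg: float = 75.0
    injected_MBq: float = 327.8
    time_ratio: float = DEFAULT_TIME_RATIO
    psf_fwhm_mm: float = 4.0
    counts_per_suv_fulltime: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.time_ratio <= 1.0):
            raise ValueError(f"time_ratio must be in (0, 1], got {self.time_ratio}")
        if self.counts_per_suv_fulltime <= 0:
            raise ValueError("counts_per_suv_fulltime must be > 0")
        if self.weight_kg <= 0 or self.injected_MBq <= 0:
            raise ValueError("weight and injected activity must be > 0")
        if any(v < 0 for v in self.organ_suv.values()):
            raise ValueError("organ SUVs must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str) -> None:
        doc = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "lesions": [
                {
                    "organ": l.organ,
                    "center_mm": list(l.center_mm),
                    "volume_ml": l.volume_ml,
                    "suv": l.suv,
                }
                for l in self.lesions
            ],
            "organ_suv": self.organ_suv,
            "organ_hu": self.organ_hu,
            "weight_kg": self.weight_kg,
            "injected_MBq": self.injected_MBq,
            "time_ratio": self.time_ratio,
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "counts_per_suv_fulltime": self.counts_per_suv_fulltime,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["shape"] = tuple(doc["shape"])
        doc["spacing"] = tuple(doc["spacing"])
        doc["lesions"] = [
            LesionSpec(
                organ=l["organ"],
                center_mm=tuple(l["center_mm"]),
                volume_ml=float(l["volume_ml"]),
                suv=float(l["suv"]),
            )
            for l in doc.get("lesions", [])
        ]
        return cls(**doc)


@dataclass
class PhantomTruth:
    """Noise-free ground truth for one phantom.

    All grids share shape and spacing; ``lesion_labels`` carries one positive
    integer per lesion, matching the ``id`` column of ``lesion_table``
    (columns: id, organ, volume_ml, suv).
    """

    activity_suv: VolumeGrid
    ct_hu: VolumeGrid
    body_mask: VolumeGrid
    organ_labels: VolumeGrid
    lesion_labels: VolumeGrid
    lesion_table: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("ct_hu", "body_mask", "organ_labels", "lesion_labels"):
            self.activity_suv.require_same_geometry(getattr(self, name), f"activity and {name}")
        lab = self.lesion_labels.values
        if np.any((lab > 0) & (self.body_mask.values == 0)):
            raise ValueError("lesion labels extend outside the body mask")
        ids = sorted(int(i) for i in np.unique(lab) if i > 0)
        table_ids = sorted(int(i) for i in self.lesion_table["id"]) if len(self.lesion_table) else []
        if ids != table_ids:
            raise ValueError(f"lesion ids in label map {ids} != lesion table {table_ids}")


def _ellipsoid(shape, spacing, center_frac, semi_frac) -> np.ndarray:
    """Boolean ellipsoid mask; center and semi-axes as fractions of extent."""
    extent = np.array(shape) * np.array(spacing)
    center = np.array(center_frac) * extent
    semi = np.maximum(np.array(semi_frac) * extent, 1e-6)
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0],
        (np.arange(shape[1]) + 0.5) * spacing[1],
        (np.arange(shape[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    d = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    return d <= 1.0


def _build_organ_labels(shape, spacing) -> np.ndarray:
    """Default whole-body layout: elliptic-cylinder torso with embedded organs."""
    labels = np.zeros(shape, dtype=np.int32)
    # torso: elliptic cylinder spanning all slices
    body = _ellipsoid(shape, spacing, (0.5, 0.5, 0.5), (10.0, 0.40, 0.46))
    labels[body] = ORGAN_LABELS["other"]
    # lungs: paired ellipsoids in the upper thorax
    for x in (0.34, 0.66):
        lung = _ellipsoid(shape, spacing, (0.24, 0.44, x), (0.17, 0.17, 0.13))
        labels[lung & body] = ORGAN_LABELS["lung"]
    # mediastinal lymph-node compartment
    nodes = _ellipsoid(shape, spacing, (0.38, 0.48, 0.50), (0.10, 0.09, 0.09))
    labels[nodes & body] = ORGAN_LABELS["lymph nodes"]
    # liver: large ellipsoid, patient right (low x), below the lungs
    liver = _ellipsoid(shape, spacing, (0.58, 0.50, 0.36), (0.16, 0.20, 0.18))
    labels[liver & body] = ORGAN_LABELS["liver"]
    # spine: posterior cylinder through all slices
    spine = _ellipsoid(shape, spacing, (0.5, 0.74, 0.50), (10.0, 0.07, 0.055))
    labels[spine & body] = ORGAN_LABELS["bones"]
    return labels


def _rasterize_sphere(shape, spacing, center_mm, volume_ml) -> np.ndarray:
    """Discrete ball of the requested volume around a point.

    Takes the n voxels whose centers are nearest the sphere center, with
    n = round(volume / voxel volume), breaking distance ties by voxel index.
    This keeps the rasterized volume within half a voxel of the request
    (plain radius thresholding can be off by several voxels)."""
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    n_target = max(1, int(round(volume_ml / voxel_ml)))
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    pad = 2.0 * max(spacing)
    lo = [max(0, int((c - radius_mm - pad) / s)) for c, s in zip(center_mm, spacing)]
    hi = [
        min(n, int((c + radius_mm + pad) / s) + 2)
        for c, s, n in zip(center_mm, spacing, shape)
    ]
    mask = np.zeros(shape, dtype=bool)
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
        (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
        (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    d2 = (zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2 + (xx - center_mm[2]) ** 2
    flat = np.argsort(d2.ravel(), kind="stable")[: min(n_target, d2.size)]
    sub = np.zeros(d2.shape, dtype=bool)
    sub.ravel()[flat] = True
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the noise-free ground truth for one phantom.

    The activity map is piecewise-constant organ background with lesions
    overwriting the background. CT HU values are assigned per tissue
    category and lightly smoothed (1 voxel sigma) to soften boundaries.

    Raises
    ------
    ValueError
        If a lesion center does not lie inside its declared organ (error
        names the lesion id), or if two lesions overlap.
    """
    shape, spacing = spec.shape, spec.spacing
    organ_labels = _build_organ_labels(shape, spacing)
    body = organ_labels > 0

    activity = np.zeros(shape, dtype=np.float64)
    ct = np.full(shape, _AIR_HU, dtype=np.float64)
    for name, lab in ORGAN_LABELS.items():
        sel = organ_labels == lab
        activity[sel] = spec.organ_suv[name]
        ct[sel] = spec.organ_hu[name]

    lesion_labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for i, les in enumerate(spec.lesions, start=1):
        cvox = tuple(int(c / s) for c, s in zip(les.center_mm, spacing))
        if not all(0 <= c < n for c, n in zip(cvox, shape)):
            raise ValueError(f"lesion {i}: center {les.center_mm} outside the grid")
        if organ_labels[cvox] != ORGAN_LABELS[les.organ]:
            raise ValueError(
                f"lesion {i}: center {les.center_mm} is not inside organ {les.organ!r}"
            )
        sphere = _rasterize_sphere(shape, spacing, les.center_mm, les.volume_ml) & body
        if np.any(lesion_labels[sphere] > 0):
            raise ValueError(f"lesion {i} overlaps a previously placed lesion")
        if not sphere.any():
            raise ValueError(f"lesion {i}: volume {les.volume_ml} ml rasterizes to 0 voxels")
        lesion_labels[sphere] = i
        activity[sphere] = les.suv
        rows.append({"id": i, "organ": les.organ, "volume_ml": les.volume_ml, "suv": les.suv})

    ct = ndi.gaussian_filter(ct, sigma=1.0)
    table = pd.DataFrame(rows, columns=["id", "organ", "volume_ml", "suv"])
    mk = lambda v, lab=False: VolumeGrid(v, spacing=spacing, is_label=lab)
    return PhantomTruth(
        activity_suv=mk(activity),
        ct_hu=mk(ct),
        body_mask=mk(body.astype(np.int32), lab=True),
        organ_labels=mk(organ_labels, lab=True),
        lesion_labels=mk(lesion_labels, lab=True),
        lesion_table=table,
    )


def simulate_pet(
    truth: PhantomTruth,
    time_ratio: float,
    spec: PhantomSpec,
    seed: int,
    noise: bool = True,
) -> VolumeGrid:
    """Simulate one PET acquisition at a fraction of the full scan time.

    Expected counts per voxel are ``lambda = SUV x C x time_ratio`` with
    ``C = spec.counts_per_suv_fulltime``; a Poisson draw divided by the same
    scale returns to SUV, then a Gaussian PSF of ``spec.psf_fwhm_mm`` is
    applied. With ``noise=False`` the output is exactly the PSF-smoothed
    activity map.
    """
    if not (0.0 < time_ratio <= 1.0):
        raise ValueError(f"time_ratio must be in (0, 1], got {time_ratio}")
    scale = spec.counts_per_suv_fulltime * time_ratio
    if scale <= 0:
        raise ValueError("calibration constant must be positive")
    activity = truth.activity_suv.values.astype(np.float64)
    if noise:
        rng = np.random.default_rng(seed)
        suv = rng.poisson(activity * scale).astype(np.float64) / scale
    else:
        suv = activity.copy()
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm / 2.3548200450309493 / s for s in truth.activity_suv.spacing]
        suv = ndi.gaussian_filter(suv, sigma=sigma_vox)
    return truth.activity_suv.with_values(suv, is_label=False)


def _subseed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % 2**31


def make_pair(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid, PhantomTruth]:
    """Generate one paired acquisition: (fulltime, extreme, truth).

    The full-time scan uses ``time_ratio=1`` with sub-seed ``spec.seed`` and
    the ultra-short scan uses ``spec.time_ratio`` with sub-seed
    ``spec.seed + 1``, so the two noise realizations are independent and the
    pair is reproducible from the spec alone.
    """
    truth = make_phantom(spec)
    fulltime = simulate_pet(truth, 1.0, spec, seed=_subseed(spec.seed, 0))
    extreme = simulate_pet(truth, spec.time_ratio, spec, seed=_subseed(spec.seed, 1))
    return fulltime, extreme, truth


def random_spec(
    seed: int,
    shape: tuple[int, int, int] = (40, 64, 64),
    spacing: tuple[float, float, float] = (3.0, 3.3, 3.3),
    n_lesions: tuple[int, int] = (1, 4),
    volume_ml_range: tuple[float, float] = (0.5, 30.0),
    suv_range: tuple[float, float] = (2.0, 27.0),
    lesion_free_fraction: float = 0.0,
    **spec_kwargs,
) -> PhantomSpec:
    """Draw a random patient: lesion count, organs, volumes and uptakes.

    Volumes and SUVs are drawn log-uniformly over the clinical ranges
    (0.5-30 ml, SUV 2-27 by default, skewing the cohort toward the small
    low-uptake lesions that dominate real readings). Lesion centers are
    sampled inside the target organ at least ~60% of the lesion radius away
    from the organ boundary so the declared organ is the modal organ under
    the mask. With probability ``lesion_free_fraction`` the patient has no
    lesions (a lesion-free control).
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec(shape=shape, spacing=spacing, seed=int(seed), **spec_kwargs)
    if lesion_free_fraction > 0 and rng.random() < lesion_free_fraction:
        return base

    organ_labels = _build_organ_labels(shape, spacing)
    k = int(rng.integers(n_lesions[0], n_lesions[1] + 1))
    # organs weighted roughly like clinical lesion frequency
    organ_pool = ["bones", "lymph nodes", "other", "liver", "lung"]
    organ_w = np.array([0.35, 0.25, 0.15, 0.13, 0.12])
    lesions: list[LesionSpec] = []
    placed = np.zeros(shape, dtype=bool)
    for _ in range(k):
        organ = str(rng.choice(organ_pool, p=organ_w))
        vol = float(np.exp(rng.uniform(np.log(volume_ml_range[0]), np.log(volume_ml_range[1]))))
        suv = float(np.exp(rng.uniform(np.log(suv_range[0]), np.log(suv_range[1]))))
        r_mm = (3.0 * vol * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        mask = organ_labels == ORGAN_LABELS[organ]
        edt = ndi.distance_transform_edt(mask, sampling=spacing)
        want = min(0.6 * r_mm, float(edt.max()))
        for _try in range(50):
            cand = np.argwhere(edt >= max(want, 1e-9))
            if len(cand) == 0:
                break
            idx = cand[rng.integers(len(cand))]
            center = tuple((float(i) + 0.5) * s for i, s in zip(idx, spacing))
            sphere = _rasterize_sphere(shape, spacing, center, vol)
            if not np.any(sphere & placed):
                placed |= sphere
                lesions.append(
                    LesionSpec(organ=organ, center_mm=center, volume_ml=vol, suv=suv)
                )
                break
    base.lesions = lesions
    return base


def make_cohort(
    n: int, seed: int, lesion_free_fraction: float = 0.3, **kwargs
) -> list[PhantomSpec]:
    """Specs for ``n`` patients with distinct sub-seeds.

    About a third of patients are lesion-free by default, mirroring a mixed
    staging cohort (the reference reader study had 17/50 lesion-free cases).
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [
        random_spec(int(s), lesion_free_fraction=lesion_free_fraction, **kwargs) for s in seeds
    ]
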