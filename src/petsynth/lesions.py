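"""Lesion-level quantification and matched-pair detection analysis.

Covers the per-lesion SUV metrics (SUV_mean, SUV_max, SUV_peak over a
1-cm^3 sphere around the hottest voxel), PERCIST measurability
(SUV_peak > 1.5 x liver mean + 2 x liver SD), IoU-based matching between
reference and synthetic-image lesion masks (a lesion counts as detected
when IoU > 0, i.e. any overlap at the correct position), detection rates
stratified by patient / organ / lesion level and PERCIST measurability,
and nonparametric group comparisons between detected and missed lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .grid import VolumeGrid
from .phantom import ORGAN_CATEGORIES, ORGAN_LABELS

__all__ = [
    "PEAK_SPHERE_RADIUS_MM",
    "LesionStats",
    "LiverReference",
    "MatchResult",
    "DetectionReport",
    "label_lesions",
    "suv_peak",
    "liver_reference",
    "percist_measurable",
    "lesion_stats",
    "match_lesions",
    "lesion_records",
    "detection_report",
    "compare_groups",
    "suv_difference_table",
    "read_lesions",
]

#: Radius of the 1-cm^3 SUV_peak sphere: (3/(4 pi))^(1/3) cm = 6.2035 mm.
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionStats:
    """SUV metrics of one lesion measured on a given image."""

    lesion_id: int
    organ: str
    volume_ml: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    percist_measurable: bool
    peak_sphere_clipped: bool = False

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be > 0")
        # the peak sphere may average in surrounding background, so peak can
        # dip below the mean (or, near hotter structures, exceed the max);
        # only mean <= max is a hard invariant
        if self.suv_mean > self.suv_max + 1e-9:
            raise ValueError("suv_mean cannot exceed suv_max")


@dataclass
class LiverReference:
    """Liver background statistics for the PERCIST threshold."""

    liver_mean: float
    liver_std: float
    voi: str = "whole-liver"

    def __post_init__(self) -> None:
        if self.liver_std < 0:
            raise ValueError("liver_std must be >= 0")

    @property
    def threshold(self) -> float:
        return 1.5 * self.liver_mean + 2.0 * self.liver_std


@dataclass
class MatchResult:
    """Best-overlap match of one reference lesion against predicted lesions."""

    ref_lesion_id: int
    matched_pred_id: int | None
    iou: float
    detected: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou <= 1.0):
            raise ValueError(f"IoU must be in [0, 1], got {self.iou}")
        self.detected = self.iou > 0.0


def label_lesions(mask: VolumeGrid) -> tuple[VolumeGrid, int]:
    """3D connected components (26-connectivity), labelled by descending size.

    Returns the labelled grid (1..K) and K; an empty mask gives K = 0.
    """
    binary = np.asarray(mask.values) > 0
    raw, n = ndi.label(binary, structure=_CONN26)
    if n == 0:
        return mask.with_values(np.zeros_like(raw, dtype=np.int32), is_label=True), 0
    sizes = ndi.sum_labels(np.ones_like(raw), raw, index=range(1, n + 1))
    order = np.argsort(-sizes, kind="stable") + 1  # old labels, largest first
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return mask.with_values(remap[raw], is_label=True), n


def _sphere_offsets(spacing, radius_mm: float) -> np.ndarray:
    """Voxel offsets whose centers lie within ``radius_mm`` of a voxel center."""
    reach = [int(radius_mm / s) + 1 for s in spacing]
    dz, dy, dx = np.mgrid[
        -reach[0] : reach[0] + 1, -reach[1] : reach[1] + 1, -reach[2] : reach[2] + 1
    ]
    d2 = (dz * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dx * spacing[2]) ** 2
    keep = d2 <= radius_mm**2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def suv_peak(
    image: VolumeGrid, lesion_mask: np.ndarray, return_clipped: bool = False
) -> float | tuple[float, bool]:
    """SUV averaged over a 1-cm^3 sphere centered on the lesion's hottest voxel.

    The sphere (radius 6.2035 mm) is discretized by the center-of-voxel
    rule; it may extend beyond the lesion mask but is clipped at the image
    boundary (flag available via ``return_clipped``). Argmax ties resolve to
    the lowest (z, y, x) index.
    """
    lesion_mask = np.asarray(lesion_mask) > 0
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    vals = np.where(lesion_mask, image.values, -np.inf)
    center = np.unravel_index(int(np.argmax(vals)), vals.shape)
    offsets = _sphere_offsets(image.spacing, PEAK_SPHERE_RADIUS_MM)
    coords = offsets + np.asarray(center)
    inside = np.all((coords >= 0) & (coords < np.asarray(image.shape)), axis=1)
    clipped = not bool(inside.all())
    kept = coords[inside]
    peak = float(image.values[kept[:, 0], kept[:, 1], kept[:, 2]].mean())
    return (peak, clipped) if return_clipped else peak


def liver_reference(
    image: VolumeGrid, liver_mask: np.ndarray, voi_diameter_mm: float = 30.0
) -> LiverReference:
    """Liver background SUV from a 3-cm spherical VOI inside the liver.

    The VOI is centered on the deepest liver voxel (maximum distance to the
    organ boundary), guaranteeing it stays inside the organ whenever the
    organ can host it; smaller livers fall back to the whole mask, recorded
    in the VOI description. The SD is the population standard deviation.
    """
    liver_mask = np.asarray(liver_mask) > 0
    if not liver_mask.any():
        raise ValueError("liver mask is empty")
    r = voi_diameter_mm / 2.0
    edt = ndi.distance_transform_edt(liver_mask, sampling=image.spacing)
    if float(edt.max()) >= r:
        center = np.unravel_index(int(np.argmax(edt)), edt.shape)
        offsets = _sphere_offsets(image.spacing, r)
        coords = offsets + np.asarray(center)
        vals = image.values[coords[:, 0], coords[:, 1], coords[:, 2]]
        voi = f"{voi_diameter_mm:g}-mm sphere at deepest liver voxel {tuple(center)}"
    else:
        vals = image.values[liver_mask]
        voi = "whole-liver (organ too small for the spherical VOI)"
    return LiverReference(float(np.mean(vals)), float(np.std(vals)), voi)


def percist_measurable(suv_peak_value: float, ref: LiverReference) -> bool:
    """Strict threshold: SUV_peak > 1.5 x liver mean + 2 x liver SD."""
    return suv_peak_value > ref.threshold


def lesion_stats(
    image: VolumeGrid,
    lesion_labels: VolumeGrid,
    organ_labels: VolumeGrid,
    liver_ref: LiverReference,
) -> list[LesionStats]:
    """Per-lesion volume, SUV_mean/max/peak, modal organ, PERCIST flag.

    A lesion whose mask overlaps no organ label is assigned to "other".
    """
    image.require_same_geometry(lesion_labels, "image and lesion labels")
    image.require_same_geometry(organ_labels, "image and organ labels")
    label_to_name = {v: k for k, v in ORGAN_LABELS.items()}
    out = []
    for lid in sorted(int(i) for i in np.unique(lesion_labels.values) if i > 0):
        sel = lesion_labels.values == lid
        vals = image.values[sel]
        peak, clipped = suv_peak(image, sel, return_clipped=True)
        organs = organ_labels.values[sel]
        organs = organs[organs > 0]
        organ = label_to_name[int(np.bincount(organs).argmax())] if organs.size else "other"
        out.append(
            LesionStats(
                lesion_id=lid,
                organ=organ,
                volume_ml=float(sel.sum()) * image.voxel_volume_ml,
                suv_mean=float(vals.mean()),
                suv_max=float(vals.max()),
                suv_peak=peak,
                percist_measurable=percist_measurable(peak, liver_ref),
                peak_sphere_clipped=clipped,
            )
        )
    return out


def match_lesions(ref_labels: VolumeGrid, pred_labels: VolumeGrid) -> list[MatchResult]:
    """Best-IoU match of every reference lesion against predicted components.

    IoU is |intersection| / |union| of the 3D voxel sets. For each
    reference lesion the highest-IoU predicted candidate is selected (ties
    break to the smaller predicted label id); a predicted component may
    match several reference lesions. IoU 0 means not detected.
    """
    ref_labels.require_same_geometry(pred_labels, "reference and predicted labels")
    ref = np.asarray(ref_labels.values)
    pred = np.asarray(pred_labels.values)
    ref_ids, ref_sizes = np.unique(ref[ref > 0], return_counts=True)
    pred_sizes = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    both = (ref > 0) & (pred > 0)
    inter: dict[tuple[int, int], int] = {}
    if both.any():
        pairs, counts = np.unique(
            np.stack([ref[both], pred[both]]), axis=1, return_counts=True
        )
        inter = {(int(r), int(p)): int(c) for (r, p), c in zip(pairs.T, counts)}
    results = []
    for rid, rsize in zip(ref_ids, ref_sizes):
        best_iou, best_pid = 0.0, None
        for (r, p), c in inter.items():
            if r != rid:
                continue
            iou = c / (rsize + pred_sizes[p] - c)
            if iou > best_iou or (iou == best_iou and best_pid is not None and p < best_pid):
                best_iou, best_pid = iou, int(p)
        results.append(MatchResult(int(rid), best_pid, float(best_iou)))
    return results


def lesion_records(
    patient_id: str, stats: list[LesionStats], matches: list[MatchResult]
) -> pd.DataFrame:
    """One row per reference lesion: organ, PERCIST flag, detected, metrics."""
    by_id = {m.ref_lesion_id: m for m in matches}
    rows = []
    for s in stats:
        m = by_id.get(s.lesion_id)
        rows.append(
            {
                "patient": patient_id,
                "lesion_id": s.lesion_id,
                "organ": s.organ,
                "percist": bool(s.percist_measurable),
                "detected": bool(m.detected) if m else False,
                "iou": m.iou if m else 0.0,
                "volume_ml": s.volume_ml,
                "suv_mean": s.suv_mean,
                "suv_max": s.suv_max,
                "suv_peak": s.suv_peak,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "lesion_id", "organ", "percist", "detected",
            "iou", "volume_ml", "suv_mean", "suv_max", "suv_peak",
        ],
    )


_STRATA = {"all": None, "percist": True, "non_percist": False}


@dataclass
class DetectionReport:
    """Detection rates at patient / organ / lesion level, by PERCIST stratum.

    ``lesion_level`` and ``organ_level`` have one row per (organ x stratum)
    plus "all"-organ rows; ``patient_level`` one row per stratum. Rates are
    kept as exact fractions (``detected``/``total``) with a 2-decimal
    ``rate`` column for table display.
    """

    lesion_level: pd.DataFrame
    organ_level: pd.DataFrame
    patient_level: pd.DataFrame
    sensitivity: float
    specificity: float
    n_positive_patients: int
    n_negative_patients: int

    def rate(self, level: str, stratum: str = "all", organ: str = "all") -> float:
        table = {"lesion": self.lesion_level, "organ": self.organ_level}.get(level)
        if table is None:
            if organ != "all":
                raise ValueError("patient level has no organ breakdown")
            table = self.patient_level
            row = table[table["stratum"] == stratum]
        else:
            row = table[(table["stratum"] == stratum) & (table["organ"] == organ)]
        if len(row) != 1:
            raise KeyError(f"no unique cell for level={level}, stratum={stratum}, organ={organ}")
        r = row.iloc[0]
        return float(r["detected"]) / float(r["total"]) if r["total"] else float("nan")


def detection_report(
    lesions: pd.DataFrame,
    patients: pd.DataFrame | None = None,
) -> DetectionReport:
    """Aggregate matched-pair detection results.

    Parameters
    ----------
    lesions : DataFrame
        One row per reference lesion with columns ``patient``, ``organ``,
        ``percist`` (bool), ``detected`` (bool) — e.g. concatenated outputs
        of :func:`lesion_records`.
    patients : DataFrame, optional
        One row per study with columns ``patient``, ``ref_positive``,
        ``pred_positive`` (any lesion read in reference / synthetic image).
        Drives patient-based sensitivity (detected positives / positives)
        and specificity (1 - false-positive rate over lesion-free patients).
        When omitted, flags are inferred from the lesion table (every listed
        patient is positive; a positive counts as predicted-positive when
        any of its lesions was detected), and specificity is NaN.
    """
    required = {"patient", "organ", "percist", "detected"}
    if not required.issubset(lesions.columns):
        raise ValueError(f"lesion table must have columns {sorted(required)}")
    bad = set(lesions["organ"]) - set(ORGAN_CATEGORIES)
    if bad:
        raise ValueError(f"unknown organ categories: {sorted(bad)}")

    def cell(frame: pd.DataFrame) -> tuple[int, int]:
        return int(frame["detected"].sum()), int(len(frame))

    lesion_rows, organ_rows, patient_rows = [], [], []
    for stratum, flag in _STRATA.items():
        sub = lesions if flag is None else lesions[lesions["percist"] == flag]
        for organ in ("all", *ORGAN_CATEGORIES):
            s = sub if organ == "all" else sub[sub["organ"] == organ]
            det, tot = cell(s)
            lesion_rows.append(
                {"stratum": stratum, "organ": organ, "detected": det, "total": tot,
                 "rate": round(det / tot, 2) if tot else float("nan")}
            )
            # organ level: a (patient, organ) cell is detected if any of its
            # reference lesions is detected
            cells = s.groupby(["patient", "organ"])["detected"].any() if len(s) else pd.Series(dtype=bool)
            det_o, tot_o = int(cells.sum()), int(len(cells))
            organ_rows.append(
                {"stratum": stratum, "organ": organ, "detected": det_o, "total": tot_o,
                 "rate": round(det_o / tot_o, 2) if tot_o else float("nan")}
            )
        by_patient = sub.groupby("patient")["detected"].any() if len(sub) else pd.Series(dtype=bool)
        det_p, tot_p = int(by_patient.sum()), int(len(by_patient))
        patient_rows.append(
            {"stratum": stratum, "detected": det_p, "total": tot_p,
             "rate": round(det_p / tot_p, 2) if tot_p else float("nan")}
        )

    if patients is None:
        pos = lesions.groupby("patient")["detected"].any()
        sens = float(pos.sum() / len(pos)) if len(pos) else float("nan")
        spec = float("nan")
        n_pos, n_neg = int(len(pos)), 0
    else:
        req = {"patient", "ref_positive", "pred_positive"}
        if not req.issubset(patients.columns):
            raise ValueError(f"patient table must have columns {sorted(req)}")
        pos = patients[patients["ref_positive"].astype(bool)]
        neg = patients[~patients["ref_positive"].astype(bool)]
        n_pos, n_neg = len(pos), len(neg)
        sens = float(pos["pred_positive"].astype(bool).sum() / n_pos) if n_pos else float("nan")
        spec = float((~neg["pred_positive"].astype(bool)).sum() / n_neg) if n_neg else float("nan")

    report = DetectionReport(
        lesion_level=pd.DataFrame(lesion_rows),
        organ_level=pd.DataFrame(organ_rows),
        patient_level=pd.DataFrame(patient_rows),
        sensitivity=sens,
        specificity=spec,
        n_positive_patients=n_pos,
        n_negative_patients=n_neg,
    )
    # stratum totals must add up
    ll = report.lesion_level
    for organ in ("all", *ORGAN_CATEGORIES):
        tot = {s: int(ll[(ll["stratum"] == s) & (ll["organ"] == organ)]["total"].iloc[0])
               for s in _STRATA}
        assert tot["percist"] + tot["non_percist"] == tot["all"]
    return report


def compare_groups(values_detected, values_missed) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between detected and missed lesions.

    Uses the exact U distribution for small tie-free samples (both groups
    n <= 8) and the tie-corrected normal approximation otherwise. Returns
    (U statistic of the first group, two-sided p-value).
    """
    a = np.asarray(values_detected, dtype=float)
    b = np.asarray(values_missed, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def suv_difference_table(
    stats_full: list[LesionStats], stats_synth: list[LesionStats]
) -> pd.DataFrame:
    """Per-organ mean +/- SD of absolute SUV differences between two images.

    Both stat lists must come from the *same* lesion masks (the reference
    segmentation applied to the full-time and the synthetic image), so the
    lesion ids must agree one-to-one. SD is the population SD; a single
    lesion reports SD 0. Rows: each organ category present plus "all".
    """
    ids_f = [s.lesion_id for s in stats_full]
    ids_s = [s.lesion_id for s in stats_synth]
    if ids_f != ids_s:
        raise ValueError("lesion ids differ between the two stat lists (masks must be shared)")
    rows = []
    diffs = pd.DataFrame(
        {
            "organ": [s.organ for s in stats_full],
            "d_mean": [abs(f.suv_mean - s.suv_mean) for f, s in zip(stats_full, stats_synth)],
            "d_max": [abs(f.suv_max - s.suv_max) for f, s in zip(stats_full, stats_synth)],
            "d_peak": [abs(f.suv_peak - s.suv_peak) for f, s in zip(stats_full, stats_synth)],
        }
    )
    groups = [("all", diffs)] + [
        (organ, diffs[diffs["organ"] == organ])
        for organ in ORGAN_CATEGORIES
        if (diffs["organ"] == organ).any()
    ]
    for organ, g in groups:
        row = {"organ": organ, "n": len(g)}
        for key, col in (("suv_mean", "d_mean"), ("suv_max", "d_max"), ("suv_peak", "d_peak")):
            row[f"{key}_diff"] = float(g[col].mean()) if len(g) else float("nan")
            row[f"{key}_sd"] = float(g[col].std(ddof=0)) if len(g) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def read_lesions(
    image: VolumeGrid,
    organ_labels: VolumeGrid,
    body_mask: np.ndarray | None = None,
    k: float = 3.0,
    min_voxels: int = 2,
    sd_floor_suv: float = 0.15,
) -> tuple[VolumeGrid, int]:
    """Surrogate reader: threshold-based lesion segmentation of a PET image.

    Stands in for the human reading step: within each organ compartment,
    voxels exceeding ``background + k x SD`` are lesion candidates, where
    background is the organ's median uptake and SD a robust (MAD-based)
    spread floored at ``sd_floor_suv``. Candidates across organs are merged,
    restricted to the body, and connected components smaller than
    ``min_voxels`` are discarded. Returns (labels, count) as in
    :func:`label_lesions`. This is a reproducible surrogate, not a model of
    a human reader; paper-defined metrics never depend on it.
    """
    image.require_same_geometry(organ_labels, "image and organ labels")
    candidates = np.zeros(image.shape, dtype=bool)
    for organ, lab in ORGAN_LABELS.items():
        region = organ_labels.values == lab
        if not region.any():
            continue
        vals = image.values[region]
        bg = float(np.median(vals))
        sd = max(1.4826 * float(np.median(np.abs(vals - bg))), sd_floor_suv)
        candidates[region] = image.values[region] > bg + k * sd
    if body_mask is not None:
        candidates &= np.asarray(body_mask) > 0
    labels, n = label_lesions(image.with_values(candidates.astype(np.int32), is_label=True))
    if n and min_voxels > 1:
        sizes = np.bincount(labels.values.ravel())
        keep = np.where(sizes >= min_voxels)[0]
        keep = keep[keep > 0]
        mask = np.isin(labels.values, keep)
        labels, n = label_lesions(image.with_values(mask.astype(np.int32), is_label=True))
    return labels, n
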