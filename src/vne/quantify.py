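"""ROI-anchored progressive-threshold lesion quantification.

Lesion segmentation follows the full-width-at-half-maximum family of
methods: the mean intensity of a remote (lesion-free) myocardial ROI sets
the floor, the mean of a blood-pool-centre ROI sets the ceiling, and a
"percentile" p selects the threshold

    threshold = remote_mean + (p / 100) * (blood_mean - remote_mean)

so p = 50, 25, 12.5 correspond to full width at half / quarter / eighth
maximum.  Myocardial pixels at or above the threshold form the lesion mask,
and per-patient lesion burden pools areas over slices:
sum(lesion areas) / sum(myocardial areas).

The "percentile" is a fraction of the remote-to-blood intensity range, not a
rank percentile of the intensity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .geometry import ImageSlice, SliceGeometry

__all__ = [
    "RoiError",
    "DegenerateReferenceError",
    "RoiSet",
    "LesionQuantification",
    "points_in_polygon",
    "contours_to_mask",
    "threshold_value",
    "lesion_mask",
    "lesion_burden",
    "progressive_quantification",
    "quantify_patient",
    "calibrate_adjusted_percentile",
    "LGE_PERCENTILES",
    "VNE_ADJUSTED_PERCENTILES",
]

#: Progressive threshold sets: FWHM / FWQM / FWEM, and the adjusted set used
#: for VNE images so that their burdens are directly comparable with LGE.
LGE_PERCENTILES = (50.0, 25.0, 12.5)
VNE_ADJUSTED_PERCENTILES = (35.0, 20.0, 10.0)


class RoiError(ValueError):
    """Invalid ROI definition."""


class DegenerateReferenceError(ValueError):
    """Blood-pool mean does not exceed remote mean; ROIs unusable."""


@dataclass
class RoiSet:
    """Contours and reference ROIs anchoring quantification on one slice.

    Contours are closed polygons in pixel coordinates, ordered [row, col];
    ``remote_roi`` and ``bloodpool_roi`` are (N, 2) integer pixel-index
    arrays.  The remote ROI samples normal (lesion-free) myocardium; the
    blood-pool ROI sits at the LV cavity centre, avoiding papillary muscles
    (the ROI provider's responsibility).
    """

    epicardial_contour: np.ndarray
    endocardial_contour: np.ndarray
    remote_roi: np.ndarray
    bloodpool_roi: np.ndarray

    def __post_init__(self) -> None:
        self.epicardial_contour = np.asarray(self.epicardial_contour, dtype=float)
        self.endocardial_contour = np.asarray(self.endocardial_contour, dtype=float)
        self.remote_roi = np.asarray(self.remote_roi, dtype=int)
        self.bloodpool_roi = np.asarray(self.bloodpool_roi, dtype=int)
        for name in ("epicardial_contour", "endocardial_contour"):
            c = getattr(self, name)
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise RoiError(f"{name} must be an (N>=3, 2) polygon")
        for name in ("remote_roi", "bloodpool_roi"):
            r = getattr(self, name)
            if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 1:
                raise RoiError(f"{name} must be a non-empty (N, 2) pixel list")

    def roi_mean(self, img: ImageSlice, which: str) -> float:
        idx = getattr(self, which)
        return float(np.asarray(img.pixels, dtype=float)[idx[:, 0], idx[:, 1]].mean())


@dataclass
class LesionQuantification:
    """Per-slice (or pooled per-patient) progressive quantification result."""

    thresholds_used: dict[float, float]
    lesion_masks: dict[float, np.ndarray]
    lesion_area_px: dict[float, int]
    myocardial_area_px: int
    burden: dict[float, float]


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorised.

    ``points``: (M, 2) [row, col]; ``polygon``: (N, 2) closed implicitly.
    Points exactly on an edge follow the half-open crossing convention.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for i in range(len(poly)):
        cond = (y0[i] > y) != (y1[i] > y)
        if not np.any(cond):
            continue
        xs = x0[i] + (y[cond] - y0[i]) * (x1[i] - x0[i]) / (y1[i] - y0[i])
        flip = np.zeros_like(inside)
        flip[cond] = x[cond] < xs
        inside ^= flip
    return inside


def _validate_contours(epi: np.ndarray, endo: np.ndarray) -> None:
    p_epi = Polygon(epi)
    p_endo = Polygon(endo)
    if not p_epi.is_valid or not p_endo.is_valid:
        raise RoiError("self-intersecting contour")
    if not p_epi.contains(p_endo):
        raise RoiError("endocardial contour is not strictly inside the epicardial contour")


def contours_to_mask(roi: RoiSet, grid: SliceGeometry) -> np.ndarray:
    """Myocardial mask: pixel centres inside epi- and outside endocardium."""
    _validate_contours(roi.epicardial_contour, roi.endocardial_contour)
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside_epi = points_in_polygon(pts, roi.epicardial_contour)
    inside_endo = points_in_polygon(pts, roi.endocardial_contour)
    mask = (inside_epi & ~inside_endo).reshape(grid.n_rows, grid.n_cols)
    if not mask.any():
        raise RoiError("degenerate contours: empty myocardial mask")
    return mask


def threshold_value(remote_mean: float, blood_mean: float, percentile: float) -> float:
    """Intensity threshold at ``percentile`` of the remote→blood range."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if blood_mean <= remote_mean:
        raise DegenerateReferenceError(
            f"blood-pool mean ({blood_mean}) must exceed remote mean ({remote_mean})"
        )
    return remote_mean + (percentile / 100.0) * (blood_mean - remote_mean)


def lesion_mask(img: ImageSlice, myo_mask: np.ndarray, threshold: float) -> np.ndarray:
    """Myocardial pixels with intensity >= threshold."""
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if myo_mask.shape != img.pixels.shape:
        raise ValueError(
            f"mask shape {myo_mask.shape} does not match image {img.pixels.shape}"
        )
    return myo_mask & (np.asarray(img.pixels, dtype=float) >= threshold)


def lesion_burden(slices: Iterable[tuple[float, float]]) -> float:
    """Pooled burden: sum of lesion areas over sum of myocardial areas.

    ``slices`` yields per-slice (lesion_area, myocardial_area) pairs.  This is
    the pooled ratio, not a mean of per-slice ratios.
    """
    pairs = list(slices)
    if not pairs:
        raise ValueError("at least one slice is required")
    lesion_total = float(sum(p[0] for p in pairs))
    myo_total = float(sum(p[1] for p in pairs))
    if myo_total <= 0:
        raise ValueError("total myocardial area must be positive")
    return lesion_total / myo_total


def progressive_quantification(
    img: ImageSlice,
    roi: RoiSet,
    percentiles: Sequence[float] = LGE_PERCENTILES,
    myo_mask: Optional[np.ndarray] = None,
    references: Optional[tuple[float, float]] = None,
) -> LesionQuantification:
    """Quantify one slice at a set of progressive thresholds.

    ``references`` optionally supplies (remote_mean, blood_mean) — e.g. pooled
    over a study — otherwise the slice's own ROI means are used.
    """
    if myo_mask is None:
        myo_mask = contours_to_mask(roi, img.geometry)
    if references is None:
        references = (roi.roi_mean(img, "remote_roi"), roi.roi_mean(img, "bloodpool_roi"))
    remote_mean, blood_mean = references
    thresholds: dict[float, float] = {}
    masks: dict[float, np.ndarray] = {}
    areas: dict[float, int] = {}
    burden: dict[float, float] = {}
    myo_area = int(myo_mask.sum())
    for p in percentiles:
        t = threshold_value(remote_mean, blood_mean, p)
        m = lesion_mask(img, myo_mask, t)
        thresholds[p] = t
        masks[p] = m
        areas[p] = int(m.sum())
        burden[p] = areas[p] / myo_area
    return LesionQuantification(
        thresholds_used=thresholds,
        lesion_masks=masks,
        lesion_area_px=areas,
        myocardial_area_px=myo_area,
        burden=burden,
    )


def quantify_patient(
    slices: Sequence[tuple[ImageSlice, RoiSet]],
    percentiles: Sequence[float] = LGE_PERCENTILES,
    pooled_references: bool = False,
) -> dict[float, float]:
    """Per-patient burden at each percentile, pooled over short-axis slices.

    With ``pooled_references`` the remote/blood means are averaged over all
    slices before thresholding; the default anchors each slice to its own
    ROI means.
    """
    if not slices:
        raise ValueError("at least one slice is required")
    shared: Optional[tuple[float, float]] = None
    if pooled_references:
        remotes = [roi.roi_mean(img, "remote_roi") for img, roi in slices]
        bloods = [roi.roi_mean(img, "bloodpool_roi") for img, roi in slices]
        shared = (float(np.mean(remotes)), float(np.mean(bloods)))
    per_slice = [
        progressive_quantification(img, roi, percentiles, references=shared)
        for img, roi in slices
    ]
    return {
        p: lesion_burden((q.lesion_area_px[p], q.myocardial_area_px) for q in per_slice)
        for p in percentiles
    }


def calibrate_adjusted_percentile(
    pairs: Sequence[tuple[ImageSlice, ImageSlice, RoiSet]],
    lge_percentile: float,
    candidates: Optional[Sequence[float]] = None,
) -> float:
    """Find the VNE percentile whose mean burden matches LGE at ``lge_percentile``.

    Grid search minimising |mean VNE burden − mean LGE burden|; ties resolve
    to the larger (more conservative) percentile.  ``pairs`` yields
    (vne_image, lge_image, roi) on a shared grid.
    """
    if len(pairs) < 2:
        raise ValueError("at least two image pairs are required for calibration")
    if candidates is None:
        candidates = np.arange(5.0, 95.0 + 1e-9, 2.5)
    candidates = sorted(float(c) for c in candidates)
    lge_burdens = []
    vne_by_candidate = {c: [] for c in candidates}
    for vne_img, lge_img, roi in pairs:
        myo = contours_to_mask(roi, lge_img.geometry)
        q_lge = progressive_quantification(lge_img, roi, [lge_percentile], myo_mask=myo)
        lge_burdens.append(q_lge.burden[lge_percentile])
        q_vne = progressive_quantification(vne_img, roi, candidates, myo_mask=myo)
        for c in candidates:
            vne_by_candidate[c].append(q_vne.burden[c])
    target = float(np.mean(lge_burdens))
    best_c, best_err = None, np.inf
    for c in candidates:  # ascending; >= keeps the larger percentile on ties
        err = abs(float(np.mean(vne_by_candidate[c])) - target)
        if err <= best_err:
            best_c, best_err = c, err
    return float(best_c)
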