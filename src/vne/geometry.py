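"""Slice geometry, triplet matching and grid resampling.

Short-axis T1 maps, cine stacks and LGE images are acquired as separate
breath-holds, so their slice planes only approximately coincide.  Images are
matched into co-planar triplets using two gates on the geometry metadata —
slice-plane cosine similarity above 0.9 and slice-location difference below
4 mm — and the matched cine/LGE images are then resampled onto the T1-map
pixel grid so that every downstream comparison is pixel-to-pixel.

Conventions: ``pixels[r, c]``; ``row_dir`` is the patient-space unit vector
along increasing row index, ``col_dir`` along increasing column index;
``position_mm`` is the patient-space location of the centre of pixel (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "SliceGeometry",
    "Modality",
    "ImageSlice",
    "CineStack",
    "NativeTriplet",
    "MatchReport",
    "slice_normal",
    "plane_cosine_similarity",
    "slice_location_difference",
    "match_triplets",
    "resample_to_reference",
    "COSINE_SIMILARITY_GATE",
    "LOCATION_DIFFERENCE_GATE_MM",
]

#: Matching gates (slice-plane cosine similarity, slice-location difference).
COSINE_SIMILARITY_GATE = 0.9
LOCATION_DIFFERENCE_GATE_MM = 4.0

_ORTHONORMALITY_TOL = 1e-6


class GeometryError(ValueError):
    """Invalid or incompatible slice geometry."""


@dataclass(frozen=True)
class SliceGeometry:
    """Patient-space placement of one 2-D image slice."""

    row_dir: np.ndarray
    col_dir: np.ndarray
    position_mm: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_dir", np.asarray(self.row_dir, dtype=float))
        object.__setattr__(self, "col_dir", np.asarray(self.col_dir, dtype=float))
        object.__setattr__(self, "position_mm", np.asarray(self.position_mm, dtype=float))
        for name in ("row_dir", "col_dir", "position_mm"):
            if getattr(self, name).shape != (3,):
                raise GeometryError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(self.row_dir) - 1.0) > _ORTHONORMALITY_TOL:
            raise GeometryError("row_dir is not unit length")
        if abs(np.linalg.norm(self.col_dir) - 1.0) > _ORTHONORMALITY_TOL:
            raise GeometryError("col_dir is not unit length")
        if abs(float(self.row_dir @ self.col_dir)) > _ORTHONORMALITY_TOL:
            raise GeometryError("row_dir and col_dir are not orthogonal")
        if min(self.pixel_spacing_mm) <= 0:
            raise GeometryError("pixel spacings must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("pixel counts must be >= 1")

    def pixel_to_patient(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Patient-space coordinates (…, 3) of pixel centres (rows, cols)."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return (
            self.position_mm
            + rows[..., None] * self.pixel_spacing_mm[0] * self.row_dir
            + cols[..., None] * self.pixel_spacing_mm[1] * self.col_dir
        )

    def allclose(self, other: "SliceGeometry", atol: float = 1e-9) -> bool:
        return (
            np.allclose(self.row_dir, other.row_dir, atol=atol)
            and np.allclose(self.col_dir, other.col_dir, atol=atol)
            and np.allclose(self.position_mm, other.position_mm, atol=atol)
            and np.allclose(self.pixel_spacing_mm, other.pixel_spacing_mm, atol=atol)
            and (self.n_rows, self.n_cols) == (other.n_rows, other.n_cols)
        )


class Modality(str, Enum):
    T1MAP = "T1MAP"
    IRW = "IRW"
    CINE = "CINE"
    LGE = "LGE"
    VNE = "VNE"


@dataclass
class ImageSlice:
    """A 2-D image (T1 map in ms, otherwise arbitrary units) plus geometry."""

    pixels: np.ndarray
    geometry: SliceGeometry
    modality: Modality
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.modality = Modality(self.modality)
        if self.pixels.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise GeometryError(
                f"pixel array {self.pixels.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if self.modality is Modality.T1MAP and np.any(self.pixels < 0):
            raise ValueError("T1 map pixels must be non-negative (ms)")


@dataclass
class CineStack:
    """Ordered cine frames over one cardiac cycle, sharing one geometry."""

    frames: list[ImageSlice]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("cine stack must contain at least one frame")
        g = self.frames[0].geometry
        for f in self.frames[1:]:
            if f.geometry is not g and not f.geometry.allclose(g):
                raise GeometryError("cine frames do not share one geometry")

    @property
    def geometry(self) -> SliceGeometry:
        return self.frames[0].geometry

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class NativeTriplet:
    """Co-registered native inputs (and optional LGE target) on the T1 grid."""

    t1_map: ImageSlice
    irw: list[ImageSlice]
    cine: list[ImageSlice]
    lge: Optional[ImageSlice] = None

    def __post_init__(self) -> None:
        if not self.irw or not self.cine:
            raise ValueError("irw and cine members must be non-empty")
        g = self.t1_map.geometry
        members = self.irw + self.cine + ([self.lge] if self.lge is not None else [])
        for s in members:
            if s.geometry is not g and not s.geometry.allclose(g):
                raise GeometryError("triplet members do not share the T1 grid")


def slice_normal(g: SliceGeometry) -> np.ndarray:
    """Unit normal of the slice plane, ``row_dir × col_dir``."""
    n = np.cross(g.row_dir, g.col_dir)
    return n / np.linalg.norm(n)


def plane_cosine_similarity(a: SliceGeometry, b: SliceGeometry) -> float:
    """|n_a · n_b| — 1 for parallel planes, 0 for perpendicular."""
    return float(abs(slice_normal(a) @ slice_normal(b)))


def slice_location_difference(a: SliceGeometry, b: SliceGeometry) -> float:
    """Distance (mm) between the two slice planes along their mean normal.

    Defined as |(position_a − position_b) · n̄| with n̄ the mean of the two
    unit normals (sign-aligned).  In-plane shifts contribute nothing.
    """
    na, nb = slice_normal(a), slice_normal(b)
    if abs(float(na @ nb)) < 1e-3:
        raise GeometryError("slice planes are near-perpendicular; location undefined")
    if float(na @ nb) < 0:
        nb = -nb
    mean_n = na + nb
    mean_n /= np.linalg.norm(mean_n)
    return float(abs((a.position_mm - b.position_mm) @ mean_n))


@dataclass
class MatchReport:
    """Outcome of triplet matching: index triples plus an exclusion log.

    ``triplets`` holds (t1_index, cine_index, lge_index).  ``exclusions`` is a
    list of dicts with keys kind/index/t1_index/reason/cosine/distance_mm.
    """

    triplets: list[tuple[int, int, int]]
    exclusions: list[dict]


def _pair_metrics(ref: SliceGeometry, cand: SliceGeometry) -> tuple[float, Optional[float]]:
    cos = plane_cosine_similarity(ref, cand)
    try:
        dist = slice_location_difference(ref, cand)
    except GeometryError:
        dist = None
    return cos, dist


def _assign(
    t1_geoms: Sequence[SliceGeometry],
    cand_geoms: Sequence[SliceGeometry],
    kind: str,
    cos_gate: float,
    dist_gate: float,
    exclusions: list[dict],
) -> dict[int, int]:
    """One-to-one T1→candidate assignment, best (distance, cosine deviation) first."""
    edges = []
    best_failure: dict[int, dict] = {}
    for j, cg in enumerate(cand_geoms):
        for i, tg in enumerate(t1_geoms):
            cos, dist = _pair_metrics(tg, cg)
            if cos > cos_gate and dist is not None and dist < dist_gate:
                edges.append((dist, 1.0 - cos, i, j))
            else:
                if dist is not None and cos > cos_gate:
                    reason = f"slice location difference {dist:.2f} mm >= {dist_gate} mm"
                else:
                    reason = f"plane cosine similarity {cos:.4f} <= {cos_gate}"
                rec = {
                    "kind": kind,
                    "index": j,
                    "t1_index": i,
                    "reason": reason,
                    "cosine": cos,
                    "distance_mm": dist,
                }
                # keep the least-bad failure per candidate for the log:
                # highest cosine, then smallest location difference
                prev = best_failure.get(j)
                key = (cos, -(dist if dist is not None else np.inf))
                prev_key = (None if prev is None else
                            (prev["cosine"],
                             -(prev["distance_mm"]
                               if prev["distance_mm"] is not None else np.inf)))
                if prev is None or key > prev_key:
                    best_failure[j] = rec
    edges.sort()
    used_t1: set[int] = set()
    used_cand: set[int] = set()
    assignment: dict[int, int] = {}
    for _, _, i, j in edges:
        if i in used_t1 or j in used_cand:
            continue
        assignment[i] = j
        used_t1.add(i)
        used_cand.add(j)
    for j, rec in sorted(best_failure.items()):
        if j not in used_cand:
            exclusions.append(rec)
    return assignment


def match_triplets(
    t1s: Sequence,
    cines: Sequence,
    lges: Sequence,
    cosine_gate: float = COSINE_SIMILARITY_GATE,
    distance_gate_mm: float = LOCATION_DIFFERENCE_GATE_MM,
) -> MatchReport:
    """Pair each T1 map with at most one cine stack and one LGE slice.

    Inputs are sequences of objects exposing ``.geometry`` (``ImageSlice`` or
    ``CineStack``).  A pair qualifies when plane cosine similarity exceeds
    ``cosine_gate`` and slice-location difference is below ``distance_gate_mm``;
    assignment is one-to-one with ties resolved by smallest location
    difference, then smallest cosine deviation.  Unmatched cine/LGE slices are
    logged with the violated criterion, never fatal.
    """
    t1_geoms = [s.geometry for s in t1s]
    exclusions: list[dict] = []
    cine_assign = _assign(t1_geoms, [s.geometry for s in cines], "CINE",
                          cosine_gate, distance_gate_mm, exclusions)
    lge_assign = _assign(t1_geoms, [s.geometry for s in lges], "LGE",
                         cosine_gate, distance_gate_mm, exclusions)
    triplets = [
        (i, cine_assign[i], lge_assign[i])
        for i in range(len(t1s))
        if i in cine_assign and i in lge_assign
    ]
    return MatchReport(triplets=triplets, exclusions=exclusions)


def resample_to_reference(
    moving: ImageSlice,
    reference: SliceGeometry,
    fill_value: float = 0.0,
    cosine_gate: float = COSINE_SIMILARITY_GATE,
    distance_gate_mm: float = LOCATION_DIFFERENCE_GATE_MM,
) -> ImageSlice:
    """Bilinearly resample ``moving`` onto the reference (T1-map) grid.

    The two planes must pass the matching gates.  Reference pixel centres are
    mapped to patient space and then into the moving image's pixel
    coordinates; intensities are bilinearly interpolated and out-of-field
    pixels receive ``fill_value`` (recorded in ``meta['fill_value']``).
    """
    cos, dist = _pair_metrics(reference, moving.geometry)
    if not (cos > cosine_gate and dist is not None and dist < distance_gate_mm):
        raise GeometryError(
            f"moving slice fails matching gates (cosine {cos:.4f}, distance "
            f"{'n/a' if dist is None else f'{dist:.2f} mm'})"
        )
    rr, cc = np.meshgrid(np.arange(reference.n_rows), np.arange(reference.n_cols),
                         indexing="ij")
    pts = reference.pixel_to_patient(rr, cc)  # (R, C, 3)
    g = moving.geometry
    d = pts - g.position_mm
    rows = (d @ g.row_dir) / g.pixel_spacing_mm[0]
    cols = (d @ g.col_dir) / g.pixel_spacing_mm[1]
    out = ndimage.map_coordinates(
        np.asarray(moving.pixels, dtype=float),
        np.stack([rows, cols]),
        order=1,
        mode="constant",
        cval=fill_value,
    )
    meta = dict(moving.meta)
    meta["fill_value"] = fill_value
    meta["resampled"] = True
    return ImageSlice(pixels=out, geometry=reference, modality=moving.modality, meta=meta)
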