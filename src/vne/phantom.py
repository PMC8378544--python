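"""Synthetic short-axis cardiac phantom studies.

Emulates the acquisition unit the method trains on — matched per-slice
triplets of native T1 map, inversion-recovery-weighted images and cine
frames, plus an LGE target — with ground-truth lesion masks, ROI
definitions and patient-space geometry metadata, so that slice matching,
generator training, lesion quantification and the agreement statistics are
all exercisable without any external data.

Anatomy is a concentric annulus (left-ventricular myocardium) around a
blood pool, with asymmetric septal thickening and optional wedge-shaped
lesions placed preferentially near the right-ventricular insertion points.
Tissue T1 defaults (normal myocardium 950 ms, blood 1600 ms, lesion
+100–200 ms) are synthetic conventions chosen for clear class separation
and are freely configurable; no claim of physiological calibration is made.
``noise_sd`` is an additive Gaussian noise scale expressed as a fraction of
each modality's dynamic range (≈1000 ms for T1 maps, 1.0 for the
unit-scaled image modalities).

All randomness flows through one seeded generator per study: identical spec
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    CineStack,
    GeometryError,
    ImageSlice,
    Modality,
    NativeTriplet,
    SliceGeometry,
)
from .quantify import (
    LGE_PERCENTILES,
    RoiSet,
    contours_to_mask,
    points_in_polygon,
    threshold_value,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomSlice",
    "PhantomStudy",
    "generate_study",
    "lge_forward_model",
    "invert_lge_forward_model",
    "jitter_metadata",
    "LGE_NULL_LEVEL",
    "LGE_SIGNAL_RANGE",
    "LGE_T1_DECAY_MS",
    "LGE_BLOOD_LEVEL",
    "LGE_BACKGROUND_LEVEL",
]

# LGE forward-model constants (unit-scaled image intensities): nulled normal
# myocardium near the image minimum, lesion intensity saturating
# monotonically with T1 elevation, bright blood pool.
LGE_NULL_LEVEL = 0.05
LGE_SIGNAL_RANGE = 0.9
LGE_T1_DECAY_MS = 200.0
LGE_BLOOD_LEVEL = 0.85
LGE_BACKGROUND_LEVEL = 0.02

_CINE_BLOOD, _CINE_MYO, _CINE_BG = 0.9, 0.25, 0.08
_IRW_TI_MIN_MS, _IRW_TI_MAX_MS = 100.0, 5000.0


@dataclass
class PhantomSpec:
    """Study-generation parameters; the seed fully determines the output."""

    image_size: int = 64
    n_patients: int = 10
    slices_per_patient: int = 3
    pixel_spacing_mm: float = 1.0
    lesion_probability: float = 0.7
    lesion_t1_elevation_ms: tuple[float, float] = (150.0, 40.0)
    noise_sd: float = 0.02
    cine_frames: int = 12
    irw_images: int = 7
    metadata_jitter: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    # synthetic tissue T1 conventions (ms), configurable
    t1_normal_ms: float = 950.0
    t1_blood_ms: float = 1600.0
    t1_background_ms: float = 300.0
    slice_gap_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("invalid spec field image_size: must be >= 32")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError("invalid spec field lesion_probability: must be in [0, 1]")
        for name in ("n_patients", "slices_per_patient", "cine_frames", "irw_images"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid spec field {name}: must be >= 1")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("invalid spec field pixel_spacing_mm: must be > 0")
        if self.noise_sd < 0:
            raise ValueError("invalid spec field noise_sd: must be >= 0")
        if min(self.metadata_jitter) < 0:
            raise ValueError("invalid spec field metadata_jitter: must be >= 0")
        if not self.t1_blood_ms > self.t1_normal_ms > self.t1_background_ms >= 0:
            raise ValueError(
                "invalid spec field t1_*_ms: require blood > normal > background >= 0"
            )


@dataclass
class GroundTruth:
    """Per-slice truth recorded at generation time.

    ``true_burden_by_threshold`` maps each default percentile to the
    fraction of myocardial pixels of the noise-free LGE image at/above that
    threshold (lesion pixels with sub-threshold elevation are genuinely
    invisible and are not counted).  The raw areas are kept so per-patient
    pooled burdens can be recomputed exactly.
    """

    lesion_mask: np.ndarray
    myocardium_mask: np.ndarray
    true_burden_by_threshold: dict[float, float]
    lesion_area_px_by_threshold: dict[float, int]
    myocardial_area_px: int

    def __post_init__(self) -> None:
        if np.any(self.lesion_mask & ~self.myocardium_mask):
            raise ValueError("lesion_mask must be a subset of myocardium_mask")
        for v in self.true_burden_by_threshold.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("burden fractions must be in [0, 1]")


@dataclass
class PhantomSlice:
    """One generated slice: triplet on the T1 grid plus ROIs and truth.

    ``raw_cine`` / ``raw_lge`` carry the (possibly jittered) acquisition
    geometry for exercising the matching stage; the triplet itself is on the
    T1 grid.
    """

    patient_id: int
    slice_index: int
    triplet: NativeTriplet
    roi: RoiSet
    truth: GroundTruth
    raw_cine: CineStack
    raw_lge: ImageSlice


@dataclass
class PhantomStudy:
    spec: PhantomSpec
    slices: list[PhantomSlice]

    def __iter__(self) -> Iterator[PhantomSlice]:
        return iter(self.slices)

    def __len__(self) -> int:
        return len(self.slices)

    def patients(self) -> dict[int, list[PhantomSlice]]:
        out: dict[int, list[PhantomSlice]] = {}
        for s in self.slices:
            out.setdefault(s.patient_id, []).append(s)
        return out


def lge_forward_model(
    t1_map: ImageSlice,
    lesion_mask: np.ndarray,
    myocardium_mask: np.ndarray,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ImageSlice:
    """Map a T1 map to a synthetic LGE appearance.

    Within the myocardium the intensity is a strictly monotone, saturating
    function of T1 elevation above the normal-myocardium reference (the
    median T1 of non-lesion myocardial pixels):

        I = null + range · (1 − exp(−ΔT1 / decay)),  ΔT1 = max(T1 − T1_ref, 0)

    so normal myocardium sits at the nulled level and lesions brighten with
    elevation.  Outside the myocardium, long-T1 pixels (blood) are bright
    and the rest dark.  Deterministic at ``noise_sd=0``.
    """
    t1 = np.asarray(t1_map.pixels, dtype=float)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if lesion_mask.shape != t1.shape or myocardium_mask.shape != t1.shape:
        raise GeometryError("masks must be on the T1 grid")
    normal = myocardium_mask & ~lesion_mask
    t1_ref = float(np.median(t1[normal])) if normal.any() else float(np.median(t1))
    out = np.full_like(t1, LGE_BACKGROUND_LEVEL)
    blood_like = ~myocardium_mask & (t1 > t1_ref + 300.0)
    out[blood_like] = LGE_BLOOD_LEVEL
    delta = np.clip(t1[myocardium_mask] - t1_ref, 0.0, None)
    out[myocardium_mask] = LGE_NULL_LEVEL + LGE_SIGNAL_RANGE * (
        1.0 - np.exp(-delta / LGE_T1_DECAY_MS)
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return ImageSlice(pixels=out, geometry=t1_map.geometry, modality=Modality.LGE,
                      meta={"t1_ref_ms": t1_ref})


def invert_lge_forward_model(intensity: np.ndarray) -> np.ndarray:
    """T1 elevation (ms) recovering the forward model inside the myocardium."""
    frac = np.clip((np.asarray(intensity, dtype=float) - LGE_NULL_LEVEL)
                   / LGE_SIGNAL_RANGE, 0.0, 1.0 - 1e-12)
    return -LGE_T1_DECAY_MS * np.log(1.0 - frac)


def jitter_metadata(
    geometry: SliceGeometry,
    translation_mm: np.ndarray,
    rotation_deg: float,
    seed: int = 0,
) -> SliceGeometry:
    """Perturb slice geometry: translate the position and/or rotate the plane.

    The rotation is about an in-plane axis (through the slice position)
    whose in-plane direction is drawn from ``seed``, so a rotation by angle
    α tilts the slice normal by exactly α.  Zero perturbation returns the
    input unchanged.
    """
    translation_mm = np.asarray(translation_mm, dtype=float)
    if not np.any(translation_mm) and rotation_deg == 0:
        return geometry
    row_dir, col_dir = geometry.row_dir, geometry.col_dir
    if rotation_deg != 0:
        psi = np.random.default_rng(seed).uniform(0.0, 2 * np.pi)
        axis = np.cos(psi) * row_dir + np.sin(psi) * col_dir
        rot = Rotation.from_rotvec(np.deg2rad(rotation_deg) * axis)
        row_dir = rot.apply(row_dir)
        col_dir = rot.apply(col_dir)
        # re-orthonormalise against accumulated float error
        row_dir = row_dir / np.linalg.norm(row_dir)
        col_dir = col_dir - (col_dir @ row_dir) * row_dir
        col_dir = col_dir / np.linalg.norm(col_dir)
    return SliceGeometry(
        row_dir=row_dir,
        col_dir=col_dir,
        position_mm=geometry.position_mm + translation_mm,
        pixel_spacing_mm=geometry.pixel_spacing_mm,
        n_rows=geometry.n_rows,
        n_cols=geometry.n_cols,
    )


def _circle_contour(center: np.ndarray, radius_fn, n_points: int = 72) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    r = radius_fn(theta)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _make_rois(
    center: np.ndarray,
    epi: np.ndarray,
    endo: np.ndarray,
    myo_mask: np.ndarray,
    lesion_mask: np.ndarray,
    lesion_angles: list[float],
    inside_endo: np.ndarray,
    theta_px: np.ndarray,
) -> RoiSet:
    # remote ROI: myocardial sector farthest (in angle) from every lesion
    candidates = np.deg2rad(np.arange(0, 360, 30))
    if lesion_angles:
        la = np.asarray(lesion_angles)

        def ang_dist(t):
            d = np.abs(np.angle(np.exp(1j * (la - t))))
            return d.min()

        scores = [ang_dist(t) for t in candidates]
        theta_r = candidates[int(np.argmax(scores))]
    else:
        theta_r = candidates[0]
    for half_width in (np.deg2rad(15), np.deg2rad(30), np.deg2rad(60), np.pi):
        in_sector = np.abs(np.angle(np.exp(1j * (theta_px - theta_r)))) <= half_width
        remote = myo_mask & ~lesion_mask & in_sector
        if remote.sum() >= 5:
            break
    remote_idx = np.argwhere(remote)
    # blood-pool ROI: small central disk well inside the endocardial border
    rr, cc = np.indices(myo_mask.shape)
    rho = np.hypot(rr - center[0], cc - center[1])
    blood = inside_endo & (rho <= 3.0)
    if blood.sum() < 3:
        blood = inside_endo & (rho <= 5.0)
    blood_idx = np.argwhere(blood)
    return RoiSet(
        epicardial_contour=epi,
        endocardial_contour=endo,
        remote_roi=remote_idx,
        bloodpool_roi=blood_idx,
    )


def generate_study(spec: PhantomSpec) -> PhantomStudy:
    """Generate a multi-patient, multi-slice synthetic study.

    Every slice yields a co-registered :class:`NativeTriplet` (T1 map,
    IR-weighted ladder, cine frames, LGE target) on the T1 grid, the ROI set
    anchoring quantification, and the recorded ground truth.  Noise-free
    tissue classes satisfy blood T1 > lesion T1 > normal myocardial T1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    tis = np.geomspace(_IRW_TI_MIN_MS, _IRW_TI_MAX_MS, spec.irw_images)
    slices: list[PhantomSlice] = []
    for pid in range(spec.n_patients):
        severity = rng.uniform(0.2, 1.0)
        patient_offset = rng.uniform(-3.0, 3.0, size=2)
        r_epi = n * rng.uniform(0.26, 0.33)
        wall_base = n * rng.uniform(0.08, 0.095)
        septal_factor = rng.uniform(1.2, 1.8)  # asymmetric septal hypertrophy
        theta_sept = np.pi  # septum fixed at 180 degrees, patient frame
        for sl in range(spec.slices_per_patient):
            center = np.array([n / 2, n / 2]) + patient_offset + rng.uniform(-1, 1, 2)
            taper = 1.0 - 0.06 * sl  # mild apical taper along the stack
            re_ = r_epi * taper

            def wall(theta):
                bump = np.exp(-0.5 * (np.angle(np.exp(1j * (theta - theta_sept)))
                                      / np.deg2rad(50)) ** 2)
                return wall_base * (1.0 + (septal_factor - 1.0) * bump)

            epi = _circle_contour(center, lambda t: np.full_like(t, re_))
            endo = _circle_contour(center, lambda t: re_ - wall(t))
            geometry = SliceGeometry(
                row_dir=np.array([1.0, 0.0, 0.0]),
                col_dir=np.array([0.0, 1.0, 0.0]),
                position_mm=np.array([
                    -n / 2 * spec.pixel_spacing_mm,
                    -n / 2 * spec.pixel_spacing_mm,
                    pid * 100.0 + sl * spec.slice_gap_mm,
                ]),
                pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
                n_rows=n,
                n_cols=n,
            )
            roi_proto_epi, roi_proto_endo = epi, endo
            myo_mask = contours_to_mask(
                RoiSet(roi_proto_epi, roi_proto_endo, np.array([[0, 0]]),
                       np.array([[0, 0]])),
                geometry,
            )
            rr, cc = np.indices((n, n))
            pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
            inside_endo = points_in_polygon(pts, endo).reshape(n, n) & ~myo_mask
            theta_px = np.arctan2(cc - center[1], rr - center[0])

            # lesions: wedges near the RV insertion points, extent scaling
            # with patient severity (placement cosmetic, not load-bearing)
            lesion_mask = np.zeros((n, n), dtype=bool)
            lesion_angles: list[float] = []
            elevation = np.zeros((n, n))
            if rng.uniform() < spec.lesion_probability:
                for _ in range(rng.integers(1, 3)):
                    insertion = theta_sept + np.deg2rad(rng.choice([-35.0, 35.0]))
                    ang = insertion + np.deg2rad(rng.uniform(-15, 15))
                    half_w = np.deg2rad(8.0 + 40.0 * severity * rng.uniform(0.5, 1.0))
                    sector = np.abs(np.angle(np.exp(1j * (theta_px - ang)))) <= half_w
                    wedge = myo_mask & sector
                    if not wedge.any():
                        continue
                    mu, sd = spec.lesion_t1_elevation_ms
                    elev = float(np.clip(rng.normal(mu, sd), 50.0, 500.0))
                    elevation[wedge] = np.maximum(elevation[wedge], elev)
                    lesion_mask |= wedge
                    lesion_angles.append(float(ang))

            # T1 map: distinct tissue classes, lesion elevated
            t1_clean = np.full((n, n), spec.t1_background_ms)
            t1_clean[inside_endo] = spec.t1_blood_ms
            t1_clean[myo_mask] = spec.t1_normal_ms
            t1_clean[lesion_mask] += elevation[lesion_mask]
            t1_slice_clean = ImageSlice(t1_clean, geometry, Modality.T1MAP)

            # noise-free LGE defines the recorded ground truth
            lge_clean = lge_forward_model(t1_slice_clean, lesion_mask, myo_mask)
            roi = _make_rois(center, epi, endo, myo_mask, lesion_mask,
                             lesion_angles, inside_endo, theta_px)
            remote_mean = roi.roi_mean(lge_clean, "remote_roi")
            blood_mean = roi.roi_mean(lge_clean, "bloodpool_roi")
            myo_area = int(myo_mask.sum())
            burdens: dict[float, float] = {}
            areas: dict[float, int] = {}
            for p in LGE_PERCENTILES:
                thr = threshold_value(remote_mean, blood_mean, p)
                area = int((myo_mask & (lge_clean.pixels >= thr)).sum())
                areas[p] = area
                burdens[p] = area / myo_area
            truth = GroundTruth(
                lesion_mask=lesion_mask,
                myocardium_mask=myo_mask,
                true_burden_by_threshold=burdens,
                lesion_area_px_by_threshold=areas,
                myocardial_area_px=myo_area,
            )

            # observed modalities (noise applied on top of the clean signal)
            def noisy(img: np.ndarray, scale: float) -> np.ndarray:
                if spec.noise_sd == 0:
                    return img.copy()
                return img + rng.normal(0.0, spec.noise_sd * scale, size=img.shape)

            t1_obs = np.clip(noisy(t1_clean, 1000.0), 0.0, None)
            t1_slice = ImageSlice(t1_obs, geometry, Modality.T1MAP)
            lge_pixels = lge_clean.pixels if spec.noise_sd == 0 else noisy(
                lge_clean.pixels, 1.0)
            lge_slice = ImageSlice(lge_pixels, geometry, Modality.LGE,
                                   meta=dict(lge_clean.meta))

            irw = [
                ImageSlice(noisy(np.abs(1.0 - 2.0 * np.exp(-ti / t1_clean)), 1.0),
                           geometry, Modality.IRW, meta={"ti_ms": float(ti)})
                for ti in tis
            ]
            cine_frames = []
            rho = np.hypot(rr - center[0], cc - center[1])
            for f in range(spec.cine_frames):
                phase = 2 * np.pi * f / spec.cine_frames
                k_endo = 1.0 - 0.12 * (1.0 - np.cos(phase)) / 2.0
                k_epi = 1.0 - 0.04 * (1.0 - np.cos(phase)) / 2.0
                r_endo_px = (re_ - wall(theta_px)) * k_endo
                frame = np.full((n, n), _CINE_BG)
                frame[(rho <= re_ * k_epi) & (rho >= r_endo_px)] = _CINE_MYO
                frame[rho < r_endo_px] = _CINE_BLOOD
                cine_frames.append(
                    ImageSlice(noisy(frame, 1.0), geometry, Modality.CINE,
                               meta={"phase": float(phase)})
                )

            # acquisition-geometry copies, optionally jittered, for matching
            jt, jr = spec.metadata_jitter
            def acq_geometry(tag: int) -> SliceGeometry:
                if jt == 0 and jr == 0:
                    return geometry
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                translation = jt * rng.uniform() * direction
                rotation = jr * rng.uniform()
                return jitter_metadata(geometry, translation, rotation,
                                       seed=int(rng.integers(2**31)))
            cine_acq_geometry = acq_geometry(0)
            raw_cine = CineStack(
                [ImageSlice(f.pixels, cine_acq_geometry, Modality.CINE, dict(f.meta))
                 for f in cine_frames]
            )
            raw_lge = ImageSlice(lge_slice.pixels, acq_geometry(1), Modality.LGE,
                                 dict(lge_slice.meta))

            triplet = NativeTriplet(t1_map=t1_slice, irw=irw, cine=cine_frames,
                                    lge=lge_slice)
            slices.append(PhantomSlice(
                patient_id=pid, slice_index=sl, triplet=triplet, roi=roi,
                truth=truth, raw_cine=raw_cine, raw_lge=raw_lge,
            ))
    return PhantomStudy(spec=spec, slices=slices)
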