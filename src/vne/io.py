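"""Study serialization: NIfTI images, JSON sidecars, CSV manifests.

A written study directory contains, per slice, one NIfTI file per modality
(cine and IR-weighted stacks as 3-D volumes, frames/inversion times along
the third axis), a JSON sidecar holding the geometry, ROI contours
(ordered [row, col] float lists), acquisition geometries and ground truth,
plus a top-level ``manifest.csv`` and the generating ``spec.json``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import CineStack, ImageSlice, Modality, NativeTriplet, SliceGeometry
from .phantom import GroundTruth, PhantomSlice, PhantomSpec, PhantomStudy
from .quantify import RoiSet

__all__ = ["write_study", "read_study", "geometry_to_dict", "geometry_from_dict"]


def geometry_to_dict(g: SliceGeometry) -> dict:
    return {
        "row_dir": g.row_dir.tolist(),
        "col_dir": g.col_dir.tolist(),
        "position_mm": g.position_mm.tolist(),
        "pixel_spacing_mm": list(g.pixel_spacing_mm),
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
    }


def geometry_from_dict(d: dict) -> SliceGeometry:
    return SliceGeometry(
        row_dir=np.asarray(d["row_dir"]),
        col_dir=np.asarray(d["col_dir"]),
        position_mm=np.asarray(d["position_mm"]),
        pixel_spacing_mm=tuple(d["pixel_spacing_mm"]),
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
    )


def _affine(g: SliceGeometry) -> np.ndarray:
    normal = np.cross(g.row_dir, g.col_dir)
    aff = np.eye(4)
    aff[:3, 0] = g.row_dir * g.pixel_spacing_mm[0]
    aff[:3, 1] = g.col_dir * g.pixel_spacing_mm[1]
    aff[:3, 2] = normal
    aff[:3, 3] = g.position_mm
    return aff


def _save_nii(path: Path, pixels: np.ndarray, g: SliceGeometry) -> None:
    nib.save(nib.Nifti1Image(np.asarray(pixels, dtype=np.float32), _affine(g)),
             str(path))


def _mask_to_pixels(mask: np.ndarray) -> list[list[int]]:
    return np.argwhere(np.asarray(mask, dtype=bool)).tolist()


def _pixels_to_mask(px: list, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if px:
        idx = np.asarray(px, dtype=int)
        mask[idx[:, 0], idx[:, 1]] = True
    return mask


def write_study(study: PhantomStudy, out_dir) -> Path:
    """Write a study directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(json.dumps(asdict(study.spec), indent=1))
    rows = []
    for s in study.slices:
        stem = f"p{s.patient_id:03d}_s{s.slice_index}"
        g = s.triplet.t1_map.geometry
        files = {
            "T1MAP": (f"{stem}_t1map.nii", s.triplet.t1_map.pixels),
            "IRW": (f"{stem}_irw.nii",
                    np.stack([im.pixels for im in s.triplet.irw], axis=-1)),
            "CINE": (f"{stem}_cine.nii",
                     np.stack([im.pixels for im in s.triplet.cine], axis=-1)),
            "LGE": (f"{stem}_lge.nii", s.triplet.lge.pixels),
        }
        for modality, (name, pixels) in files.items():
            _save_nii(out / name, pixels, g)
            rows.append({"patient": s.patient_id, "slice": s.slice_index,
                         "modality": modality, "path": name,
                         "sidecar": f"{stem}.json"})
        sidecar = {
            "patient": s.patient_id,
            "slice": s.slice_index,
            "geometry": geometry_to_dict(g),
            "acquisition_geometry": {
                "CINE": geometry_to_dict(s.raw_cine.geometry),
                "LGE": geometry_to_dict(s.raw_lge.geometry),
            },
            "irw_ti_ms": [im.meta.get("ti_ms") for im in s.triplet.irw],
            "roi": {
                "epicardial_contour": s.roi.epicardial_contour.tolist(),
                "endocardial_contour": s.roi.endocardial_contour.tolist(),
                "remote_roi": s.roi.remote_roi.tolist(),
                "bloodpool_roi": s.roi.bloodpool_roi.tolist(),
            },
            "ground_truth": {
                "lesion_pixels": _mask_to_pixels(s.truth.lesion_mask),
                "myocardium_pixels": _mask_to_pixels(s.truth.myocardium_mask),
                "true_burden_by_threshold": {
                    str(k): v for k, v in s.truth.true_burden_by_threshold.items()},
                "lesion_area_px_by_threshold": {
                    str(k): v for k, v in s.truth.lesion_area_px_by_threshold.items()},
                "myocardial_area_px": s.truth.myocardial_area_px,
            },
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_study(study_dir) -> PhantomStudy:
    """Reload a study directory written by :func:`write_study`."""
    d = Path(study_dir)
    spec_d = json.loads((d / "spec.json").read_text())
    for key in ("lesion_t1_elevation_ms", "metadata_jitter"):
        spec_d[key] = tuple(spec_d[key])
    spec = PhantomSpec(**spec_d)
    manifest = pd.read_csv(d / "manifest.csv")
    slices: list[PhantomSlice] = []
    for (pid, sl), grp in manifest.groupby(["patient", "slice"], sort=True):
        sidecar = json.loads((d / grp.iloc[0]["sidecar"]).read_text())
        g = geometry_from_dict(sidecar["geometry"])
        shape = (g.n_rows, g.n_cols)
        vols = {
            row["modality"]: np.asarray(
                nib.load(str(d / row["path"])).dataobj, dtype=float)
            for _, row in grp.iterrows()
        }
        t1 = ImageSlice(vols["T1MAP"], g, Modality.T1MAP)
        irw = [ImageSlice(vols["IRW"][..., i], g, Modality.IRW,
                          meta={"ti_ms": sidecar["irw_ti_ms"][i]})
               for i in range(vols["IRW"].shape[-1])]
        cine = [ImageSlice(vols["CINE"][..., i], g, Modality.CINE)
                for i in range(vols["CINE"].shape[-1])]
        lge = ImageSlice(vols["LGE"], g, Modality.LGE)
        roi = RoiSet(
            epicardial_contour=np.asarray(sidecar["roi"]["epicardial_contour"]),
            endocardial_contour=np.asarray(sidecar["roi"]["endocardial_contour"]),
            remote_roi=np.asarray(sidecar["roi"]["remote_roi"]),
            bloodpool_roi=np.asarray(sidecar["roi"]["bloodpool_roi"]),
        )
        gt = sidecar["ground_truth"]
        truth = GroundTruth(
            lesion_mask=_pixels_to_mask(gt["lesion_pixels"], shape),
            myocardium_mask=_pixels_to_mask(gt["myocardium_pixels"], shape),
            true_burden_by_threshold={
                float(k): v for k, v in gt["true_burden_by_threshold"].items()},
            lesion_area_px_by_threshold={
                float(k): v for k, v in gt["lesion_area_px_by_threshold"].items()},
            myocardial_area_px=int(gt["myocardial_area_px"]),
        )
        g_cine = geometry_from_dict(sidecar["acquisition_geometry"]["CINE"])
        g_lge = geometry_from_dict(sidecar["acquisition_geometry"]["LGE"])
        slices.append(PhantomSlice(
            patient_id=int(pid), slice_index=int(sl),
            triplet=NativeTriplet(t1_map=t1, irw=irw, cine=cine, lge=lge),
            roi=roi, truth=truth,
            raw_cine=CineStack([ImageSlice(f.pixels, g_cine, Modality.CINE)
                                for f in cine]),
            raw_lge=ImageSlice(lge.pixels, g_lge, Modality.LGE),
        ))
    return PhantomStudy(spec=spec, slices=slices)
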