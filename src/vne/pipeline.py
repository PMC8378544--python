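"""End-to-end orchestration: simulate → match → train → infer → quantify → evaluate.

A run is driven by one :class:`RunConfig` and one global seed.  Patients are
randomised into a development group and a held-out test group; the
development group is further split into training (90%) and validation (10%)
patients inside :func:`vne.model.train`.  Slices of a test patient are
never seen during training.  Every stage's parameters and outputs are
logged and written into the run directory, so each output file is traceable
to the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .evaluate import AgreementReport, PairedMeasurements, agreement_report
from .geometry import match_triplets
from .model import GeneratorConfig, TrainedModel, infer_vne, save_checkpoint, train
from .phantom import PhantomSpec, PhantomStudy, generate_study
from .quantify import LGE_PERCENTILES, VNE_ADJUSTED_PERCENTILES, quantify_patient

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "patient_burdens",
           "split_patients"]

log = logging.getLogger("vne")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cosine_gate: float = 0.9
    distance_gate_mm: float = 4.0
    percentiles: tuple[float, ...] = LGE_PERCENTILES
    vne_adjusted_percentiles: tuple[float, ...] = VNE_ADJUSTED_PERCENTILES
    test_fraction: float = 0.25
    seed: int = 0
    out_dir: str = "vne_run"
    log_level: str = "INFO"
    write_images: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        # one global seed drives every stochastic stage
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed)
        self.generator = dataclasses.replace(self.generator, seed=self.seed + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for key in ("lesion_t1_elevation_ms", "metadata_jitter"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomSpec(**ph)
        if "generator" in kwargs:
            gc = dict(kwargs["generator"])
            if "loss_weights" in gc:
                gc["loss_weights"] = tuple(gc["loss_weights"])
            kwargs["generator"] = GeneratorConfig(**gc)
        for key in ("percentiles", "vne_adjusted_percentiles"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class PipelineResult:
    """Objects and file paths produced by one pipeline run."""

    config: RunConfig
    study: PhantomStudy
    model: TrainedModel
    train_patients: list[int]
    test_patients: list[int]
    burdens: pd.DataFrame
    reports: dict[str, AgreementReport]
    run_dir: Path


def split_patients(patient_ids: list[int], test_fraction: float,
                   seed: int) -> tuple[list[int], list[int]]:
    """Seeded patient-level development/test split (never by slice)."""
    rng = np.random.default_rng(seed)
    ids = sorted(set(patient_ids))
    order = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = sorted(ids[i] for i in order[:n_test])
    dev = sorted(set(ids) - set(test))
    return dev, test


def patient_burdens(study: PhantomStudy, patient_ids, images_by_slice,
                    percentiles) -> pd.DataFrame:
    """Per-patient pooled burdens of given per-slice images at percentiles.

    ``images_by_slice`` maps id(slice record is positional): a list aligned
    with ``study.slices`` giving the image to quantify for each slice (or
    None to skip).
    """
    rows = []
    by_patient: dict[int, list] = {}
    for s, img in zip(study.slices, images_by_slice):
        if img is None or s.patient_id not in patient_ids:
            continue
        by_patient.setdefault(s.patient_id, []).append((img, s.roi))
    for pid in sorted(by_patient):
        burdens = quantify_patient(by_patient[pid], percentiles)
        for p, b in burdens.items():
            rows.append({"patient": pid, "percentile": p, "burden": b})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; returns results and writes the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(run_dir / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, run_dir)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, run_dir: Path) -> PipelineResult:
    config.to_yaml(run_dir / "config.yaml")

    log.info("simulate: %d patients x %d slices, seed %d",
             config.phantom.n_patients, config.phantom.slices_per_patient,
             config.seed)
    study = generate_study(config.phantom)
    if config.write_images:
        vio.write_study(study, run_dir / "study")

    log.info("match: gates cosine>%.2f, distance<%.1f mm",
             config.cosine_gate, config.distance_gate_mm)
    t1s = [s.triplet.t1_map for s in study.slices]
    report = match_triplets(t1s, [s.raw_cine for s in study.slices],
                            [s.raw_lge for s in study.slices],
                            cosine_gate=config.cosine_gate,
                            distance_gate_mm=config.distance_gate_mm)
    matched_t1 = {t for t, _, _ in report.triplets}
    match_rows = [{"t1_index": t, "cine_index": c, "lge_index": l,
                   "included": True, "reason": ""} for t, c, l in report.triplets]
    match_rows += [{"t1_index": e["t1_index"], "cine_index": None,
                    "lge_index": e["index"] if e["kind"] == "LGE" else None,
                    "included": False, "reason": e["reason"]}
                   for e in report.exclusions]
    pd.DataFrame(match_rows).to_csv(run_dir / "matching.csv", index=False)
    log.info("match: %d/%d triplets matched, %d exclusions",
             len(report.triplets), len(study.slices), len(report.exclusions))

    all_patients = [s.patient_id for s in study.slices]
    dev, test = split_patients(all_patients, config.test_fraction, config.seed)
    assert not set(dev) & set(test)
    log.info("split: %d development / %d test patients", len(dev), len(test))

    train_slices = [i for i in sorted(matched_t1)
                    if study.slices[i].patient_id in dev]
    dataset = [study.slices[i].triplet for i in train_slices]
    patient_ids = [study.slices[i].patient_id for i in train_slices]
    if not dataset:
        raise RuntimeError("stage train failed: no matched development triplets")
    log.info("train: %d triplets, %d steps", len(dataset), config.generator.steps)
    model = train(dataset, config.generator, patient_ids=patient_ids)
    save_checkpoint(model, run_dir / "model.npz")
    pd.DataFrame({k: pd.Series(v) for k, v in model.history.items()}).to_csv(
        run_dir / "training_history.csv", index=False)

    log.info("infer: %d test patients", len(test))
    vne_images = [
        infer_vne(model, s.triplet)
        if (s.patient_id in test and i in matched_t1) else None
        for i, s in enumerate(study.slices)
    ]

    log.info("quantify: percentiles %s (VNE adjusted %s)",
             config.percentiles, config.vne_adjusted_percentiles)
    all_pcts = tuple(dict.fromkeys(
        tuple(config.percentiles) + tuple(config.vne_adjusted_percentiles)))
    q_vne = patient_burdens(study, set(test), vne_images, all_pcts)
    q_vne["method"] = "VNE"
    lge_images = [s.triplet.lge if v is not None else None
                  for s, v in zip(study.slices, vne_images)]
    q_lge = patient_burdens(study, set(test), lge_images, config.percentiles)
    q_lge["method"] = "LGE"
    burdens = pd.concat([q_vne, q_lge], ignore_index=True)
    burdens.to_csv(run_dir / "burdens.csv", index=False)

    reports: dict[str, AgreementReport] = {}
    for p in config.percentiles:
        a = q_vne[q_vne.percentile == p].set_index("patient").burden
        b = q_lge[q_lge.percentile == p].set_index("patient").burden
        common = sorted(set(a.index) & set(b.index))
        if len(common) >= 3:
            pm = PairedMeasurements(common, a.loc[common].values,
                                    b.loc[common].values,
                                    label=f"burden@{p}")
            reports[f"p{p}"] = agreement_report(pm)
    report_json = {
        k: {f.name: getattr(r, f.name) for f in dataclasses.fields(r)}
        for k, r in reports.items()
    }
    (run_dir / "statistics.json").write_text(
        json.dumps(report_json, indent=1, default=lambda o: list(o)
                   if isinstance(o, tuple) else o))
    log.info("done: %s", run_dir)
    return PipelineResult(config=config, study=study, model=model,
                          train_patients=dev, test_patients=test,
                          burdens=burdens, reports=reports, run_dir=run_dir)
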