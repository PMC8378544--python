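"""Virtual native enhancement generator, discriminator and training.

The generator maps contrast-free native acquisitions — a T1 map, its
inversion-recovery-weighted source images, and cine frames — to an LGE-like
image.  It has three parallel encoder–decoder U-Net streams (one per input
modality) whose final feature maps are concatenated and fused by a further
convolutional block into a single output image on the T1-map grid.

Training is a conditional adversarial game: a patch discriminator,
conditioned on the native input channels, learns to tell synthesized images
from real LGE (least-squares adversarial loss), while the generator
minimises a weighted sum of the adversarial term and a perceptual term —
mean absolute differences of the two images' feature maps under a fixed
(frozen) convolutional feature extractor, with the raw image included as
layer zero.  The feature extractor uses seeded random weights by default
and accepts any substitute implementing ``features()``.

All computation runs on the package's numpy autodiff engine; everything is
seeded and reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .geometry import ImageSlice, Modality, NativeTriplet

__all__ = [
    "GeneratorConfig",
    "Generator",
    "Discriminator",
    "FeatureNet",
    "TrainedModel",
    "InterfaceError",
    "build_generator",
    "perceptual_distance",
    "train",
    "infer_vne",
    "prepare_inputs",
    "save_checkpoint",
    "load_checkpoint",
    "T1_SCALE_MS",
]

#: Fixed T1 normalisation constant (ms): native myocardial and blood T1 at
#: 1.5T fall well below this, so T1/T1_SCALE_MS lands in ~[0, 1].
T1_SCALE_MS = 2000.0


class InterfaceError(TypeError):
    """An LGE image was offered where only native inputs are allowed."""


@dataclass
class GeneratorConfig:
    """Desk-scale configuration for the generator/discriminator pair.

    Defaults are sized to train on one CPU in minutes: 64×64 images, 3
    resolution levels, 8 base channels.  ``loss_weights`` is
    (adversarial λ, perceptual λ).
    """

    image_size: int = 64
    streams: int = 3  # cine, IR-weighted, T1 — fixed
    unet_depth: int = 3
    base_channels: int = 8
    fusion_channels: int = 16
    cine_frames_used: int = 3
    irw_images_used: int = 3
    loss_weights: tuple[float, float] = (0.05, 1.0)
    learning_rate: float = 2e-3
    steps: int = 1200
    batch_size: int = 4
    val_fraction: float = 0.1
    val_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.streams != 3:
            raise ValueError("the generator has exactly 3 input streams")
        if self.unet_depth < 2:
            raise ValueError("unet_depth must be >= 2")
        if self.base_channels < 4 or self.fusion_channels < 4:
            raise ValueError("channel counts must be >= 4")
        lam_adv, lam_perc = self.loss_weights
        if lam_adv < 0 or lam_perc < 0 or (lam_adv == 0 and lam_perc == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")
        if self.image_size % (2 ** self.unet_depth) != 0:
            raise ValueError("image_size must be divisible by 2**unet_depth")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Net:
    """Base class: a named parameter store with save/load."""

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}

    def _conv(self, rng: np.random.Generator, name: str, c_in: int, c_out: int,
              k: int = 3) -> None:
        self.params[f"{name}/w"] = Tensor(_he_init(rng, (c_out, c_in, k, k)),
                                          requires_grad=True)
        self.params[f"{name}/b"] = Tensor(np.zeros(c_out, dtype=np.float32),
                                          requires_grad=True)

    def _apply(self, name: str, x: Tensor, act: bool = True) -> Tensor:
        out = ad.conv2d(x, self.params[f"{name}/w"], self.params[f"{name}/b"])
        return ad.leaky_relu(out) if act else out

    def param_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))


class Generator(_Net):
    """Three parallel U-Net streams plus a fusion block."""

    STREAMS = ("cine", "irw", "t1")

    def __init__(self, config: GeneratorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        d = config.unet_depth
        in_ch = {"cine": config.cine_frames_used, "irw": config.irw_images_used, "t1": 1}
        ch = [c * 2**l for l in range(d)]
        for s in self.STREAMS:
            prev = in_ch[s]
            for l in range(d):  # encoder: two convs per level, fine to coarse
                self._conv(rng, f"{s}/enc{l}/c0", prev, ch[l])
                self._conv(rng, f"{s}/enc{l}/c1", ch[l], ch[l])
                prev = ch[l]
            for l in reversed(range(d - 1)):  # decoder with skip connections
                self._conv(rng, f"{s}/dec{l}/c0", ch[l + 1] + ch[l], ch[l])
                self._conv(rng, f"{s}/dec{l}/c1", ch[l], ch[l])
        self._conv(rng, "fuse/c0", 3 * c, config.fusion_channels)
        self._conv(rng, "fuse/c1", config.fusion_channels, config.fusion_channels)
        self._conv(rng, "fuse/c2", config.fusion_channels, 1)

    def _stream(self, name: str, x: Tensor) -> Tensor:
        d = self.config.unet_depth
        skips = []
        h = x
        for l in range(d):
            if l > 0:
                h = ad.avg_pool2(h)
            h = self._apply(f"{name}/enc{l}/c0", h)
            h = self._apply(f"{name}/enc{l}/c1", h)
            if l < d - 1:
                skips.append(h)
        for l in reversed(range(d - 1)):
            h = ad.upsample2(h)
            h = ad.concat([h, skips[l]])
            h = self._apply(f"{name}/dec{l}/c0", h)
            h = self._apply(f"{name}/dec{l}/c1", h)
        return h

    def forward(self, t1: Tensor, irw: Tensor, cine: Tensor) -> Tensor:
        """Map normalised (N,C,H,W) native inputs to an (N,1,H,W) image."""
        expected = {
            "t1": 1,
            "irw": self.config.irw_images_used,
            "cine": self.config.cine_frames_used,
        }
        for name, x in (("t1", t1), ("irw", irw), ("cine", cine)):
            if x.data.ndim != 4 or x.data.shape[1] != expected[name]:
                raise ValueError(
                    f"{name} input must be (N, {expected[name]}, H, W); got {x.data.shape}"
                )
        feats = ad.concat([
            self._stream("cine", cine),
            self._stream("irw", irw),
            self._stream("t1", t1),
        ])
        h = self._apply("fuse/c0", feats)
        h = self._apply("fuse/c1", h)
        return self._apply("fuse/c2", h, act=False)


class Discriminator(_Net):
    """Patch classifier conditioned on the native input channels."""

    def __init__(self, config: GeneratorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed + 1)
        c = config.base_channels
        cond = 1 + config.irw_images_used + config.cine_frames_used
        self._conv(rng, "d/c0", cond + 1, c)
        self._conv(rng, "d/c1", c, 2 * c)
        self._conv(rng, "d/c2", 2 * c, 4 * c)
        self._conv(rng, "d/out", 4 * c, 1)

    def forward(self, cond: Tensor, img: Tensor) -> Tensor:
        h = ad.concat([cond, img])
        h = ad.avg_pool2(self._apply("d/c0", h))
        h = ad.avg_pool2(self._apply("d/c1", h))
        h = ad.avg_pool2(self._apply("d/c2", h))
        return self._apply("d/out", h, act=False)


class FeatureNet:
    """Frozen convolutional feature extractor for the perceptual objective.

    Two 3×3 convolution + leaky-ReLU layers with seeded random weights
    (average-pooled between layers); the raw image is exposed as layer zero
    so the perceptual distance is zero only for identical images.  A
    pretrained extractor can be substituted by implementing ``features``.
    """

    def __init__(self, channels: int = 8, seed: int = 12345,
                 include_input: bool = True):
        rng = np.random.default_rng(seed)
        self.include_input = include_input
        self.w1 = Tensor(_he_init(rng, (channels, 1, 3, 3)))
        self.w2 = Tensor(_he_init(rng, (channels, channels, 3, 3)))

    def features(self, x: Tensor) -> list[Tensor]:
        out = [x] if self.include_input else []
        h = ad.leaky_relu(ad.conv2d(x, self.w1))
        out.append(h)
        h = ad.leaky_relu(ad.conv2d(ad.avg_pool2(h), self.w2))
        out.append(h)
        return out


def build_generator(config: GeneratorConfig) -> Generator:
    """Construct the 3-stream generator for a configuration."""
    return Generator(config)


def _perceptual(a: Tensor, b: Tensor, feature_net: FeatureNet) -> Tensor:
    terms = [
        ad.mean(ad.absolute(ad.sub(fa, fb)))
        for fa, fb in zip(feature_net.features(a), feature_net.features(b))
    ]
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return total


def perceptual_distance(a: ImageSlice, b: ImageSlice,
                        feature_net: Optional[FeatureNet] = None) -> float:
    """Perceptual distance: summed mean-|Δ| over feature layers. Symmetric, ≥0."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"shape mismatch: {a.pixels.shape} vs {b.pixels.shape}")
    if feature_net is None:
        feature_net = FeatureNet()
    ta = Tensor(np.asarray(a.pixels, dtype=np.float32)[None, None])
    tb = Tensor(np.asarray(b.pixels, dtype=np.float32)[None, None])
    return float(_perceptual(ta, tb, feature_net).data)


# ---------------------------------------------------------------------------
# input preparation


def _robust_norm(img: np.ndarray) -> np.ndarray:
    """Scale one image to [0, 1] by its 1st–99th intensity percentiles."""
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def prepare_inputs(triplet: NativeTriplet, config: GeneratorConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalise and channel-stack one triplet's native inputs.

    T1 is divided by the fixed constant ``T1_SCALE_MS``; IR-weighted images
    (the earliest ``irw_images_used``) and cine frames (``cine_frames_used``
    sampled evenly over the cycle) are robustly scaled per image.  Raises
    :class:`InterfaceError` if any offered input is an LGE image.
    """
    for s in [triplet.t1_map] + triplet.irw + triplet.cine:
        if s.modality in (Modality.LGE, Modality.VNE):
            raise InterfaceError(f"{s.modality.value} image offered as a native input")
    if len(triplet.irw) < config.irw_images_used:
        raise ValueError(f"need >= {config.irw_images_used} IR-weighted images")
    if len(triplet.cine) < config.cine_frames_used:
        raise ValueError(f"need >= {config.cine_frames_used} cine frames")
    t1 = (np.asarray(triplet.t1_map.pixels, dtype=np.float32) / T1_SCALE_MS)[None]
    irw = np.stack([
        _robust_norm(np.asarray(s.pixels, dtype=float))
        for s in triplet.irw[: config.irw_images_used]
    ])
    idx = np.linspace(0, len(triplet.cine) - 1, config.cine_frames_used)
    cine = np.stack([
        _robust_norm(np.asarray(triplet.cine[int(round(i))].pixels, dtype=float))
        for i in idx
    ])
    return t1.astype(np.float32), irw, cine


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained generator/discriminator pair with its history and config."""

    generator: Generator
    discriminator: Discriminator
    history: dict[str, list]
    config: GeneratorConfig
    seed: int
    best_val_loss: float


def _stack_dataset(dataset: Sequence[NativeTriplet], config: GeneratorConfig):
    t1s, irws, cines, targets = [], [], [], []
    for tr in dataset:
        if tr.lge is None:
            raise ValueError("every training triplet needs an LGE target")
        t1, irw, cine = prepare_inputs(tr, config)
        t1s.append(t1)
        irws.append(irw)
        cines.append(cine)
        targets.append(_robust_norm(np.asarray(tr.lge.pixels, dtype=float))[None])
    return (np.stack(t1s), np.stack(irws), np.stack(cines), np.stack(targets))


def _split_by_patient(patient_ids: Sequence, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ids = np.asarray(patient_ids)
    unique = sorted(set(ids.tolist()))
    order = rng.permutation(len(unique))
    n_val = max(1, int(round(val_fraction * len(unique)))) if len(unique) > 1 else 0
    val_patients = {unique[i] for i in order[:n_val]}
    val_mask = np.array([p in val_patients for p in ids])
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def train(dataset: Sequence[NativeTriplet], config: GeneratorConfig,
          patient_ids: Optional[Sequence] = None,
          feature_net: Optional[FeatureNet] = None) -> TrainedModel:
    """Adversarial training of the generator on LGE-targeted triplets.

    The dataset is split into training (90%) and validation (10%) by patient,
    never by slice.  Each step alternates a discriminator update
    (least-squares real/fake loss) and a generator update
    (λ_adv · adversarial + λ_perc · perceptual).  The returned model carries
    the parameters with the best validation perceptual loss and the full
    per-step history; identical seeds give identical histories.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if patient_ids is None:
        patient_ids = list(range(len(dataset)))
    if len(patient_ids) != len(dataset):
        raise ValueError("patient_ids must align with dataset")
    rng = np.random.default_rng(config.seed)
    t1, irw, cine, target = _stack_dataset(dataset, config)
    train_idx, val_idx = _split_by_patient(patient_ids, config.val_fraction, rng)
    if len(train_idx) == 0:
        raise ValueError("training split is empty")

    gen = Generator(config)
    disc = Discriminator(config)
    if feature_net is None:
        feature_net = FeatureNet(seed=config.seed + 2)
    opt_g = ad.Adam(gen.param_list(), lr=config.learning_rate)
    opt_d = ad.Adam(disc.param_list(), lr=config.learning_rate)
    lam_adv, lam_perc = config.loss_weights

    history: dict[str, list] = {"step": [], "d_loss": [], "g_adv": [], "g_perc": [],
                                "val_step": [], "val_perc": []}
    best_val = np.inf
    best_state = gen.state_dict()

    def batch(idx: np.ndarray):
        sel = rng.choice(idx, size=min(config.batch_size, len(idx)), replace=False)
        return (Tensor(t1[sel]), Tensor(irw[sel]), Tensor(cine[sel]),
                Tensor(target[sel]), Tensor(np.concatenate(
                    [cine[sel], irw[sel], t1[sel]], axis=1)))

    def validate() -> float:
        if len(val_idx) == 0:
            return np.nan
        tot = 0.0
        for i in val_idx:
            fake = gen.forward(Tensor(t1[i : i + 1]), Tensor(irw[i : i + 1]),
                               Tensor(cine[i : i + 1]))
            tot += float(_perceptual(fake, Tensor(target[i : i + 1]), feature_net).data)
        return tot / len(val_idx)

    for step in range(1, config.steps + 1):
        bt1, birw, bcine, breal, bcond = batch(train_idx)
        # one generator forward feeds both updates: its detached copy trains
        # the discriminator, the live graph trains the generator
        fake = gen.forward(bt1, birw, bcine)
        opt_d.zero_grad()
        d_loss = ad.add(
            ad.mean(ad.square(ad.sub(disc.forward(bcond, breal),
                                     Tensor(np.float32(1.0))))),
            ad.mean(ad.square(disc.forward(bcond, fake.detach()))),
        )
        d_loss.backward()
        opt_d.step()
        # generator: adversarial + perceptual
        opt_g.zero_grad()
        opt_d.zero_grad()
        g_adv = ad.mean(ad.square(ad.sub(disc.forward(bcond, fake),
                                         Tensor(np.float32(1.0)))))
        g_perc = _perceptual(fake, breal, feature_net)
        g_loss = ad.add(ad.mul_const(g_adv, lam_adv), ad.mul_const(g_perc, lam_perc))
        g_loss.backward()
        opt_g.step()
        history["step"].append(step)
        history["d_loss"].append(float(d_loss.data))
        history["g_adv"].append(float(g_adv.data))
        history["g_perc"].append(float(g_perc.data))
        if step % config.val_interval == 0 or step == config.steps:
            val = validate()
            history["val_step"].append(step)
            history["val_perc"].append(val)
            if np.isfinite(val) and val < best_val:
                best_val = val
                best_state = gen.state_dict()

    if np.isfinite(best_val):
        gen.load_state_dict(best_state)
    else:
        best_val = history["g_perc"][-1]
    return TrainedModel(generator=gen, discriminator=disc, history=history,
                        config=config, seed=config.seed, best_val_loss=float(best_val))


def infer_vne(model: TrainedModel, triplet: NativeTriplet) -> ImageSlice:
    """Generate a virtual native enhancement image for one triplet.

    Deterministic given the model parameters; the output shares the T1 map's
    geometry.  Only native inputs are consumed — the triplet's LGE member (if
    any) is never read, and LGE images offered among the native inputs raise
    :class:`InterfaceError`.
    """
    t1, irw, cine = prepare_inputs(triplet, model.config)
    out = model.generator.forward(Tensor(t1[None]), Tensor(irw[None]),
                                  Tensor(cine[None]))
    pixels = np.asarray(out.data[0, 0], dtype=float)
    return ImageSlice(pixels=pixels, geometry=triplet.t1_map.geometry,
                      modality=Modality.VNE,
                      meta={"source": "vne-generator", "seed": model.seed})


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedModel, path: str) -> None:
    """Single-file archive: parameters, history, config snapshot and seed."""
    arrays = {f"gen::{k}": v for k, v in model.generator.state_dict().items()}
    arrays.update({f"disc::{k}": v for k, v in model.discriminator.state_dict().items()})
    for k, v in model.history.items():
        arrays[f"hist::{k}"] = np.asarray(v)
    cfg = asdict(model.config)
    cfg["loss_weights"] = list(cfg["loss_weights"])
    arrays["meta"] = np.frombuffer(
        json.dumps({"config": cfg, "seed": model.seed,
                    "best_val_loss": model.best_val_loss}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> TrainedModel:
    """Reload a checkpoint to bit-identical inference."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        cfg = meta["config"]
        cfg["loss_weights"] = tuple(cfg["loss_weights"])
        config = GeneratorConfig(**cfg)
        gen = Generator(config)
        disc = Discriminator(config)
        gen.load_state_dict(
            {k.split("::", 1)[1]: z[k] for k in z.files if k.startswith("gen::")})
        disc.load_state_dict(
            {k.split("::", 1)[1]: z[k] for k in z.files if k.startswith("disc::")})
        history = {k.split("::", 1)[1]: z[k].tolist()
                   for k in z.files if k.startswith("hist::")}
    return TrainedModel(generator=gen, discriminator=disc, history=history,
                        config=config, seed=meta["seed"],
                        best_val_loss=meta["best_val_loss"])
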