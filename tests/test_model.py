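"""Generator architecture, perceptual objective, training and inference."""

import numpy as np
import pytest
from scipy import ndimage

from vne._autodiff import Tensor
from vne.geometry import ImageSlice, Modality
from vne.model import (
    FeatureNet,
    GeneratorConfig,
    InterfaceError,
    _robust_norm,
    build_generator,
    infer_vne,
    load_checkpoint,
    perceptual_distance,
    prepare_inputs,
    save_checkpoint,
    train,
)
from vne.phantom import PhantomSpec, generate_study

from conftest import make_image

TINY = dict(image_size=32, steps=12, val_interval=6, seed=3)


@pytest.fixture(scope="module")
def tiny_model(noise_free_study32):
    study = noise_free_study32
    cfg = GeneratorConfig(**TINY)
    return train([s.triplet for s in study.slices], cfg,
                 patient_ids=[s.patient_id for s in study.slices]), study


@pytest.fixture(scope="module")
def noise_free_study32():
    return generate_study(PhantomSpec(n_patients=3, image_size=32,
                                      noise_sd=0.0, seed=21))


class TestBuildGenerator:
    def test_identical_configs_identical_parameter_counts(self):
        cfg = GeneratorConfig(image_size=32)
        assert build_generator(cfg).n_parameters() == \
            build_generator(cfg).n_parameters()

    def test_parameter_count_analytic_small_config(self):
        cfg = GeneratorConfig(image_size=32, unet_depth=2, base_channels=4,
                              fusion_channels=4, cine_frames_used=3,
                              irw_images_used=3)

        def conv(cin, cout):
            return cout * cin * 9 + cout

        expected = 0
        for cin in (3, 3, 1):  # cine, IRW, T1 streams
            expected += conv(cin, 4) + conv(4, 4)      # encoder level 0
            expected += conv(4, 8) + conv(8, 8)        # encoder level 1 (bottom)
            expected += conv(8 + 4, 4) + conv(4, 4)    # decoder level 0 with skip
        expected += conv(12, 4) + conv(4, 4) + conv(4, 1)  # fusion block
        assert build_generator(cfg).n_parameters() == expected

    def test_doubling_base_channels_increases_parameters(self):
        small = build_generator(GeneratorConfig(image_size=32, base_channels=4))
        big = build_generator(GeneratorConfig(image_size=32, base_channels=8))
        assert big.n_parameters() > small.n_parameters()

    @pytest.mark.parametrize("size", [32, 64])
    def test_output_matches_t1_spatial_size(self, size):
        cfg = GeneratorConfig(image_size=size)
        gen = build_generator(cfg)
        rng = np.random.default_rng(0)
        out = gen.forward(
            Tensor(rng.normal(size=(1, 1, size, size)).astype(np.float32)),
            Tensor(rng.normal(size=(1, 3, size, size)).astype(np.float32)),
            Tensor(rng.normal(size=(1, 3, size, size)).astype(np.float32)),
        )
        assert out.data.shape == (1, 1, size, size)

    def test_input_shape_mismatch_raises(self):
        gen = build_generator(GeneratorConfig(image_size=32))
        x = Tensor(np.zeros((1, 2, 32, 32), dtype=np.float32))
        with pytest.raises(ValueError):
            gen.forward(x, x, x)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(unet_depth=1)
        with pytest.raises(ValueError):
            GeneratorConfig(loss_weights=(0.0, 0.0))
        with pytest.raises(ValueError):
            GeneratorConfig(image_size=50)


class TestPerceptualDistance:
    def test_zero_iff_identical(self, axial_geometry):
        g = axial_geometry(n=16)
        rng = np.random.default_rng(1)
        a = make_image(rng.normal(size=(16, 16)), g)
        assert perceptual_distance(a, a) == 0.0
        b = make_image(a.pixels + 0.01, g)
        assert perceptual_distance(a, b) > 0.0

    def test_symmetry(self, axial_geometry):
        g = axial_geometry(n=16)
        rng = np.random.default_rng(2)
        a = make_image(rng.normal(size=(16, 16)), g)
        b = make_image(rng.normal(size=(16, 16)), g)
        assert perceptual_distance(a, b) == pytest.approx(
            perceptual_distance(b, a), rel=1e-6)

    def test_toy_two_layer_net_matches_hand_computation(self, axial_geometry):
        """Fixed known weights on 4x4 inputs vs explicit convolution."""
        g = axial_geometry(n=4)
        net = FeatureNet(channels=1, seed=0)
        w1 = np.zeros((1, 1, 3, 3), dtype=np.float32)
        w1[0, 0, 1, 1] = 2.0  # scaled identity kernel
        w2 = np.zeros((1, 1, 3, 3), dtype=np.float32)
        w2[0, 0, 1, 2] = 1.0  # shift kernel
        net.w1 = Tensor(w1)
        net.w2 = Tensor(w2)
        a_px = np.arange(16, dtype=float).reshape(4, 4)
        b_px = np.zeros((4, 4))

        def features(x):
            f1 = np.maximum(2.0 * x, 0.2 * x)  # leaky relu of identity conv
            pooled = f1.reshape(2, 2, 2, 2).mean(axis=(1, 3))
            conv2 = ndimage.correlate(pooled, w2[0, 0], mode="constant")
            f2 = np.maximum(conv2, 0.1 * conv2)
            return [x, f1, f2]

        expected = sum(np.abs(fa - fb).mean()
                       for fa, fb in zip(features(a_px), features(b_px)))
        got = perceptual_distance(make_image(a_px, g), make_image(b_px, g), net)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_shape_mismatch_raises(self, axial_geometry):
        a = make_image(np.zeros((16, 16)), axial_geometry(n=16))
        b = make_image(np.zeros((8, 8)), axial_geometry(n=8))
        with pytest.raises(ValueError):
            perceptual_distance(a, b)


class TestTraining:
    def test_pure_perceptual_training_reduces_loss(self, noise_free_study32):
        study = noise_free_study32
        cfg = GeneratorConfig(image_size=32, steps=60, loss_weights=(0.0, 1.0),
                              val_interval=30, seed=4)
        model = train([s.triplet for s in study.slices], cfg,
                      patient_ids=[s.patient_id for s in study.slices])
        perc = model.history["g_perc"]
        assert np.mean(perc[-5:]) < np.mean(perc[:5])

    def test_same_seed_identical_history_and_parameters(self, noise_free_study32):
        study = noise_free_study32
        cfg = GeneratorConfig(**TINY)
        args = ([s.triplet for s in study.slices], cfg)
        kwargs = dict(patient_ids=[s.patient_id for s in study.slices])
        m1 = train(*args, **kwargs)
        m2 = train(*args, **kwargs)
        assert m1.history["g_perc"] == m2.history["g_perc"]
        assert m1.history["d_loss"] == m2.history["d_loss"]
        for k in m1.generator.params:
            assert np.array_equal(m1.generator.params[k].data,
                                  m2.generator.params[k].data)

    def test_missing_lge_target_rejected(self, noise_free_study32):
        triplet = noise_free_study32.slices[0].triplet
        bare = type(triplet)(t1_map=triplet.t1_map, irw=triplet.irw,
                             cine=triplet.cine, lge=None)
        with pytest.raises(ValueError):
            train([bare], GeneratorConfig(**TINY))

    def test_history_length_matches_steps(self, tiny_model):
        model, _ = tiny_model
        assert len(model.history["step"]) == model.config.steps


class TestInference:
    def test_repeated_inference_bit_identical(self, tiny_model):
        model, study = tiny_model
        t = study.slices[0].triplet
        assert np.array_equal(infer_vne(model, t).pixels,
                              infer_vne(model, t).pixels)

    def test_output_geometry_is_t1_geometry(self, tiny_model):
        model, study = tiny_model
        t = study.slices[0].triplet
        out = infer_vne(model, t)
        assert out.geometry is t.t1_map.geometry
        assert out.modality is Modality.VNE

    def test_no_leakage_lge_perturbation_does_not_change_output(self, tiny_model):
        model, study = tiny_model
        t = study.slices[0].triplet
        baseline = infer_vne(model, t).pixels
        perturbed = type(t)(
            t1_map=t.t1_map, irw=t.irw, cine=t.cine,
            lge=ImageSlice(t.lge.pixels + 123.0, t.lge.geometry, Modality.LGE),
        )
        assert np.array_equal(infer_vne(model, perturbed).pixels, baseline)

    def test_lge_offered_as_native_input_raises(self, tiny_model):
        model, study = tiny_model
        t = study.slices[0].triplet
        smuggled = [ImageSlice(s.pixels, s.geometry, Modality.LGE)
                    for s in t.irw]
        bad = type(t)(t1_map=t.t1_map, irw=smuggled, cine=t.cine, lge=t.lge)
        with pytest.raises(InterfaceError):
            infer_vne(model, bad)

    def test_checkpoint_roundtrip_bit_identical(self, tiny_model, tmp_path):
        model, study = tiny_model
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        t = study.slices[0].triplet
        assert np.array_equal(infer_vne(model, t).pixels,
                              infer_vne(back, t).pixels)
        assert back.config == model.config

    def test_trained_beats_untrained_by_factor_five(self, noise_free_study32):
        """Training shrinks per-pixel error vs the true LGE by >= 5x."""
        study = noise_free_study32
        held_out = study.slices[-1]
        rest = study.slices[:-1]
        cfg = GeneratorConfig(image_size=32, steps=300, val_interval=50, seed=5)
        model = train([s.triplet for s in rest], cfg,
                      patient_ids=[s.patient_id for s in rest])
        untrained = build_generator(cfg)
        t1, irw, cine = prepare_inputs(held_out.triplet, cfg)
        raw = untrained.forward(Tensor(t1[None]), Tensor(irw[None]),
                                Tensor(cine[None])).data[0, 0]
        target = _robust_norm(held_out.triplet.lge.pixels)
        err = np.abs(infer_vne(model, held_out.triplet).pixels - target).mean()
        err0 = np.abs(raw - target).mean()
        assert err0 >= 5.0 * err


class TestPrepareInputs:
    def test_channel_counts_and_t1_scaling(self, noise_free_study32):
        t = noise_free_study32.slices[0].triplet
        cfg = GeneratorConfig(image_size=32)
        t1, irw, cine = prepare_inputs(t, cfg)
        assert t1.shape == (1, 32, 32)
        assert irw.shape == (cfg.irw_images_used, 32, 32)
        assert cine.shape == (cfg.cine_frames_used, 32, 32)
        assert np.allclose(t1[0] * 2000.0, t.t1_map.pixels, atol=0.5)
        assert irw.max() <= 1.0 and irw.min() >= 0.0
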