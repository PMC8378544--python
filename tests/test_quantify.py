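"""FWHM-family thresholding, masks and burden pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vne.geometry import Modality
from vne.quantify import (
    DegenerateReferenceError,
    RoiError,
    RoiSet,
    calibrate_adjusted_percentile,
    contours_to_mask,
    lesion_burden,
    lesion_mask,
    progressive_quantification,
    quantify_patient,
    threshold_value,
)

from conftest import make_image


# -- independent oracles ------------------------------------------------------


def point_in_polygon_scalar(r, c, poly):
    """Even-odd crossing test for one point, written independently."""
    inside = False
    n = len(poly)
    for i in range(n):
        r0, c0 = poly[i]
        r1, c1 = poly[(i + 1) % n]
        if (c0 > c) != (c1 > c):
            r_cross = r0 + (c - c0) * (r1 - r0) / (c1 - c0)
            if r < r_cross:
                inside = not inside
    return inside


def brute_force_myo_mask(epi, endo, shape):
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = point_in_polygon_scalar(r, c, epi) and not \
                point_in_polygon_scalar(r, c, endo)
    return mask


def brute_force_lesion_mask(pixels, myo, threshold):
    out = np.zeros_like(myo)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            out[r, c] = myo[r, c] and pixels[r, c] >= threshold
    return out


def star_polygon(rng, center, r_min, r_max, n_vertices=9):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    return np.column_stack([center[0] + radii * np.cos(angles),
                            center[1] + radii * np.sin(angles)])


# -- threshold_value ----------------------------------------------------------


@pytest.mark.parametrize(
    "remote, blood, p, expected",
    [(0.0, 100.0, 50.0, 50.0), (200.0, 600.0, 25.0, 300.0),
     (200.0, 600.0, 12.5, 250.0), (200.0, 600.0, 35.0, 340.0)],
)
def test_threshold_interpolates_remote_to_blood_range(remote, blood, p, expected):
    assert threshold_value(remote, blood, p) == pytest.approx(expected)


def test_threshold_rejects_degenerate_references():
    with pytest.raises(DegenerateReferenceError):
        threshold_value(300.0, 300.0, 50.0)


@settings(max_examples=100, derandomize=True)
@given(
    remote=st.floats(-1e3, 1e3),
    span=st.floats(1e-3, 1e3),
    p1=st.floats(0.01, 99.99),
    p2=st.floats(0.01, 99.99),
)
def test_threshold_is_monotone_and_bracketed(remote, span, p1, p2):
    """Thresholds stay inside (remote, blood) and increase with percentile."""
    blood = remote + span
    t1, t2 = threshold_value(remote, blood, p1), threshold_value(remote, blood, p2)
    assert remote < t1 < blood
    if p1 < p2:
        assert t1 < t2


@settings(max_examples=100, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(0, 50), st.integers(51, 200)), min_size=1, max_size=8))
def test_burden_bounded_and_between_slice_extremes(pairs):
    """Pooled burden lies in [0, 1] and within the per-slice ratio range."""
    b = lesion_burden(pairs)
    ratios = [l / m for l, m in pairs]
    assert 0.0 <= b <= 1.0
    assert min(ratios) - 1e-12 <= b <= max(ratios) + 1e-12


# -- contours_to_mask ---------------------------------------------------------


class TestContoursToMask:
    def test_concentric_squares_area(self, square_annulus):
        g, roi = square_annulus
        mask = contours_to_mask(roi, g)
        assert mask.sum() == 100 - 16

    def test_degenerate_equal_contours_raise(self, square_annulus):
        g, roi = square_annulus
        bad = RoiSet(roi.epicardial_contour, roi.epicardial_contour,
                     roi.remote_roi, roi.bloodpool_roi)
        with pytest.raises(RoiError):
            contours_to_mask(bad, g)

    def test_non_nested_contours_raise(self, square_annulus, axial_geometry):
        g, roi = square_annulus
        shifted_endo = roi.endocardial_contour + 20.0
        bad = RoiSet(roi.epicardial_contour, shifted_endo,
                     roi.remote_roi, roi.bloodpool_roi)
        with pytest.raises(RoiError):
            contours_to_mask(bad, g)

    def test_matches_brute_force_on_random_star_annuli(self, axial_geometry):
        g = axial_geometry(n=20)
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            epi = star_polygon(rng, (10, 10), 6.0, 9.0)
            endo = star_polygon(rng, (10, 10), 1.0, 3.5)
            roi = RoiSet(epi, endo, np.array([[1, 1]]), np.array([[10, 10]]))
            try:
                mask = contours_to_mask(roi, g)
            except RoiError:
                continue  # degenerate random draw: not a valid nested pair
            expected = brute_force_myo_mask(epi, endo, (20, 20))
            assert np.array_equal(mask, expected)
            checked += 1


# -- lesion_mask --------------------------------------------------------------


class TestLesionMask:
    def test_all_below_threshold_empty(self, square_annulus):
        g, roi = square_annulus
        img = make_image(np.zeros((16, 16)), g)
        myo = contours_to_mask(roi, g)
        assert lesion_mask(img, myo, 1.0).sum() == 0

    def test_plateau_at_threshold_included(self, square_annulus):
        g, roi = square_annulus
        img = make_image(np.full((16, 16), 5.0), g)
        myo = contours_to_mask(roi, g)
        assert lesion_mask(img, myo, 5.0).sum() == myo.sum()

    def test_matches_brute_force_on_random_images(self, axial_geometry):
        g = axial_geometry(n=16)
        rng = np.random.default_rng(11)
        for _ in range(100):
            pixels = rng.normal(size=(16, 16))
            myo = rng.uniform(size=(16, 16)) < 0.4
            thr = rng.normal()
            img = make_image(pixels, g)
            assert np.array_equal(lesion_mask(img, myo, thr),
                                  brute_force_lesion_mask(pixels, myo, thr))

    def test_grid_mismatch_raises(self, square_annulus):
        g, roi = square_annulus
        img = make_image(np.zeros((16, 16)), g)
        with pytest.raises(ValueError):
            lesion_mask(img, np.zeros((8, 8), dtype=bool), 0.0)


# -- lesion_burden ------------------------------------------------------------


def test_burden_single_slice_half():
    assert lesion_burden([(42, 84)]) == pytest.approx(0.5)


def test_burden_pools_areas_not_ratios():
    assert lesion_burden([(10, 100), (30, 50)]) == pytest.approx(40 / 150)
    assert lesion_burden([(10, 100), (30, 50)]) != pytest.approx(0.35)


def test_burden_zero_when_no_lesion():
    assert lesion_burden([(0, 80), (0, 90)]) == 0.0


def test_burden_requires_positive_myocardium():
    with pytest.raises(ValueError):
        lesion_burden([(0, 0)])


# -- progressive quantification ----------------------------------------------


class TestProgressiveQuantification:
    def _tiered_image(self, square_annulus):
        """Three intensity tiers inside the annulus straddling the thresholds."""
        g, roi = square_annulus
        myo = contours_to_mask(roi, g)
        pixels = np.zeros((16, 16))
        pixels[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
        free = myo.copy()  # keep the remote ROI at the floor intensity
        free[roi.remote_roi[:, 0], roi.remote_roi[:, 1]] = False
        rows, cols = np.nonzero(free)
        n_free = len(rows)
        q = n_free // 4
        pixels[rows[:q], cols[:q]] = 0.6                 # above the 50% threshold
        pixels[rows[q: 2 * q], cols[q: 2 * q]] = 0.3     # between 25% and 50%
        return g, roi, myo, pixels, int(myo.sum()), q

    def test_uniform_myocardium_all_burdens_zero(self, square_annulus):
        g, roi = square_annulus
        pixels = np.zeros((16, 16))
        pixels[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
        q = progressive_quantification(make_image(pixels, g), roi)
        assert all(b == 0.0 for b in q.burden.values())

    def test_tiered_areas_match_hand_counts(self, square_annulus):
        g, roi, myo, pixels, n_myo, q_size = self._tiered_image(square_annulus)
        q = progressive_quantification(make_image(pixels, g), roi)
        # remote mean 0, blood mean 1: thresholds 0.5, 0.25, 0.125
        assert q.lesion_area_px[50.0] == q_size
        assert q.lesion_area_px[25.0] == 2 * q_size
        assert q.lesion_area_px[12.5] == 2 * q_size
        assert q.burden[50.0] == pytest.approx(q_size / n_myo)

    def test_nesting_invariant_on_random_fixtures(self, square_annulus):
        g, roi = square_annulus
        rng = np.random.default_rng(5)
        for _ in range(50):
            pixels = rng.uniform(-0.2, 0.8, size=(16, 16))
            pixels[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
            pixels[roi.remote_roi[:, 0], roi.remote_roi[:, 1]] = 0.0
            q = progressive_quantification(make_image(pixels, g), roi)
            assert q.burden[50.0] <= q.burden[25.0] <= q.burden[12.5]
            assert np.all(q.lesion_masks[25.0] >= q.lesion_masks[50.0])
            assert np.all(q.lesion_masks[12.5] >= q.lesion_masks[25.0])

    def test_scale_equivariance(self, square_annulus):
        g, roi = square_annulus
        rng = np.random.default_rng(6)
        pixels = rng.uniform(0.0, 1.0, size=(16, 16))
        pixels[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
        pixels[roi.remote_roi[:, 0], roi.remote_roi[:, 1]] = 0.0
        q1 = progressive_quantification(make_image(pixels, g), roi)
        q2 = progressive_quantification(make_image(pixels * 37.5, g), roi)
        for p in q1.lesion_masks:
            assert np.array_equal(q1.lesion_masks[p], q2.lesion_masks[p])


# -- calibration --------------------------------------------------------------


class TestCalibrateAdjustedPercentile:
    def _random_pair_set(self, square_annulus, transform):
        g, roi = square_annulus
        myo = contours_to_mask(roi, g)
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(4):
            lge = rng.uniform(0.0, 1.0, size=(16, 16))
            lge[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
            lge[roi.remote_roi[:, 0], roi.remote_roi[:, 1]] = 0.0
            vne = transform(lge, myo)
            pairs.append((make_image(vne, g, Modality.VNE), make_image(lge, g), roi))
        return pairs

    def test_identical_images_self_calibrate(self, square_annulus):
        pairs = self._random_pair_set(square_annulus, lambda x, myo: x.copy())
        assert calibrate_adjusted_percentile(pairs, 50.0) == 50.0

    def test_rescaled_myocardium_returns_35(self, square_annulus):
        def squeeze(lge, myo):
            vne = lge.copy()
            vne[myo] = 0.7 * lge[myo]  # VNE@35 mask == LGE@50 mask by construction
            return vne

        pairs = self._random_pair_set(square_annulus, squeeze)
        got = calibrate_adjusted_percentile(pairs, 50.0,
                                            candidates=[20, 25, 30, 35, 40, 45])
        assert got == 35.0

    def test_single_candidate_returned(self, square_annulus):
        pairs = self._random_pair_set(square_annulus, lambda x, myo: x.copy())
        assert calibrate_adjusted_percentile(pairs, 50.0, candidates=[30.0]) == 30.0

    def test_requires_two_pairs(self, square_annulus):
        pairs = self._random_pair_set(square_annulus, lambda x, myo: x.copy())
        with pytest.raises(ValueError):
            calibrate_adjusted_percentile(pairs[:1], 50.0)


# -- patient-level quantification --------------------------------------------


def test_quantify_patient_pools_slices(square_annulus):
    g, roi = square_annulus
    rng = np.random.default_rng(9)
    imgs = []
    for _ in range(3):
        pixels = rng.uniform(0.0, 1.0, size=(16, 16))
        pixels[roi.bloodpool_roi[:, 0], roi.bloodpool_roi[:, 1]] = 1.0
        pixels[roi.remote_roi[:, 0], roi.remote_roi[:, 1]] = 0.0
        imgs.append(make_image(pixels, g))
    slices = [(img, roi) for img in imgs]
    burdens = quantify_patient(slices, (50.0,))
    per_slice = [progressive_quantification(img, roi, (50.0,)) for img in imgs]
    expected = sum(q.lesion_area_px[50.0] for q in per_slice) / sum(
        q.myocardial_area_px for q in per_slice)
    assert burdens[50.0] == pytest.approx(expected)
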