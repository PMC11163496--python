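"""DD and signed gamma maps: closed forms, oracle equivalence, properties."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from qaerr.dose import DoseGrid, beam_dose, measure
from qaerr.errors import inject_closing, inject_opening
from qaerr.maps import (
    GAMMA_2_1,
    GAMMA_3_2,
    GammaParams,
    dd_map,
    gamma_magnitude,
    make_stack,
    resize_bilinear,
    signed_gamma_map,
    threshold_mask,
)


def brute_force_gamma(ref, ev, p, pitch=10.0):
    """Exhaustive gamma search, written independently of the library path:
    separable bilinear upsampling via RegularGridInterpolator and a literal
    per-reference-point minimum over every fine position in the radius."""
    n, m = ref.shape
    f = p.fine_factor
    step = pitch / f
    interp = RegularGridInterpolator(
        (np.arange(n) * pitch, np.arange(m) * pitch), ev, method="linear")
    fy = np.arange((n - 1) * f + 1) * step
    fx = np.arange((m - 1) * f + 1) * step
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    fine = interp(np.stack([FY.ravel(), FX.ravel()], axis=1)).reshape(FY.shape)
    gmax = ref.max()
    dtol = p.dose_criterion_pct / 100.0 * gmax
    out = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            if ref[i, j] < p.threshold_pct / 100.0 * gmax:
                continue
            d2 = (FY - i * pitch) ** 2 + (FX - j * pitch) ** 2
            mask = d2 <= p.search_radius_mm**2 + 1e-12
            g2 = d2[mask] / p.dta_mm**2 + ((fine[mask] - ref[i, j]) / dtol) ** 2
            out[i, j] = np.sqrt(g2.min())
    return out


def _random_grid_pair(rng, n):
    ref = rng.uniform(5.0, 100.0, (n, n))
    ev = ref * rng.uniform(0.9, 1.1, (n, n)) + rng.normal(0, 1.0, (n, n))
    return ref, np.clip(ev, 0, None)


class TestDDMap:
    def test_identical_inputs_all_zero(self):
        ref = np.random.default_rng(0).uniform(1, 100, (27, 27))
        np.testing.assert_array_equal(dd_map(ref, ref), np.zeros((27, 27)))

    def test_five_percent_scales_to_half(self):
        ref = np.full((3, 3), 50.0)
        ref[0, 0] = 100.0
        ev = ref.copy()
        ev[1, 1] = 55.0
        out = dd_map(ref, ev)
        assert out[1, 1] == pytest.approx(0.5)
        assert out[0, 0] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(10, 100, (9, 9))
        delta = rng.normal(0, 3, (9, 9))
        np.testing.assert_allclose(dd_map(ref, ref + delta),
                                   -dd_map(ref, ref - delta), atol=1e-12)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            dd_map(np.zeros((4, 4)), np.ones((4, 4)))


class TestGammaClosedForms:
    def test_identical_inputs_zero_map(self):
        ref = np.random.default_rng(1).uniform(10, 100, (15, 15))
        out = signed_gamma_map(ref, ref, GAMMA_3_2)
        np.testing.assert_array_equal(out, np.zeros_like(ref))

    def test_single_point_hot_spot_at_criterion(self):
        # 3% of 100 = 3 dose units: a +3 difference is gamma exactly 1
        out = signed_gamma_map(np.array([[100.0]]), np.array([[103.0]]),
                               GAMMA_3_2)
        assert out[0, 0] == pytest.approx(1.0 / 1.5)

    def test_single_point_cold_spot_sign(self):
        out = signed_gamma_map(np.array([[100.0]]), np.array([[97.0]]),
                               GAMMA_3_2)
        assert out[0, 0] == pytest.approx(-1.0 / 1.5)

    def test_clip_maps_large_gamma_to_exactly_one(self):
        hot = signed_gamma_map(np.array([[100.0]]), np.array([[200.0]]),
                               GAMMA_3_2)
        cold = signed_gamma_map(np.array([[100.0]]), np.array([[0.0]]),
                                GAMMA_3_2)
        assert hot[0, 0] == 1.0
        assert cold[0, 0] == -1.0


class TestGammaOracle:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(3, 16))
            ref, ev = _random_grid_pair(rng, n)
            for p in (GAMMA_3_2, GAMMA_2_1):
                ours = gamma_magnitude(ref, ev, p)
                oracle = brute_force_gamma(ref, ev, p)
                np.testing.assert_allclose(ours, oracle, atol=1e-9)


class TestGammaProperties:
    def test_sign_coherence_with_dd(self):
        rng = np.random.default_rng(7)
        ref, ev = _random_grid_pair(rng, 11)
        g = signed_gamma_map(ref, ev, GAMMA_3_2)
        dd = ev - ref
        mask = (np.abs(dd) > 0) & (g != 0)
        assert np.all(np.sign(g[mask]) == np.sign(dd[mask]))

    def test_stricter_criterion_inflates_gamma(self):
        rng = np.random.default_rng(8)
        ref, ev = _random_grid_pair(rng, 11)
        g32 = gamma_magnitude(ref, ev, GAMMA_3_2)
        g21 = gamma_magnitude(ref, ev, GAMMA_2_1)
        valid = ~np.isnan(g32)
        assert np.all(g21[valid] >= g32[valid] - 1e-12)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        ref, ev = _random_grid_pair(rng, 11)
        counts = []
        for thr in (5.0, 10.0, 20.0, 40.0):
            p = GammaParams(3.0, 2.0, threshold_pct=thr)
            counts.append(np.count_nonzero(signed_gamma_map(ref, ev, p)))
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_stored_channels_bounded(self):
        rng = np.random.default_rng(10)
        ref, ev = _random_grid_pair(rng, 13)
        ev = ev * 3.0  # force gamma past the clip ceiling
        g = signed_gamma_map(ref, ev, GAMMA_3_2)
        assert np.abs(g).max() <= 1.0

    def test_validity_mask_matches_threshold(self):
        ref = np.linspace(0, 100, 27 * 27).reshape(27, 27)
        mask = threshold_mask(ref, 10.0)
        assert np.array_equal(mask, ref >= 10.0)


class TestResize:
    def test_constant_preserved(self):
        out = resize_bilinear(np.full((27, 27), 0.3), 224)
        np.testing.assert_allclose(out, 0.3, atol=1e-7)

    def test_corners_preserved(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(27, 27))
        out = resize_bilinear(arr, 224)
        for (i, j), (oi, oj) in zip([(0, 0), (0, 26), (26, 0), (26, 26)],
                                    [(0, 0), (0, 223), (223, 0), (223, 223)]):
            assert out[oi, oj] == pytest.approx(arr[i, j], abs=1e-7)

    def test_bounds_never_exceeded(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(27, 27))
        out = resize_bilinear(arr, 224)
        assert out.min() >= arr.min() - 1e-7
        assert out.max() <= arr.max() + 1e-7

    def test_round_trip_on_smooth_input(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(7)
        arr = gaussian_filter(rng.normal(size=(27, 27)), 2.0)
        back = resize_bilinear(resize_bilinear(arr, 224), 27)
        assert np.abs(back - arr).max() < 0.02


class TestMakeStack:
    def test_identical_doses_zero_stack(self, synth_beam, noiseless_engine):
        dose = beam_dose(synth_beam, noiseless_engine)
        stack = make_stack(dose, dose, label="error_free", size=96)
        assert stack.label == "error_free"
        np.testing.assert_array_equal(stack.channels, 0.0)

    def test_channel_ranges_bounded(self, synth_beam, engine):
        free = beam_dose(synth_beam, engine)
        meas = measure(free, engine)
        pred = beam_dose(inject_opening(synth_beam, 2.0), engine)
        stack = make_stack(pred, meas, size=96)
        assert np.abs(stack.channels).max() <= 1.0

    def test_single_channel_extraction(self, synth_beam, engine):
        free = beam_dose(synth_beam, engine)
        stack = make_stack(free, measure(free, engine), size=96)
        for name, idx in (("dd", 0), ("gamma32", 1), ("gamma21", 2)):
            ch = stack.channel(name)
            assert ch.shape == (96, 96, 1)
            np.testing.assert_array_equal(ch[:, :, 0], stack.channels[:, :, idx])

    def test_opening_ring_is_cold_closing_ring_is_hot(self, synth_beam,
                                                      noiseless_engine):
        """With reference = predicted-with-error and evaluated = error-free
        measurement, a widened predicted field makes the expanded ring COLD
        (measured below prediction) and a narrowed field makes it HOT."""
        free = beam_dose(synth_beam, noiseless_engine)
        ring = None
        for op, sign in ((inject_opening, -1), (inject_closing, +1)):
            pred = beam_dose(op(synth_beam, 2.0), noiseless_engine)
            dd = dd_map(pred, free)
            ring = np.abs(pred.values - free.values) > 0.02 * free.values.max()
            assert ring.any()
            assert sign * dd[ring].mean() > 0
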