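"""Orientation preference maps: learning, filtering, composites, spectra."""

import numpy as np
import pytest

import v1field as vf
from v1field.orientation_map import (
    MapLearningConfig,
    OrientationMap,
    band_filter,
    composite,
    learn_map,
    pinwheel_count,
    resample_map,
    sample_locations,
    spectral_power,
    synthetic_map,
)


class TestLearning:
    def test_first_update_local_to_footprint(self, dom64, kernels64):
        cfg = MapLearningConfig(steps=1, seed=5, t_learn=150.0, dt=2.0)
        omap = learn_map(cfg, dom64, kernels64, apply_filter=False)
        total = np.abs(omap.J).sum(axis=0)
        # the footprint edge is a Gaussian ring, so "outside" means beyond
        # its numerically relevant support
        changed = total > 1e-3 * total.max()
        assert changed.any()
        # everything beyond the stimulated neighbourhood stays exactly zero
        ys, xs = np.nonzero(changed)
        coords = dom64.coords
        # the changed set must fit inside one stimulated footprint
        # (plateau + 3 edge widths around an unknown random center)
        lam = omap.Lambda
        max_r = (0.7 + 3 * 0.3) * lam
        dy = dom64.wrap(coords[ys] - coords[ys[0]])
        dx = dom64.wrap(coords[xs] - coords[xs[0]])
        assert np.hypot(dy, dx).max() <= 2 * max_r

    def test_learned_values_rectified(self, learned_map64):
        assert learned_map64.J.min() >= -1.0
        assert learned_map64.J.max() <= 1.0

    def test_spectral_peak_near_hypercolumn_wavenumber(self, learned_map64):
        _, _, k_peak, _ = spectral_power(
            learned_map64.complex_field(), learned_map64.domain
        )
        k0 = 2 * np.pi / learned_map64.Lambda
        assert abs(k_peak - k0) <= 0.2 * k0

    def test_pinwheel_trace_recorded(self, learned_map64):
        trace = learned_map64.provenance["pinwheel_trace"]
        assert len(trace) == 2  # checkpoints at 400 and 800 of the reduced schedule
        assert all(count > 0 for _, count in trace)

    def test_orientation_representation_roughly_equal(self, learned_map64):
        pref, _ = composite(learned_map64)
        counts, _ = np.histogram(pref[~np.isnan(pref)], bins=8, range=(0, 180))
        # the reduced 800-step schedule is not fully converged; the flatness
        # bound here is a regression guard, tighter bounds hold at full length
        assert counts.max() / counts.min() <= 1.8

    def test_learning_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            MapLearningConfig(h_a=0.0)


class TestBandFilter:
    def test_components_near_zero_mean(self, dom64):
        rng = np.random.default_rng(0)
        raw = OrientationMap(domain=dom64, J=rng.uniform(0, 1, size=(4, 64, 64)))
        filtered = band_filter(raw, saturate_percentile=None)
        for i in range(4):
            comp = filtered.J[i]
            assert abs(comp.mean()) <= 1e-6 * np.abs(comp).max()

    def test_plane_wave_at_peak_passes(self, dom64):
        x = dom64.coords
        k0 = 1.0
        wave = np.cos(k0 * x)[None, :] * np.ones((dom64.N, 1))
        J = np.stack([wave, np.zeros_like(wave), -wave, np.zeros_like(wave)])
        omap = OrientationMap(domain=dom64, J=0.5 * J)
        filtered = band_filter(omap, k0=k0, saturate_percentile=None)
        ratio = np.abs(filtered.complex_field()).max() / np.abs(omap.complex_field()).max()
        assert ratio >= 0.9

    def test_peak_wavenumber_stable_under_filtering(self, learned_map64):
        dom = learned_map64.domain
        _, _, k_before, _ = spectral_power(learned_map64.complex_field(), dom)
        again = band_filter(learned_map64, saturate_percentile=None)
        _, _, k_after, _ = spectral_power(again.complex_field(), dom)
        assert abs(k_after - k_before) <= np.pi / dom.L + 1e-12

    def test_empty_pass_band_rejected(self, synth_map64):
        with pytest.raises(ValueError):
            band_filter(synth_map64, k0=1.0, halfwidth=0.0)


class TestComposite:
    def _map_with(self, dom, j0=0.0, j45=0.0, j90=0.0, j135=0.0):
        J = np.zeros((4, dom.N, dom.N))
        J[0] = j0
        J[1] = j45
        J[2] = j90
        J[3] = j135
        return OrientationMap(domain=dom, J=J)

    def test_single_component_zero_degrees(self, dom64):
        pref, sel = composite(self._map_with(dom64, j0=1.0))
        assert np.allclose(pref, 0.0)
        assert np.allclose(sel, 1.0)

    def test_single_component_45_degrees(self, dom64):
        pref, sel = composite(self._map_with(dom64, j45=0.5))
        assert np.allclose(pref, 45.0)
        assert np.allclose(sel, 0.5)

    def test_equal_components_cancel(self, dom64):
        pref, sel = composite(self._map_with(dom64, j0=0.3, j45=0.3, j90=0.3, j135=0.3))
        assert np.allclose(sel, 0.0)
        assert np.all(np.isnan(pref))


class TestSpectralPower:
    def test_plane_wave_peak_bin(self, dom64):
        x = dom64.coords
        k0 = 1.5
        z = np.exp(1j * k0 * x)[None, :] * np.ones((dom64.N, 1))
        k_centers, power, k_peak, _ = spectral_power(z, dom64)
        dk = np.pi / dom64.L
        assert abs(k_peak - k0) <= dk

    def test_white_noise_has_no_dominant_bin(self):
        dom = vf.Domain(L=30.0, N=256)
        rng = np.random.default_rng(0)
        z = rng.normal(size=(256, 256)) + 1j * rng.normal(size=(256, 256))
        _, power, _, _ = spectral_power(z, dom)
        med = np.median(power[1:])
        assert power[1:].max() <= 3 * med

    def test_generated_map_single_dominant_peak(self, synth_map128):
        k_centers, power, k_peak, _ = spectral_power(
            synth_map128.complex_field(), synth_map128.domain
        )
        i_peak = int(np.argmax(power[1:])) + 1
        mask = np.ones(len(power), dtype=bool)
        mask[max(0, i_peak - 2) : i_peak + 3] = False
        mask[0] = False
        assert power[mask].max() < 0.5

    def test_constant_field_degenerate(self, dom64):
        with pytest.warns(UserWarning, match="degenerate"):
            _, power, k_peak, _ = spectral_power(np.ones((64, 64)), dom64)
        assert k_peak == 0.0
        assert np.all(power == 0.0)


class TestPinwheels:
    def test_translation_invariance(self, synth_map64):
        n0 = pinwheel_count(synth_map64)
        rolled = OrientationMap(
            domain=synth_map64.domain,
            J=np.roll(synth_map64.J, 7, axis=2),
            Lambda=synth_map64.Lambda,
        )
        assert pinwheel_count(rolled) == n0

    def test_synthetic_map_has_pinwheels(self, synth_map128):
        # pinwheel density of realistic maps is of order pi per Lambda^2
        n = pinwheel_count(synth_map128)
        area_hypercolumns = (2 * 30.0) ** 2 / synth_map128.Lambda**2
        assert n > area_hypercolumns  # at least ~1 per hypercolumn


class TestSampleLocations:
    def test_cardinality_and_determinism(self, synth_map64):
        a = sample_locations(synth_map64, 5, seed=3)
        b = sample_locations(synth_map64, 5, seed=3)
        assert len(a) == 5
        assert a == b

    def test_all_locations_away_from_pinwheels(self, synth_map64):
        from v1field.tuning import local_kappa

        for loc in sample_locations(synth_map64, 5, seed=4):
            assert local_kappa(synth_map64, loc) >= 1.0

    def test_different_seeds_differ(self, synth_map64):
        assert sample_locations(synth_map64, 5, seed=1) != sample_locations(
            synth_map64, 5, seed=2
        )


class TestResample:
    def test_round_trip_preserves_band_limited_map(self, dom64):
        # an unsaturated filtered map is exactly band-limited, so Fourier
        # up/down-sampling is lossless
        rng = np.random.default_rng(0)
        raw = OrientationMap(domain=dom64, J=rng.uniform(-0.5, 0.5, size=(4, 64, 64)))
        omap = band_filter(raw, saturate_percentile=None)
        up = resample_map(omap, vf.Domain(L=30.0, N=128))
        down = resample_map(up, vf.Domain(L=30.0, N=64))
        np.testing.assert_allclose(down.J, omap.J, atol=1e-6)

    def test_requires_same_physical_domain(self, synth_map64):
        with pytest.raises(ValueError):
            resample_map(synth_map64, vf.Domain(L=20.0, N=128))


def test_synthetic_map_deterministic(dom64):
    a = synthetic_map(dom64, seed=9)
    b = synthetic_map(dom64, seed=9)
    np.testing.assert_array_equal(a.J, b.J)


def test_filtering_commutes_with_translation():
    dom = vf.Domain(L=30.0, N=64)
    omap = synthetic_map(dom, seed=2)
    rolled = OrientationMap(domain=dom, J=np.roll(omap.J, 5, axis=1), Lambda=omap.Lambda)
    f_then_roll = np.roll(band_filter(omap, saturate_percentile=None).J, 5, axis=1)
    roll_then_f = band_filter(rolled, saturate_percentile=None).J
    np.testing.assert_allclose(roll_then_f, f_then_roll, atol=1e-10)
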