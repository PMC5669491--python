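"""Neural field dynamics: sigmoid, inputs, spectral convolution, integration."""

import numpy as np
import pytest
import scipy.fft as sfft

import v1field as vf
from v1field.simulator import (
    ORIENTATIONS,
    ModelParams,
    StimulusSpec,
    _RHS,
    input_field,
    integrate,
    sigmoid,
)


class TestSigmoid:
    def test_zero_at_rest(self):
        assert sigmoid(0.0) == 0.0

    def test_value_at_threshold(self):
        # u = theta/mu is the midpoint of the logistic
        expect = 0.5 - 1.0 / (1.0 + np.exp(5.6))
        assert sigmoid(5.6 / 2.3) == pytest.approx(expect, abs=1e-5)
        assert expect == pytest.approx(0.49632, abs=1e-5)

    def test_upper_asymptote(self):
        expect = 1.0 - 1.0 / (1.0 + np.exp(5.6))
        assert sigmoid(1e3) == pytest.approx(expect, abs=1e-8)
        assert expect == pytest.approx(0.99632, abs=1e-5)

    def test_strictly_increasing(self):
        u = np.linspace(-5, 8, 200)
        assert np.all(np.diff(sigmoid(u)) > 0)


class TestModelParams:
    def test_threshold_contracts_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(k1=2.0)  # mu*k1 < theta
        with pytest.raises(ValueError):
            ModelParams(k2=3.0)  # mu*k2 > theta

    def test_defaults_satisfy_contracts(self):
        p = ModelParams()
        assert p.mu * p.k1 > p.theta
        assert p.mu * p.k2 < p.theta
        assert p.k1 == 2 * p.k2


class TestInputField:
    def test_plateau_value(self, dom64):
        stim = StimulusSpec(orientation=0, center=(0.0, 0.0))
        assert stim.radial_profile(np.array(0.0)) == 1.0

    def test_edge_value_one_sigma_out(self):
        stim = StimulusSpec()
        lam = stim.Lambda
        assert stim.radial_profile(np.array(lam)) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_ramp_midpoint(self):
        stim = StimulusSpec()
        assert stim.ramp_factor(70.0) == 0.5
        assert stim.ramp_factor(0.0) == 0.0
        assert stim.ramp_factor(500.0) == 1.0

    def test_gain_weighting(self, dom64):
        p = ModelParams()
        stim = StimulusSpec(orientation=90, center=(0.0, 0.0))
        fields = input_field(stim, dom64, p, J=None, t=None)
        j = ORIENTATIONS.index(90)
        center = (0, dom64.N // 2)  # x=0 is at index N/2; y=0 likewise
        iy, ix = dom64.nearest_node((0.0, 0.0))
        assert fields[j, iy, ix] == pytest.approx(p.k1)
        for other in set(range(4)) - {j}:
            assert fields[other, iy, ix] == pytest.approx(p.k2)

    def test_center_outside_domain_rejected(self, dom64):
        stim = StimulusSpec(center=(45.0, 0.0))
        with pytest.raises(ValueError):
            input_field(stim, dom64, ModelParams(), None)

    def test_half_max_footprint_radius(self):
        stim = StimulusSpec()
        r_ff = stim.r_ff
        assert stim.radial_profile(np.array(r_ff)) == pytest.approx(0.5, rel=1e-12)
        assert r_ff > stim.plateau_radius


class TestRHS:
    def test_zero_state_zero_input_is_fixed_point(self, dom64, kernels64):
        stim = StimulusSpec(amplitude=0.0)
        f = _RHS(ModelParams(), dom64, kernels64, None, stim)
        du = f(100.0, np.zeros((4, 64, 64)))
        assert np.abs(du).max() == 0.0

    def test_uniform_state_pure_decay_with_zero_kernels(self, dom64, kernels64):
        import copy

        k = copy.copy(kernels64)
        k.spec_eloc = np.zeros_like(kernels64.spec_eloc)
        k.spec_elat = np.zeros_like(kernels64.spec_elat)
        k.spec_i = np.zeros_like(kernels64.spec_i)
        p = ModelParams()
        stim = StimulusSpec(amplitude=0.0)
        f = _RHS(p, dom64, k, None, stim)
        u = np.ones((4, 64, 64)) * np.array([1.0, 2.0, -1.0, 0.5])[:, None, None]
        du = f(0.0, u)
        expect = -(p.rho_same * u + p.rho_cross * (u.sum(axis=0) - u)) / p.tau
        np.testing.assert_allclose(du, expect, atol=1e-12)

    def test_spectral_convolution_matches_direct_double_sum(self):
        """FFT convolution equals the brute-force periodic double sum."""
        rng = np.random.default_rng(0)
        n = 16
        field = rng.normal(size=(n, n))
        kern = rng.normal(size=(n, n))
        direct = np.zeros((n, n))
        for iy in range(n):
            for ix in range(n):
                acc = 0.0
                for jy in range(n):
                    for jx in range(n):
                        acc += kern[(iy - jy) % n, (ix - jx) % n] * field[jy, jx]
                direct[iy, ix] = acc
        spectral = sfft.irfft2(sfft.rfft2(field) * sfft.rfft2(kern), s=(n, n))
        np.testing.assert_allclose(spectral, direct, atol=1e-10)


class TestIntegrate:
    def test_resting_state_without_input(self, dom64, kernels64):
        stim = StimulusSpec(amplitude=0.0, t_final=300.0, snapshot_dt=100.0)
        res = integrate(ModelParams(), dom64, kernels64, None, stim, dt=1.0)
        assert res.diagnostics["max_abs_u"] <= 1e-8
        assert not res.unbounded

    def test_small_perturbation_decays(self, dom64, kernels64):
        rng = np.random.default_rng(1)
        u0 = 0.01 * rng.uniform(-1, 1, size=(4, 64, 64))
        stim = StimulusSpec(amplitude=0.0, t_final=200.0, snapshot_dt=100.0)
        res = integrate(ModelParams(), dom64, kernels64, None, stim, dt=1.0, u0=u0)
        assert np.abs(res.u_final).max() <= 1e-6

    def test_population_symmetry_under_orientation_relabeling(self, dom64, kernels64):
        """With a flat map the four sub-populations are interchangeable."""
        p = ModelParams()
        res0 = integrate(
            p, dom64, kernels64, None,
            StimulusSpec(orientation=0, t_final=200.0, snapshot_dt=200.0), dt=1.0,
        )
        res45 = integrate(
            p, dom64, kernels64, None,
            StimulusSpec(orientation=45, t_final=200.0, snapshot_dt=200.0), dt=1.0,
        )
        perm = np.roll(res0.u_final, 1, axis=0)  # 0->45, 45->90, ...
        np.testing.assert_allclose(res45.u_final, perm, atol=1e-10)

    def test_translation_equivariance(self, dom64, kernels64):
        p = ModelParams()
        h = dom64.h
        res_a = integrate(
            p, dom64, kernels64, None,
            StimulusSpec(center=(0.0, 0.0), t_final=150.0, snapshot_dt=150.0), dt=1.0,
        )
        res_b = integrate(
            p, dom64, kernels64, None,
            StimulusSpec(center=(5 * h, 3 * h), t_final=150.0, snapshot_dt=150.0), dt=1.0,
        )
        shifted = np.roll(np.roll(res_a.u_final, 3, axis=1), 5, axis=2)
        np.testing.assert_allclose(res_b.u_final, shifted, atol=1e-8)

    def test_only_stimulated_population_supra_threshold(self, dom64, kernels64, synth_map64):
        """Regression for the cross-decay level: rho_cross = 0.1 < 0.2 keeps
        non-stimulated sub-populations below the activation threshold."""
        p = ModelParams()
        stim = StimulusSpec(orientation=0, t_final=400.0, snapshot_dt=400.0)
        res = integrate(p, dom64, kernels64, synth_map64, stim, dt=1.0)
        thr = p.theta / p.mu
        assert res.u_final[0].max() > thr
        assert res.u_final[1:].max() < thr

    def test_bumps_align_with_map_maxima(self, dom64, kernels64, synth_map64):
        """With beta_inp = 0.25 the multi-bump phase locks to the map."""
        from scipy.ndimage import maximum_filter

        p = ModelParams()
        stim = StimulusSpec(orientation=0, center=(0.0, 0.0), t_final=400.0, snapshot_dt=400.0)
        res = integrate(p, dom64, kernels64, synth_map64, stim, dt=1.0)
        u0 = res.u_final[0]
        r = dom64.radius_from((0.0, 0.0))
        thr = p.theta / p.mu
        bumps = (u0 == maximum_filter(u0, size=3)) & (u0 > thr) & (r < stim.r_ff)
        assert bumps.any()
        j0 = synth_map64.J[0]
        jmax = (j0 == maximum_filter(j0, size=5)) & (j0 > 0.5)
        ys, xs = np.nonzero(bumps)
        my, mx = np.nonzero(jmax)
        coords = dom64.coords
        for y, x in zip(ys, xs):
            d = np.hypot(
                dom64.wrap(coords[mx] - coords[x]), dom64.wrap(coords[my] - coords[y])
            )
            assert d.min() <= 0.15 * synth_map64.Lambda

    def test_unbounded_flag_in_reduced_inhibition_regime(self, dom64, synth_map64):
        prof = vf.build_profile(vf.ConnectivityParams(C=-0.2))
        res = integrate(
            ModelParams(beta_rec=0.9), dom64, prof, synth_map64,
            StimulusSpec(orientation=0, t_final=550.0, snapshot_dt=550.0), dt=2.0,
        )
        assert res.unbounded

    def test_rk45_matches_rk4_on_short_run(self, dom64, kernels64, synth_map64):
        stim = StimulusSpec(orientation=0, t_final=150.0, snapshot_dt=150.0)
        a = integrate(ModelParams(), dom64, kernels64, synth_map64, stim, method="rk4", dt=0.5)
        b = integrate(ModelParams(), dom64, kernels64, synth_map64, stim, method="rk45")
        assert np.abs(a.u_final - b.u_final).max() < 1e-3
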