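"""Brush force law and the two-regime Hertz + brush decomposition."""

import dataclasses
import math

import numpy as np
import pytest

from glycoforce import (
    BrushHertzModel,
    CurveSim,
    GlycoforceError,
    brush_force,
    correct_baseline,
    decompose_curve,
    fit_brush,
    fit_hertz,
    simulate_curve,
)
from glycoforce._constants import BOLTZMANN_PN_NM


class TestBrushForce:
    def test_closed_form_value(self):
        # independent SI evaluation: 50 kB T R N^{3/2} L exp(-2 pi h / L)
        kb = 1.380649e-23
        expected_n = 50 * kb * 309.35 * 1.25e-6 * (1e14) ** 1.5 * 300e-9 \
            * math.exp(-2 * math.pi * 90 / 300)
        got = brush_force(300.0, 1e14, 1.25, 309.35, 90.0)
        assert got == pytest.approx(expected_n / 1e-12, rel=1e-9)
        assert got == pytest.approx(12.2, rel=5e-3)

    def test_exponential_decay(self):
        f0 = brush_force(250.0, 1e14, 1.25, 309.35, 0.0)
        f_far = brush_force(250.0, 1e14, 1.25, 309.35, 2500.0)
        assert f_far < 1e-2 * f0

    def test_log_slope_is_minus_two_pi_over_L(self):
        L = 217.0
        h = np.linspace(10, 400, 200)
        f = brush_force(L, 2e14, 1.25, 309.35, h)
        slopes = np.diff(np.log(f)) / np.diff(h)
        np.testing.assert_allclose(slopes, -2 * np.pi / L, rtol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(GlycoforceError):
            brush_force(-1.0, 1e14, 1.25, 309.35, 10.0)
        with pytest.raises(GlycoforceError):
            brush_force(300.0, 1e14, 1.25, 309.35, -5.0)


class TestFitBrush:
    def test_noiseless_round_trip(self, noiseless_decomposition):
        res, truth = noiseless_decomposition
        assert res.brush_detected
        assert res.params["L_nm"] == pytest.approx(truth.L_nm, rel=0.01)
        assert res.params["N_per_m2"] == pytest.approx(truth.N_per_m2, rel=0.05)

    def test_pure_hertz_curve_has_no_brush(self):
        curve, _ = simulate_curve(CurveSim(brush=False, noise_sd_pn=0.0),
                                  seed=11)
        decomp = decompose_curve(curve)
        assert not decomp.brush_detected
        assert decomp.brush is None
        assert "no_brush" in decomp.quality_flags

    def test_loglinear_initializer_matches_regression_oracle(self):
        # the weighted log-linear stage must equal the closed-form weighted
        # regression (numpy polyfit with sqrt-weight convention)
        from glycoforce.brush import _loglinear_init
        h = np.linspace(30, 240, 60)
        f = brush_force(300.0, 1e14, 1.25, 309.35, h)
        slope, intercept, r2 = _loglinear_init(h, np.asarray(f))
        oracle = np.polyfit(h, np.log(f), 1, w=np.asarray(f))
        assert slope == pytest.approx(oracle[0], abs=1e-9)
        assert intercept == pytest.approx(oracle[1], abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_ensemble_median_L(self):
        Ls = []
        for seed in range(40):
            curve, truth = simulate_curve(CurveSim(noise_sd_pn=3.0),
                                          seed=500 + seed)
            res = BrushHertzModel(curve).fit()
            if res.brush_detected:
                Ls.append(res.params["L_nm"])
        assert len(Ls) >= 25
        assert np.median(Ls) == pytest.approx(300.0, rel=0.10)

    def test_L_invariant_under_N_rescaling(self):
        # N enters only the intercept of the log-linear law, so L must not
        # move when the grafting density changes
        Ls = []
        for N in (5e13, 1e14, 4e14):
            curve, _ = simulate_curve(
                CurveSim(noise_sd_pn=0.0, N_per_m2=N), seed=12)
            res = BrushHertzModel(curve).fit()
            Ls.append(res.params["L_nm"])
        assert max(Ls) / min(Ls) - 1 < 0.01


class TestDecompose:
    def test_joint_round_trip(self):
        curve, truth = simulate_curve(
            CurveSim(E_pa=2000.0, L_nm=250.0, N_per_m2=2e14, noise_sd_pn=0.0),
            seed=13)
        decomp = decompose_curve(curve)
        assert decomp.hertz.E_pa == pytest.approx(2000.0, rel=0.005)
        assert decomp.brush.L_nm == pytest.approx(250.0, rel=0.02)

    def test_rigid_substrate_brush_recovery(self):
        curve, truth = simulate_curve(
            CurveSim(rigid_substrate=True, L_nm=300.0, noise_sd_pn=0.0),
            seed=14)
        decomp = decompose_curve(curve)
        assert decomp.brush_detected
        assert decomp.brush.L_nm == pytest.approx(300.0, rel=0.05)

    def test_deterministic_bitwise(self, noiseless_curve):
        curve, _ = noiseless_curve
        a = decompose_curve(curve)
        b = decompose_curve(curve)
        assert dataclasses.asdict(a.hertz) == dataclasses.asdict(b.hertz)
        assert dataclasses.asdict(a.brush) == dataclasses.asdict(b.brush)
        assert a.quality_flags == b.quality_flags

    def test_errors_converge_with_vanishing_noise(self):
        # the ensemble-median estimate converges to truth as force noise
        # vanishes; single-curve scatter grows with the noise level
        med_dev = {}
        for sd in (0.0, 1.0, 3.0, 10.0):
            Ls = []
            for seed in range(12):
                curve, truth = simulate_curve(CurveSim(noise_sd_pn=sd),
                                              seed=700 + seed)
                res = BrushHertzModel(curve).fit()
                if res.brush_detected:
                    Ls.append(res.params["L_nm"])
            # a level where no brush is ever separated counts as failure
            med_dev[sd] = abs(np.median(Ls) / 300.0 - 1) if Ls else np.inf
        assert med_dev[0.0] < 1e-3
        assert med_dev[0.0] <= med_dev[10.0]
        assert med_dev[1.0] <= 0.05 and med_dev[3.0] <= 0.10

    def test_pyramid_probe_rejected(self):
        from glycoforce import ProbeGeometry
        curve, _ = simulate_curve(
            CurveSim(brush=False, probe=ProbeGeometry.pyramid(),
                     spring_constant=0.01, delta_max_nm=300.0,
                     noise_sd_pn=0.0), seed=15)
        with pytest.raises(GlycoforceError, match="spherical"):
            decompose_curve(curve)

    def test_fit_brush_requires_hertz_subtraction_inputs(self, noiseless_curve):
        curve, _ = noiseless_curve
        work = correct_baseline(curve)
        hf = fit_hertz(work, fit_offset=True)
        bf = fit_brush(work, hf)
        assert bf is not None
        assert 0.1 * bf.L_nm <= bf.h_window_nm[0] * 1.2  # window near band
        assert bf.r_squared_loglinear > 0.99
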