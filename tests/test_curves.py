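"""Curve container, I/O dialect, baseline correction and tip-sample kinematics."""

import numpy as np
import pytest

from glycoforce import (
    CantileverCalibration,
    CurveParseError,
    CurveSim,
    ForceCurve,
    GlycoforceError,
    InvariantError,
    MapHeader,
    ProbeGeometry,
    correct_baseline,
    fit_hertz,
    read_curves,
    read_map,
    simulate_curve,
    to_tip_sample,
    write_curves,
    write_map,
)


def _flat_curve(n=32, force=0.0, z0=None, k=0.02):
    z = np.linspace(1000.0, 0.0, n)
    calib = CantileverCalibration(spring_constant=k)
    f = np.full(n, float(force))
    return ForceCurve(z_nm=z, force_pn=f, deflection_nm=f / calib.k_pn_per_nm,
                      calibration=calib)


class TestIO:
    def test_roundtrip_preserves_channels_and_metadata(self, tmp_path,
                                                       noiseless_curve):
        curve, _ = noiseless_curve
        path = tmp_path / "c.tsv"
        write_curves(path, curve)
        (back,) = read_curves(path)
        np.testing.assert_allclose(back.z_nm, curve.z_nm, rtol=1e-9)
        np.testing.assert_allclose(back.force_pn, curve.force_pn, rtol=1e-9)
        np.testing.assert_allclose(back.deflection(), curve.deflection(),
                                   rtol=1e-9)
        assert back.probe == curve.probe
        assert back.calibration == curve.calibration
        assert back.segment == "approach"
        assert back.temperature_k == curve.temperature_k

    def test_multi_record_file(self, tmp_path, noiseless_curve,
                               hertz_only_curve):
        c1, _ = noiseless_curve
        c2, _ = hertz_only_curve
        path = tmp_path / "two.tsv"
        write_curves(path, [c1, c2])
        curves = read_curves(path)
        assert len(curves) == 2
        np.testing.assert_allclose(curves[1].force_pn, c2.force_pn, rtol=1e-9)

    def test_channel_length_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["# glycoforce-curve v1", "# segment: approach"]
        lines += [f"{1000 - i}\t0.0" for i in range(20)]
        lines.append("42.0")  # ragged row
        path.write_text("\n".join(lines))
        with pytest.raises(CurveParseError, match="columns"):
            read_curves(path)

    def test_non_monotone_approach_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        z = list(range(20))
        z[5] = 3  # break monotonicity
        lines = ["# glycoforce-curve v1"] + [f"{zi}\t0.0" for zi in z]
        path.write_text("\n".join(lines))
        with pytest.raises(CurveParseError, match="monotone"):
            read_curves(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(CurveParseError):
            read_curves(tmp_path / "nope.tsv")

    def test_map_roundtrip(self, tmp_path, noiseless_curve):
        curve, _ = noiseless_curve
        header = MapHeader(grid_shape=(2, 2), step_um=1.5)
        grid = [[curve, None], [None, curve]]
        write_map(tmp_path / "m", header, grid)
        back_header, back = read_map(tmp_path / "m")
        assert back_header == header
        assert back[0][1] is None and back[1][0] is None
        np.testing.assert_allclose(back[1][1].force_pn, curve.force_pn,
                                   rtol=1e-9)


class TestInvariants:
    def test_too_few_samples_rejected(self):
        with pytest.raises(InvariantError, match="samples"):
            _flat_curve(n=10)

    def test_force_deflection_consistency_enforced(self):
        z = np.linspace(100.0, 0.0, 20)
        with pytest.raises(InvariantError, match="spring_constant"):
            ForceCurve(z_nm=z, force_pn=np.ones(20),
                       deflection_nm=np.ones(20))  # k=0.02 -> F should be 20

    def test_probe_geometry_validation(self):
        with pytest.raises(InvariantError):
            ProbeGeometry(kind="sphere", radius_um=-1.0)
        with pytest.raises(InvariantError):
            ProbeGeometry(kind="pyramid", half_angle_deg=95.0)
        with pytest.raises(InvariantError):
            ProbeGeometry(kind="sphere", radius_um=1.0, half_angle_deg=10.0)


class TestBaseline:
    @pytest.mark.parametrize("offset,slope", [(5.0, 0.0), (5.0, 0.01)])
    def test_removes_offset_and_tilt(self, offset, slope):
        curve, _ = simulate_curve(
            CurveSim(noise_sd_pn=0.0, baseline_offset_pn=offset,
                     baseline_slope_pn_per_nm=slope), seed=3)
        corr = correct_baseline(curve, 0.3)
        far = corr.force_pn[: corr.n // 5]  # non-contact end
        assert abs(far.mean()) < 1e-6
        assert abs(np.polyfit(corr.z_nm[: corr.n // 5], far, 1)[0]) < 1e-6

    def test_idempotent(self, noiseless_curve):
        curve, _ = noiseless_curve
        once = correct_baseline(curve, 0.3)
        twice = correct_baseline(once, 0.3)
        np.testing.assert_allclose(twice.force_pn, once.force_pn, atol=1e-9)

    def test_offset_does_not_change_fitted_modulus(self):
        clean, _ = simulate_curve(CurveSim(brush=False, noise_sd_pn=0.0), seed=4)
        shifted, _ = simulate_curve(
            CurveSim(brush=False, noise_sd_pn=0.0, baseline_offset_pn=12.0),
            seed=4)
        E_clean = fit_hertz(correct_baseline(clean)).E_pa
        E_shift = fit_hertz(correct_baseline(shifted)).E_pa
        assert abs(E_shift / E_clean - 1) < 1e-3

    def test_window_too_small_rejected(self):
        curve = _flat_curve(n=20)
        with pytest.raises(GlycoforceError, match="window"):
            correct_baseline(curve, 0.1)  # 2 samples < 8


class TestTipSample:
    def test_rigid_sample_limit(self):
        curve = _flat_curve(n=32)  # d == 0 everywhere
        out = to_tip_sample(curve, contact_z0=400.0)
        expected = np.maximum(0.0, 400.0 - curve.z_nm)
        np.testing.assert_allclose(out.indentation_nm, expected, atol=1e-12)

    def test_infinitely_soft_cantilever_surrogate(self):
        z = np.linspace(1000.0, 0.0, 64)
        z0 = 500.0
        calib = CantileverCalibration(spring_constant=0.02)
        d = np.maximum(0.0, z0 - z)  # all travel absorbed by deflection
        curve = ForceCurve(z_nm=z, force_pn=calib.k_pn_per_nm * d,
                           deflection_nm=d, calibration=calib)
        out = to_tip_sample(curve, z0)
        np.testing.assert_allclose(out.indentation_nm, 0.0, atol=1e-12)

    def test_generator_bookkeeping(self, noiseless_curve):
        curve, truth = noiseless_curve
        out = to_tip_sample(curve, truth.z0_nm)
        np.testing.assert_allclose(out.indentation_nm,
                                   truth.true_indentation_nm, atol=1e-9)
        np.testing.assert_allclose(out.separation_nm,
                                   truth.true_separation_nm, atol=1e-9)

    def test_z0_out_of_range_rejected(self):
        curve = _flat_curve()
        with pytest.raises(GlycoforceError, match="range"):
            to_tip_sample(curve, 5000.0)
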