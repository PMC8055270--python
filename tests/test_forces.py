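"""Weight-support normalization, lift/drag geometry, and force assembly."""

import numpy as np
import pytest

import winghum as wh
from winghum.forces import build_wing_forces


@pytest.fixture(scope="module")
def hb_trajs(medium):
    spec = wh.make_preset("hummingbird").spec
    return (
        wh.source_trajectory(spec, medium, "left", 256, 2),
        wh.source_trajectory(spec, medium, "right", 256, 2),
    )


class TestNormalizeWeightSupport:
    def test_constant_profile_rescales_to_weight(self):
        out = wh.normalize_weight_support(np.full(64, 2.0), body_mass=0.005)
        np.testing.assert_allclose(out, 0.04905, rtol=1e-12)

    def test_half_sine_mean_is_body_weight(self):
        tau = np.arange(256) / 256
        prof = np.where(tau < 0.5, np.sin(2 * np.pi * tau), 0.0)
        out = wh.normalize_weight_support(prof, body_mass=0.03)
        assert out.mean() == pytest.approx(0.03 * 9.81, rel=1e-12)

    def test_shape_preserved_up_to_scalar(self):
        prof = 1.0 + 0.5 * np.cos(2 * np.pi * np.arange(64) / 64)
        out = wh.normalize_weight_support(prof, body_mass=0.005)
        ratio = out / prof
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    @pytest.mark.parametrize("bad", [np.zeros(16), -np.ones(16), np.array([])])
    def test_degenerate_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            wh.normalize_weight_support(bad, body_mass=0.005)

    def test_hummingbird_profile_has_strong_first_two_harmonics(self):
        series = wh.normalize_weight_support(
            wh.make_preset("hummingbird").profile, body_mass=0.005
        ).series
        a1, a2 = series.harmonic_amplitude(1), series.harmonic_amplitude(2)
        a3 = series.harmonic_amplitude(3)
        assert a1 > 2 * a3 and a2 > 2 * a3
        assert 0.5 < a1 / a2 < 2.0


class TestDragFromLift:
    def test_constant_ratio(self):
        D = wh.drag_from_lift(np.full(8, 0.1), 2.0)
        np.testing.assert_allclose(D, 0.05)

    def test_zero_lift_gives_zero_drag(self):
        assert wh.drag_from_lift(np.zeros(8), 1.7).max() == 0.0

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            wh.drag_from_lift(np.ones(8), 0.0)

    def test_symmetric_lift_gives_even_harmonic_drag(self):
        """|L| of a sign-flipping half-stroke lift is even-harmonic dominated."""
        tau = np.arange(256) / 256
        L = np.sin(2 * np.pi * tau)  # flips sign each half stroke
        D = wh.drag_from_lift(L, 2.0)
        X = np.abs(np.fft.rfft(D - D.mean()))
        assert X[2] > 5 * X[1] and X[2] > X[3]


class TestAssembleForceVector:
    def test_sign_flipping_lift_supports_weight_both_half_strokes(self, hb_trajs):
        left, _ = hb_trajs
        n = left.samples_per_period
        tau = np.arange(n) / n
        L = 0.02 * np.sign(np.sin(2 * np.pi * tau) + 1e-30) * np.abs(np.sin(2 * np.pi * tau))
        F = wh.assemble_force_vector(left, L, np.zeros(n))
        fz = F.one_period()[:, 2]
        moving = np.abs(L) > 0.2 * np.abs(L).max()
        assert (fz[moving] > 0).all()

    def test_drag_alternates_and_cancels_over_wingbeat(self, medium):
        spec = wh.FlappingSpec(body_mass=5e-3, wing_length=0.058)  # symmetric stroke
        left = wh.source_trajectory(spec, medium, "left", 256, 1)
        n = left.samples_per_period
        D = np.full(n, 0.01)
        F = wh.assemble_force_vector(left, np.zeros(n), D)
        fx = F.one_period()[:, 0]
        assert fx.max() > 0 and fx.min() < 0
        assert abs(np.mean(fx)) < 1e-4 * np.abs(fx).max()

    def test_zero_inputs_give_zero_force(self, hb_trajs):
        left, _ = hb_trajs
        n = left.samples_per_period
        F = wh.assemble_force_vector(left, np.zeros(n), np.zeros(n))
        assert np.abs(F.force).max() == 0.0

    def test_lateral_components_cancel_for_symmetric_inputs(self, hb_trajs):
        left, right = hb_trajs
        forces = build_wing_forces(
            left, right, wh.make_preset("hummingbird").profile, 5e-3
        )
        fy = forces["left"].force[:, 1] + forces["right"].force[:, 1]
        scale = np.abs(forces["left"].force).max()
        np.testing.assert_allclose(fy, 0.0, atol=1e-12 * scale)

    def test_nonfinite_inputs_rejected(self, hb_trajs):
        left, _ = hb_trajs
        n = left.samples_per_period
        bad = np.zeros(n)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            wh.assemble_force_vector(left, bad, np.zeros(n))


class TestDecomposeNetForce:
    def test_roundtrip_recovers_lift_and_drag(self, hb_trajs):
        left, right = hb_trajs
        n = left.samples_per_period
        tau = np.arange(n) / n
        L = 0.02 * np.sign(np.sin(2 * np.pi * tau) + 1e-30) * (
            0.5 + 0.5 * np.abs(np.sin(2 * np.pi * tau))
        )
        D = np.abs(L) / 2.0
        net = (
            wh.assemble_force_vector(left, L, D).one_period()
            + wh.assemble_force_vector(right, L, D).one_period()
        )
        rec = wh.decompose_net_force(net, left, right)
        speed = np.linalg.norm(left.velocity[:n], axis=1)
        away = speed > 0.2 * speed.max()
        for side in ("left", "right"):
            np.testing.assert_allclose(rec[side].lift[away], L[away], rtol=1e-9)
            np.testing.assert_allclose(rec[side].drag[away], D[away], rtol=1e-9)

    def test_zero_net_force(self, hb_trajs):
        left, right = hb_trajs
        n = left.samples_per_period
        rec = wh.decompose_net_force(np.zeros((n, 3)), left, right)
        assert np.abs(rec["left"].lift).max() == 0.0
        assert np.abs(rec["right"].drag).max() == 0.0

    def test_grid_mismatch_rejected(self, hb_trajs):
        left, right = hb_trajs
        with pytest.raises(ValueError):
            wh.decompose_net_force(np.zeros((100, 3)), left, right)


class TestLowpassForces:
    def test_dc_gain_is_unity(self):
        out = wh.lowpass_forces(np.full(2048, 3.7), order=8, cutoff=180, sample_rate=4000)
        np.testing.assert_allclose(out, 3.7, rtol=1e-9)

    def test_passband_tone_preserved(self):
        t = np.arange(8192) / 4000.0
        x = np.sin(2 * np.pi * 44.2 * t)
        y = wh.lowpass_forces(x, order=8, cutoff=180, sample_rate=4000)
        mid = slice(2048, -2048)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated(self):
        t = np.arange(8192) / 4000.0
        x = np.sin(2 * np.pi * 400.0 * t)
        y = wh.lowpass_forces(x, order=8, cutoff=180, sample_rate=4000)
        mid = slice(2048, -2048)
        atten_db = 20 * np.log10(np.abs(y[mid]).max())
        assert atten_db < -20.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            wh.lowpass_forces(np.zeros(128), cutoff=2500, sample_rate=4000)


class TestConservation:
    @pytest.mark.parametrize("group", wh.PARADIGM_GROUPS)
    def test_mean_vertical_force_equals_weight(self, group, medium):
        """Wingbeat-mean vertical force of both wings equals m*g per preset."""
        preset = wh.make_preset(group)
        left = wh.source_trajectory(preset.spec, medium, "left", 256, 1)
        right = wh.source_trajectory(preset.spec, medium, "right", 256, 1)
        forces = build_wing_forces(left, right, preset.profile, preset.spec.body_mass, medium)
        mean_fz = sum(f.one_period()[:, 2].mean() for f in forces.values())
        target = preset.spec.body_mass * medium.gravity
        assert mean_fz == pytest.approx(target, rel=1e-10)

    def test_first_harmonic_lift_still_mixes_into_second_harmonic_vertical(self, hb_trajs):
        """Half-stroke lift flipping doubles the frequency of vertical force."""
        left, _ = hb_trajs
        n = left.samples_per_period
        tau = np.arange(n) / n
        L = 0.02 * np.sin(2 * np.pi * tau)  # pure harmonic 1, flips with stroke
        F = wh.assemble_force_vector(left, L, np.zeros(n))
        fz = F.one_period()[:, 2]
        X = np.abs(np.fft.rfft(fz - fz.mean()))
        assert X[2] > 0.01 * X.max()
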