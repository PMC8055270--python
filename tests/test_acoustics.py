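"""Moving point-force radiation: retarded time, Eq-form pressures, compactness."""

import numpy as np
import pytest
from scipy.optimize import brentq

import winghum as wh


class TestEmissionMap:
    def test_stationary_source_constant_delay(self, medium):
        times = np.linspace(0, 0.1, 64)
        pos = np.tile([0.0, 0.0, 0.0], (64, 1))
        arrival = wh.emission_map(pos, times, wh.Observer([0, 0, 343.0]), medium)
        np.testing.assert_allclose(arrival - times, 1.0, rtol=1e-12)

    def test_overhead_observer_delay_bounded_by_r3(self, hummingbird_model_short):
        model = hummingbird_model_short
        traj = model.trajectories["left"]
        obs = wh.Observer([0, 0, 0.5])
        arrival = wh.emission_map(traj.position, traj.times, obs, model.medium)
        delay = arrival - traj.times
        bound = model.spec.r3 / model.medium.speed_of_sound
        assert delay.max() - delay.min() <= 2 * bound + 1e-12

    def test_arrival_monotone_and_matches_root_finding(self, hummingbird_model_short):
        """Forward map inverse agrees with direct root finding of the
        retarded-time equation t_obs - t - |r(t)|/ao = 0 within 1e-9 s."""
        model = hummingbird_model_short
        traj = model.trajectories["left"]
        obs = wh.Observer([1.0, 0.2, 0.3])
        arrival = wh.emission_map(traj.position, traj.times, obs, model.medium)
        assert (np.diff(arrival) > 0).all()

        from scipy.interpolate import CubicSpline

        ao = model.medium.speed_of_sound
        n = traj.samples_per_period
        pos_spline = CubicSpline(traj.times[: 2 * n], traj.position[: 2 * n], axis=0)

        def residual(t, t_obs):
            return t_obs - t - np.linalg.norm(obs.position - pos_spline(t)) / ao

        inverse = CubicSpline(arrival, traj.times)
        for t_obs in np.linspace(arrival[8], arrival[n], 5):
            t_emit = brentq(residual, traj.times[0], traj.times[2 * n - 1], args=(t_obs,))
            assert inverse(t_obs) == pytest.approx(t_emit, abs=1e-9)


class TestPressureEq1:
    def test_static_constant_force_quarter_pi(self, medium):
        n = 256
        F = np.tile([0.0, 0.0, 1.0], (n, 1))
        force, traj = wh.stationary_point_source(F, [0, 0, 0], 44.2, n, 2)
        tr = wh.pressure_eq1(force, traj, wh.Observer([0, 0, 1.0]), medium)
        np.testing.assert_allclose(tr.pressure, 1.0 / (4 * np.pi), rtol=1e-12)
        assert np.abs(tr.channels["farfield"]).max() < 1e-12

    def test_oscillating_dipole_matches_closed_form(self, oscillating_dipole, medium):
        """Farfield amplitude of a stationary dipole: 2*pi*f*F0*cos(theta)/(4*pi*ao*r)."""
        force, traj = oscillating_dipole
        f0, r = 44.2, 10.0
        for theta in (0.0, 0.4, 1.1):
            obs = wh.Observer([r * np.sin(theta), 0.0, r * np.cos(theta)])
            tr = wh.pressure_eq1(force, traj, obs, medium)
            ff = tr.channels["farfield"]
            amp = (ff.max() - ff.min()) / 2
            pred = 2 * np.pi * f0 * abs(np.cos(theta)) / (4 * np.pi * 343 * r)
            assert amp == pytest.approx(pred, rel=0.01)

    def test_channels_sum_to_total(self, hummingbird_model_short):
        tr = hummingbird_model_short.pressure(wh.Observer([0.3, 0.1, 0.9]))
        resid = tr.pressure - tr.channels["nearfield"] - tr.channels["farfield"]
        assert np.abs(resid).max() < 1e-10
        resid_wings = tr.pressure - tr.channels["wing_left"] - tr.channels["wing_right"]
        assert np.abs(resid_wings).max() < 1e-10

    def test_superposition_linearity(self, hummingbird_model_short, medium):
        model = hummingbird_model_short
        obs = wh.Observer([0.5, 0.2, 0.8])
        forces = [model.forces["left"], model.forces["right"]]
        trajs = [model.trajectories["left"], model.trajectories["right"]]
        both = wh.pressure_eq1(forces, trajs, obs, medium)
        single = [
            wh.pressure_eq1(f, t, obs, medium, t_start=both.times[0])
            for f, t in zip(forces, trajs)
        ]
        total = single[0].pressure + single[1].pressure
        assert np.abs(both.pressure - total).max() < 1e-10

    def test_periodic_steady_state(self, hummingbird_model_short):
        tr = hummingbird_model_short.pressure(wh.Observer([0, 0, 1.0]))
        n = tr.samples_per_period
        np.testing.assert_allclose(
            tr.pressure[:n], tr.pressure[n : 2 * n], atol=1e-9 * np.abs(tr.pressure).max()
        )

    def test_zero_force_zero_pressure(self, medium):
        n = 256
        force, traj = wh.stationary_point_source(np.zeros((n, 3)), [0.01, 0, 0], 50.0, n, 2)
        tr = wh.pressure_eq1(force, traj, wh.Observer([0, 0, 1.0]), medium)
        assert np.abs(tr.pressure).max() == 0.0

    def test_decay_law_exponents(self, hummingbird_model_short):
        """Nearfield-term rms falls as 1/r^2, farfield-term rms as 1/r."""
        model = hummingbird_model_short
        radii = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 20.0])
        near, far = [], []
        for r in radii:
            tr = model.pressure(wh.Observer([0.6 * r, 0.0, 0.8 * r]))
            nf, ff = tr.channels["nearfield"], tr.channels["farfield"]
            near.append(np.sqrt(np.mean((nf - nf.mean()) ** 2)))
            far.append(np.sqrt(np.mean((ff - ff.mean()) ** 2)))
        near_exp = np.polyfit(np.log(radii), np.log(near), 1)[0]
        far_exp = np.polyfit(np.log(radii), np.log(far), 1)[0]
        assert near_exp == pytest.approx(-2.0, abs=0.02)
        assert far_exp == pytest.approx(-1.0, abs=0.02)

    def test_frequency_mixing_above_bandlimit(self):
        """Forces bandlimited to harmonic 4 still radiate energy above it."""
        model = wh.make_model("hummingbird", n_periods=18, bandlimit=4)
        tr = model.pressure(wh.Observer([0.3, 0.4, 0.8]))
        table = wh.harmonic_bands(wh.spl_spectrum(tr), model.spec.flap_frequency)
        high = table.band_ms[4:].sum()
        assert 0 < high < 0.01 * table.band_ms.sum()


class TestPressureEq3:
    def test_matches_eq1_for_static_dipole(self, oscillating_dipole, medium):
        force, traj = oscillating_dipole
        obs = wh.Observer([0, 0, 10.0])
        tr1 = wh.pressure_eq1(force, traj, obs, medium)
        tr3 = wh.pressure_eq3(
            force, traj, obs, medium, stroke_amplitude=1e-12, t_start=tr1.times[0]
        )
        scale = np.abs(tr1.pressure).max()
        np.testing.assert_allclose(tr3.pressure, tr1.pressure, atol=1e-6 * scale)

    def test_band_spls_match_eq1_within_1db(self):
        m1 = wh.make_model("hummingbird", n_periods=18, equation="eq1")
        m3 = wh.make_model("hummingbird", n_periods=18, equation="eq3")
        for pos in ([0, 0, 1.0], [0.5, 0.5, 0.7], [0, 0, 10.0]):
            obs = wh.Observer(pos)
            t1 = wh.harmonic_bands(wh.spl_spectrum(m1.pressure(obs)), 44.2)
            t3 = wh.harmonic_bands(wh.spl_spectrum(m3.pressure(obs)), 44.2)
            np.testing.assert_allclose(t1.band_spl[:4], t3.band_spl[:4], atol=1.0)

    def test_zero_force_zero_pressure(self, medium):
        n = 256
        force, traj = wh.stationary_point_source(np.zeros((n, 3)), [0.01, 0, 0], 50.0, n, 2)
        tr = wh.pressure_eq3(force, traj, wh.Observer([0, 0, 1.0]), medium)
        assert np.abs(tr.pressure).max() == 0.0


class TestPressureDistributed:
    @staticmethod
    def _hummingbird_lift_drag(model):
        from winghum.forces import _direction_frame, drag_from_lift, normalize_weight_support

        n = model.samples_per_period
        vert = normalize_weight_support(
            model.profile.samples(n), model.spec.body_mass, model.medium
        )
        _, lhat = _direction_frame(model.trajectories["left"])
        sign = np.sign(lhat[:n, 2])
        sign[sign == 0] = 1.0
        lift = sign * vert / 2.0
        return lift, drag_from_lift(lift, 2.0)

    def test_single_source_is_bitwise_eq1(self, hummingbird_model_short):
        model = hummingbird_model_short
        lift, drag = self._hummingbird_lift_drag(model)
        obs = wh.Observer([0.4, 0.3, 0.9])
        p1 = wh.pressure_distributed(
            model.spec, model.medium, lift, drag, obs, n_sources=1,
            samples_per_period=model.samples_per_period, n_periods=model.n_periods,
        )
        from winghum.forces import assemble_force_vector

        forces, trajs = [], []
        for side in ("left", "right"):
            traj = wh.source_trajectory(
                model.spec, model.medium, side, model.samples_per_period, model.n_periods
            )
            forces.append(assemble_force_vector(traj, lift, drag))
            trajs.append(traj)
        direct = wh.pressure_eq1(forces, trajs, obs, model.medium, t_start=p1.times[0])
        np.testing.assert_array_equal(p1.pressure, direct.pressure)

    def test_compactness_ten_sources_within_half_db(self):
        """Compact source: 10-station span model differs < 0.5 dB per harmonic."""
        model = wh.make_model("hummingbird", n_periods=18)
        lift, drag = self._hummingbird_lift_drag(model)
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(6):
            u = rng.standard_normal(3)
            obs = wh.Observer(1.0 * u / np.linalg.norm(u))
            kw = dict(
                samples_per_period=model.samples_per_period, n_periods=model.n_periods
            )
            p1 = wh.pressure_distributed(
                model.spec, model.medium, lift, drag, obs, n_sources=1, **kw
            )
            p10 = wh.pressure_distributed(
                model.spec, model.medium, lift, drag, obs, n_sources=10, **kw
            )
            t1 = wh.harmonic_bands(wh.spl_spectrum(p1), 44.2)
            t10 = wh.harmonic_bands(wh.spl_spectrum(p10), 44.2)
            diffs.append(np.abs(t1.band_spl[:4] - t10.band_spl[:4]))
        assert np.median(np.stack(diffs), axis=0).max() < 0.5

    def test_station_weights_conserve_force_and_torque(self):
        from winghum.acoustics import _span_stations

        radii, weights = _span_stations(10, 0.058, 0.55 * 0.058)
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (radii * weights).sum() == pytest.approx(0.55 * 0.058, rel=1e-12)


class TestCompactness:
    def test_hummingbird_value(self):
        assert wh.compactness(0.058, 44.2) == pytest.approx(0.007, abs=5e-4)

    def test_zero_wing_length(self):
        assert wh.compactness(0.0, 100.0) == 0.0

    def test_first_harmonic_wavelength(self):
        assert wh.wavelength(44.2) == pytest.approx(7.8, abs=0.05)
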