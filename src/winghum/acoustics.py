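"""Acoustic pressure from moving point forces (loading noise).

Implements the moving point-force (dipole loading-noise) radiation
equation: a point force ``Fwing(t)`` translating subsonically through still
air generates, at an earth-fixed observer, the pressure

.. math::

    p = \\underbrace{\\frac{1}{4\\pi|r|^2(1-M_r)^2}
        \\Big(\\frac{1}{|r|}\\frac{1-M^2}{1-M_r}(r\\cdot F)
        - F\\cdot M\\Big)}_{\\text{nearfield}}
      + \\underbrace{\\frac{1}{4\\pi a_o |r|^2(1-M_r)^2}
        \\Big(r\\cdot\\dot F + \\frac{\\dot M_r}{1-M_r}(r\\cdot F)\\Big)
        }_{\\text{farfield}}

with every bracketed quantity evaluated at the *retarded* (emission) time:
``r`` runs from the instantaneous source position to the observer, ``M`` is
the source Mach vector and ``M_r`` its component along ``r``.  The
nearfield term decays as 1/r^2 and dominates within about one wavelength;
the farfield term decays as 1/r.

Because wing kinematics and forces are exactly periodic, the solver works
in the source-time (forward-mapping) formulation: pressures are evaluated
on the uniform emission grid, mapped to arrival times
``t + |r(t)|/a_o``, and cubic-interpolated onto a uniform observer-time
grid.  Monotonicity of the arrival map is guaranteed for |M| < 1 and
checked.  The emission series is tiled cyclically, so the returned trace is
the exact periodic steady state (no startup transient survives).

A compact-source simplification replaces the moving geometry by the pivot
point::

    p = (r.F)/(4 pi |r|^3)
      + 1/(4 pi a_o |r|^2) * [ r.dF/dt + (4 Phi_o R fw^2 / a_o) (r.F) ]

valid when the wing is acoustically compact (R/lambda_1 << 1, which holds
from hummingbirds to mosquitoes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .forces import (
    DEFAULT_LIFT_DRAG_RATIO,
    WeightSupportProfile,
    WingForceTrajectory,
    build_wing_forces,
)
from .kinematics import (
    FlappingSpec,
    Medium,
    SourceTrajectory,
    source_trajectory,
    spectral_derivative,
)

__all__ = [
    "Observer",
    "PressureTrace",
    "emission_map",
    "pressure_eq1",
    "pressure_eq3",
    "pressure_distributed",
    "compactness",
    "wavelength",
    "stationary_point_source",
    "HumModel",
]

#: Doppler-factor guard: |1 - Mr| below this raises (model singular).
DOPPLER_EPS = 1e-6


@dataclass(frozen=True)
class Observer:
    """An earth-fixed microphone position."""

    position: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError("observer position must be finite")
        object.__setattr__(self, "position", p)

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.position))


@dataclass(frozen=True)
class PressureTrace:
    """Pressure time series at one observer, with term/wing decomposition.

    ``channels`` holds the nearfield term, farfield term, and per-wing
    contributions; channel sums reproduce the total to rounding error.
    """

    observer: Observer
    times: np.ndarray           # (n,) uniform observer times, s
    pressure: np.ndarray        # (n,) Pa
    channels: dict[str, np.ndarray]
    flap_frequency: float
    samples_per_period: int

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def n_periods(self) -> int:
        return self.pressure.size // self.samples_per_period

    @property
    def duration(self) -> float:
        return self.pressure.size * self.dt

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.pressure**2)))


def wavelength(frequency: float, medium: Medium | None = None) -> float:
    """Acoustic wavelength ``a_o / f`` in m."""
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    return (medium or Medium()).speed_of_sound / frequency


def compactness(wing_length: float, flap_frequency: float, medium: Medium | None = None) -> float:
    """Compactness ratio ``R / lambda_1 = R * fw / a_o`` (dimensionless).

    Values << 1 mean the whole wing fits deep inside one acoustic
    wavelength at the wingbeat frequency, so its distributed forcing can be
    collapsed to a single point.
    """
    if wing_length < 0 or flap_frequency <= 0:
        raise ValueError("wing_length must be >= 0 and flap_frequency > 0")
    return wing_length * flap_frequency / (medium or Medium()).speed_of_sound


def emission_map(
    positions: np.ndarray,
    times: np.ndarray,
    observer: Observer,
    medium: Medium | None = None,
) -> np.ndarray:
    """Arrival times at the observer for each emission sample.

    ``arrival(t) = t + |x_obs - r_s(t)| / a_o``; strictly increasing for a
    subsonic source (checked — a non-monotone map would imply a sonic or
    supersonic line-of-sight approach speed).
    """
    ao = (medium or Medium()).speed_of_sound
    r = observer.position[None, :] - np.asarray(positions, dtype=float)
    arrival = np.asarray(times, dtype=float) + np.linalg.norm(r, axis=1) / ao
    if np.any(np.diff(arrival) <= 0):
        raise ValueError(
            "non-monotone arrival times: source approaches the observer at "
            "|M| >= 1 along the line of sight"
        )
    return arrival


def _emission_channels(
    force: WingForceTrajectory,
    traj: SourceTrajectory,
    observer: Observer,
    medium: Medium,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-period nearfield/farfield pressures and arrival times (emission grid)."""
    n = traj.samples_per_period
    pos = traj.position[:n]
    mach = traj.mach[:n]
    F = force.force[:n]
    ao = medium.speed_of_sound
    period = traj.period

    r = observer.position[None, :] - pos
    dist = np.linalg.norm(r, axis=1)
    if dist.min() < 1e-12:
        raise ValueError("observer coincides with a source sample position")
    Mr = np.einsum("ij,ij->i", mach, r) / dist
    one_m_Mr = 1.0 - Mr
    if np.abs(one_m_Mr).min() < DOPPLER_EPS:
        raise ValueError("Doppler singularity: |1 - Mr| < 1e-6 along the trajectory")
    M2 = np.einsum("ij,ij->i", mach, mach)
    rdotF = np.einsum("ij,ij->i", r, F)

    dFdt = spectral_derivative(F, period, axis=0)
    dMr_dt = spectral_derivative(Mr, period, axis=0)

    common = 1.0 / (4.0 * np.pi * dist**2 * one_m_Mr**2)
    near = common * (
        (1.0 / dist) * ((1.0 - M2) / one_m_Mr) * rdotF - np.einsum("ij,ij->i", F, mach)
    )
    far = (common / ao) * (
        np.einsum("ij,ij->i", r, dFdt) + (dMr_dt / one_m_Mr) * rdotF
    )
    arrival = traj.times[:n] + dist / ao
    if np.any(np.diff(np.append(arrival, arrival[0] + period)) <= 0):
        raise ValueError("non-monotone arrival times (sonic line-of-sight approach)")
    return near, far, arrival


def _default_start_time(observer: Observer, max_excursion: float, dt: float, ao: float) -> float:
    """Grid-aligned observer start time guaranteed past the longest delay.

    Depends on the observer only through its pivot distance, so observers at
    equal radius automatically share a time grid (needed for coherent array
    sums).
    """
    max_delay = (observer.distance + 1.001 * max_excursion) / ao
    return np.ceil(max_delay / dt + 1) * dt


def _interp_to_observer(
    channels: dict[str, np.ndarray],
    arrival: np.ndarray,
    period: float,
    t_obs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Cyclically tile one-period emission channels and spline onto t_obs."""
    m_lo = int(np.floor((t_obs[0] - arrival.max()) / period)) - 1
    m_hi = int(np.ceil((t_obs[-1] - arrival.min()) / period)) + 2
    shifts = np.arange(m_lo, m_hi) * period
    t_tiled = (arrival[None, :] + shifts[:, None]).ravel()
    out: dict[str, np.ndarray] = {}
    for name, vals in channels.items():
        v_tiled = np.tile(vals, shifts.size)
        out[name] = CubicSpline(t_tiled, v_tiled)(t_obs)
    return out


def _as_wing_lists(forces, traj):
    flist = list(forces) if isinstance(forces, (list, tuple)) else [forces]
    tlist = list(traj) if isinstance(traj, (list, tuple)) else [traj]
    if len(flist) != len(tlist):
        raise ValueError("forces and trajectories must pair up one per wing")
    for f, t in zip(flist, tlist):
        if f.samples_per_period != t.samples_per_period or f.force.shape[0] != t.times.shape[0]:
            raise ValueError("force and trajectory time grids mismatch")
    return flist, tlist


def pressure_eq1(
    forces,
    traj,
    observer: Observer,
    medium: Medium | None = None,
    n_periods: int | None = None,
    t_start: float | None = None,
) -> PressureTrace:
    """Pressure at an observer from moving point forces (full equation).

    ``forces``/``traj`` are a single wing's :class:`WingForceTrajectory` /
    :class:`SourceTrajectory` or per-wing sequences; wing contributions are
    summed.  The trace spans ``n_periods`` wingbeats (default: the
    trajectory's), uniformly sampled at the emission resolution, and carries
    ``nearfield``/``farfield`` and per-wing channels.
    """
    medium = medium or Medium()
    flist, tlist = _as_wing_lists(forces, traj)
    t0 = tlist[0]
    n = t0.samples_per_period
    dt = t0.dt
    period = t0.period
    n_out = (n_periods if n_periods is not None else t0.n_periods) * n
    if t_start is None:
        excursion = max(np.linalg.norm(t.position, axis=1).max() for t in tlist)
        t_start = _default_start_time(observer, excursion, dt, medium.speed_of_sound)
    t_obs = t_start + np.arange(n_out) * dt

    total_channels: dict[str, np.ndarray] = {
        "nearfield": np.zeros(n_out),
        "farfield": np.zeros(n_out),
    }
    for f, t in zip(flist, tlist):
        near, far, arrival = _emission_channels(f, t, observer, medium)
        interp = _interp_to_observer({"near": near, "far": far}, arrival, period, t_obs)
        total_channels["nearfield"] += interp["near"]
        total_channels["farfield"] += interp["far"]
        key = f"wing_{t.side}" if t.side else f"wing_{len(total_channels)}"
        total_channels[key] = total_channels.get(key, 0) + interp["near"] + interp["far"]
    pressure = total_channels["nearfield"] + total_channels["farfield"]
    return PressureTrace(
        observer=observer,
        times=t_obs,
        pressure=pressure,
        channels=total_channels,
        flap_frequency=t0.flap_frequency,
        samples_per_period=n,
    )


def pressure_eq3(
    forces,
    traj,
    observer: Observer,
    medium: Medium | None = None,
    stroke_amplitude: float = 2.0,
    wing_length: float | None = None,
    n_periods: int | None = None,
    t_start: float | None = None,
) -> PressureTrace:
    """Compact-source simplified pressure (pivot-fixed geometry).

    Evaluates ``p = (r.F)/(4 pi |r|^3) + [r.dF/dt + (4 Phi_o R fw^2/a_o)(r.F)]
    / (4 pi a_o |r|^2)`` with ``r`` taken from the body pivot, so source
    motion enters only through the convective correction term
    ``4 Phi_o R fw^2 / a_o``.  The trajectory argument supplies the time
    grid and (if ``wing_length`` is omitted) the wing radius via its source
    excursion.
    """
    medium = medium or Medium()
    flist, tlist = _as_wing_lists(forces, traj)
    t0 = tlist[0]
    n = t0.samples_per_period
    dt = t0.dt
    period = t0.period
    fw = t0.flap_frequency
    ao = medium.speed_of_sound
    n_out = (n_periods if n_periods is not None else t0.n_periods) * n
    R = wing_length if wing_length is not None else float(
        np.linalg.norm(t0.position, axis=1).max() / 0.55
    )
    conv = 4.0 * stroke_amplitude * R * fw**2 / ao

    r = observer.position
    dist = float(np.linalg.norm(r))
    if dist < 1e-12:
        raise ValueError("observer coincides with the pivot")
    delay = dist / ao
    if t_start is None:
        t_start = np.ceil(delay / dt + 1) * dt
    t_obs = t_start + np.arange(n_out) * dt

    channels: dict[str, np.ndarray] = {
        "nearfield": np.zeros(n_out),
        "farfield": np.zeros(n_out),
    }
    # Emission phase for each observer sample: p is periodic, evaluate cyclically.
    for f, t in zip(flist, tlist):
        F = f.force[:n]
        rdotF = F @ r
        dFdt = spectral_derivative(F, period, axis=0)
        near1 = rdotF / (4.0 * np.pi * dist**3)
        far1 = (dFdt @ r + conv * rdotF) / (4.0 * np.pi * ao * dist**2)
        arrival = t.times[:n] + delay
        interp = _interp_to_observer({"near": near1, "far": far1}, arrival, period, t_obs)
        channels["nearfield"] += interp["near"]
        channels["farfield"] += interp["far"]
        key = f"wing_{t.side}"
        channels[key] = channels.get(key, 0) + interp["near"] + interp["far"]
    pressure = channels["nearfield"] + channels["farfield"]
    return PressureTrace(
        observer=observer,
        times=t_obs,
        pressure=pressure,
        channels=channels,
        flap_frequency=fw,
        samples_per_period=n,
    )


def _span_stations(n_sources: int, wing_length: float, r3: float) -> tuple[np.ndarray, np.ndarray]:
    """Span stations and force weights for the distributed-source model.

    Stations sit at the centers of ``n`` equal-width span strips; weights
    follow a linear spanwise loading ``w_i = a + b*r_i`` solved so that both
    the total force (sum w = 1) and the pivot torque (sum w*r = R3) match
    the single-point model.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if n_sources == 1:
        return np.array([r3]), np.array([1.0])
    edges = np.linspace(0.0, wing_length, n_sources + 1)
    radii = 0.5 * (edges[:-1] + edges[1:])
    A = np.array([[n_sources, radii.sum()], [radii.sum(), (radii**2).sum()]])
    a, b = np.linalg.solve(A, np.array([1.0, r3]))
    weights = a + b * radii
    return radii, weights


def pressure_distributed(
    spec: FlappingSpec,
    medium: Medium,
    lift: np.ndarray,
    drag: np.ndarray,
    observer: Observer,
    n_sources: int = 10,
    samples_per_period: int = 1024,
    n_periods: int = 4,
    sides: tuple[str, ...] = ("left", "right"),
    t_start: float | None = None,
) -> PressureTrace:
    """Superpose point sources distributed along the wingspan.

    Each span station follows the same angular kinematics at its own radius
    and carries its share of the per-wing lift/drag (``lift``/``drag``
    sampled on the one-period phase grid).  Station weights conserve the
    instantaneous total force and pivot torque of the single-point model;
    ``n_sources=1`` reproduces :func:`pressure_eq1` at R3 exactly.
    """
    from .forces import assemble_force_vector  # local to avoid cycle noise

    radii, weights = _span_stations(n_sources, spec.wing_length, spec.r3)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("distribution weights do not sum to the total force")
    forces_all, trajs_all = [], []
    for side in sides:
        for radius, w in zip(radii, weights):
            st = spec.with_(r3_fraction=radius / spec.wing_length)
            traj = source_trajectory(st, medium, side, samples_per_period, n_periods)
            forces_all.append(assemble_force_vector(traj, w * lift, w * drag))
            trajs_all.append(traj)
    if t_start is None:
        dt = trajs_all[0].dt
        t_start = _default_start_time(
            observer, 1.0 * spec.wing_length, dt, medium.speed_of_sound
        )
    return pressure_eq1(forces_all, trajs_all, observer, medium, t_start=t_start)


def stationary_point_source(
    force_series: np.ndarray,
    position,
    flap_frequency: float,
    samples_per_period: int = 1024,
    n_periods: int = 4,
    medium: Medium | None = None,
    side: str = "left",
) -> tuple[WingForceTrajectory, SourceTrajectory]:
    """A non-moving point force: the classical oscillating-dipole geometry.

    ``force_series`` is the one-period (samples_per_period, 3) force in N;
    ``position`` the fixed source location.  Useful for validating against
    stationary-dipole closed forms and for synthetic directivity patterns.
    """
    medium = medium or Medium()
    n = int(samples_per_period)
    F1 = np.asarray(force_series, dtype=float)
    if F1.shape != (n, 3):
        raise ValueError(f"force_series must be shaped ({n}, 3)")
    pos = np.asarray(position, dtype=float).reshape(3)
    period = 1.0 / flap_frequency
    times = np.arange(n * n_periods) * (period / n)
    traj = SourceTrajectory(
        times=times,
        position=np.tile(pos, (n * n_periods, 1)),
        velocity=np.zeros((n * n_periods, 3)),
        mach=np.zeros((n * n_periods, 3)),
        side=side,
        flap_frequency=flap_frequency,
        samples_per_period=n,
        n_periods=n_periods,
    )
    force = WingForceTrajectory(
        times=times,
        force=np.tile(F1, (n_periods, 1)),
        side=side,
        flap_frequency=flap_frequency,
        samples_per_period=n,
        n_periods=n_periods,
    )
    return force, traj


class HumModel:
    """Bundle of animal spec, medium, and force profile ready to radiate.

    Builds the left/right source trajectories and wing forces once and
    exposes pressure evaluation at arbitrary observers via the full moving
    point-force equation (``equation='eq1'``, default) or the
    compact-source simplification (``'eq3'``).
    """

    def __init__(
        self,
        spec: FlappingSpec,
        profile: WeightSupportProfile,
        medium: Medium | None = None,
        lift_drag_ratio=DEFAULT_LIFT_DRAG_RATIO,
        samples_per_period: int = 1024,
        n_periods: int = 4,
        bandlimit: int | None = None,
        equation: str = "eq1",
    ):
        if equation not in ("eq1", "eq3"):
            raise ValueError("equation must be 'eq1' or 'eq3'")
        self.spec = spec
        self.profile = profile
        self.medium = medium or Medium()
        self.lift_drag_ratio = lift_drag_ratio
        self.samples_per_period = int(samples_per_period)
        self.n_periods = int(n_periods)
        self.bandlimit = bandlimit
        self.equation = equation
        self.trajectories = {
            side: source_trajectory(
                spec, self.medium, side, self.samples_per_period, self.n_periods
            )
            for side in ("left", "right")
        }
        self.forces = build_wing_forces(
            self.trajectories["left"],
            self.trajectories["right"],
            profile,
            spec.body_mass,
            self.medium,
            lift_drag_ratio,
            bandlimit=bandlimit,
        )

    @property
    def dt(self) -> float:
        return self.trajectories["left"].dt

    def default_start_time(self, max_radius: float) -> float:
        """Shared grid-aligned start time for a set of observers within max_radius."""
        obs = Observer(np.array([max_radius, 0.0, 0.0]))
        return _default_start_time(
            obs, self.spec.wing_length, self.dt, self.medium.speed_of_sound
        )

    def pressure(
        self,
        observer: Observer,
        n_periods: int | None = None,
        t_start: float | None = None,
    ) -> PressureTrace:
        forces = [self.forces["left"], self.forces["right"]]
        trajs = [self.trajectories["left"], self.trajectories["right"]]
        if self.equation == "eq1":
            return pressure_eq1(
                forces, trajs, observer, self.medium, n_periods=n_periods, t_start=t_start
            )
        return pressure_eq3(
            forces,
            trajs,
            observer,
            self.medium,
            stroke_amplitude=self.spec.stroke_amplitude,
            wing_length=self.spec.wing_length,
            n_periods=n_periods,
            t_start=t_start,
        )

    def compactness(self) -> float:
        return compactness(self.spec.wing_length, self.spec.flap_frequency, self.medium)
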