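"""Wing kinematics and the moving acoustic source point.

A hovering animal flaps each wing back and forth about the shoulder joint.
The net aerodynamic force of one wing is collapsed onto a single point at
the third moment of area radius, R3 (about 55% of wing length for a
hummingbird), and the sound field is computed from that moving point force.
This module represents the wingbeat kinematics — stroke angle ``phi`` within
the (horizontal) stroke plane and deviation angle ``theta`` out of it, both
periodic in the wingbeat phase ``tau = t * fw mod 1`` — and evaluates the 3D
position, velocity, and Mach vector of the source point for each wing.

Coordinate frame (right-handed, earth-fixed, pivot at the origin):

* ``x`` anterior (forward),
* ``y`` toward the animal's left,
* ``z`` up.

The stroke plane is horizontal; ``phi`` is measured from the y-axis
(wing abeam at mid-stroke) positive toward anterior, and ``theta`` is the
elevation out of the stroke plane.  ``tau = 0`` marks the start of the
downstroke.  The left wing points toward ``+y``; the right wing is the
mirror image through the sagittal (x-z) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Medium",
    "HarmonicSeries",
    "FlappingSpec",
    "SourceTrajectory",
    "eval_kinematics",
    "source_trajectory",
    "spectral_derivative",
]

#: Number of kinematic harmonics kept by default when fitting measured series.
DEFAULT_KINEMATIC_HARMONICS = 5


@dataclass(frozen=True)
class Medium:
    """Physical properties of the acoustic medium (air).

    Parameters
    ----------
    speed_of_sound : float
        ``ao`` in m/s.
    air_density : float
        ``rho_o`` in kg/m^3.
    gravity : float
        ``g`` in m/s^2, used to convert body mass to weight support.
    """

    speed_of_sound: float = 343.0
    air_density: float = 1.23
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in ("speed_of_sound", "air_density", "gravity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Medium.{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class HarmonicSeries:
    """Real truncated Fourier series on the unit circle.

    Evaluates ``f(tau) = mean + sum_k cos_k*cos(2*pi*k*tau) + sin_k*sin(2*pi*k*tau)``
    for ``tau`` in wingbeat fractions. ``cos`` and ``sin`` hold coefficients for
    harmonics ``k = 1..K``.
    """

    mean: float = 0.0
    cos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sin: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.cos, dtype=float))
        s = np.atleast_1d(np.asarray(self.sin, dtype=float))
        if c.size != s.size:
            n = max(c.size, s.size)
            c = np.pad(c, (0, n - c.size))
            s = np.pad(s, (0, n - s.size))
        object.__setattr__(self, "cos", c)
        object.__setattr__(self, "sin", s)
        if not (np.isfinite(self.mean) and np.all(np.isfinite(c)) and np.all(np.isfinite(s))):
            raise ValueError("HarmonicSeries coefficients must be finite")

    @property
    def n_harmonics(self) -> int:
        return int(self.cos.size)

    def __call__(self, tau: np.ndarray | float) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if tau.size == 0:
            raise ValueError("empty phase array")
        k = np.arange(1, self.n_harmonics + 1)
        ang = 2.0 * np.pi * np.multiply.outer(tau, k)
        return self.mean + np.cos(ang) @ self.cos + np.sin(ang) @ self.sin

    def derivative(self) -> "HarmonicSeries":
        """Analytic derivative with respect to tau (per wingbeat fraction)."""
        k = np.arange(1, self.n_harmonics + 1)
        w = 2.0 * np.pi * k
        return HarmonicSeries(0.0, w * self.sin, -w * self.cos)

    def harmonic_amplitude(self, k: int) -> float:
        """Amplitude ``sqrt(cos_k^2 + sin_k^2)`` of harmonic ``k >= 1``."""
        if not 1 <= k <= self.n_harmonics:
            return 0.0
        return float(np.hypot(self.cos[k - 1], self.sin[k - 1]))

    def ptp(self, n: int = 4096) -> float:
        """Peak-to-peak value on a dense phase grid."""
        vals = self(np.arange(n) / n)
        return float(vals.max() - vals.min())

    @classmethod
    def from_samples(
        cls,
        phase: np.ndarray,
        values: np.ndarray,
        n_harmonics: int = DEFAULT_KINEMATIC_HARMONICS,
    ) -> "HarmonicSeries":
        """Least-squares fit of a truncated Fourier series to phase samples.

        ``phase`` need not be uniform; it must cover the wingbeat reasonably
        (largest gap < 1/(2*n_harmonics)) so the fit is well conditioned.
        """
        phase = np.asarray(phase, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if phase.size != values.size or phase.size == 0:
            raise ValueError("phase and values must be nonempty and equally sized")
        if not (np.all(np.isfinite(phase)) and np.all(np.isfinite(values))):
            raise ValueError("non-finite samples")
        tau = np.mod(phase, 1.0)
        gaps = np.diff(np.sort(np.concatenate([tau, tau[:1] + 1.0])))
        if gaps.max() >= 0.5 / n_harmonics:
            raise ValueError(
                "phase coverage too sparse for the requested harmonics: "
                f"largest gap {gaps.max():.3f} of a wingbeat "
                f"(need < {0.5 / n_harmonics:.3f})"
            )
        k = np.arange(1, n_harmonics + 1)
        ang = 2.0 * np.pi * np.multiply.outer(tau, k)
        design = np.hstack([np.ones((tau.size, 1)), np.cos(ang), np.sin(ang)])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        return cls(coef[0], coef[1 : n_harmonics + 1], coef[n_harmonics + 1 :])


def _pure_cosine_stroke(amplitude: float) -> HarmonicSeries:
    # Negative cosine: tau=0 starts the downstroke with the wing at its
    # posterior reversal, sweeping anterior (forward) during tau in (0, 1/2).
    return HarmonicSeries(0.0, np.array([-amplitude / 2.0]), np.array([0.0]))


@dataclass(frozen=True)
class FlappingSpec:
    """Morphology and wingbeat parameterization of one flapping animal.

    Parameters
    ----------
    body_mass : float
        ``m`` in kg.
    wing_length : float
        ``R`` in m, measured from the body center.
    r3_fraction : float
        ``R3/R``, the fractional radius of the equivalent point source
        (0.55 for the hummingbird wing's third moment of area).
    flap_frequency : float
        ``fw`` in Hz.
    stroke_amplitude : float
        ``Phi_o`` in rad, the peak-to-peak stroke excursion.
    stroke, deviation : HarmonicSeries
        Stroke angle ``phi(tau)`` and deviation angle ``theta(tau)`` in rad.
        If ``stroke`` is omitted, a pure first-harmonic cosine with
        peak-to-peak ``stroke_amplitude`` is used.
    downstroke_fraction : float
        Fraction of the wingbeat spent in downstroke (metadata; the series
        themselves carry the shape).
    """

    body_mass: float
    wing_length: float
    r3_fraction: float = 0.55
    flap_frequency: float = 44.2
    stroke_amplitude: float = 2.0
    stroke: HarmonicSeries | None = None
    deviation: HarmonicSeries = field(default_factory=HarmonicSeries)
    downstroke_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.stroke is None:
            object.__setattr__(self, "stroke", _pure_cosine_stroke(self.stroke_amplitude))
        checks = {
            "body_mass": self.body_mass > 0,
            "wing_length": self.wing_length > 0,
            "r3_fraction": 0 < self.r3_fraction <= 1,
            "flap_frequency": self.flap_frequency > 0,
            "stroke_amplitude": 0 < self.stroke_amplitude < np.pi,
            "downstroke_fraction": 0 < self.downstroke_fraction < 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid FlappingSpec field(s): {', '.join(bad)}")
        ptp = self.stroke.ptp()
        if not np.isclose(ptp, self.stroke_amplitude, rtol=0.02, atol=1e-9):
            raise ValueError(
                f"stroke series peak-to-peak ({ptp:.4f} rad) does not match "
                f"stroke_amplitude ({self.stroke_amplitude:.4f} rad)"
            )

    @property
    def r3(self) -> float:
        """Source radius ``R3`` in m."""
        return self.r3_fraction * self.wing_length

    @property
    def period(self) -> float:
        """Wingbeat period ``1/fw`` in s."""
        return 1.0 / self.flap_frequency

    @classmethod
    def from_series(
        cls,
        body_mass: float,
        wing_length: float,
        stroke: HarmonicSeries,
        deviation: HarmonicSeries | None = None,
        **kwargs,
    ) -> "FlappingSpec":
        """Build a spec from fitted series, deriving Phi_o from the stroke."""
        return cls(
            body_mass=body_mass,
            wing_length=wing_length,
            stroke=stroke,
            deviation=deviation if deviation is not None else HarmonicSeries(),
            stroke_amplitude=stroke.ptp(),
            **kwargs,
        )

    def with_(self, **kwargs) -> "FlappingSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SourceTrajectory:
    """Position, velocity, and Mach vector of one wing's source point.

    Arrays span ``n_periods`` wingbeats at ``samples_per_period`` uniform
    samples per wingbeat; all per-sample quantities are exactly periodic at
    the wingbeat period.
    """

    times: np.ndarray           # (n,) s
    position: np.ndarray        # (n, 3) m, pivot at origin
    velocity: np.ndarray        # (n, 3) m/s
    mach: np.ndarray            # (n, 3) v/ao
    side: str                   # "left" | "right"
    flap_frequency: float
    samples_per_period: int
    n_periods: int

    @property
    def period(self) -> float:
        return 1.0 / self.flap_frequency

    @property
    def dt(self) -> float:
        return self.period / self.samples_per_period

    @property
    def phases(self) -> np.ndarray:
        return np.mod(self.times * self.flap_frequency, 1.0)

    @property
    def max_mach(self) -> float:
        return float(np.linalg.norm(self.mach, axis=1).max())

    def one_period(self, arr: np.ndarray | None = None) -> np.ndarray:
        """First-wingbeat slice of ``arr`` (default: position)."""
        if arr is None:
            arr = self.position
        return arr[: self.samples_per_period]


def eval_kinematics(spec: FlappingSpec, phases) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate stroke and deviation angles (rad) at wingbeat fractions.

    Returns ``(phi, theta)``.  Phases outside [0, 1) are wrapped (the series
    are periodic by construction).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase array")
    if not np.all(np.isfinite(phases)):
        raise ValueError("non-finite phases")
    return spec.stroke(phases), spec.deviation(phases)


def spectral_derivative(values: np.ndarray, period: float, axis: int = 0) -> np.ndarray:
    """Time derivative of a uniformly sampled periodic signal via the FFT.

    ``values`` must hold exactly one period (or an integer tiling of one);
    accuracy is spectral for bandlimited signals.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    freqs = np.fft.rfftfreq(n, d=period / n)
    spec = np.fft.rfft(values, axis=axis)
    shape = [1] * values.ndim
    shape[axis] = freqs.size
    omega = (2j * np.pi * freqs).reshape(shape)
    dspec = spec * omega
    if n % 2 == 0:
        # Zero the Nyquist bin: its derivative is not representable on the grid.
        idx = [slice(None)] * values.ndim
        idx[axis] = -1
        dspec[tuple(idx)] = 0.0
    return np.fft.irfft(dspec, n=n, axis=axis)


def _source_direction(phi: np.ndarray, theta: np.ndarray, side: str) -> np.ndarray:
    """Unit vector from the pivot to the source point for one wing."""
    y_sign = {"left": 1.0, "right": -1.0}.get(side)
    if y_sign is None:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    ct = np.cos(theta)
    return np.stack(
        [ct * np.sin(phi), y_sign * ct * np.cos(phi), np.sin(theta)], axis=-1
    )


def source_trajectory(
    spec: FlappingSpec,
    medium: Medium,
    side: str = "left",
    samples_per_period: int = 1024,
    n_periods: int = 4,
) -> SourceTrajectory:
    """Compute the source-point trajectory at radius R3 for one wing.

    The position over one wingbeat is evaluated from the kinematic series,
    differentiated spectrally (the signal is exactly periodic), and tiled to
    ``n_periods``.  Raises if the source would move supersonically (the
    moving point-force equation requires |M| < 1).
    """
    if samples_per_period < 64:
        raise ValueError("samples_per_period must be >= 64")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    n = int(samples_per_period)
    tau = np.arange(n) / n
    phi, theta = eval_kinematics(spec, tau)
    pos1 = spec.r3 * _source_direction(phi, theta, side)
    vel1 = spectral_derivative(pos1, spec.period, axis=0)
    mach1 = vel1 / medium.speed_of_sound
    mmax = np.linalg.norm(mach1, axis=1).max()
    if mmax >= 1.0:
        raise ValueError(
            f"supersonic source point (max |M| = {mmax:.3f}); "
            "the moving point-force model requires |M| < 1"
        )
    reps = int(n_periods)
    times = np.arange(n * reps) * (spec.period / n)
    return SourceTrajectory(
        times=times,
        position=np.tile(pos1, (reps, 1)),
        velocity=np.tile(vel1, (reps, 1)),
        mach=np.tile(mach1, (reps, 1)),
        side=side,
        flap_frequency=spec.flap_frequency,
        samples_per_period=n,
        n_periods=reps,
    )
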