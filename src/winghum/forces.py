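"""Per-wing oscillating aerodynamic force vectors.

The acoustic source strength of a flapping wing is its oscillating net
aerodynamic force ``Fwing(t)``, decomposed into lift (perpendicular to the
wing velocity at the source point) and drag (antiparallel to it).  In hover
the wingbeat-mean vertical force of both wings must equal body weight
``m*g``; a *weight support profile* expresses the instantaneous vertical
force in units of bodyweight versus wingbeat phase and is the portable way
to specify a species' force waveform.

Sign conventions follow the hovering-hummingbird picture: lift is positive
during the downstroke and negative during the upstroke (the lift direction
``v_hat x s_hat`` flips with the stroke direction, so the resulting force is
upward in both half-strokes); drag is a nonnegative magnitude applied
against the velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .kinematics import HarmonicSeries, Medium, SourceTrajectory

__all__ = [
    "WeightSupportProfile",
    "LiftDragProfile",
    "WingForceTrajectory",
    "normalize_weight_support",
    "drag_from_lift",
    "assemble_force_vector",
    "lowpass_forces",
    "decompose_net_force",
    "bandlimit_periodic",
    "build_wing_forces",
]

#: Fraction of the peak source speed below which the velocity direction is
#: considered undefined (stroke reversal) and carried over from neighbors.
REVERSAL_SPEED_FRACTION = 1e-6

#: Default constant lift/drag ratio standing in for quasi-steady Anna's
#: hummingbird lift/drag data; configurable per call or via a phase table.
DEFAULT_LIFT_DRAG_RATIO = 2.0

PARADIGM_GROUPS = (
    "elongated_fly",
    "compact_fly",
    "lepidoptera",
    "hummingbird",
    "generalist_bird",
)


@dataclass(frozen=True)
class WeightSupportProfile:
    """Normalized vertical force (units of bodyweight) vs. wingbeat phase.

    Stored as a truncated Fourier series; ``samples(n)`` evaluates it on a
    uniform phase grid.  ``group`` labels which paradigm animal the shape
    follows ("custom" for user data).
    """

    series: HarmonicSeries
    group: str = "custom"

    def samples(self, n: int) -> np.ndarray:
        return self.series(np.arange(n) / n)

    @property
    def mean(self) -> float:
        return float(self.series.mean)

    def normalized(self) -> "WeightSupportProfile":
        """Rescaled so the phase-mean is exactly 1 bodyweight."""
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValueError(
                f"weight support profile has non-positive mean ({self.mean!r}); "
                "cannot normalize to bodyweight"
            )
        s = self.series
        f = 1.0 / self.mean
        return WeightSupportProfile(HarmonicSeries(1.0, s.cos * f, s.sin * f), self.group)

    @classmethod
    def from_samples(cls, phase, values, n_harmonics: int = 8, group: str = "custom"):
        return cls(HarmonicSeries.from_samples(phase, values, n_harmonics), group)


@dataclass(frozen=True)
class LiftDragProfile:
    """Per-wing lift and drag sampled on a uniform phase grid.

    ``lift`` is signed (negative during upstroke under the hummingbird
    convention); ``drag`` is a nonnegative magnitude.
    """

    lift: np.ndarray
    drag: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.lift, dtype=float)
        D = np.asarray(self.drag, dtype=float)
        if L.shape != D.shape or L.ndim != 1 or L.size == 0:
            raise ValueError("lift and drag must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(L)) and np.all(np.isfinite(D))):
            raise ValueError("non-finite lift/drag samples")
        object.__setattr__(self, "lift", L)
        object.__setattr__(self, "drag", D)


@dataclass(frozen=True)
class WingForceTrajectory:
    """3-D point-force vector of one wing over the simulated wingbeats."""

    times: np.ndarray           # (n,) s
    force: np.ndarray           # (n, 3) N
    side: str
    flap_frequency: float
    samples_per_period: int
    n_periods: int

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite force samples")
        object.__setattr__(self, "force", f)

    @property
    def period(self) -> float:
        return 1.0 / self.flap_frequency

    def one_period(self) -> np.ndarray:
        return self.force[: self.samples_per_period]


def normalize_weight_support(
    profile: WeightSupportProfile | np.ndarray,
    body_mass: float,
    medium: Medium | None = None,
) -> np.ndarray | WeightSupportProfile:
    """Scale a weight support shape so its phase-mean is exactly ``m*g`` (N).

    Accepts either a :class:`WeightSupportProfile` (returns a profile whose
    series is in newtons) or a raw sample array (returns the scaled array).
    The shape is preserved up to the single scalar factor.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    g = (medium or Medium()).gravity
    target = body_mass * g
    if isinstance(profile, WeightSupportProfile):
        norm = profile.normalized()
        s = norm.series
        return WeightSupportProfile(
            HarmonicSeries(target, s.cos * target, s.sin * target), profile.group
        )
    values = np.asarray(profile, dtype=float)
    if values.size == 0:
        raise ValueError("empty weight support profile")
    mean = values.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"weight support profile has non-positive mean ({mean!r})")
    return values * (target / mean)


def drag_from_lift(lift: np.ndarray, ratio) -> np.ndarray:
    """Drag magnitude from signed lift via a lift/drag ratio rule.

    ``ratio`` is a positive scalar or an array/callable of the same phase
    grid as ``lift``; ``D = |L| / ratio`` is nonnegative by construction.
    """
    L = np.asarray(lift, dtype=float)
    r = np.asarray(ratio(np.arange(L.size) / L.size) if callable(ratio) else ratio, dtype=float)
    r = np.broadcast_to(r, L.shape)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("lift/drag ratio must be finite and > 0 everywhere")
    return np.abs(L) / r


def _fill_reversals(unit: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace direction vectors at reversal samples by the nearest valid one."""
    if valid.all():
        return unit
    if not valid.any():
        raise ValueError("wing velocity is zero everywhere; force direction undefined")
    n = valid.size
    idx = np.arange(n)
    valid_idx = idx[valid]
    # Periodic nearest neighbor: replicate valid indices one period left/right.
    ext = np.concatenate([valid_idx - n, valid_idx, valid_idx + n])
    pos = np.searchsorted(ext, idx)
    left = np.clip(pos - 1, 0, ext.size - 1)
    right = np.clip(pos, 0, ext.size - 1)
    nearest = np.where(np.abs(ext[left] - idx) <= np.abs(ext[right] - idx), ext[left], ext[right])
    out = unit.copy()
    out[~valid] = unit[np.mod(nearest[~valid], n)]
    return out


def _direction_frame(traj: SourceTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Unit drag and lift directions along the trajectory.

    Drag direction is ``-v_hat``; lift direction is ``unit(v_hat x s_hat)``
    for the left wing and its mirror for the right wing, where ``s_hat`` is
    the outboard spanwise unit vector.  At stroke reversals (|v| below
    ``REVERSAL_SPEED_FRACTION`` of the peak) the directions are carried over
    from the nearest moving sample.
    """
    v = traj.velocity
    speed = np.linalg.norm(v, axis=1)
    valid = speed > REVERSAL_SPEED_FRACTION * speed.max()
    vhat = np.zeros_like(v)
    vhat[valid] = v[valid] / speed[valid, None]
    vhat = _fill_reversals(vhat, valid)
    shat = traj.position / np.linalg.norm(traj.position, axis=1, keepdims=True)
    side_sign = 1.0 if traj.side == "left" else -1.0
    lraw = side_sign * np.cross(vhat, shat)
    lnorm = np.linalg.norm(lraw, axis=1)
    lvalid = valid & (lnorm > 1e-12)
    lhat = np.zeros_like(lraw)
    lhat[lvalid] = lraw[lvalid] / lnorm[lvalid, None]
    lhat = _fill_reversals(lhat, lvalid)
    return -vhat, lhat


def assemble_force_vector(
    traj: SourceTrajectory,
    lift: np.ndarray,
    drag: np.ndarray,
) -> WingForceTrajectory:
    """Compose the 3-D wing force from lift and drag phase series.

    ``lift`` and ``drag`` must be sampled on the trajectory's one-period
    phase grid (length ``samples_per_period``); they are tiled over the
    simulated periods.  ``Fwing = L * l_hat + D * d_hat`` with ``d_hat``
    antiparallel to the source velocity and ``l_hat`` perpendicular to it,
    flipping with the stroke direction so a sign-flipping lift yields upward
    force in both half-strokes.
    """
    n = traj.samples_per_period
    L = np.asarray(lift, dtype=float)
    D = np.asarray(drag, dtype=float)
    if L.shape != (n,) or D.shape != (n,):
        raise ValueError(
            f"lift/drag must be sampled on the {n}-point phase grid, "
            f"got shapes {L.shape} and {D.shape}"
        )
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(D))):
        raise ValueError("non-finite lift/drag samples")
    dhat, lhat = _direction_frame(traj)
    Lf = np.tile(L, traj.n_periods)
    Df = np.tile(D, traj.n_periods)
    force = Lf[:, None] * lhat + Df[:, None] * dhat
    return WingForceTrajectory(
        times=traj.times,
        force=force,
        side=traj.side,
        flap_frequency=traj.flap_frequency,
        samples_per_period=n,
        n_periods=traj.n_periods,
    )


def decompose_net_force(
    net_force: np.ndarray,
    traj_left: SourceTrajectory,
    traj_right: SourceTrajectory,
) -> dict[str, LiftDragProfile]:
    """Split a net 3-D force series into per-wing lift/drag profiles.

    Assumes bilaterally symmetric flight: each wing carries half the net
    force.  Per wing, drag is the component antiparallel to the source
    velocity and lift the signed magnitude of the perpendicular residual
    (sign taken along the wing's lift direction).
    """
    F = np.asarray(net_force, dtype=float)
    n = traj_left.samples_per_period
    if F.shape != (n, 3):
        raise ValueError(
            f"net force must be shaped ({n}, 3) to match the trajectory grid, got {F.shape}"
        )
    if traj_right.samples_per_period != n:
        raise ValueError("left/right trajectory grids mismatch")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite net force")
    # The lateral (y) components of the two wings cancel in the net force, so
    # each wing's force is reconstructed from the observable x/z half-force by
    # requiring it to lie in the wing's instantaneous lift-drag plane
    # span{-v_hat, l_hat}: a 2x2 solve per sample for (drag, lift).
    out: dict[str, LiftDragProfile] = {}
    half_xz = F[:, [0, 2]] / 2.0
    for traj in (traj_left, traj_right):
        dhat, lhat = _direction_frame(traj)
        dhat, lhat = dhat[:n], lhat[:n]
        A = np.stack([dhat[:, [0, 2]], lhat[:, [0, 2]]], axis=2)  # (n, 2, 2)
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        ok = np.abs(det) > 1e-9
        drag = np.zeros(n)
        lift = np.zeros(n)
        inv_det = np.where(ok, det, 1.0)
        drag[ok] = ((A[:, 1, 1] * half_xz[:, 0] - A[:, 0, 1] * half_xz[:, 1]) / inv_det)[ok]
        lift[ok] = ((-A[:, 1, 0] * half_xz[:, 0] + A[:, 0, 0] * half_xz[:, 1]) / inv_det)[ok]
        if not ok.all():
            # Degenerate plane projection (near reversals): naive projection.
            naive_d = -np.einsum("ij,ij->i", F / 2.0, -dhat)
            perp = F / 2.0 - (-naive_d)[:, None] * (-dhat)
            drag[~ok] = naive_d[~ok]
            lift[~ok] = np.einsum("ij,ij->i", perp, lhat)[~ok]
        out[traj.side] = LiftDragProfile(lift=lift, drag=drag)
    return out


def lowpass_forces(
    series: np.ndarray,
    order: int = 8,
    cutoff: float = 180.0,
    sample_rate: float = 4000.0,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth lowpass, as applied to measured force data.

    Forward-backward application (``filtfilt``) doubles the effective order
    rolloff and preserves DC exactly.  Defaults mirror force-plate
    conditioning (order 8 at 180 Hz, 4 kHz sampling); kinematics use order 4
    at 400 Hz.
    """
    nyquist = sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyquist} Hz), got {cutoff}")
    sos = _signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return _signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=axis)


def bandlimit_periodic(values: np.ndarray, n_harmonics: int, axis: int = 0) -> np.ndarray:
    """Truncate a one-period sampled signal to its first ``n_harmonics``.

    Keeps the mean and harmonics ``1..n_harmonics`` of the wingbeat
    fundamental, zeroing everything above — an ideal (brick-wall) lowpass
    for strictly periodic series.
    """
    values = np.asarray(values, dtype=float)
    spec = np.fft.rfft(values, axis=axis)
    idx = [slice(None)] * values.ndim
    idx[axis] = slice(n_harmonics + 1, None)
    spec[tuple(idx)] = 0.0
    return np.fft.irfft(spec, n=values.shape[axis], axis=axis)


def build_wing_forces(
    traj_left: SourceTrajectory,
    traj_right: SourceTrajectory,
    profile: WeightSupportProfile,
    body_mass: float,
    medium: Medium | None = None,
    lift_drag_ratio=DEFAULT_LIFT_DRAG_RATIO,
    bandlimit: int | None = None,
) -> dict[str, WingForceTrajectory]:
    """Per-wing force trajectories from a weight support profile.

    The profile is normalized so total vertical force averages ``m*g``; each
    wing carries half, with the lift sign flipping between half-strokes so
    the vertical force stays supportive throughout.  Because lift tilts
    slightly with the deviation angle and drag has a small vertical
    component, a final scalar rescale enforces the mean-vertical-force
    identity exactly.  ``bandlimit`` truncates the assembled force vectors
    to the first N wingbeat harmonics (ideal periodic lowpass).
    """
    medium = medium or Medium()
    n = traj_left.samples_per_period
    vertical = np.asarray(
        normalize_weight_support(profile.samples(n), body_mass, medium), dtype=float
    )
    target = body_mass * medium.gravity
    out: dict[str, WingForceTrajectory] = {}
    for traj in (traj_left, traj_right):
        _, lhat = _direction_frame(traj)
        sign = np.sign(lhat[:n, 2])
        sign[sign == 0] = 1.0
        lift = sign * vertical / 2.0
        drag = drag_from_lift(lift, lift_drag_ratio)
        out[traj.side] = assemble_force_vector(traj, lift, drag)
    mean_vertical = sum(f.one_period()[:, 2].mean() for f in out.values())
    if mean_vertical <= 0:
        raise ValueError("assembled forces do not support weight (mean vertical <= 0)")
    scale = target / mean_vertical
    for side, f in out.items():
        force = f.force * scale
        if bandlimit is not None:
            one = bandlimit_periodic(force[:n], bandlimit, axis=0)
            force = np.tile(one, (f.n_periods, 1))
        out[side] = WingForceTrajectory(
            times=f.times,
            force=force,
            side=side,
            flap_frequency=f.flap_frequency,
            samples_per_period=n,
            n_periods=f.n_periods,
        )
    return out
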