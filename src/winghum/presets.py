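"""Synthetic paradigm animals and test signals.

Five groups of flapping fliers are represented by paradigm animals whose
weight-support waveforms have qualitatively distinct harmonic signatures:

* ``elongated_fly`` (mosquito-like): dominant second harmonic with
  substantial content up through the sixth — the buzz; shallow strokes.
* ``compact_fly`` (drosophilid-like): dominant second harmonic plus
  higher-harmonic content.
* ``lepidoptera`` (hawkmoth-like): strong first and second harmonics.
* ``hummingbird``: first and second harmonics of comparable strength — the
  hum.
* ``generalist_bird`` (parrotlet-like): a downstroke-only half-sine, so
  nearly all energy sits in the first harmonic — the whoosh.

The profile shapes are parameterized Fourier stand-ins with the documented
harmonic rankings; externally digitized profiles can be supplied through
the table interface with the same schema.  Morphology defaults are
round-number literature-scale values for each paradigm animal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acoustics import HumModel
from .forces import DEFAULT_LIFT_DRAG_RATIO, PARADIGM_GROUPS, WeightSupportProfile
from .kinematics import FlappingSpec, HarmonicSeries, Medium

__all__ = [
    "PARADIGM_GROUPS",
    "ParadigmPreset",
    "make_preset",
    "make_model",
    "make_test_signal",
]


@dataclass(frozen=True)
class ParadigmPreset:
    """Morphology, kinematics, and force waveform of one paradigm animal."""

    group: str
    spec: FlappingSpec
    profile: WeightSupportProfile
    lift_drag_ratio: float = DEFAULT_LIFT_DRAG_RATIO

    def with_(self, **spec_overrides) -> "ParadigmPreset":
        """Copy with FlappingSpec fields overridden (e.g. body_mass=...)."""
        return replace(self, spec=self.spec.with_(**spec_overrides))


def _stroke_locked_profile(sharpness: float, asymmetry: float, group: str) -> WeightSupportProfile:
    """Weight support locked to the stroke: peaks at the two mid-strokes.

    ``w(tau) = |sin(2 pi tau)|^sharpness * (1 + asymmetry*sin(2 pi tau))``,
    normalized to unit mean.  Force vanishes at the stroke reversals
    (tau = 0, 1/2) where the wing is momentarily still; ``sharpness``
    narrows the mid-stroke force peaks (more high-harmonic content) and
    ``asymmetry`` biases support toward the downstroke (odd harmonics).
    """
    tau = np.arange(4096) / 4096
    w = np.abs(np.sin(2 * np.pi * tau)) ** sharpness
    w *= 1.0 + asymmetry * np.sin(2 * np.pi * tau)
    w /= w.mean()
    return WeightSupportProfile.from_samples(tau, w, n_harmonics=8, group=group)


def _half_sine_profile(group: str, downstroke_fraction: float = 0.5) -> WeightSupportProfile:
    """Downstroke-only half-sine weight support, unit mean."""
    tau = np.arange(4096) / 4096
    w = np.where(
        tau < downstroke_fraction,
        np.sin(np.pi * tau / downstroke_fraction),
        0.0,
    )
    w /= w.mean()
    return WeightSupportProfile.from_samples(tau, w, n_harmonics=8, group=group)


# Paradigm waveforms (bodyweights; unit mean).  Harmonic signatures:
# flies put most energy in harmonic 2 with substantial content through 6;
# hummingbirds/hawkmoths pair harmonics 1 and 2; the generalist bird's
# downstroke-only half-sine concentrates energy in harmonic 1.
_PROFILES = {
    "elongated_fly": _stroke_locked_profile(4.0, 0.25, "elongated_fly"),
    "compact_fly": _stroke_locked_profile(3.0, 0.35, "compact_fly"),
    "lepidoptera": _stroke_locked_profile(1.0, 0.60, "lepidoptera"),
    "hummingbird": _stroke_locked_profile(1.2, 0.55, "hummingbird"),
    "generalist_bird": _half_sine_profile("generalist_bird"),
}

# Morphology defaults: (mass kg, wing length m, fw Hz, stroke amplitude rad).
_MORPHOLOGY = {
    "elongated_fly": (2.5e-6, 0.0035, 600.0, 0.8),
    "compact_fly": (2.0e-6, 0.0030, 200.0, 2.0),
    "lepidoptera": (1.5e-3, 0.050, 26.0, 2.0),
    "hummingbird": (5.0e-3, 0.058, 44.2, 2.0),
    "generalist_bird": (3.0e-2, 0.095, 18.0, 2.0),
}

#: Hummingbird deviation series: negligible first-harmonic content, the
#: figure-of-eight wiggle concentrated in harmonics 2-3 (rad).
_HUMMINGBIRD_DEVIATION = HarmonicSeries(
    0.0, np.array([0.02, 0.12, 0.0]), np.array([0.0, 0.0, 0.06])
)


def make_preset(group: str, **spec_overrides) -> ParadigmPreset:
    """Build the paradigm preset for a group, optionally overriding spec fields.

    Raises for unrecognized groups, listing the valid names.
    """
    if group not in _PROFILES:
        raise ValueError(
            f"unknown paradigm group {group!r}; valid groups: {', '.join(PARADIGM_GROUPS)}"
        )
    m, R, fw, amp = _MORPHOLOGY[group]
    deviation = _HUMMINGBIRD_DEVIATION if group == "hummingbird" else HarmonicSeries()
    spec = FlappingSpec(
        body_mass=m,
        wing_length=R,
        r3_fraction=0.55,
        flap_frequency=fw,
        stroke_amplitude=amp,
        deviation=deviation,
    )
    if spec_overrides:
        spec = spec.with_(**spec_overrides)
    return ParadigmPreset(group=group, spec=spec, profile=_PROFILES[group])


def make_model(
    group_or_preset,
    medium: Medium | None = None,
    samples_per_period: int = 1024,
    n_periods: int = 4,
    bandlimit: int | None = None,
    equation: str = "eq1",
    **spec_overrides,
) -> HumModel:
    """Convenience: a ready-to-radiate HumModel from a group name or preset."""
    preset = (
        group_or_preset
        if isinstance(group_or_preset, ParadigmPreset)
        else make_preset(group_or_preset)
    )
    if spec_overrides:
        preset = preset.with_(**spec_overrides)
    return HumModel(
        preset.spec,
        preset.profile,
        medium=medium,
        lift_drag_ratio=preset.lift_drag_ratio,
        samples_per_period=samples_per_period,
        n_periods=n_periods,
        bandlimit=bandlimit,
        equation=equation,
    )


def make_test_signal(
    kind: str,
    sample_rate: float = 8192.0,
    duration: float = 1.0,
    seed: int = 0,
    **params,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic test signals with known analytic spectra.

    Kinds
    -----
    ``sine``: ``amplitude`` (default 1) at ``frequency`` (default 100 Hz);
    rms = amplitude/sqrt(2).
    ``two_tone``: ``amplitudes`` (a1, a2) at ``frequencies`` (f1, f2);
    per-tone band power a_i^2/2.
    ``bandlimited_noise``: Gaussian white noise brick-walled to
    [``f_lo``, ``f_hi``] (defaults 20-500 Hz), unit variance before
    filtering; reproducible from ``seed``.

    Returns ``(times, values)``.
    """
    n = int(round(sample_rate * duration))
    if n < 2:
        raise ValueError("duration too short for the sample rate")
    t = np.arange(n) / sample_rate
    if kind == "sine":
        a = params.get("amplitude", 1.0)
        f = params.get("frequency", 100.0)
        return t, a * np.sin(2.0 * np.pi * f * t)
    if kind == "two_tone":
        a1, a2 = params.get("amplitudes", (1.0, 0.5))
        f1, f2 = params.get("frequencies", (100.0, 250.0))
        return t, a1 * np.sin(2.0 * np.pi * f1 * t) + a2 * np.sin(2.0 * np.pi * f2 * t)
    if kind == "bandlimited_noise":
        f_lo = params.get("f_lo", 20.0)
        f_hi = params.get("f_hi", 500.0)
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        X = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        X[(freqs < f_lo) | (freqs > f_hi)] = 0.0
        return t, np.fft.irfft(X, n=n)
    raise ValueError(f"unknown test signal kind {kind!r} (sine | two_tone | bandlimited_noise)")
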