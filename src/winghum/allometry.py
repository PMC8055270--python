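"""Allometric scaling of radiated acoustic power across species.

Dimensional analysis of the moving point-force equation collapses the
far-field radiated power of a hovering flapper to the scaling law

.. math::

    P_o = \\frac{4 F_o^2 \\Phi_o^2 f_w^2}{\\pi \\rho_o a_o^3}
        \\approx 2.5\\times10^{-6}\\,\\Phi_o^2 m^2 f_w^2,

where ``F_o = m g`` is the weight the wings must support, ``Phi_o`` the
stroke amplitude (rad) and ``f_w`` the wingbeat frequency.  This module
evaluates the law, runs the full acoustic model over species tables
(mass, wing length, frequency, paradigm group), and fits log-log slopes of
simulated power against body mass or against the scaling-law predictor —
the machinery behind cross-species power comparisons.  Under geometric
similarity (isometry) the simulated power tracks the predictor with slope
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .fields import radiated_power
from .forces import PARADIGM_GROUPS
from .kinematics import HarmonicSeries, Medium
from .presets import make_model, make_preset

__all__ = [
    "SpeciesRecord",
    "ScalingResult",
    "power_law",
    "power_law_prefactor",
    "species_sweep",
    "fit_allometry",
    "isometric_grid",
]

#: Default stroke amplitude (rad) when a record omits it; order one across
#: flapping fliers.  Elongated flies stroke markedly shallower.
DEFAULT_STROKE_AMPLITUDE = 2.0
GROUP_STROKE_AMPLITUDE = {"elongated_fly": 0.8}


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: group membership plus the three scaling variables."""

    name: str
    group: str
    body_mass: float            # kg
    wing_length: float          # m
    flap_frequency: float       # Hz
    stroke_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.group not in PARADIGM_GROUPS:
            raise ValueError(
                f"species {self.name!r} has unmapped group {self.group!r}; "
                f"valid groups: {', '.join(PARADIGM_GROUPS)}"
            )
        if min(self.body_mass, self.wing_length, self.flap_frequency) <= 0:
            raise ValueError(f"species {self.name!r} has non-positive mass/length/frequency")

    @property
    def amplitude(self) -> float:
        if self.stroke_amplitude is not None:
            return self.stroke_amplitude
        return GROUP_STROKE_AMPLITUDE.get(self.group, DEFAULT_STROKE_AMPLITUDE)


@dataclass
class ScalingResult:
    """Per-species simulated and scaling-law powers."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def empty(self) -> bool:
        return self.table.empty

    def __len__(self) -> int:
        return len(self.table)


def power_law_prefactor(medium: Medium | None = None) -> float:
    """The constant ``4 g^2 / (pi rho_o a_o^3)`` in kg^-1 s^-1."""
    m = medium or Medium()
    return 4.0 * m.gravity**2 / (np.pi * m.air_density * m.speed_of_sound**3)


def power_law(
    body_mass: float,
    stroke_amplitude: float,
    flap_frequency: float,
    medium: Medium | None = None,
) -> float:
    """Scaling-law radiated power ``4 (m g)^2 Phi_o^2 fw^2 / (pi rho_o a_o^3)`` (W)."""
    if min(body_mass, stroke_amplitude, flap_frequency) <= 0:
        raise ValueError("mass, stroke amplitude, and frequency must be > 0")
    return (
        power_law_prefactor(medium)
        * (body_mass * stroke_amplitude * flap_frequency) ** 2
    )


def scaling_predictor(
    body_mass: float,
    stroke_amplitude: float,
    flap_frequency: float,
    medium: Medium | None = None,
) -> float:
    """The predictor ``X = 4 Fo^2 Phi_o^2 fw^2 / (pi rho_o a_o^3)`` (W).

    Identical to :func:`power_law`; kept as a named alias because the
    log-log fits regress simulated power on this quantity.
    """
    return power_law(body_mass, stroke_amplitude, flap_frequency, medium)


def species_sweep(
    records: list[SpeciesRecord],
    medium: Medium | None = None,
    model: str = "eq1",
    samples_per_period: int = 256,
    n_nodes: int = 128,
    radius_wavelengths: float = 2.0,
) -> ScalingResult:
    """Run the acoustic model for every species and tabulate powers.

    Each species gets its paradigm group's weight-support profile
    (normalized to its own body weight), a pure first-harmonic stroke at
    its amplitude and frequency, and a far-field power integration on a
    sphere of ``radius_wavelengths`` first-harmonic wavelengths.
    """
    medium = medium or Medium()
    rows = []
    for rec in records:
        preset = make_preset(rec.group).with_(
            body_mass=rec.body_mass,
            wing_length=rec.wing_length,
            flap_frequency=rec.flap_frequency,
            stroke_amplitude=rec.amplitude,
            stroke=None,                 # rebuild pure-cosine stroke at this amplitude
            deviation=HarmonicSeries(),  # horizontal stroke plane across the sweep
        )
        hum = make_model(
            preset,
            medium=medium,
            samples_per_period=samples_per_period,
            n_periods=2,
            equation=model,
        )
        radius = radius_wavelengths * medium.speed_of_sound / rec.flap_frequency
        p_sim = radiated_power(hum, radius, n_nodes=n_nodes, medium=medium)
        rows.append(
            {
                "name": rec.name,
                "group": rec.group,
                "mass_kg": rec.body_mass,
                "wing_length_m": rec.wing_length,
                "flap_freq_hz": rec.flap_frequency,
                "stroke_amp_rad": rec.amplitude,
                "p_sim_w": p_sim,
                "p_law_w": power_law(rec.body_mass, rec.amplitude, rec.flap_frequency, medium),
                "predictor_w": scaling_predictor(
                    rec.body_mass, rec.amplitude, rec.flap_frequency, medium
                ),
            }
        )
    return ScalingResult(pd.DataFrame(rows))


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of log10(P_sim) vs log10(x) with a 95% confidence interval."""

    slope: float
    intercept: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int
    group: str = "all"


def fit_allometry(result: ScalingResult, x: str = "predictor") -> dict[str, SlopeFit]:
    """Log-log OLS slopes of simulated power, pooled and per group.

    ``x`` selects the abscissa: ``"mass"`` (body mass, kg) or
    ``"predictor"`` (the scaling-law power).  Groups with fewer than three
    species are skipped in the per-group fits.
    """
    col = {"mass": "mass_kg", "predictor": "predictor_w"}.get(x)
    if col is None:
        raise ValueError("x must be 'mass' or 'predictor'")
    df = result.table
    if df.empty:
        return {}
    if (df["p_sim_w"] <= 0).any() or (df[col] <= 0).any():
        raise ValueError("non-positive powers cannot be fit in log space")
    fits: dict[str, SlopeFit] = {}

    def _fit(sub: pd.DataFrame, label: str) -> SlopeFit | None:
        if len(sub) < 3:
            return None
        lx = np.log10(sub[col].to_numpy())
        ly = np.log10(sub["p_sim_w"].to_numpy())
        if np.ptp(lx) == 0:
            raise ValueError(f"degenerate abscissa for group {label!r}")
        res = _stats.linregress(lx, ly)
        tcrit = _stats.t.ppf(0.975, len(sub) - 2) if len(sub) > 2 else np.inf
        return SlopeFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            stderr=float(res.stderr),
            ci_low=float(res.slope - tcrit * res.stderr),
            ci_high=float(res.slope + tcrit * res.stderr),
            n=len(sub),
            group=label,
        )

    pooled = _fit(df, "all")
    if pooled:
        fits["all"] = pooled
    for group, sub in df.groupby("group"):
        f = _fit(sub, str(group))
        if f:
            fits[str(group)] = f
    return fits


def isometric_grid(
    n: int = 6,
    group: str = "hummingbird",
    mass_range: tuple[float, float] = (1e-3, 1e-1),
    reference_mass: float = 5e-3,
    reference_wing: float = 0.058,
    reference_freq: float = 44.2,
    freq_exponent: float = -1.0 / 3.0,
) -> list[SpeciesRecord]:
    """Synthetic species grid obeying geometric similarity.

    Wing length scales as ``m^(1/3)`` and flapping frequency as
    ``m^freq_exponent`` (default -1/3, the isometric choice) about a
    reference animal, with a fixed group profile and stroke amplitude — a
    controlled input for validating the scaling-law machinery.
    """
    masses = np.geomspace(*mass_range, n)
    return [
        SpeciesRecord(
            name=f"iso{i}",
            group=group,
            body_mass=float(m),
            wing_length=float(reference_wing * (m / reference_mass) ** (1.0 / 3.0)),
            flap_frequency=float(reference_freq * (m / reference_mass) ** freq_exponent),
        )
        for i, m in enumerate(masses)
    ]
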