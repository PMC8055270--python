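"""Pressure field sampling, directivity sections, and radiated power.

The pressure field of a flapping animal is sampled on quasi-uniform
spherical lattices (Fibonacci point sets, whose equal-area property makes
spherical quadrature a plain average) and on angular rings in the two
anatomical planes:

* sagittal (side view): the x-z plane; in-plane angle measured from the
  anterior (+x) axis, so 90 deg is vertical and angles > 90 deg tilt aft;
* coronal (front view): the y-z plane; angle from the animal's left (+y)
  axis, 90 deg vertical.

Per-harmonic directivity uses the +-2.5 Hz band mean-square pressure at
each node.  The *principal directivity axis* of a lobed (dipole-like)
section is the axis perpendicular to the "waistline" chord joining the two
angular minima of the pattern.  Radiated acoustic power integrates
``p_rms^2 / (rho_o a_o)`` over a far-field sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .acoustics import HumModel, Observer, PressureTrace
from .kinematics import Medium
from .spectra import harmonic_bands, spl_spectrum

__all__ = [
    "BROADBAND_RANGE",
    "FieldMap",
    "DirectivitySection",
    "fibonacci_sphere",
    "sample_sphere",
    "directivity_section",
    "principal_axis",
    "radiated_power",
]

#: Broadband analysis range, Hz (excludes the steady/DC pressure offset).
BROADBAND_RANGE = (3.0, 500.0)

_PLANES = {
    "sagittal": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    "coronal": (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])),
}


@dataclass(frozen=True)
class FieldMap:
    """Pressure summary over a lattice of observer nodes."""

    nodes: np.ndarray           # (n, 3) m
    radius: float | None        # sphere radius, or None for planar grids
    rms: np.ndarray             # (n,) broadband rms, Pa
    band_rms: np.ndarray | None  # (n, n_harmonics) per-harmonic band rms, Pa
    flap_frequency: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.nodes, columns=["x_m", "y_m", "z_m"])
        df.insert(0, "node_id", np.arange(self.nodes.shape[0]))
        df["rms_pa"] = self.rms
        if self.band_rms is not None:
            for k in range(self.band_rms.shape[1]):
                df[f"band{k + 1}_rms_pa"] = self.band_rms[:, k]
        return df


@dataclass(frozen=True)
class DirectivitySection:
    """Band rms vs. polar angle on a ring in an anatomical plane."""

    plane: str                  # "sagittal" | "coronal"
    radius: float               # m
    angles: np.ndarray          # (n,) deg, in [0, 360)
    band_rms: np.ndarray        # (n,) Pa
    band: int | str             # harmonic index or "broadband"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.angles, "rms_pa": self.band_rms})


def fibonacci_sphere(n_nodes: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform (equal-area) point lattice on a sphere."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    i = np.arange(n_nodes)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_nodes
    theta = np.arccos(np.clip(z, -1, 1))
    phi = 2.0 * np.pi * i / golden
    return radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), z], axis=1
    )


def _trace_broadband_rms(trace: PressureTrace, band=BROADBAND_RANGE) -> float:
    spec = spl_spectrum(trace)
    return float(np.sqrt(spec.band_ms(*band)))


def _trace_band_rms(trace: PressureTrace, n_harmonics: int) -> np.ndarray:
    spec = spl_spectrum(trace)
    table = harmonic_bands(spec, trace.flap_frequency, n_harmonics)
    return np.sqrt(table.band_ms)


def _pressure_fn(model):
    """Accept a HumModel or any callable Observer -> PressureTrace."""
    if isinstance(model, HumModel):
        return model.pressure
    if callable(model):
        return model
    raise TypeError("model must be a HumModel or a callable observer -> PressureTrace")


def sample_sphere(
    model,
    radius: float,
    n_nodes: int = 512,
    n_harmonics: int | None = None,
    min_radius: float | None = None,
) -> FieldMap:
    """Sample the pressure field on an equal-area spherical lattice.

    Records the broadband (3-500 Hz) rms at every node and, if
    ``n_harmonics`` is given, the +-2.5 Hz band rms around each wingbeat
    harmonic (requires a trace long enough for 2.5 Hz resolution).
    """
    fn = _pressure_fn(model)
    if min_radius is None and isinstance(model, HumModel):
        min_radius = model.spec.r3
    if min_radius is not None and radius <= min_radius:
        raise ValueError(f"radius {radius} m inside the source region (> {min_radius} m needed)")
    nodes = fibonacci_sphere(n_nodes, radius)
    t_start = (
        model.default_start_time(radius) if isinstance(model, HumModel) else None
    )
    rms = np.empty(n_nodes)
    band = np.empty((n_nodes, n_harmonics)) if n_harmonics else None
    fw = None
    for i, node in enumerate(nodes):
        trace = (
            fn(Observer(node, label=f"node{i}"), t_start=t_start)
            if t_start is not None
            else fn(Observer(node, label=f"node{i}"))
        )
        fw = trace.flap_frequency
        rms[i] = _trace_broadband_rms(trace)
        if band is not None:
            band[i] = _trace_band_rms(trace, n_harmonics)
    return FieldMap(nodes, radius, rms, band, fw)


def directivity_section(
    model,
    plane: str,
    radius: float,
    band: int | str = "broadband",
    n_angles: int = 360,
) -> DirectivitySection:
    """Band rms vs. polar angle on a ring in an anatomical plane.

    ``band`` is a harmonic index (+-2.5 Hz band) or ``"broadband"``
    (3-500 Hz).  Angles run counterclockwise from the in-plane horizontal
    axis (+x for sagittal, +y for coronal); 90 deg is straight up.
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r}; choose from {sorted(_PLANES)}")
    fn = _pressure_fn(model)
    e1, e2 = _PLANES[plane]
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rad = np.deg2rad(angles)
    nodes = radius * (np.cos(rad)[:, None] * e1 + np.sin(rad)[:, None] * e2)
    t_start = model.default_start_time(radius) if isinstance(model, HumModel) else None
    vals = np.empty(n_angles)
    for i, node in enumerate(nodes):
        trace = (
            fn(Observer(node), t_start=t_start) if t_start is not None else fn(Observer(node))
        )
        if band == "broadband":
            vals[i] = _trace_broadband_rms(trace)
        else:
            vals[i] = _trace_band_rms(trace, int(band))[int(band) - 1]
    return DirectivitySection(plane, radius, angles, vals, band)


def _circular_smooth(values: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    ext = np.concatenate([values[-pad:], values, values[:pad]])
    return np.convolve(ext, kernel, mode="valid")


def principal_axis(section: DirectivitySection, smooth_width: int = 3) -> float:
    """Principal directivity axis (deg in [0, 180)) of a lobed section.

    Finds the two angular minima ("waist") of the smoothed polar pattern,
    forms the waistline chord between them, and returns the in-plane axis
    perpendicular to that chord.  Raises for patterns without two distinct
    minima (axisymmetric fields have no waist).
    """
    vals = _circular_smooth(section.band_rms, smooth_width)
    n = vals.size
    prev_v = np.roll(vals, 1)
    next_v = np.roll(vals, -1)
    is_min = (vals < prev_v) & (vals <= next_v)
    idx = np.flatnonzero(is_min)
    if idx.size < 2:
        spread = vals.max() - vals.min()
        raise ValueError(
            "no lobed waist found: pattern has "
            f"{idx.size} local minima (relative spread {spread / max(vals.max(), 1e-300):.2e}); "
            "an axisymmetric field has no principal axis"
        )
    # Two deepest minima, preferring roughly opposite ones; ties -> smaller angle.
    order = idx[np.argsort(vals[idx], kind="stable")]
    i1 = order[0]
    opposite = [j for j in order[1:] if 0.25 * n <= (j - i1) % n <= 0.75 * n]
    i2 = opposite[0] if opposite else order[1]
    a1, a2 = np.deg2rad(section.angles[[i1, i2]])
    r1, r2 = vals[i1], vals[i2]
    p1 = np.array([r1 * np.cos(a1), r1 * np.sin(a1)])
    p2 = np.array([r2 * np.cos(a2), r2 * np.sin(a2)])
    chord = p2 - p1
    axis = np.degrees(np.arctan2(chord[1], chord[0])) + 90.0
    return float(np.mod(axis, 180.0))


def radiated_power(
    model,
    radius: float,
    n_nodes: int = 512,
    medium: Medium | None = None,
    fieldmap: FieldMap | None = None,
) -> float:
    """Total radiated acoustic power (W) by spherical quadrature.

    ``P = sum(p_rms^2 / (rho_o a_o)) * 4 pi r^2 / n`` over an equal-area
    node set.  ``radius`` should be at least one wavelength of the first
    harmonic; inside that the 1/r^2 nearfield term makes the integral
    radius-dependent (a warning is emitted).
    """
    if medium is None:
        medium = model.medium if isinstance(model, HumModel) else Medium()
    if isinstance(model, HumModel):
        lam1 = medium.speed_of_sound / model.spec.flap_frequency
        if radius < lam1:
            warnings.warn(
                f"radius {radius} m is inside the first-harmonic wavelength "
                f"({lam1:.1f} m); radiated power is not radius-invariant there",
                stacklevel=2,
            )
    fm = fieldmap if fieldmap is not None else sample_sphere(model, radius, n_nodes)
    area = 4.0 * np.pi * radius**2
    intensity = fm.rms**2 / (medium.air_density * medium.speed_of_sound)
    return float(intensity.mean() * area)
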