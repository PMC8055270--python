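"""Configuration, table I/O, WAV export, and run manifests.

All tabular interchange uses delimited text (CSV) with documented column
schemas; configs are YAML or JSON.  Conventions stamped into every output
header: angles in degrees, positions in meters, pressure in Pa, SPL in dB
re 20 uPa (configurable), coordinate frame x anterior / y left / z up with
the shoulder pivot at the origin.

Schemas
-------
kinematics table:  ``phase, stroke_rad, deviation_rad``
force table:       ``phase, lift_N, drag_N``  or  ``phase, weight_support_bw``
observer set:      ``label, x, y, z``
species table:     ``name, group, mass_kg, wing_length_m, flap_freq_hz[, stroke_amp_rad]``
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile as _wavfile

from .acoustics import Observer, PressureTrace
from .allometry import SpeciesRecord
from .forces import LiftDragProfile, WeightSupportProfile, lowpass_forces
from .kinematics import FlappingSpec, HarmonicSeries, Medium

__all__ = [
    "RunConfig",
    "COORDINATE_NOTE",
    "read_kinematics_table",
    "read_force_table",
    "read_in_vivo_tables",
    "read_observers",
    "read_species_table",
    "write_kinematics_table",
    "write_force_table",
    "write_trace",
    "write_wav",
    "write_manifest",
    "observer_preset",
]

logger = logging.getLogger("winghum")

COORDINATE_NOTE = (
    "# frame: x anterior, y left, z up; pivot at origin; angles deg; "
    "positions m; pressure Pa; SPL dB re configured reference"
)

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Serializable description of one simulation run.

    A run is reproducible from its config alone: animal preset (or explicit
    spec fields), medium overrides, observer set, resolution, and analysis
    options are all here, and :meth:`config_hash` fingerprints the lot.
    """

    preset: str = "hummingbird"
    spec_overrides: dict = field(default_factory=dict)
    medium: dict = field(default_factory=dict)
    observers: list = field(default_factory=lambda: [["overhead_1m", 0.0, 0.0, 1.0]])
    samples_per_period: int = 1024
    n_periods: int = 18
    equation: str = "eq1"
    bandlimit: int | None = None
    n_harmonics: int = 10
    band_half_width_hz: float = 2.5
    broadband_hz: list = field(default_factory=lambda: [3.0, 500.0])
    spl_reference_pa: float = 20e-6
    section_radius_m: float = 10.0
    section_angles: int = 360
    output_dir: str = "winghum_out"
    write_wav: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ValueError(f"unreadable config {path}: {exc}") from exc
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_medium(self) -> Medium:
        return Medium(**self.medium)

    def build_observers(self) -> list[Observer]:
        out = []
        for row in self.observers:
            label, x, y, z = row
            out.append(Observer(np.array([x, y, z], dtype=float), str(label)))
        if not out:
            raise ValueError("config defines no observers")
        return out


def _read_csv(path, expected_cols: dict[str, set[str] | None]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _check_phase_coverage(phase: np.ndarray, path) -> None:
    tau = np.mod(np.asarray(phase, dtype=float), 1.0)
    if tau.size < 8:
        raise ValueError(f"{path}: too few phase samples ({tau.size}) for a periodic fit")
    srt = np.sort(tau)
    gaps = np.diff(np.concatenate([srt, srt[:1] + 1.0]))
    if gaps.max() > 0.2:
        raise ValueError(
            f"{path}: phase coverage has a gap of {gaps.max():.2f} wingbeats; "
            "series is gap-ridden or not phase-wrapped"
        )


def read_kinematics_table(
    path,
    n_harmonics: int = 5,
    lowpass: tuple[int, float, float] | None = None,
) -> tuple[HarmonicSeries, HarmonicSeries]:
    """Fit stroke/deviation Fourier series from a ``phase, stroke_rad,
    deviation_rad`` table.

    ``lowpass=(order, cutoff_hz, sample_rate_hz)`` optionally applies the
    zero-phase Butterworth conditioning used for tracked kinematics
    (order 4 at 400 Hz) before fitting; requires uniform phase sampling.
    """
    df = _read_csv(path, {})
    _require_columns(df, ["phase", "stroke_rad", "deviation_rad"], path)
    phase = df["phase"].to_numpy(dtype=float)
    _check_phase_coverage(phase, path)
    stroke = df["stroke_rad"].to_numpy(dtype=float)
    deviation = df["deviation_rad"].to_numpy(dtype=float)
    if lowpass is not None:
        order, cutoff, fs = lowpass
        stroke = lowpass_forces(stroke, order=order, cutoff=cutoff, sample_rate=fs)
        deviation = lowpass_forces(deviation, order=order, cutoff=cutoff, sample_rate=fs)
    return (
        HarmonicSeries.from_samples(phase, stroke, n_harmonics),
        HarmonicSeries.from_samples(phase, deviation, n_harmonics),
    )


def read_force_table(
    path,
    n_harmonics: int = 8,
    lowpass: tuple[int, float, float] | None = None,
):
    """Read a per-wing force table.

    Returns a :class:`LiftDragProfile` for ``phase, lift_N, drag_N`` columns
    or a :class:`WeightSupportProfile` for ``phase, weight_support_bw``.
    ``lowpass`` mirrors force-plate conditioning (order 8 at 180 Hz).
    """
    df = _read_csv(path, {})
    if "phase" not in df.columns:
        raise ValueError(f"{path}: missing required column 'phase'")
    phase = df["phase"].to_numpy(dtype=float)
    _check_phase_coverage(phase, path)

    def _cond(vals):
        if lowpass is None:
            return vals
        order, cutoff, fs = lowpass
        return lowpass_forces(vals, order=order, cutoff=cutoff, sample_rate=fs)

    if {"lift_N", "drag_N"} <= set(df.columns):
        order = np.argsort(np.mod(phase, 1.0), kind="stable")
        lift = _cond(df["lift_N"].to_numpy(dtype=float)[order])
        drag = _cond(df["drag_N"].to_numpy(dtype=float)[order])
        return LiftDragProfile(lift=lift, drag=drag)
    if "weight_support_bw" in df.columns:
        vals = _cond(df["weight_support_bw"].to_numpy(dtype=float))
        return WeightSupportProfile.from_samples(phase, vals, n_harmonics)
    raise ValueError(
        f"{path}: expected columns 'lift_N, drag_N' or 'weight_support_bw', "
        f"found {list(df.columns)}"
    )


def read_in_vivo_tables(
    kinematics_path,
    forces_path,
    body_mass: float,
    wing_length: float,
    flap_frequency: float,
    r3_fraction: float = 0.55,
    n_harmonics: int = 5,
    kinematics_lowpass: tuple[int, float, float] | None = None,
    forces_lowpass: tuple[int, float, float] | None = None,
):
    """Ingest measured kinematics + force tables into model-ready objects.

    Returns ``(FlappingSpec, LiftDragProfile | WeightSupportProfile)``.
    Morphology (mass, wing length, wingbeat frequency) is not in the phase
    tables and must be supplied.  Lowpass tuples are ``(order, cutoff_hz,
    sample_rate_hz)``; measured data conventions are order 4 at 400 Hz for
    kinematics and order 8 at 180 Hz for forces.
    """
    stroke, deviation = read_kinematics_table(
        kinematics_path, n_harmonics, kinematics_lowpass
    )
    spec = FlappingSpec.from_series(
        body_mass=body_mass,
        wing_length=wing_length,
        stroke=stroke,
        deviation=deviation,
        r3_fraction=r3_fraction,
        flap_frequency=flap_frequency,
    )
    profile = read_force_table(forces_path, lowpass=forces_lowpass)
    return spec, profile


def read_observers(path) -> list[Observer]:
    """Load an observer set from a ``label, x, y, z`` table."""
    df = _read_csv(path, {})
    _require_columns(df, ["label", "x", "y", "z"], path)
    return [
        Observer(np.array([r.x, r.y, r.z], dtype=float), str(r.label))
        for r in df.itertuples()
    ]


def observer_preset(name: str, spacing: float = 0.02, half_extent: float = 0.12) -> list[Observer]:
    """Planar microphone-array presets 8 cm from the source region.

    ``top_plane`` / ``bottom_plane``: horizontal grids 8 cm above/below the
    pivot; ``front_plane``: vertical grid 8 cm anterior.
    """
    offsets = {"top_plane": (2, 0.08), "bottom_plane": (2, -0.08), "front_plane": (0, 0.08)}
    if name not in offsets:
        raise ValueError(f"unknown observer preset {name!r}; choose from {sorted(offsets)}")
    axis, off = offsets[name]
    u = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    out = []
    for i, a in enumerate(u):
        for j, b in enumerate(u):
            pos = np.zeros(3)
            pos[axis] = off
            other = [k for k in range(3) if k != axis]
            pos[other[0]], pos[other[1]] = a, b
            out.append(Observer(pos, f"{name}_{i}_{j}"))
    return out


def read_species_table(path) -> list[SpeciesRecord]:
    """Load species records from the documented CSV schema."""
    df = _read_csv(path, {})
    _require_columns(df, ["name", "group", "mass_kg", "wing_length_m", "flap_freq_hz"], path)
    if df.empty:
        raise ValueError(f"{path}: species table is empty")
    records = []
    for r in df.itertuples():
        amp = getattr(r, "stroke_amp_rad", None)
        amp = None if amp is None or (isinstance(amp, float) and np.isnan(amp)) else float(amp)
        records.append(
            SpeciesRecord(
                name=str(r.name),
                group=str(r.group),
                body_mass=float(r.mass_kg),
                wing_length=float(r.wing_length_m),
                flap_frequency=float(r.flap_freq_hz),
                stroke_amplitude=amp,
            )
        )
    return records


def _write_df(df: pd.DataFrame, path, header_note: str = COORDINATE_NOTE) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header_note + "\n")
        df.to_csv(fh, index=False)


def write_kinematics_table(path, spec: FlappingSpec, n: int = 256) -> None:
    tau = np.arange(n) / n
    _write_df(
        pd.DataFrame(
            {"phase": tau, "stroke_rad": spec.stroke(tau), "deviation_rad": spec.deviation(tau)}
        ),
        path,
    )


def write_force_table(path, profile, n: int = 256) -> None:
    tau = np.arange(n) / n
    if isinstance(profile, WeightSupportProfile):
        df = pd.DataFrame({"phase": tau, "weight_support_bw": profile.series(tau)})
    elif isinstance(profile, LiftDragProfile):
        m = profile.lift.size
        df = pd.DataFrame(
            {"phase": np.arange(m) / m, "lift_N": profile.lift, "drag_N": profile.drag}
        )
    else:
        raise TypeError("profile must be WeightSupportProfile or LiftDragProfile")
    _write_df(df, path)


def write_trace(path, trace: PressureTrace) -> None:
    """Pressure trace (and decomposition channels) as delimited text."""
    df = pd.DataFrame({"time_s": trace.times, "pressure_pa": trace.pressure})
    for name, vals in trace.channels.items():
        df[f"{name}_pa"] = vals
    _write_df(df, path)


def write_wav(path, trace: PressureTrace, normalize: bool = True) -> None:
    """Render a pressure trace as a mono 32-bit float WAV.

    ``normalize=True`` scales the peak to 0.5 full scale for audibility;
    otherwise raw pascals are written (tiny for a hum at a distance).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = trace.pressure.astype(np.float32)
    if normalize and np.abs(data).max() > 0:
        data = 0.5 * data / np.abs(data).max()
    _wavfile.write(path, int(round(trace.sample_rate)), data)


def write_manifest(path, config: RunConfig, outputs: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "winghum_version": _VERSION,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": sorted(outputs),
    }
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
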