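"""SPL spectra, harmonic band powers, and array-summed spectra.

Spectral levels are reported as sound pressure level, ``SPL = 10*log10(
<p^2> / p_ref^2)`` dB with the standard airborne reference ``p_ref = 20
uPa`` (configurable: relative, inter-harmonic levels are reference-free).
For strictly periodic simulated traces the default analysis window is
rectangular over an exact integer number of wingbeats, which places every
harmonic exactly on a bin and makes Parseval's identity hold to rounding
error; Welch/Hann estimation is available for measured recordings.

Harmonic accounting follows the band convention used for hum spectra:
mean-square pressure is summed within +-2.5 Hz of each wingbeat harmonic
``k*fw``, for harmonics 1..10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .acoustics import PressureTrace

__all__ = [
    "SPL_REFERENCE",
    "Spectrum",
    "HarmonicTable",
    "spl_spectrum",
    "harmonic_bands",
    "power_concentration",
    "summed_array_spectrum",
    "spl_from_ms",
    "ms_from_spl",
]

#: Standard airborne reference pressure, Pa.
SPL_REFERENCE = 20e-6

#: Half-width of the band around each wingbeat harmonic, Hz.
HARMONIC_BAND_HALF_WIDTH = 2.5

#: Numerical floor used for log arguments on silent bins.
_MS_FLOOR = 1e-300


def spl_from_ms(ms_pressure, reference: float = SPL_REFERENCE) -> np.ndarray:
    """Mean-square pressure (Pa^2) to SPL (dB re ``reference``)."""
    ms = np.maximum(np.asarray(ms_pressure, dtype=float), _MS_FLOOR)
    return 10.0 * np.log10(ms / reference**2)


def ms_from_spl(spl, reference: float = SPL_REFERENCE) -> np.ndarray:
    """SPL (dB) back to mean-square pressure (Pa^2); inverse of spl_from_ms."""
    return reference**2 * 10.0 ** (np.asarray(spl, dtype=float) / 10.0)


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum of a pressure trace.

    ``ms_pressure[k]`` is the mean-square pressure (Pa^2) carried by bin
    ``k``; with the rectangular window their sum equals the time-domain
    mean square exactly (Parseval).
    """

    frequencies: np.ndarray     # (n,) Hz
    ms_pressure: np.ndarray     # (n,) Pa^2 per bin
    reference: float = SPL_REFERENCE
    total_ms: float | None = None   # time-domain mean square of the source trace

    @property
    def spl(self) -> np.ndarray:
        return spl_from_ms(self.ms_pressure, self.reference)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_ms(self, f_lo: float, f_hi: float) -> float:
        """Summed mean-square pressure over bins with f_lo <= f <= f_hi."""
        sel = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return float(self.ms_pressure[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "ms_pressure_pa2": self.ms_pressure,
                "spl_db": self.spl,
            }
        )


@dataclass(frozen=True)
class HarmonicTable:
    """Per-harmonic band levels around integer multiples of ``fw``."""

    harmonic: np.ndarray        # 1..n
    frequency: np.ndarray       # k * fw, Hz
    band_ms: np.ndarray         # Pa^2
    reference: float = SPL_REFERENCE
    total_ms: float | None = None

    @property
    def band_spl(self) -> np.ndarray:
        return spl_from_ms(self.band_ms, self.reference)

    @property
    def relative_spl(self) -> np.ndarray:
        """Band SPL minus the strongest band's SPL (reference-free)."""
        return self.band_spl - self.band_spl.max()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "harmonic": self.harmonic,
                "frequency_hz": self.frequency,
                "band_ms_pa2": self.band_ms,
                "band_spl_db": self.band_spl,
                "relative_spl_db": self.relative_spl,
            }
        )


def _as_pressure(trace) -> tuple[np.ndarray, float]:
    if isinstance(trace, PressureTrace):
        return trace.pressure, trace.sample_rate
    raise TypeError("expected a PressureTrace; use Spectrum directly for raw arrays")


def spl_spectrum(
    trace: PressureTrace,
    window: str = "rectangular",
    nperseg: int | None = None,
    reference: float = SPL_REFERENCE,
) -> Spectrum:
    """One-sided SPL spectrum of a pressure trace.

    ``window='rectangular'`` (default) transforms the full trace, exact for
    periodic simulations spanning integer wingbeats; any other window name
    is passed to Welch's method (``nperseg`` defaults to half the trace)
    for measured, noisy data.
    """
    p, fs = _as_pressure(trace)
    if trace.n_periods < 2:
        raise ValueError("trace too short for spectral analysis (need >= 2 wingbeats)")
    # Total acoustic power excludes the steady (DC) pressure offset that the
    # mean aerodynamic force induces in the nearfield: it does not radiate.
    total_ms = float(np.mean((p - p.mean()) ** 2))
    if window == "rectangular":
        n = p.size
        X = np.fft.rfft(p)
        ms = (np.abs(X) / n) ** 2
        ms[1:] *= 2.0
        if n % 2 == 0:
            ms[-1] /= 2.0
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        return Spectrum(freqs, ms, reference, total_ms)
    if nperseg is None:
        nperseg = p.size // 2
    freqs, psd = _signal.welch(p, fs=fs, window=window, nperseg=nperseg)
    ms = psd * (freqs[1] - freqs[0])
    return Spectrum(freqs, ms, reference, total_ms)


def harmonic_bands(
    spectrum: Spectrum,
    flap_frequency: float,
    n_harmonics: int = 10,
    half_width: float = HARMONIC_BAND_HALF_WIDTH,
) -> HarmonicTable:
    """Band mean-square pressure within +-``half_width`` of each harmonic.

    Requires the spectral resolution to be at least as fine as the band
    half-width and non-overlapping bands (``fw > 2*half_width``).
    """
    if flap_frequency <= 2 * half_width:
        raise ValueError(
            f"harmonic bands overlap: fw = {flap_frequency} Hz <= {2 * half_width} Hz"
        )
    if spectrum.df > half_width:
        raise ValueError(
            f"spectral resolution {spectrum.df:.3f} Hz coarser than the "
            f"{half_width} Hz band half-width; analyze a longer trace"
        )
    k = np.arange(1, n_harmonics + 1)
    centers = k * flap_frequency
    band_ms = np.array(
        [spectrum.band_ms(c - half_width, c + half_width) for c in centers]
    )
    return HarmonicTable(k, centers, band_ms, spectrum.reference, spectrum.total_ms)


def power_concentration(harmonics: HarmonicTable, k: int) -> float:
    """Fraction of total trace power captured by harmonic bands 1..k.

    The denominator is the time-domain mean-square pressure of the trace
    the spectrum came from (total power); the numerator sums the +-2.5 Hz
    band powers of the first ``k`` harmonics.
    """
    if not 1 <= k <= harmonics.harmonic.size:
        raise ValueError(f"k must be in 1..{harmonics.harmonic.size}")
    if harmonics.total_ms is None or harmonics.total_ms <= 0:
        raise ValueError("zero or unknown total trace power")
    return float(harmonics.band_ms[:k].sum() / harmonics.total_ms)


def summed_array_spectrum(
    traces: list[PressureTrace],
    window: str = "rectangular",
    coherent: bool = True,
    reference: float = SPL_REFERENCE,
) -> Spectrum:
    """Spectrum of an array of microphones.

    ``coherent=True`` (default) sums the pressure signals sample-wise
    before the transform (requires identical time grids); ``coherent=False``
    averages the per-microphone power spectra instead.
    """
    if not traces:
        raise ValueError("no traces given")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.times.shape != t0.times.shape or not np.allclose(
            tr.times, t0.times, rtol=0, atol=1e-12 * max(1.0, abs(t0.times[-1]))
        ):
            raise ValueError("traces have mismatched time grids")
    if coherent:
        summed = PressureTrace(
            observer=t0.observer,
            times=t0.times,
            pressure=np.sum([tr.pressure for tr in traces], axis=0),
            channels={},
            flap_frequency=t0.flap_frequency,
            samples_per_period=t0.samples_per_period,
        )
        return spl_spectrum(summed, window=window, reference=reference)
    spectra = [spl_spectrum(tr, window=window, reference=reference) for tr in traces]
    ms = np.mean([s.ms_pressure for s in spectra], axis=0)
    total = float(np.mean([s.total_ms for s in spectra]))
    return Spectrum(spectra[0].frequencies, ms, reference, total)
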