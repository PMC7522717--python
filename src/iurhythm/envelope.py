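"""Wideband speech-envelope extraction.

The envelope is built the standard way for speech-tracking work: the audio
is band-pass filtered into ``n_bands`` channels whose cut-offs are equally
spaced on the human cochlear map (Greenwood position–frequency function),
the magnitude of the analytic signal gives each narrowband envelope, the
narrowband envelopes are averaged into the wideband envelope, which is then
anti-alias low-pass filtered, resampled to a low envelope rate (default
100 Hz) and optionally scaled to a 0–1 range.

All filtering is zero-phase (forward-backward Butterworth), so envelope
timing carries no filter phase distortion into the downstream phase
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeSignal",
    "FilterbankSpec",
    "greenwood_position",
    "greenwood_frequency",
    "cochlear_band_edges",
    "compute_envelope",
]

# Greenwood human position-frequency map, f(x) = A (10**(a x) - 1) with x
# the fractional distance from apex (0..1): A = 165.4 Hz, a = 2.1.
_GREENWOOD_A_HZ = 165.4
_GREENWOOD_SLOPE = 2.1


@dataclass(frozen=True)
class EnvelopeSignal:
    """Nonnegative amplitude envelope at a reduced sample rate."""

    values: np.ndarray
    sample_rate_hz: float
    recording_id: str = ""
    normalization: str = "unit_max"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("envelope must be one-dimensional")
        if np.any(values < 0):
            raise ValueError("envelope values must be nonnegative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.normalization not in ("unit_max", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "values", values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate_hz


@dataclass(frozen=True)
class FilterbankSpec:
    """Band edges of a cochlear-spaced filterbank."""

    n_bands: int
    f_lo_hz: float
    f_hi_hz: float
    edges_hz: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_hz, dtype=float)
        if len(edges) != self.n_bands + 1:
            raise ValueError("need n_bands + 1 edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges_hz", edges)


def greenwood_position(f_hz):
    """Fractional cochlear position (0 apex .. 1 base) of frequency ``f_hz``."""
    return np.log10(np.asarray(f_hz, dtype=float) / _GREENWOOD_A_HZ + 1.0) / _GREENWOOD_SLOPE


def greenwood_frequency(x):
    """Inverse map: characteristic frequency at fractional position ``x``."""
    return _GREENWOOD_A_HZ * (10.0 ** (_GREENWOOD_SLOPE * np.asarray(x, dtype=float)) - 1.0)


def cochlear_band_edges(n_bands: int, f_lo_hz: float = 100.0,
                        f_hi_hz: float = 8000.0) -> FilterbankSpec:
    """Band edges equidistant on the Greenwood human cochlear map.

    Positions between ``x(f_lo)`` and ``x(f_hi)`` are divided into
    ``n_bands`` equal steps and mapped back to frequency.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not 0 < f_lo_hz < f_hi_hz:
        raise ValueError("need 0 < f_lo_hz < f_hi_hz")
    x = np.linspace(greenwood_position(f_lo_hz), greenwood_position(f_hi_hz),
                    n_bands + 1)
    edges = greenwood_frequency(x)
    edges[0], edges[-1] = f_lo_hz, f_hi_hz  # exact endpoints
    return FilterbankSpec(n_bands, f_lo_hz, f_hi_hz, edges)


def compute_envelope(
    w: Waveform,
    spec: FilterbankSpec | None = None,
    env_rate_hz: float = 100.0,
    normalization: str = "unit_max",
    band_order: int = 4,
    antialias_order: int = 8,
) -> EnvelopeSignal:
    """Compute the wideband envelope of a waveform.

    Per band: zero-phase Butterworth band-pass (order ``band_order``),
    then the magnitude of the analytic (Hilbert) signal.  Narrowband
    envelopes are averaged, low-pass filtered at ``0.4 * env_rate_hz``
    (zero-phase Butterworth, order ``antialias_order``) and resampled to
    ``env_rate_hz`` by linear interpolation on the filtered signal.
    """
    if len(w.samples) == 0:
        raise ValueError("waveform is empty")
    if env_rate_hz > w.sample_rate_hz:
        raise ValueError("env_rate_hz must not exceed the audio rate")
    if spec is None:
        spec = cochlear_band_edges(10, 100.0, min(8000.0, 0.99 * w.sample_rate_hz / 2))
    nyq = w.sample_rate_hz / 2
    if spec.f_hi_hz > nyq:
        raise ValueError(
            f"filterbank upper edge {spec.f_hi_hz} Hz exceeds Nyquist {nyq} Hz"
        )

    acc = np.zeros(len(w.samples))
    for lo, hi in zip(spec.edges_hz[:-1], spec.edges_hz[1:]):
        sos = signal.butter(band_order, [lo, hi], btype="bandpass",
                            fs=w.sample_rate_hz, output="sos")
        band = signal.sosfiltfilt(sos, w.samples)
        acc += np.abs(signal.hilbert(band))
    wideband = acc / spec.n_bands

    cutoff = 0.4 * env_rate_hz
    if cutoff < nyq:
        sos = signal.butter(antialias_order, cutoff, btype="lowpass",
                            fs=w.sample_rate_hz, output="sos")
        wideband = signal.sosfiltfilt(sos, wideband)
    wideband = np.maximum(wideband, 0.0)  # filtering can leave tiny negatives

    n_out = int(round(w.duration_s * env_rate_hz))
    t_out = np.arange(n_out) / env_rate_hz
    t_in = np.arange(len(wideband)) / w.sample_rate_hz
    values = np.interp(t_out, t_in, wideband)

    if normalization == "unit_max":
        peak = values.max(initial=0.0)
        if peak > 0:
            values = values / peak
        else:
            logger.warning("silent input: unit_max normalization skipped")
    return EnvelopeSignal(values, env_rate_hz, recording_id=w.recording_id,
                          normalization=normalization)
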