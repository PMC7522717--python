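"""Point–field phase consistency of IU onsets with the speech envelope.

Envelope windows centered on each intonation-unit onset are demeaned,
Hann-tapered and Fourier transformed; the phase angle at every positive
frequency bin is compared across events with the pairwise phase
consistency (PPC) estimator — the mean cosine of the phase difference
over all distinct event pairs.  PPC estimates squared phase-locking
strength without bias from the number of events, which is what makes
per-speaker spectra with very different IU counts comparable.

Spectra are computed per speaker (speakers contributing more than five
retained onsets) and averaged with equal speaker weights; uncertainty of
the group mean comes from a percentile bootstrap over speakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows as _windows

from .envelope import EnvelopeSignal
from .io import IUAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ConsistencySpectrum",
    "GroupSpectrum",
    "MIN_EVENTS",
    "extract_windows",
    "window_phases",
    "window_phasors",
    "ppc",
    "ppc_from_phasors",
    "speaker_spectrum",
    "speaker_spectra",
    "group_spectrum",
]

#: speakers must produce strictly more than this many retained IU onsets
MIN_EVENTS = 5

# amplitude below which a bin's phase is treated as undefined
_AMP_EPS = 1e-12


@dataclass(frozen=True)
class ConsistencySpectrum:
    """Per-speaker PPC value per frequency bin."""

    frequencies_hz: np.ndarray
    ppc: np.ndarray
    n_events: int
    speaker_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        v = np.asarray(self.ppc, dtype=float)
        if f.shape != v.shape:
            raise ValueError("frequency and ppc arrays differ in length")
        with np.errstate(invalid="ignore"):
            if np.any(np.abs(v[np.isfinite(v)]) > 1 + 1e-9):
                raise ValueError("PPC values must lie in [-1, 1]")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "ppc", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_hz": self.frequencies_hz,
                             "ppc": self.ppc})


@dataclass(frozen=True)
class GroupSpectrum:
    """Speaker-averaged PPC spectrum with bootstrap confidence band."""

    frequencies_hz: np.ndarray
    mean_ppc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_speakers: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies_hz,
                "ppc": self.mean_ppc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def extract_windows(
    env: EnvelopeSignal,
    onsets: np.ndarray,
    window_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut equal-length envelope windows centered on each onset.

    Each window spans ``[onset - window_s/2, onset + window_s/2)``;
    onsets whose window would cross the recording bounds are dropped.

    Returns
    -------
    windows : (n_kept, n_samples) array
    kept : boolean mask over ``onsets`` marking retained events
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    fs = env.sample_rate_hz
    n = int(round(window_s * fs))
    starts = np.round((onsets - window_s / 2) * fs).astype(int)
    kept = (starts >= 0) & (starts + n <= len(env.values))
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("dropped %d/%d onsets with out-of-bounds windows",
                    n_dropped, len(onsets))
    if not kept.any():
        raise ValueError("no onset window fits inside the recording")
    idx = starts[kept, None] + np.arange(n)[None, :]
    return env.values[idx], kept


def _positive_freqs(n: int, window_s: float) -> np.ndarray:
    # bins k / window_s for k = 1 .. Nyquist-1 (DC and Nyquist excluded)
    n_pos = (n - 1) // 2 if n % 2 else n // 2 - 1
    return np.arange(1, n_pos + 1) / window_s


def window_phasors(windows: np.ndarray, window_s: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unit phasors per event and positive-frequency bin.

    Pipeline per window: subtract the window mean, apply one full-length
    symmetric Hann taper, DFT without zero padding, keep bins
    ``k/window_s`` for k = 1..Nyquist-1.  Bins where the tapered window
    has (numerically) zero amplitude get NaN — the event carries no
    defined phase there.

    Returns ``(frequencies_hz, phasors)`` with ``phasors`` complex of
    shape (n_events, n_bins), unit modulus or NaN.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    n = windows.shape[1]
    taper = _windows.hann(n, sym=True)
    demeaned = windows - windows.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(demeaned * taper, axis=1)
    freqs = _positive_freqs(n, window_s)
    spec = spec[:, 1:1 + len(freqs)]
    amp = np.abs(spec)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(amp > _AMP_EPS, spec / amp, np.nan + 0j)
    n_bad = int(np.isnan(phasors.real).sum())
    if n_bad:
        logger.warning("%d event-bin phases undefined (zero amplitude); "
                       "dropped from those bins", n_bad)
    return freqs, phasors


def window_phases(windows: np.ndarray, window_s: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Phase angle in (-pi, pi] per event and positive-frequency bin.

    NaN marks bins where the demeaned, tapered window has zero amplitude.
    """
    freqs, phasors = window_phasors(windows, window_s)
    with np.errstate(invalid="ignore"):
        phases = np.angle(phasors)
        phases = np.where(np.isnan(phasors.real), np.nan, phases)
    return freqs, phases


def ppc(angles: np.ndarray) -> float:
    """Pairwise phase consistency of a set of phase angles.

    The mean over all distinct pairs (j, k) of cos(theta_j - theta_k),
    computed via the O(N) identity
    ``((sum cos)^2 + (sum sin)^2 - N) / (N (N - 1))``.  NaN angles
    (undefined phases) are ignored.  Requires at least two valid angles.
    """
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    n = len(angles)
    if n < 2:
        raise ValueError("PPC needs at least 2 phase angles")
    c = np.cos(angles).sum()
    s = np.sin(angles).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


def ppc_from_phasors(phasors: np.ndarray) -> np.ndarray:
    """Per-bin PPC from an (n_events, n_bins) unit-phasor matrix.

    NaN entries are excluded per bin; bins with fewer than two valid
    events yield NaN.
    """
    valid = np.isfinite(phasors.real)
    z = np.where(valid, phasors, 0.0)
    resultant = z.sum(axis=0)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (np.abs(resultant) ** 2 - n) / (n * (n - 1))
    out[n < 2] = np.nan
    return out


def speaker_spectrum(
    env: EnvelopeSignal,
    ann: IUAnnotation,
    speaker: str,
    window_s: float = 2.0,
    max_freq_hz: float = 10.0,
) -> ConsistencySpectrum:
    """PPC spectrum of one speaker's IU onsets against the envelope.

    Raises ``ValueError`` if the speaker has five or fewer retained
    onsets (too few events for a stable pairwise estimate).
    """
    onsets = ann.onsets(speaker)
    if len(onsets) == 0:
        raise ValueError(f"speaker {speaker!r} has no IUs")
    wins, kept = extract_windows(env, onsets, window_s)
    n_events = int(kept.sum())
    if n_events <= MIN_EVENTS:
        raise ValueError(
            f"speaker {speaker!r} has {n_events} retained onsets; "
            f"more than {MIN_EVENTS} required"
        )
    freqs, phasors = window_phasors(wins, window_s)
    sel = freqs <= max_freq_hz + 1e-9
    values = ppc_from_phasors(phasors[:, sel])
    return ConsistencySpectrum(freqs[sel], values, n_events,
                               speaker_id=speaker)


def speaker_spectra(env: EnvelopeSignal, ann: IUAnnotation,
                    window_s: float = 2.0, max_freq_hz: float = 10.0
                    ) -> list[ConsistencySpectrum]:
    """Spectra for every eligible speaker; ineligible speakers are logged."""
    out = []
    for speaker in ann.speakers:
        try:
            out.append(speaker_spectrum(env, ann, speaker, window_s,
                                        max_freq_hz))
        except ValueError as exc:
            logger.info("excluding speaker %r: %s", speaker, exc)
    return out


def group_spectrum(
    spectra: list[ConsistencySpectrum],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> GroupSpectrum:
    """Equal-weight speaker average with a percentile bootstrap CI.

    Speakers are resampled with replacement ``n_boot`` times; the CI is
    the 2.5/97.5 percentile band of the resampled means (for the default
    95% level).
    """
    if not spectra:
        raise ValueError("no speaker spectra to average")
    grid = spectra[0].frequencies_hz
    for s in spectra[1:]:
        if s.frequencies_hz.shape != grid.shape or not np.allclose(
                s.frequencies_hz, grid):
            raise ValueError(
                f"frequency grid of speaker {s.speaker_id!r} does not match "
                f"speaker {spectra[0].speaker_id!r}"
            )
    mat = np.vstack([s.ppc for s in spectra])
    mean = np.nanmean(mat, axis=0)
    rng = np.random.default_rng(seed)
    n_spk = len(spectra)
    idx = rng.integers(0, n_spk, size=(n_boot, n_spk))
    boot_means = np.nanmean(mat[idx], axis=1)
    alpha = (1.0 - ci_level) / 2
    ci_low = np.nanpercentile(boot_means, 100 * alpha, axis=0)
    ci_high = np.nanpercentile(boot_means, 100 * (1 - alpha), axis=0)
    return GroupSpectrum(grid, mean, ci_low, ci_high, n_spk)
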