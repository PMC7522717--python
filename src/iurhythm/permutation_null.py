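"""Trough-constrained permutation null for the group consistency spectrum.

An IU onset is necessarily a syllable boundary, and syllable boundaries
sit at troughs of the envelope, so a fair null hypothesis keeps that
association: surrogate onset sets are drawn uniformly (without
replacement) from the detected envelope troughs, preserving each
speaker's onset count and recording.  The full per-speaker-spectrum →
group-mean pipeline is re-run for every surrogate, per-bin p-values are
exceedance proportions with the +1 correction, and significance across
frequency bins is controlled with the Benjamini–Hochberg step-up rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.stats.multitest import multipletests

from .envelope import EnvelopeSignal
from .io import IUAnnotation
from .phase_consistency import (
    MIN_EVENTS,
    extract_windows,
    ppc_from_phasors,
    window_phasors,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TroughSet",
    "PermutationResult",
    "detect_troughs",
    "surrogate_onsets",
    "permutation_test",
    "bh_fdr",
]


@dataclass(frozen=True)
class TroughSet:
    """Detected envelope troughs (local minima) of one recording."""

    times_s: np.ndarray
    recording_id: str = ""
    min_magnitude: float = 0.01
    min_separation_s: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if len(t) > 1 and np.any(np.diff(t) < self.min_separation_s - 1e-9):
            raise ValueError("trough times violate the minimum separation")
        object.__setattr__(self, "times_s", t)

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class PermutationResult:
    """Observed group spectrum with its surrogate null and FDR mask."""

    frequencies_hz: np.ndarray
    observed_mean_ppc: np.ndarray
    surrogate_means: np.ndarray  # (n_perm, n_bins)
    p_value: np.ndarray
    significant: np.ndarray
    fdr_threshold: float
    n_perm: int
    seed: int | None
    n_speakers: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies_hz,
                "ppc": self.observed_mean_ppc,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )


def detect_troughs(
    env: EnvelopeSignal,
    min_magnitude: float = 0.01,
    min_separation_s: float = 0.2,
) -> TroughSet:
    """Local envelope minima with prominence and separation constraints.

    A trough must have prominence (depth relative to the surrounding
    envelope) of at least ``min_magnitude`` on the 0–1 envelope scale;
    troughs closer together than ``min_separation_s`` are thinned
    deepest-first so every retained pair is at least that far apart.
    """
    if env.normalization != "unit_max":
        logger.warning("trough magnitude threshold assumes a 0-1 envelope; "
                       "normalization is %r", env.normalization)
    distance = max(1, int(round(min_separation_s * env.sample_rate_hz)))
    idx, _ = find_peaks(-env.values, prominence=min_magnitude,
                        distance=distance)
    return TroughSet(idx / env.sample_rate_hz, env.recording_id,
                     min_magnitude, min_separation_s)


def surrogate_onsets(
    troughs: TroughSet,
    n_onsets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_onsets`` trough times uniformly without replacement, sorted."""
    if n_onsets > len(troughs):
        raise ValueError(
            f"need {n_onsets} onsets but only {len(troughs)} troughs "
            f"available (short by {n_onsets - len(troughs)})"
        )
    pick = rng.choice(len(troughs), size=n_onsets, replace=False)
    return np.sort(troughs.times_s[pick])


def bh_fdr(p_values: Sequence[float], q: float = 0.01) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _as_env_map(envs) -> Mapping[str, EnvelopeSignal]:
    if isinstance(envs, EnvelopeSignal):
        return {envs.recording_id: envs}
    return dict(envs)


def _as_ann_list(anns) -> list[IUAnnotation]:
    if isinstance(anns, IUAnnotation):
        return [anns]
    return list(anns)


def permutation_test(
    envs: EnvelopeSignal | Mapping[str, EnvelopeSignal],
    anns: IUAnnotation | Iterable[IUAnnotation],
    window_s: float = 2.0,
    n_perm: int = 1000,
    fdr_q: float = 0.01,
    seed: int | None = None,
    max_freq_hz: float = 10.0,
    min_magnitude: float = 0.01,
    min_separation_s: float = 0.2,
) -> PermutationResult:
    """Permutation test of the group PPC spectrum against a trough null.

    For every one of ``n_perm`` surrogates, each speaker's onsets are
    replaced by a uniform draw (without replacement, same count) from
    the troughs of that speaker's own recording and the group spectrum
    recomputed; the per-bin p-value is ``(r + 1) / (n_perm + 1)`` where
    ``r`` counts surrogate group means at or above the observed one.
    Speakers whose recording lacks enough usable troughs are excluded
    from both the observed and the surrogate spectra, so the comparison
    always uses identical data.
    """
    env_map = _as_env_map(envs)
    ann_list = _as_ann_list(anns)

    # troughs + phase phasors at every usable trough, once per recording
    trough_phasors: dict[str, np.ndarray] = {}
    freqs = None
    for rec_id, env in env_map.items():
        troughs = detect_troughs(env, min_magnitude, min_separation_s)
        if len(troughs) == 0:
            logger.warning("recording %r has no troughs", rec_id)
            trough_phasors[rec_id] = np.empty((0, 0), dtype=complex)
            continue
        wins, kept = extract_windows(env, troughs.times_s, window_s)
        f, phasors = window_phasors(wins, window_s)
        sel = f <= max_freq_hz + 1e-9
        trough_phasors[rec_id] = phasors[:, sel]
        freqs = f[sel]
    if freqs is None:
        raise ValueError("no recording yielded any troughs")

    # observed per-speaker phasors, applying the same eligibility rules
    # to the observed and the surrogate analyses
    speakers: list[tuple[str, np.ndarray, int]] = []  # (rec_id, phasors, n)
    for ann in ann_list:
        rec_id = ann.recording_id
        if rec_id not in env_map:
            raise KeyError(f"no envelope for recording {rec_id!r}")
        env = env_map[rec_id]
        for speaker in ann.speakers:
            onsets = ann.onsets(speaker)
            try:
                wins, kept = extract_windows(env, onsets, window_s)
            except ValueError:
                logger.info("excluding speaker %r: no retained windows",
                            speaker)
                continue
            n_events = int(kept.sum())
            if n_events <= MIN_EVENTS:
                logger.info("excluding speaker %r: %d retained onsets",
                            speaker, n_events)
                continue
            if n_events > len(trough_phasors[rec_id]):
                logger.info(
                    "excluding speaker %r: %d onsets exceed %d usable "
                    "troughs in recording %r", speaker, n_events,
                    len(trough_phasors[rec_id]), rec_id)
                continue
            f, phasors = window_phasors(wins, window_s)
            speakers.append((rec_id, phasors[:, f <= max_freq_hz + 1e-9],
                             n_events))
    if not speakers:
        raise ValueError("no eligible speaker for the observed spectrum")

    observed = np.nanmean(
        np.vstack([ppc_from_phasors(ph) for _, ph, _ in speakers]), axis=0)

    rng = np.random.default_rng(seed)
    surrogate = np.empty((n_perm, len(freqs)))
    for b in range(n_perm):
        spectra = np.empty((len(speakers), len(freqs)))
        for i, (rec_id, _, n_events) in enumerate(speakers):
            pool = trough_phasors[rec_id]
            pick = rng.choice(len(pool), size=n_events, replace=False)
            spectra[i] = ppc_from_phasors(pool[pick])
        surrogate[b] = np.nanmean(spectra, axis=0)

    r = (surrogate >= observed[None, :]).sum(axis=0)
    p = (r + 1) / (n_perm + 1)
    significant = bh_fdr(p, fdr_q)
    return PermutationResult(freqs, observed, surrogate, p, significant,
                             fdr_q, n_perm, seed, n_speakers=len(speakers))
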