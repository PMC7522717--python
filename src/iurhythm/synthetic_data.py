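"""Synthetic speech-envelope data with ground-truth IU annotations.

The generator emulates the statistical structure of conversational
speech that the analysis relies on, without any phonetic content:

* syllables are raised-cosine amplitude bursts delivered at roughly the
  canonical syllable rate (~5 Hz), so the envelope carries strong 2-7 Hz
  modulation and a trough at every syllable boundary;
* syllables group into intonation units (IUs) of a few syllables whose
  onset-to-onset interval targets ``iu_period_s`` (~1 s) with lognormal
  jitter, the headline delta-band rhythm;
* each IU starts with a full-amplitude burst (IU-initial reset), its
  last syllable is lengthened (IU-final lengthening) and burst peaks
  decay toward the IU end;
* IUs are separated by exponentially distributed pauses (most below
  1 s), and IUs are grouped into turns taken by several speakers.

Everything is driven by one ``numpy`` Generator, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .envelope import EnvelopeSignal
from .io import IUAnnotation, IURecord, Waveform
from .permutation_null import detect_troughs

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "generate_envelope", "generate_audio",
           "null_annotation"]

# raised-cosine support is this multiple of the syllable duration; < 2
# leaves a trough between neighbouring syllable bursts
_PULSE_WIDTH_FACTOR = 1.2
# minimal silent gap enforced between an IU offset and the next onset
_MIN_GAP_S = 0.02


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic conversation generator.

    ``iu_period_s`` is the target mean IU onset-to-onset interval before
    pauses; ``final_lengthening`` multiplies the duration of each IU's
    last syllable; ``amplitude_decay`` is the last/first syllable peak
    ratio within an IU.
    """

    duration_s: float = 300.0
    n_speakers: int = 4
    syllable_rate_hz: float = 5.0
    syllables_per_iu: tuple[int, int] = (3, 7)  # inclusive uniform range
    iu_period_s: float = 1.0
    period_jitter_cv: float = 0.1
    final_lengthening: float = 1.5
    amplitude_decay: float = 0.7
    pause_mean_s: float = 0.2
    pause_max_s: float = 2.0
    noise_floor: float = 0.005
    env_rate_hz: float = 100.0
    mean_ius_per_turn: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 2.0 <= self.syllable_rate_hz <= 7.0:
            raise ValueError("syllable_rate_hz must lie in [2, 7]")
        if self.n_speakers < 0:
            raise ValueError("n_speakers must be nonnegative")
        lo, hi = self.syllables_per_iu
        if not 1 <= lo <= hi:
            raise ValueError("invalid syllables_per_iu range")
        if self.iu_period_s < lo / self.syllable_rate_hz:
            # reconcile: the shortest possible IU must fit in one period
            fixed = lo / self.syllable_rate_hz
            logger.warning("iu_period_s %.3g shorter than the minimum IU "
                           "(%.3g s); extending", self.iu_period_s, fixed)
            object.__setattr__(self, "iu_period_s", fixed)
        for name in ("duration_s", "final_lengthening", "env_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.amplitude_decay <= 1:
            raise ValueError("amplitude_decay must lie in (0, 1]")


def _syllable_plan(cfg: SynthConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Durations and peak amplitudes of one IU's syllables."""
    lo, hi = cfg.syllables_per_iu
    n = int(rng.integers(lo, hi + 1))
    base = 1.0 / cfg.syllable_rate_hz
    durs = np.full(n, base)
    durs[-1] *= cfg.final_lengthening
    if n >= 2:
        # ease into the lengthened final syllable
        durs[-2] *= (1.0 + cfg.final_lengthening) / 2.0
    if n == 1:
        amps = np.array([1.0])
    else:
        amps = cfg.amplitude_decay ** (np.arange(n) / (n - 1))
    return durs, amps


def _pause(cfg: SynthConfig, rng: np.random.Generator) -> float:
    if cfg.pause_mean_s <= 0:
        return 0.0
    return float(min(rng.exponential(cfg.pause_mean_s), cfg.pause_max_s))


def generate_envelope(cfg: SynthConfig,
                      seed: int | np.random.Generator | None = None,
                      recording_id: str = "synthetic",
                      ) -> tuple[EnvelopeSignal, IUAnnotation]:
    """Simulate one multi-speaker recording's envelope and annotation.

    IUs are laid down sequentially; onset-to-onset intervals are
    ``iu_period_s`` times a unit-mean lognormal (coefficient of
    variation ``period_jitter_cv``) plus an exponential pause, extended
    whenever the IU itself is longer (counted and logged).  Speakers
    take turns of geometrically many IUs.  The returned envelope is
    unit-max normalized; the annotation holds the true onsets, offsets
    and speaker labels.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    fs = cfg.env_rate_hz
    n_samples = int(round(cfg.duration_s * fs))
    values = np.zeros(n_samples)

    records: list[IURecord] = []
    if cfg.n_speakers > 0:
        cv = cfg.period_jitter_cv
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = -0.5 * sigma * sigma  # unit-mean lognormal
        speaker = int(rng.integers(cfg.n_speakers))
        turn_left = _turn_length(cfg, rng)
        n_extended = 0
        onset = 0.25 + _pause(cfg, rng)
        while True:
            durs, amps = _syllable_plan(cfg, rng)
            half = _PULSE_WIDTH_FACTOR / 2.0
            centers = np.empty(len(durs))
            centers[0] = onset + half * durs[0]
            for j in range(1, len(durs)):
                centers[j] = centers[j - 1] + (durs[j - 1] + durs[j]) / 2.0
            iu_dur = centers[-1] + half * durs[-1] - onset
            offset = onset + iu_dur
            if offset > cfg.duration_s:
                break
            for c, d, a in zip(centers, durs, amps):
                _add_pulse(values, fs, c, half * d, a)
            records.append(IURecord(onset, offset, f"S{speaker}"))

            turn_left -= 1
            if turn_left == 0 and cfg.n_speakers > 1:
                speaker = int((speaker + 1 + rng.integers(cfg.n_speakers - 1))
                              % cfg.n_speakers)
                turn_left = _turn_length(cfg, rng)
            elif turn_left == 0:
                turn_left = _turn_length(cfg, rng)

            if cv > 0:
                interval = cfg.iu_period_s * rng.lognormal(mu, sigma)
            else:
                interval = cfg.iu_period_s
            interval += _pause(cfg, rng)
            if interval < iu_dur + _MIN_GAP_S:
                interval = iu_dur + _MIN_GAP_S
                n_extended += 1
            onset = onset + interval
        if n_extended:
            logger.warning("extended %d/%d onset intervals to fit IUs longer "
                           "than the period", n_extended, len(records))

    values += rng.uniform(0.0, cfg.noise_floor, size=n_samples)
    peak = values.max(initial=0.0)
    if peak > 0:
        values /= peak
    env = EnvelopeSignal(values, fs, recording_id=recording_id,
                         normalization="unit_max")
    ann = IUAnnotation(tuple(records), recording_id=recording_id)
    return env, ann


def _turn_length(cfg: SynthConfig, rng: np.random.Generator) -> int:
    if cfg.mean_ius_per_turn <= 1:
        return 1
    return int(rng.geometric(1.0 / cfg.mean_ius_per_turn))


def _add_pulse(values: np.ndarray, fs: float, center: float,
               half_width: float, amp: float) -> None:
    """Add one raised-cosine burst in place."""
    i0 = max(0, int(np.ceil((center - half_width) * fs)))
    i1 = min(len(values), int(np.floor((center + half_width) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    values[i0:i1] += amp * 0.5 * (1.0 + np.cos(np.pi * (t - center)
                                               / half_width))


def generate_audio(cfg: SynthConfig,
                   seed: int | np.random.Generator | None = None,
                   audio_rate_hz: float = 16000.0,
                   recording_id: str = "synthetic",
                   ) -> tuple[Waveform, IUAnnotation]:
    """Render the designed envelope as amplitude-modulated speech-band noise.

    The carrier is white noise band-passed to 100-4000 Hz, multiplied by
    the envelope from :func:`generate_envelope` (same annotation), so
    the standard envelope-extraction pipeline recovers the designed
    envelope.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    env, ann = generate_envelope(cfg, seed=rng, recording_id=recording_id)
    n = int(round(cfg.duration_s * audio_rate_hz))
    if cfg.n_speakers == 0:
        return Waveform(np.zeros(n), audio_rate_hz, recording_id), ann
    carrier = rng.standard_normal(n)
    sos = signal.butter(4, [100.0, 4000.0], btype="bandpass",
                        fs=audio_rate_hz, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier /= np.max(np.abs(carrier))
    t = np.arange(n) / audio_rate_hz
    gain = np.interp(t, env.times_s, env.values)
    samples = carrier * gain
    samples /= max(np.max(np.abs(samples)), 1e-12)
    return Waveform(samples * 0.9, audio_rate_hz, recording_id), ann


def null_annotation(env: EnvelopeSignal,
                    n_onsets: int | list[int] | np.ndarray,
                    rng: np.random.Generator | int | None = None,
                    iu_duration_s: float = 0.5,
                    min_magnitude: float = 0.01,
                    min_separation_s: float = 0.2,
                    ) -> IUAnnotation:
    """Onsets placed at randomly chosen envelope troughs (complete null).

    ``n_onsets`` may be one count or a per-speaker list; onsets are
    drawn without replacement from the detected troughs, assigned to
    speakers round-robin in time order, and given nominal offsets
    ``onset + iu_duration_s`` (clipped to the recording end).  Used to
    verify type-I error and FDR calibration of the permutation test.
    """
    rng = np.random.default_rng(rng)
    counts = (np.atleast_1d(np.asarray(n_onsets, dtype=int))
              if not np.isscalar(n_onsets) else np.array([int(n_onsets)]))
    total = int(counts.sum())
    troughs = detect_troughs(env, min_magnitude, min_separation_s)
    if total > len(troughs):
        raise ValueError(f"need {total} troughs but found {len(troughs)}")
    pick = rng.choice(len(troughs), size=total, replace=False)
    times = np.sort(troughs.times_s[pick])
    labels = np.repeat([f"S{i}" for i in range(len(counts))], counts)
    rng.shuffle(labels)
    eps = 1.0 / env.sample_rate_hz
    records = tuple(
        IURecord(t, min(t + iu_duration_s, env.duration_s), lab)
        for t, lab in zip(times, labels)
        if t + eps < env.duration_s
    )
    return IUAnnotation(records, recording_id=env.recording_id)
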