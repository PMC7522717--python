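"""IU duration distributions and the inter-IU-interval robustness filter.

Durations are pooled across speakers, summarized as a 50 ms-bin
probability histogram and a median with a percentile-bootstrap 95%
confidence interval.  The robustness filter keeps only IUs that follow
an inter-IU interval (previous offset to current onset, across speakers)
below a threshold — used to check that phase-consistency results are not
driven by long pauses or recording onsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IUAnnotation

logger = logging.getLogger(__name__)

__all__ = ["DurationStats", "iu_durations", "duration_stats",
           "filter_recent_iu"]


@dataclass(frozen=True)
class DurationStats:
    durations_s: np.ndarray
    median_s: float
    ci_low_s: float
    ci_high_s: float
    bin_edges_s: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_s": self.bin_edges_s[:-1],
                "bin_hi_s": self.bin_edges_s[1:],
                "probability": self.probabilities,
            }
        )


def iu_durations(ann: IUAnnotation) -> np.ndarray:
    """Duration (offset - onset) of every IU, in annotation order."""
    return np.array([r.offset_s - r.onset_s for r in ann.records])


def duration_stats(
    durations: np.ndarray,
    n_boot: int = 1000,
    bin_s: float = 0.05,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> DurationStats:
    """Histogram (probability per ``bin_s`` bin), median and bootstrap CI.

    The CI is a percentile bootstrap of the median, resampling pooled
    IUs with replacement ``n_boot`` times.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 2:
        raise ValueError("need at least 2 durations")
    n_bins = int(np.floor(durations.max() / bin_s)) + 1  # last edge > max
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(durations, bins=edges)
    probs = counts / len(durations)
    median = float(np.median(durations))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(durations), size=(n_boot, len(durations)))
    boot_medians = np.median(durations[idx], axis=1)
    alpha = (1.0 - ci_level) / 2
    lo = float(np.percentile(boot_medians, 100 * alpha))
    hi = float(np.percentile(boot_medians, 100 * (1 - alpha)))
    return DurationStats(durations, median, lo, hi, edges, probs)


def filter_recent_iu(
    ann: IUAnnotation,
    max_gap_s: float = 1.0,
    same_speaker_only: bool = False,
) -> tuple[IUAnnotation, float]:
    """Keep IUs that follow an inter-IU interval below ``max_gap_s``.

    The interval is the current onset minus the immediately preceding
    IU's offset in the ORIGINAL sequence (across speakers by default;
    ``same_speaker_only`` restricts the predecessor to the same
    speaker).  The first IU (no predecessor) is always dropped.  Because
    gaps are measured on the original sequence, applying the filter
    twice changes nothing beyond the first pass dropping its new first
    record; treat the returned annotation as final.

    Returns the filtered annotation and the retained fraction.
    """
    records = ann.records
    kept = []
    prev_offset: dict[str | None, float] = {}
    for rec in records:
        key = rec.speaker_id if same_speaker_only else None
        prev = prev_offset.get(key)
        if prev is not None and rec.onset_s - prev < max_gap_s:
            kept.append(rec)
        prev_offset[key] = rec.offset_s
    frac = len(kept) / len(records) if records else 0.0
    logger.info("robustness filter retained %d/%d IUs (%.1f%%)",
                len(kept), len(records), 100 * frac)
    return IUAnnotation(tuple(kept), recording_id=ann.recording_id), frac
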