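"""Reading audio and intonation-unit annotations, writing analysis tables.

Annotations travel as CSV with columns ``onset_s, offset_s, speaker_id``
(times in seconds from recording start); Praat TextGrid interval tiers are
supported read-only, one tier per speaker.  Spectra and test results are
written as comma-delimited text with a ``#``-comment metadata header so the
numeric payload round-trips at full float precision.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "IURecord",
    "IUAnnotation",
    "read_waveform",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "write_spectrum",
    "read_spectrum",
    "load_config",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples with their sample rate.

    Samples are float64 in arbitrary pressure units (PCM files are scaled
    to [-1, 1]).
    """

    samples: np.ndarray
    sample_rate_hz: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class IURecord:
    onset_s: float
    offset_s: float
    speaker_id: str


@dataclass(frozen=True)
class IUAnnotation:
    """Per-recording intonation-unit intervals, sorted by onset."""

    records: tuple[IURecord, ...]
    recording_id: str = ""

    def __post_init__(self) -> None:
        records = tuple(self.records)
        for rec in records:
            if not (0.0 <= rec.onset_s < rec.offset_s):
                raise ValueError(
                    f"invalid interval ({rec.onset_s}, {rec.offset_s}) "
                    f"for speaker {rec.speaker_id!r}: need 0 <= onset < offset"
                )
        if any(
            records[i].onset_s > records[i + 1].onset_s
            for i in range(len(records) - 1)
        ):
            records = tuple(sorted(records, key=lambda r: r.onset_s))
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def speakers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.speaker_id, None)
        return tuple(seen)

    def onsets(self, speaker_id: str | None = None) -> np.ndarray:
        return np.array(
            [r.onset_s for r in self.records
             if speaker_id is None or r.speaker_id == speaker_id]
        )

    def for_speaker(self, speaker_id: str) -> "IUAnnotation":
        return IUAnnotation(
            tuple(r for r in self.records if r.speaker_id == speaker_id),
            recording_id=self.recording_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [r.onset_s for r in self.records],
                "offset_s": [r.offset_s for r in self.records],
                "speaker_id": [r.speaker_id for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# audio

_PCM_SCALE = {np.dtype("int16"): 2.0 ** 15, np.dtype("int32"): 2.0 ** 31,
              np.dtype("uint8"): 2.0 ** 7}


def read_waveform(path: str | Path) -> Waveform:
    """Read a PCM WAV file as a mono :class:`Waveform`.

    Integer PCM is scaled to [-1, 1]; stereo files are averaged to mono
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unsupported WAV encoding in {path}: {exc}") from exc
    if data.dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype("uint8"):
            samples = samples - 1.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise ValueError(
            f"unsupported WAV sample format {data.dtype} in {path}"
        )
    if samples.ndim == 2:
        logger.warning("%s has %d channels; averaging to mono",
                       path.name, samples.shape[1])
        samples = samples.mean(axis=1)
    return Waveform(samples, float(rate), recording_id=path.stem)


def write_wav(w: Waveform, path: str | Path) -> None:
    """Write a waveform as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    samples = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(samples * (2 ** 15 - 1)).astype(np.int16)
    wavfile.write(Path(path), int(round(w.sample_rate_hz)), pcm)


# ---------------------------------------------------------------------------
# annotations

def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    recording_id: str | None = None,
) -> IUAnnotation:
    """Read IU intervals from CSV or a Praat TextGrid.

    CSV must carry columns ``onset_s, offset_s, speaker_id``.  TextGrid
    interval tiers are mapped one tier per speaker; empty-text intervals
    are discarded.  Records are returned sorted by onset; any record with
    onset >= offset is rejected with an error naming the offending row.
    """
    path = Path(path)
    if recording_id is None:
        recording_id = path.stem
    if dialect == "csv":
        records = _read_annotation_csv(path)
    elif dialect == "textgrid":
        records = _read_textgrid(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if any(records[i].onset_s > records[i + 1].onset_s
           for i in range(len(records) - 1)):
        logger.warning("%s: records were not sorted by onset; sorting",
                       path.name)
    return IUAnnotation(tuple(records), recording_id=recording_id)


def _read_annotation_csv(path: Path) -> list[IURecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"onset_s", "offset_s", "speaker_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        onset, offset = float(row.onset_s), float(row.offset_s)
        if not onset < offset:
            raise ValueError(
                f"{path}: row {i + 1} has onset_s={onset} >= offset_s={offset}"
            )
        records.append(IURecord(onset, offset, str(row.speaker_id)))
    return records


_TG_INTERVAL = re.compile(
    r"intervals\s*\[\d+\]\s*:?\s*"
    r"xmin\s*=\s*([\d.eE+-]+)\s*"
    r"xmax\s*=\s*([\d.eE+-]+)\s*"
    r'text\s*=\s*"((?:[^"]|"")*)"',
)
_TG_TIER = re.compile(r'name\s*=\s*"((?:[^"]|"")*)"')


def _read_textgrid(path: Path) -> list[IURecord]:
    """Parse interval tiers from a long-format ooTextFile TextGrid."""
    text = path.read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text.split("\n", 1)[0]:
        raise ValueError(f"{path}: not a Praat TextGrid (missing ooTextFile header)")
    records: list[IURecord] = []
    # split into tiers on 'item [k]:' boundaries; tier name precedes intervals
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for chunk in chunks:
        if "IntervalTier" not in chunk:
            continue
        name_m = _TG_TIER.search(chunk)
        speaker = name_m.group(1).replace('""', '"') if name_m else ""
        for m in _TG_INTERVAL.finditer(chunk):
            label = m.group(3).replace('""', '"').strip()
            if not label:
                continue
            onset, offset = float(m.group(1)), float(m.group(2))
            if not onset < offset:
                raise ValueError(
                    f"{path}: tier {speaker!r} interval at xmin={onset} has "
                    f"xmin >= xmax={offset}"
                )
            records.append(IURecord(onset, offset, speaker))
    records.sort(key=lambda r: r.onset_s)
    return records


def write_annotations(ann: IUAnnotation, path: str | Path,
                      header: Mapping[str, object] | None = None) -> None:
    """Write an annotation as canonical CSV (full float precision)."""
    _write_table(ann.to_frame(), path, header)


# ---------------------------------------------------------------------------
# spectra and result tables

def _write_table(df: pd.DataFrame, path: str | Path,
                 header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_spectrum(spectrum, path: str | Path,
                   header: Mapping[str, object] | None = None) -> None:
    """Write a per-speaker, group, or permutation spectrum as CSV.

    Accepts any object exposing ``to_frame()`` (ConsistencySpectrum,
    GroupSpectrum, PermutationResult) or a DataFrame.  Group results gain
    ``ci_low/ci_high`` columns; permutation results gain ``p_value`` and a
    0/1 ``significant`` column.
    """
    df = spectrum if isinstance(spectrum, pd.DataFrame) else spectrum.to_frame()
    if "significant" in df.columns:
        df = df.assign(significant=df["significant"].astype(int))
    _write_table(df, path, header)


def read_spectrum(path: str | Path) -> pd.DataFrame:
    """Read a spectrum table written by :func:`write_spectrum`."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML config file (nested sections per module)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return cfg
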