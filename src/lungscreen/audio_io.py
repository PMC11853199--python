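"""WAV input/output for auscultation recordings.

Recordings carry the metadata the screening application attaches to each
measurement: an opaque subject identifier, the chest-wall measurement point
(five standard auscultation positions), and an optional class label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from lungscreen.errors import ContractError, EmptyInputError, FormatError

#: Default working sample rate. Nyquist (2000 Hz) clears the 1000 Hz upper
#: band edge, and a 6 s segment then holds 24000 samples, enough for a
#: 10-level db7 decomposition.
DEFAULT_SAMPLE_RATE = 4000


class ClassLabel(str, Enum):
    """The four screening classes.

    ``OTHER`` pools coronavirus disease, LRTI, URTI, asthma, bronchiolitis
    and bronchiectasis into a single class.
    """

    HEALTHY = "healthy"
    PNEUMONIA = "pneumonia"
    COPD = "copd"
    OTHER = "other"


#: Canonical class ordering used by the classifier output layer and reports.
CLASS_ORDER = (ClassLabel.HEALTHY, ClassLabel.PNEUMONIA, ClassLabel.COPD, ClassLabel.OTHER)


@dataclass
class AudioRecording:
    """A mono auscultation recording plus measurement metadata."""

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    measurement_point: Optional[int] = None
    label: Optional[ClassLabel] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ContractError("samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise EmptyInputError("recording has no samples")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ContractError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        if self.measurement_point is not None and self.measurement_point not in (1, 2, 3, 4, 5):
            raise ContractError(
                f"measurement_point must be in 1..5, got {self.measurement_point!r}"
            )
        if self.label is not None:
            self.label = ClassLabel(self.label)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioRecording":
        """Copy of this recording with new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def _to_float(data: np.ndarray) -> np.ndarray:
    """Map PCM integer samples onto [-1, 1); pass floats through."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    info = np.iinfo(data.dtype)
    return data.astype(np.float64) / (info.max + 1)


def load_recording(
    path: Union[str, Path],
    target_rate: Optional[int] = None,
    subject_id: str = "",
    measurement_point: Optional[int] = None,
    label: Optional[ClassLabel] = None,
) -> AudioRecording:
    """Read a RIFF/WAVE file as a mono recording.

    Multichannel audio is averaged across channels. When ``target_rate`` is
    given and differs from the file's native rate, the signal is resampled
    with a polyphase filter.
    """
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"WAV file {path} contains no audio")
    samples = _to_float(np.asarray(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if target_rate is not None and target_rate != rate:
        if target_rate <= 0:
            raise ContractError("target_rate must be positive")
        ratio = Fraction(int(target_rate), int(rate))
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
        rate = int(target_rate)
    return AudioRecording(
        samples=samples,
        sample_rate=int(rate),
        subject_id=subject_id,
        measurement_point=measurement_point,
        label=label,
    )


def save_recording(
    recording: AudioRecording, path: Union[str, Path], subtype: str = "pcm16"
) -> None:
    """Write a recording as WAV (16-bit PCM by default, or float32).

    Amplitudes must lie in [-1, 1] for PCM encoding; the round trip
    ``load_recording(save_recording(x))`` reproduces samples within one
    quantization step and the sample rate exactly.
    """
    peak = float(np.max(np.abs(recording.samples)))
    if subtype == "pcm16":
        if peak > 1.0 + 1e-12:
            raise ContractError(
                f"peak amplitude {peak:.4g} exceeds the PCM-encodable range [-1, 1]"
            )
        quantized = np.clip(np.round(recording.samples * 32768.0), -32768, 32767)
        wavfile.write(str(path), recording.sample_rate, quantized.astype(np.int16))
    elif subtype == "float32":
        wavfile.write(str(path), recording.sample_rate, recording.samples.astype(np.float32))
    else:
        raise ContractError(f"unknown subtype {subtype!r}; use 'pcm16' or 'float32'")


MANIFEST_COLUMNS = ["recording_path", "subject_id", "measurement_point", "label"]


def write_manifest(rows: list[dict], path: Union[str, Path]) -> None:
    """Write a label manifest CSV (recording_path, subject_id, measurement_point, label)."""
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    frame.to_csv(path, index=False)


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a label manifest CSV, validating its schema and labels."""
    frame = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    for value in frame["label"].dropna():
        ClassLabel(value)  # raises ValueError on unknown labels
    return frame


def load_manifest_recordings(
    manifest_path: Union[str, Path], target_rate: Optional[int] = None
) -> list[AudioRecording]:
    """Load every recording listed in a manifest, resolving relative paths."""
    frame = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    recordings = []
    for row in frame.itertuples(index=False):
        wav = Path(row.recording_path)
        if not wav.is_absolute():
            wav = base / wav
        point = row.measurement_point
        if point is None or (isinstance(point, float) and math.isnan(point)):
            point = None
        else:
            point = int(point)
        label = None if pd.isna(row.label) else ClassLabel(row.label)
        recordings.append(
            load_recording(
                wav,
                target_rate=target_rate,
                subject_id=str(row.subject_id),
                measurement_point=point,
                label=label,
            )
        )
    return recordings
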