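"""Wavelet and entropy features of 6-second auscultation segments.

Each segment is decomposed with a 10-level discrete wavelet transform using
the Daubechies db7 mother wavelet, yielding one approximation set (cA, the
lowest band) and ten detail sets (cD1 finest ... cD10 coarsest). The feature
vector has 13 entries:

* ``Entropy`` — Shannon entropy (bits) of the amplitude distribution of the
  raw segment, estimated on 256 equal-width bins over [-1, 1];
* ``Spec.Entropy`` — Shannon entropy (bits) of the normalized one-sided
  power spectral density of the raw segment;
* ``RMScA``, ``RMScD1`` ... ``RMScD10`` — root mean square of each wavelet
  coefficient set, sqrt(sum(D_i^2)/N).

Both entropies are computed on the segment before the wavelet transform.
Feature extraction is a pure, deterministic function of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import pywt

from lungscreen.errors import ContractError, DegenerateInputError
from lungscreen.preprocessing import Segment, power_spectrum

WAVELET_NAME = "db7"
DWT_LEVELS = 10
ENTROPY_BINS = 256

#: Canonical feature order used in every table, model and report.
FEATURE_NAMES = ("Entropy", "Spec.Entropy", "RMScA") + tuple(
    f"RMScD{k}" for k in range(1, DWT_LEVELS + 1)
)


@dataclass(frozen=True)
class WaveletCoefficients:
    """Approximation (cA, level 10) and detail sets cD1..cD10 (cD1 finest)."""

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]  # indexed so details[k-1] == cD(k)

    def __post_init__(self) -> None:
        if len(self.details) != DWT_LEVELS:
            raise ContractError(f"expected {DWT_LEVELS} detail sets, got {len(self.details)}")

    @property
    def all_sets(self) -> tuple[np.ndarray, ...]:
        return (self.approximation,) + self.details


@dataclass(frozen=True)
class FeatureVector:
    """The 13 named features of one segment, in canonical order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ContractError(f"feature vector must have {len(FEATURE_NAMES)} entries")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("feature values must be finite")

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def dwt_decompose(
    segment_or_samples: Union[Segment, np.ndarray],
    wavelet_name: str = WAVELET_NAME,
    levels: int = DWT_LEVELS,
    mode: str = "symmetric",
) -> WaveletCoefficients:
    """Multilevel DWT of a segment.

    ``mode`` is the boundary extension; the default symmetric extension is
    used for feature extraction, while ``"periodization"`` makes the
    transform exactly orthogonal (energy-preserving) on dyadic lengths.
    """
    samples = (
        segment_or_samples.samples
        if isinstance(segment_or_samples, Segment)
        else np.asarray(segment_or_samples, dtype=np.float64)
    )
    max_level = pywt.dwt_max_level(samples.size, pywt.Wavelet(wavelet_name).dec_len)
    if levels > max_level:
        raise ContractError(
            f"segment of {samples.size} samples supports at most {max_level} "
            f"levels with {wavelet_name}, requested {levels}"
        )
    coeffs = pywt.wavedec(samples, wavelet_name, mode=mode, level=levels)
    approximation = coeffs[0]
    details_coarse_to_fine = coeffs[1:]  # cD(levels) ... cD1
    details = tuple(reversed(details_coarse_to_fine))  # cD1 ... cD(levels)
    return WaveletCoefficients(approximation=approximation, details=details)


def shannon_entropy(values: Sequence[float], n_bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of the amplitude distribution.

    Amplitudes are histogrammed on ``n_bins`` equal-width bins over [-1, 1];
    bin probabilities are counts over the total and the entropy is
    -sum(p * log2(p)) with 0*log(0) taken as 0. Result lies in
    [0, log2(n_bins)].
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ContractError("cannot compute entropy of an empty sequence")
    if n_bins < 2:
        raise ContractError("n_bins must be at least 2")
    counts, _ = np.histogram(np.clip(values, -1.0, 1.0), bins=n_bins, range=(-1.0, 1.0))
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log2(p)))


def spectral_entropy(segment: Union[Segment, np.ndarray], sample_rate: int = None) -> float:
    """Shannon entropy (bits) of the normalized power spectral density.

    The one-sided periodogram is normalized to sum to one over its grid and
    treated as a probability distribution over frequency bins.
    """
    spectrum = power_spectrum(segment, sample_rate)
    total = float(np.sum(spectrum.power))
    if total <= 0.0:
        raise DegenerateInputError("spectral entropy undefined for a zero-power signal")
    p = spectrum.power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def rms(values: Sequence[float]) -> float:
    """Root mean square sqrt(sum(D_i^2) / N) of a coefficient set."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ContractError("cannot compute RMS of an empty sequence")
    return float(np.sqrt(np.mean(values**2)))


def extract_feature_vector(segment: Segment, n_bins: int = ENTROPY_BINS) -> FeatureVector:
    """Compute the 13-feature vector of one segment."""
    coeffs = dwt_decompose(segment)
    values = [
        shannon_entropy(segment.samples, n_bins=n_bins),
        spectral_entropy(segment),
        rms(coeffs.approximation),
    ]
    values.extend(rms(d) for d in coeffs.details)
    return FeatureVector(values=np.asarray(values))


def feature_table(
    segments: Sequence[Segment], labels: Sequence[str] = None
) -> pd.DataFrame:
    """Feature vectors of many segments as a DataFrame.

    Columns: the 13 features in canonical order, plus ``recording_id``,
    ``segment_index`` and (when labels are given) ``label``.
    """
    rows = []
    for i, seg in enumerate(segments):
        row = extract_feature_vector(seg).as_dict()
        row["recording_id"], row["segment_index"] = seg.origin
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV with the canonical header."""
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV, checking that all 13 features are present."""
    table = pd.read_csv(path)
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ContractError(f"feature table missing columns: {missing}")
    return table
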