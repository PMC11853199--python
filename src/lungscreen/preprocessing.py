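"""Digital filtering, normalization, segmentation and power spectra.

Lung-sound conduction through the chest wall is band-limited to roughly
80–1000 Hz, so the pipeline's first stage is a bandpass built as a cascade of
a high-pass section at the lower edge and a low-pass section at the upper
edge. Butterworth is the working family; Chebyshev type 1/2 and elliptic
designs are available for frequency-response comparison. Filters are applied
forward-backward (zero phase), which squares the magnitude response: the
single-pass -3 dB cutoffs become -6 dB points of the applied response.

Processing order for a recording: filter -> normalize to [-1, 1] ->
segment into consecutive 6 s windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import signal as sps

from lungscreen.audio_io import AudioRecording
from lungscreen.errors import ContractError, DegenerateInputError, TooShortError

FILTER_FAMILIES = ("butterworth", "chebyshev1", "chebyshev2", "elliptic")

#: Segment length in seconds; one breathing cycle fits comfortably inside.
SEGMENT_SECONDS = 6.0


@dataclass(frozen=True)
class FilterSpec:
    """A designed bandpass: cascaded second-order sections plus its recipe."""

    family: str
    order: int
    low_cut_hz: float
    high_cut_hz: float
    sample_rate: int
    sos: np.ndarray
    ripple_db: Optional[float] = None
    attenuation_db: Optional[float] = None


@dataclass(frozen=True)
class Segment:
    """A fixed-length analysis window of a normalized recording."""

    samples: np.ndarray
    sample_rate: int
    origin: tuple[str, int] = ("", 0)  # (recording id, segment index)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ContractError("segment samples must lie in [-1, 1]")


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum: P(f) on a frequency grid up to Nyquist."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ContractError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-15):
            raise ContractError("power values must be non-negative")


def design_filter(
    family: str,
    order: int,
    low_cut_hz: float,
    high_cut_hz: float,
    sample_rate: int,
    ripple_db: float = 1.0,
    attenuation_db: float = 40.0,
) -> FilterSpec:
    """Design a bandpass as a high-pass/low-pass cascade of the given family.

    ``order`` is the order of each section, so the default 5th-order design
    is a 5th-order high-pass at ``low_cut_hz`` in series with a 5th-order
    low-pass at ``high_cut_hz``. ``ripple_db`` applies to Chebyshev type 1
    and elliptic passbands, ``attenuation_db`` to Chebyshev type 2 and
    elliptic stopbands.
    """
    if family not in FILTER_FAMILIES:
        raise ContractError(f"unknown filter family {family!r}; choose from {FILTER_FAMILIES}")
    if order < 1:
        raise ContractError("order must be a positive integer")
    nyquist = sample_rate / 2
    if not 0 < low_cut_hz < high_cut_hz < nyquist:
        raise ContractError(
            f"band ({low_cut_hz}, {high_cut_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyquist})"
        )

    def _section(btype: str, cutoff: float) -> np.ndarray:
        if family == "butterworth":
            return sps.butter(order, cutoff, btype=btype, fs=sample_rate, output="sos")
        if family == "chebyshev1":
            return sps.cheby1(order, ripple_db, cutoff, btype=btype, fs=sample_rate, output="sos")
        if family == "chebyshev2":
            return sps.cheby2(order, attenuation_db, cutoff, btype=btype, fs=sample_rate, output="sos")
        return sps.ellip(order, ripple_db, attenuation_db, cutoff, btype=btype, fs=sample_rate, output="sos")

    sos = np.vstack([_section("highpass", low_cut_hz), _section("lowpass", high_cut_hz)])
    return FilterSpec(
        family=family,
        order=order,
        low_cut_hz=low_cut_hz,
        high_cut_hz=high_cut_hz,
        sample_rate=sample_rate,
        sos=sos,
        ripple_db=ripple_db if family in ("chebyshev1", "elliptic") else None,
        attenuation_db=attenuation_db if family in ("chebyshev2", "elliptic") else None,
    )


def frequency_response(spec: FilterSpec, n_points: int = 2048) -> PowerSpectrum:
    """Magnitude response |H(f)| on a linear grid from 0 to Nyquist."""
    if n_points < 2:
        raise ContractError("n_points must be at least 2")
    freqs, h = sps.sosfreqz(spec.sos, worN=n_points, fs=spec.sample_rate)
    return PowerSpectrum(frequencies=np.asarray(freqs), power=np.abs(h))


def apply_filter(spec: FilterSpec, recording: AudioRecording) -> AudioRecording:
    """Zero-phase (forward-backward) filtering; output length equals input length."""
    if recording.sample_rate != spec.sample_rate:
        raise ContractError(
            f"recording rate {recording.sample_rate} != filter design rate {spec.sample_rate}"
        )
    filtered = sps.sosfiltfilt(spec.sos, recording.samples)
    return recording.with_samples(filtered)


def normalize(recording: AudioRecording) -> AudioRecording:
    """Scale by the peak magnitude so samples span [-1, 1] with peak exactly 1."""
    peak = float(np.max(np.abs(recording.samples)))
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero signal")
    return recording.with_samples(recording.samples / peak)


def segment(
    recording: AudioRecording, seg_seconds: float = SEGMENT_SECONDS
) -> list[Segment]:
    """Split into consecutive non-overlapping windows of ``seg_seconds``.

    The trailing remainder shorter than one window is discarded. A recording
    shorter than one window is an error.
    """
    seg_len = int(round(seg_seconds * recording.sample_rate))
    n = recording.samples.size
    if n < seg_len:
        raise TooShortError(
            f"recording of {n / recording.sample_rate:.2f} s is shorter than one "
            f"{seg_seconds:.0f} s segment"
        )
    n_segments = n // seg_len
    return [
        Segment(
            samples=recording.samples[i * seg_len : (i + 1) * seg_len],
            sample_rate=recording.sample_rate,
            origin=(recording.subject_id, i),
        )
        for i in range(n_segments)
    ]


def power_spectrum(
    samples_or_segment: Union[np.ndarray, Segment, AudioRecording],
    sample_rate: Optional[int] = None,
    window: str = "boxcar",
) -> PowerSpectrum:
    """One-sided periodogram normalized so that sum(power) = mean(sample^2).

    With the default rectangular window this is the discrete Parseval
    convention: total spectral power equals the signal's mean square.
    """
    if isinstance(samples_or_segment, (Segment, AudioRecording)):
        samples = samples_or_segment.samples
        sample_rate = samples_or_segment.sample_rate
    else:
        samples = np.asarray(samples_or_segment, dtype=np.float64)
        if sample_rate is None:
            raise ContractError("sample_rate is required for a bare sample array")
    if samples.size < 2:
        raise ContractError("power spectrum needs at least 2 samples")
    freqs, power = sps.periodogram(
        samples, fs=sample_rate, window=window, scaling="spectrum", detrend=False
    )
    return PowerSpectrum(frequencies=freqs, power=power)
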