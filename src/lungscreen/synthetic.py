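"""Seeded synthetic auscultation corpora.

Real lung-sound corpora mix vesicular breath noise with class-dependent
adventitious sounds: pneumonia adds short crackle transients (airflow through
fluid-filled small airways), obstructive disease adds sustained tonal wheezes
(fluttering of narrowed airways). The generator emulates exactly that
phenomenology — band-limited breath noise shaped by a raised-cosine breathing
envelope, plus per-class adventitious components — so every downstream stage
(filtering, wavelet/entropy features, rank selection, classification) can be
exercised and validated without any external download.

It is a testability model, not an airway-acoustics simulation; see
docs/methods.md for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.signal import butter, sosfiltfilt

from lungscreen.audio_io import (
    AudioRecording,
    ClassLabel,
    save_recording,
    write_manifest,
)
from lungscreen.errors import ContractError


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus.

    Defaults are the conditions used throughout the test suite: 4 kHz
    working rate, 12 s recordings (two 6 s analysis segments each), a 4 s
    breathing cycle, breath noise in the 80–1000 Hz conduction band, and a
    10 dB signal-to-noise ratio against broadband sensor noise.
    """

    sample_rate: int = 4000
    duration: float = 12.0
    breath_cycle_period: float = 4.0
    base_noise_band: tuple[float, float] = (80.0, 1000.0)
    crackle_rate: float = 20.0  # expected crackles per breathing cycle (pneumonia)
    crackle_gain: float = 8.0  # crackle peak relative to overall breath RMS
    wheeze_frequencies: tuple[float, ...] = (150.0, 400.0)  # Hz (COPD)
    snr_db: float = 10.0
    counts_per_class: dict[ClassLabel, int] = field(
        default_factory=lambda: {label: 10 for label in ClassLabel}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 6:
            raise ContractError("duration must be at least 6 s (one analysis segment)")
        low, high = self.base_noise_band
        if not 0 < low < high < self.sample_rate / 2:
            raise ContractError("base_noise_band must lie inside (0, Nyquist)")
        for f in self.wheeze_frequencies:
            if not 80.0 <= f <= 1000.0:
                raise ContractError(f"wheeze frequency {f} Hz outside the 80-1000 Hz band")
        if any(c < 0 for c in self.counts_per_class.values()):
            raise ContractError("class counts must be non-negative")


def _breath_envelope(t: np.ndarray, period: float, insp_frac: float = 0.4,
                     exp_frac: float = 0.45, exp_gain: float = 0.7) -> np.ndarray:
    """Raised-cosine inspiration/expiration amplitude envelope, floor 0.05."""
    phase = (t % period) / period
    env = np.full_like(t, 0.05)
    insp = phase < insp_frac
    env[insp] += np.sin(np.pi * phase[insp] / insp_frac) ** 2
    exp = (phase >= insp_frac) & (phase < insp_frac + exp_frac)
    env[exp] += exp_gain * np.sin(np.pi * (phase[exp] - insp_frac) / exp_frac) ** 2
    return env


def _expiratory_gate(t: np.ndarray, period: float, insp_frac: float = 0.4,
                     exp_frac: float = 0.45) -> np.ndarray:
    """Smooth 0/1 gate over the expiratory phase (for wheeze placement)."""
    phase = (t % period) / period
    gate = np.zeros_like(t)
    exp = (phase >= insp_frac) & (phase < insp_frac + exp_frac)
    gate[exp] = np.sin(np.pi * (phase[exp] - insp_frac) / exp_frac) ** 2
    return gate


def _band_noise(rng: np.random.Generator, n: int, fs: int,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def _crackle(rng: np.random.Generator, fs: int) -> np.ndarray:
    """One exponentially damped sinusoid, 200-600 Hz center, 5-15 ms."""
    f = rng.uniform(200.0, 600.0)
    dur = rng.uniform(0.005, 0.015)
    n = max(int(dur * fs), 4)
    t = np.arange(n) / fs
    # decay so the tail is ~5% of the onset amplitude at the end
    return np.exp(-3.0 * t / dur) * np.sin(2 * np.pi * f * t)


def _place_crackles(rng: np.random.Generator, t: np.ndarray, fs: int,
                    period: float, rate: float, amplitude: float) -> np.ndarray:
    """Poisson-place crackles within inspiratory phases."""
    out = np.zeros_like(t)
    n_cycles = int(np.ceil(t[-1] / period))
    for cycle in range(n_cycles):
        n_events = rng.poisson(rate)
        for _ in range(n_events):
            onset = (cycle + rng.uniform(0.0, 0.4)) * period  # inspiratory window
            start = int(onset * fs)
            burst = amplitude * rng.uniform(0.6, 1.4) * _crackle(rng, fs)
            stop = min(start + burst.size, out.size)
            if start < out.size:
                out[start:stop] += burst[: stop - start]
    return out


def generate_recording(
    label: ClassLabel, spec: SyntheticSpec, seed: int, subject_id: str = ""
) -> AudioRecording:
    """Synthesize one labeled recording; deterministic in (label, spec, seed).

    healthy    band-limited breath noise under the breathing envelope
    pneumonia  healthy + damped-sinusoid crackle transients in inspiration
    copd       healthy + sustained tonal wheezes during expiration
    other      healthy variant: slower cycle, narrowed band, mild low wheeze —
               a distributional mixture standing in for the pooled residual
               disease class
    """
    label = ClassLabel(label)
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    period = spec.breath_cycle_period
    band = spec.base_noise_band

    if label is ClassLabel.OTHER:
        # altered envelope and spectrum, plus a faint low-frequency wheeze
        period = period * rng.uniform(1.3, 1.7)
        low, high = band
        band = (low, low + (high - low) * rng.uniform(0.35, 0.55))

    breath = _band_noise(rng, n, fs, band) * _breath_envelope(t, period)
    signal = breath
    breath_rms = np.sqrt(np.mean(breath**2))

    if label is ClassLabel.PNEUMONIA:
        signal = signal + _place_crackles(
            rng, t, fs, period, spec.crackle_rate, amplitude=spec.crackle_gain * breath_rms
        )
    elif label is ClassLabel.COPD:
        gate = _expiratory_gate(t, period)
        for f in spec.wheeze_frequencies:
            phase = rng.uniform(0, 2 * np.pi)
            signal = signal + 2.0 * breath_rms * gate * np.sin(2 * np.pi * f * t + phase)
    elif label is ClassLabel.OTHER:
        gate = _expiratory_gate(t, period)
        f = rng.uniform(100.0, 160.0)
        signal = signal + 0.8 * breath_rms * gate * np.sin(2 * np.pi * f * t)

    # broadband sensor/ambient noise at the requested SNR
    sig_power = np.mean(signal**2)
    noise_power = sig_power / 10 ** (spec.snr_db / 10)
    signal = signal + rng.standard_normal(n) * np.sqrt(noise_power)

    # leave headroom so 16-bit PCM round trips without clipping
    signal = 0.9 * signal / np.max(np.abs(signal))
    return AudioRecording(
        samples=signal, sample_rate=fs, subject_id=subject_id, label=label
    )


def generate_corpus(
    spec: SyntheticSpec, out_dir: Optional[Union[str, Path]] = None
) -> tuple[list[AudioRecording], list[dict]]:
    """Generate a labeled corpus with exactly ``spec.counts_per_class`` recordings.

    Per-recording seeds are spawned deterministically from ``spec.seed``.
    When ``out_dir`` is given, WAV files and a manifest CSV are written there.

    Returns the recordings and the manifest rows.
    """
    total = sum(spec.counts_per_class.values())
    if total < 1:
        raise ContractError("counts_per_class must request at least one recording")
    seed_seq = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(total)]

    recordings: list[AudioRecording] = []
    manifest: list[dict] = []
    index = 0
    for label in ClassLabel:
        for k in range(spec.counts_per_class.get(label, 0)):
            subject = f"{label.value}-{k:03d}"
            rec = generate_recording(label, spec, child_seeds[index], subject_id=subject)
            recordings.append(rec)
            manifest.append(
                {
                    "recording_path": f"{subject}.wav",
                    "subject_id": subject,
                    "measurement_point": None,
                    "label": label.value,
                }
            )
            index += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, manifest):
            save_recording(rec, out_dir / row["recording_path"])
        write_manifest(manifest, out_dir / "manifest.csv")
    return recordings, manifest
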