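import numpy as np
import pytest

from lungscreen.audio_io import AudioRecording
from lungscreen.errors import ContractError, DegenerateInputError, TooShortError
from lungscreen.preprocessing import (
    apply_filter,
    design_filter,
    frequency_response,
    normalize,
    power_spectrum,
    segment,
)

FS = 4000


def _db(x):
    return 20 * np.log10(np.maximum(x, 1e-300))


@pytest.fixture(scope="module")
def butter_spec():
    return design_filter("butterworth", 5, 80, 1000, FS)


class TestDesignFilter:
    def test_dc_gain_vanishes(self, butter_spec):
        resp = frequency_response(butter_spec, n_points=4096)
        assert resp.power[0] < 1e-6

    def test_band_center_near_unity(self, butter_spec):
        """|H| at the geometric band center (~283 Hz) within 0.1 dB of 1."""
        resp = frequency_response(butter_spec, n_points=8192)
        center = np.sqrt(80 * 1000)
        idx = np.argmin(np.abs(resp.frequencies - center))
        assert abs(_db(resp.power[idx])) < 0.1

    @pytest.mark.parametrize("edge", [80.0, 1000.0])
    def test_minus_3db_at_cutoffs(self, butter_spec, edge):
        """Each section's -3 dB cutoff survives in the cascade (the other
        section is essentially transparent there)."""
        resp = frequency_response(butter_spec, n_points=2**15)
        idx = np.argmin(np.abs(resp.frequencies - edge))
        assert abs(_db(resp.power[idx]) + 3.0) < 0.5

    def test_band_edges_validated(self):
        with pytest.raises(ContractError):
            design_filter("butterworth", 5, 80, 2500, FS)
        with pytest.raises(ContractError):
            design_filter("butterworth", 5, 0, 1000, FS)

    def test_unknown_family_rejected(self):
        with pytest.raises(ContractError):
            design_filter("bessel", 5, 80, 1000, FS)


class TestFrequencyResponse:
    @staticmethod
    def _interior_ripples(resp, lo, hi):
        """Peak-to-trough swings between successive interior extrema (dB)."""
        inside = (resp.frequencies >= lo) & (resp.frequencies <= hi)
        gains_db = _db(resp.power[inside])
        d = np.diff(gains_db)
        extrema = np.where(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1
        return np.abs(np.diff(gains_db[extrema]))

    def test_butterworth_passband_maximally_flat(self, butter_spec):
        """Maximally flat: at most a single interior maximum inside
        150-800 Hz, so no ripple swing above 0.05 dB."""
        resp = frequency_response(butter_spec, n_points=2**14)
        ripples = self._interior_ripples(resp, 150, 800)
        assert ripples.size == 0 or ripples.max() < 0.05

    def test_chebyshev1_cascade_shows_equiripple_oscillation(self):
        """The HP+LP cascade superposes each section's 1 dB equiripple, so
        the passband oscillates with swings of order 1-2 dB (unlike the
        monotone Butterworth)."""
        spec = design_filter("chebyshev1", 5, 80, 1000, FS, ripple_db=1.0)
        resp = frequency_response(spec, n_points=2**15)
        ripples = self._interior_ripples(resp, 120, 900)
        assert ripples.size >= 2
        assert 0.8 < ripples.max() < 2.2

    @pytest.mark.parametrize("family", ["butterworth", "chebyshev1", "chebyshev2", "elliptic"])
    def test_bandpass_shape_all_families(self, family):
        spec = design_filter(family, 5, 80, 1000, FS)
        resp = frequency_response(spec, n_points=4096)
        center_idx = np.argmin(np.abs(resp.frequencies - 283))
        assert resp.power[-1] < resp.power[center_idx]


class TestApplyFilter:
    def _tone(self, freq, seconds=2.0):
        t = np.arange(int(FS * seconds)) / FS
        return AudioRecording(samples=np.sin(2 * np.pi * freq * t), sample_rate=FS)

    def test_stopband_tone_attenuated(self, butter_spec):
        rec = self._tone(40)
        out = apply_filter(butter_spec, rec)
        assert np.sqrt(np.mean(out.samples**2)) < 0.05 * np.sqrt(np.mean(rec.samples**2))

    def test_passband_tone_transparent(self, butter_spec):
        rec = self._tone(300)
        out = apply_filter(butter_spec, rec)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(rec.samples**2))
        assert abs(ratio - 1.0) < 0.05

    def test_zero_in_zero_out(self, butter_spec):
        rec = AudioRecording(samples=np.zeros(FS), sample_rate=FS)
        out = apply_filter(butter_spec, rec)
        assert np.allclose(out.samples, 0.0)

    def test_length_preserved(self, butter_spec, tone_recording):
        assert apply_filter(butter_spec, tone_recording).samples.size == tone_recording.samples.size

    def test_rate_mismatch_rejected(self, butter_spec):
        rec = AudioRecording(samples=np.ones(100), sample_rate=8000)
        with pytest.raises(ContractError):
            apply_filter(butter_spec, rec)

    def test_linearity(self, butter_spec):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(FS)
        y = rng.standard_normal(FS)
        fx = apply_filter(butter_spec, AudioRecording(samples=x, sample_rate=FS)).samples
        fy = apply_filter(butter_spec, AudioRecording(samples=y, sample_rate=FS)).samples
        fxy = apply_filter(
            butter_spec, AudioRecording(samples=2.0 * x + 3.0 * y, sample_rate=FS)
        ).samples
        np.testing.assert_allclose(fxy, 2.0 * fx + 3.0 * fy, rtol=1e-9, atol=1e-12)

    def test_zero_phase_no_group_delay(self, butter_spec, tone_recording):
        """Cross-correlation of a passband tone with its filtered self peaks at lag 0."""
        out = apply_filter(butter_spec, tone_recording)
        x, y = tone_recording.samples, out.samples
        lags = np.arange(-50, 51)
        corr = [np.dot(x[max(0, -l) : len(x) - max(0, l)], y[max(0, l) : len(y) - max(0, -l)]) for l in lags]
        assert lags[int(np.argmax(corr))] == 0


class TestNormalize:
    def test_scale_by_peak(self):
        rec = AudioRecording(samples=np.array([2.0, -4.0, 1.0]), sample_rate=FS)
        np.testing.assert_allclose(normalize(rec).samples, [0.5, -1.0, 0.25])

    def test_idempotent_at_unit_peak(self):
        rec = AudioRecording(samples=np.array([0.5, -1.0, 0.25]), sample_rate=FS)
        np.testing.assert_allclose(normalize(rec).samples, rec.samples)

    def test_all_zero_rejected(self):
        rec = AudioRecording(samples=np.zeros(10), sample_rate=FS)
        with pytest.raises(DegenerateInputError):
            normalize(rec)


class TestSegment:
    def test_fifteen_seconds_gives_two_segments(self):
        rec = AudioRecording(samples=np.random.default_rng(0).uniform(-1, 1, 15 * FS), sample_rate=FS)
        segs = segment(rec)
        assert len(segs) == 2
        assert all(s.samples.size == 6 * FS for s in segs)

    def test_exactly_six_seconds_one_segment(self):
        rec = AudioRecording(samples=np.ones(6 * FS) * 0.5, sample_rate=FS)
        assert len(segment(rec)) == 1

    def test_too_short_rejected(self):
        rec = AudioRecording(samples=np.ones(5 * FS) * 0.5, sample_rate=FS)
        with pytest.raises(TooShortError):
            segment(rec)

    def test_normalized_bound_preserved_in_segments(self):
        rng = np.random.default_rng(1)
        rec = normalize(AudioRecording(samples=rng.standard_normal(13 * FS), sample_rate=FS))
        for seg in segment(rec):
            assert np.max(np.abs(seg.samples)) <= 1.0


class TestPowerSpectrum:
    def test_aligned_tone_single_dominant_bin(self):
        t = np.arange(FS) / FS  # 1 s -> 1 Hz bins, 100 Hz is aligned
        ps = power_spectrum(np.sin(2 * np.pi * 100 * t), FS)
        assert ps.power.max() / ps.power.sum() >= 0.99

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(6 * FS)
        ps = power_spectrum(x, FS)
        assert np.isclose(ps.power.sum(), np.mean(x**2), rtol=1e-9)

    def test_filtered_noise_stopband_30db_down(self, butter_spec):
        rng = np.random.default_rng(4)
        rec = AudioRecording(samples=rng.standard_normal(8 * FS), sample_rate=FS)
        out = apply_filter(butter_spec, rec)
        ps = power_spectrum(out.samples, FS)
        passband = (ps.frequencies >= 100) & (ps.frequencies <= 900)
        stopband = (ps.frequencies >= 1200) & (ps.frequencies <= 2000)
        ratio_db = 10 * np.log10(ps.power[passband].mean() / ps.power[stopband].mean())
        assert ratio_db >= 30
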