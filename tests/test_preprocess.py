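"""Tests for EEG record handling, filtering and epoch selection."""

import numpy as np
import pytest

from rdfc.preprocess import (
    EEGEpoch,
    EEGRecord,
    MontageError,
    bandpass,
    has_flatline,
    notch,
    read_annotations,
    read_record,
    rereference,
    resample,
    select_epoch,
)
from rdfc.synth import write_annotations, write_fixture


def sine_record(freqs, rate=256.0, duration=30.0, labels=None):
    t = np.arange(int(duration * rate)) / rate
    samples = np.vstack([np.sin(2 * np.pi * f * t) * 50 for f in freqs])
    labels = labels or [f"CH{i+1}" for i in range(len(freqs))]
    return EEGRecord(samples=samples, rate=rate, labels=labels)


def mid_amplitude(x, rate):
    """Peak amplitude away from filter edge transients (0.5 Hz high-pass
    transients persist for seconds)."""
    n = int(8 * rate)
    return np.max(np.abs(x[n:-n]))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = bandpass(sine_record([10.0]), 0.5, 70.0)
        assert mid_amplitude(rec.samples[0], rec.rate) == pytest.approx(50.0, rel=0.01)

    def test_out_of_band_tone_attenuated(self):
        rec = bandpass(sine_record([100.0]), 0.5, 70.0)
        assert mid_amplitude(rec.samples[0], rec.rate) < 0.1 * 50.0

    def test_zero_phase_impulse_symmetric(self):
        # long buffer so the slow 0.5 Hz transient dies before the edges
        n, mid = 1 << 15, 1 << 14
        x = np.zeros((1, n))
        x[0, mid] = 1.0
        rec = bandpass(EEGRecord(x, 256.0, ["A"]), 0.5, 70.0)
        h = rec.samples[0]
        assert np.allclose(h[mid - 2000 : mid], h[mid + 1 : mid + 2001][::-1], atol=1e-9)
        assert np.argmax(np.abs(h)) == mid  # response peaks at the impulse

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            bandpass(sine_record([10.0]), 0.5, 200.0)  # above Nyquist
        with pytest.raises(ValueError):
            bandpass(sine_record([10.0]), 70.0, 0.5)

    def test_shape_and_labels_preserved(self):
        rec = sine_record([10.0, 20.0, 30.0])
        out = notch(bandpass(rec), 50.0)
        assert out.samples.shape == rec.samples.shape
        assert out.labels == rec.labels


class TestNotch:
    def test_notch_removes_line_frequency(self):
        rec = notch(sine_record([50.0]), 50.0)
        assert mid_amplitude(rec.samples[0], rec.rate) < 0.05 * 50.0

    def test_out_of_notch_tone_preserved(self):
        rec = notch(sine_record([10.0]), 50.0)
        assert mid_amplitude(rec.samples[0], rec.rate) == pytest.approx(50.0, rel=0.02)

    def test_frequency_at_rate_rejected(self):
        with pytest.raises(ValueError):
            notch(sine_record([10.0]), 256.0)


class TestRereference:
    def test_average_reference_sums_to_zero(self, rng):
        rec = EEGRecord(rng.standard_normal((4, 500)), 100.0, list("ABCD"))
        out = rereference(rec, "average")
        assert np.allclose(out.samples.sum(axis=0), 0.0, atol=1e-10)

    def test_average_reference_is_idempotent(self, rng):
        rec = EEGRecord(rng.standard_normal((4, 500)), 100.0, list("ABCD"))
        once = rereference(rec, "average")
        twice = rereference(once, "average")
        assert np.allclose(once.samples, twice.samples, atol=1e-12)

    def test_common_reference_zeroes_target(self, rng):
        rec = EEGRecord(rng.standard_normal((3, 100)), 100.0, ["A", "B", "C"])
        out = rereference(rec, "common:B")
        assert np.allclose(out.channel("B"), 0.0)

    def test_bipolar_chain_telescopes(self, rng):
        # Fp1-F7 + F7-T3 telescopes to Fp1 referenced to T3
        v = {lab: rng.standard_normal(200) for lab in ("Fp1", "F7", "T3")}
        rec = EEGRecord(
            np.vstack([v["Fp1"] - v["F7"], v["F7"] - v["T3"]]),
            100.0,
            ["Fp1-F7", "F7-T3"],
        )
        out = rereference(rec, "common:T3")
        assert np.allclose(out.channel("Fp1"), v["Fp1"] - v["T3"], atol=1e-12)
        assert np.allclose(out.channel("F7"), v["F7"] - v["T3"], atol=1e-12)

    def test_disconnected_bipolar_montage_refused(self, rng):
        rec = EEGRecord(
            rng.standard_normal((2, 100)), 100.0, ["Fp1-F7", "O1-O2"]
        )
        with pytest.raises(MontageError, match="skip"):
            rereference(rec, "common:F7")

    def test_unknown_scheme_rejected(self, rng):
        rec = EEGRecord(rng.standard_normal((2, 50)), 100.0, ["A", "B"])
        with pytest.raises(ValueError):
            rereference(rec, "laplacian")


class TestResample:
    def test_sample_count_follows_rate_ratio(self, rng):
        rec = EEGRecord(rng.standard_normal((2, 30_000)), 2500.0, ["A", "B"])
        out = resample(rec, 250.0)
        assert out.samples.shape == (2, 3000)
        assert out.rate == 250.0
        assert abs(out.duration - rec.duration) <= 1 / 250.0

    def test_identity_resample(self, rng):
        rec = EEGRecord(rng.standard_normal((1, 1000)), 250.0, ["A"])
        out = resample(rec, 250.0)
        assert np.allclose(out.samples, rec.samples)

    def test_tone_survives_decimation(self):
        rate = 2500.0
        t = np.arange(int(4 * rate)) / rate
        rec = EEGRecord(np.sin(2 * np.pi * 10 * t)[None, :], rate, ["A"])
        out = resample(rec, 250.0)
        t2 = np.arange(out.samples.shape[1]) / 250.0
        ideal = np.sin(2 * np.pi * 10 * t2)
        sl = slice(100, -100)  # ignore boundary transients
        r = np.corrcoef(out.samples[0][sl], ideal[sl])[0, 1]
        assert r > 0.999


class TestFlatline:
    def test_constant_second_detected(self, rng):
        x = rng.standard_normal(1000)
        x[300:500] = 1.23
        assert has_flatline(x, rate=100.0)

    def test_short_plateau_ignored(self, rng):
        x = rng.standard_normal(1000)
        x[300:350] = 1.23  # half a second at 100 Hz
        assert not has_flatline(x, rate=100.0)

    def test_low_amplitude_noise_not_flat(self, rng):
        x = 1e-4 * rng.standard_normal(1000)
        assert not has_flatline(x, rate=100.0)


class TestSelectEpoch:
    def make_record(self, rng, minutes=20, rate=32.0):
        n = int(minutes * 60 * rate)
        return EEGRecord(rng.standard_normal((3, n)), rate, ["A", "B", "C"])

    def test_second_epoch_on_grid(self, rng):
        ep = select_epoch(self.make_record(rng), index=2, duration=300.0)
        assert ep.start_time == 300.0
        assert ep.duration == 300.0
        assert ep.meta["epoch_index"] == 2

    def test_sample_count_at_256hz(self, rng):
        rec = EEGRecord(rng.standard_normal((1, 2 * 76_800)), 256.0, ["A"])
        ep = select_epoch(rec, index=1, duration=300.0)
        assert ep.samples.shape == (1, 76_800)  # 5 * 60 * 256

    def test_flat_epoch_substituted(self, rng):
        rec = self.make_record(rng)
        n_per = int(300 * rec.rate)
        rec.samples[1, n_per + 100 : n_per + 200] = 0.5  # >1 s flat inside epoch 2
        ep = select_epoch(rec, index=2, duration=300.0)
        assert ep.start_time == 600.0
        assert ep.meta["substituted_from_index"] == 2

    def test_record_too_short_raises(self, rng):
        rec = EEGRecord(rng.standard_normal((1, 100)), 32.0, ["A"])
        with pytest.raises(ValueError, match="shorter"):
            select_epoch(rec, index=1, duration=300.0)

    def test_all_epochs_flat_raises(self, rng):
        rec = EEGRecord(np.ones((1, int(900 * 32.0))), 32.0, ["A"])
        with pytest.raises(ValueError, match="epoch"):
            select_epoch(rec, index=1, duration=300.0)

    def test_grid_is_exhaustive_and_disjoint(self, rng):
        rec = self.make_record(rng, minutes=15)
        starts = [
            select_epoch(rec, index=k, duration=300.0, skip_flat=False).start_time
            for k in (1, 2, 3)
        ]
        assert starts == [0.0, 300.0, 600.0]


class TestEdfRoundTrip:
    def test_write_read_identity_within_quantization(self, tmp_path, rng):
        samples = 40.0 * rng.standard_normal((3, 4 * 128))
        ep = EEGEpoch(samples, 128.0, ["C3", "T3", "T5"], start_time=0.0, duration=4.0)
        path = write_fixture(ep, tmp_path / "fix.edf", format="edf")
        rec = read_record(path, format="edf")
        assert rec.rate == 128.0
        assert rec.labels == ["C3", "T3", "T5"]
        # 16-bit quantization of the per-channel physical span
        for i in range(3):
            span = samples[i].max() - samples[i].min()
            assert np.max(np.abs(rec.samples[i] - samples[i])) < 2 * span / 65_536

    def test_channel_count_and_rate_metadata(self, tmp_path, rng):
        samples = rng.standard_normal((23, 2 * 256))
        labels = [f"EEG{i:02d}" for i in range(23)]
        ep = EEGEpoch(samples, 256.0, labels, start_time=0.0, duration=2.0)
        path = write_fixture(ep, tmp_path / "many.edf")
        rec = read_record(path)
        assert rec.rate == 256.0
        assert len(rec.labels) == 23

    def test_truncated_file_raises(self, tmp_path, rng):
        samples = rng.standard_normal((2, 256))
        ep = EEGEpoch(samples, 256.0, ["A", "B"], start_time=0.0, duration=1.0)
        path = write_fixture(ep, tmp_path / "t.edf")
        data = path.read_bytes()
        path.write_bytes(data[:100])  # cut inside the header
        with pytest.raises((ValueError, OSError)):
            read_record(path)

    def test_tabular_round_trip(self, tmp_path, rng):
        samples = rng.standard_normal((2, 64))
        ep = EEGEpoch(samples, 32.0, ["A", "B"], start_time=0.0, duration=2.0)
        path = write_fixture(ep, tmp_path / "fix.csv", format="csv")
        rec = read_record(path, format="csv")
        assert np.allclose(rec.samples, samples, atol=1e-6)
        assert rec.rate == pytest.approx(32.0)

    def test_annotations_round_trip(self, tmp_path):
        ann = [(123.456789, "seizure_onset"), (8000.0, "seizure_end")]
        path = write_annotations(ann, tmp_path / "ann.txt")
        back = read_annotations(path)
        assert back[0][1] == "seizure_onset"
        assert back[0][0] == pytest.approx(123.456789, abs=1e-6)
        assert back[1][0] == 8000.0
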