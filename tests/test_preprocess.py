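import numpy as np
import pytest

from neglect_eeg import preprocess as pp
from neglect_eeg.montage import make_montage

from conftest import make_recording


@pytest.fixture(scope="module")
def m32():
    return make_montage(32)


def tone(freq, rate, duration=60.0):
    return np.sin(2 * np.pi * freq * np.arange(0, duration, 1.0 / rate))


class TestBandpass:
    def test_dc_is_removed(self, m32):
        rec = make_recording(np.full((32, 2560), 5.0), m32, rate=256.0)
        out = pp.bandpass_filter(rec)
        assert np.abs(out.data).max() < 1e-3 * 5.0

    def test_passband_tone_preserved_at_zero_lag(self, m32):
        x = tone(10.0, 256.0)
        rec = make_recording(np.tile(x, (32, 1)), m32, rate=256.0)
        out = pp.bandpass_filter(rec)
        mid = slice(2560, -2560)
        gain = out.data[0, mid].std() / x[mid].std()
        assert abs(gain - 1.0) < 0.01
        xc = np.correlate(out.data[0, mid], x[mid], "full")
        lag = np.argmax(xc) - (len(x[mid]) - 1)
        assert lag == 0
        assert out.n_samples == rec.n_samples

    def test_stopband_attenuation_beyond_40db(self, m32):
        x = tone(60.0, 256.0)
        rec = make_recording(np.tile(x, (32, 1)), m32, rate=256.0)
        out = pp.bandpass_filter(rec)
        mid = slice(2560, -2560)
        att = 20 * np.log10(x[mid].std() / out.data[0, mid].std())
        assert att >= 40.0

    def test_band_edges_outside_nyquist_rejected(self, m32):
        rec = make_recording(np.zeros((32, 256)), m32, rate=128.0)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_filter(rec, 1.0, 70.0)


class TestResample:
    def test_decimation_length_arithmetic(self, m32):
        rec = make_recording(np.random.default_rng(0).standard_normal((32, 1024 * 360)), m32, rate=1024.0)
        out = pp.resample(rec, 128.0)
        assert abs(out.n_samples - rec.n_samples / 8) <= 1
        assert out.rate == 128.0

    def test_tone_survives_decimation(self, m32):
        x = tone(5.0, 1024.0)
        rec = make_recording(np.tile(x, (32, 1)), m32, rate=1024.0)
        out = pp.resample(rec, 128.0)
        ref = tone(5.0, 128.0, duration=out.n_samples / 128.0)[: out.n_samples]
        r = np.corrcoef(out.data[0][100:-100], ref[100:-100])[0, 1]
        assert r > 0.999

    def test_identity_when_rate_unchanged(self, m32):
        rec = make_recording(np.random.default_rng(1).standard_normal((32, 512)), m32)
        out = pp.resample(rec, 128.0)
        assert out.data is rec.data


class TestSphericalSpline:
    def test_smooth_field_reconstruction(self, m32):
        # low-order spherical-harmonic field over the cap
        field = 1.5 * m32.positions[:, 2] + 0.5 * m32.positions[:, 0]
        rec = make_recording(np.tile(field[:, None], (1, 200)), m32)
        out = pp.interpolate_bad_channels(rec, ["Cz"])
        i = m32.index("Cz")
        err = abs(out.data[i, 0] - field[i]) / np.sqrt((field**2).mean())
        assert err < 0.05
        good = [j for j in range(32) if j != i]
        assert np.array_equal(out.data[good], rec.data[good])
        assert any("interpolated" in note for note in out.provenance)

    def test_empty_bad_list_is_identity(self, m32):
        rec = make_recording(np.random.default_rng(2).standard_normal((32, 100)), m32)
        assert pp.interpolate_bad_channels(rec, []) is rec

    def test_too_many_bad_channels_rejected(self, m32):
        rec = make_recording(np.zeros((32, 100)), m32)
        with pytest.raises(ValueError, match="good"):
            pp.interpolate_bad_channels(rec, m32.labels[:30])


class TestAverageReference:
    def test_channel_mean_zero_and_idempotent(self, m32):
        rec = make_recording(np.random.default_rng(3).standard_normal((32, 500)) + 3.0, m32)
        out = pp.rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        again = pp.rereference_average(out)
        assert np.allclose(again.data, out.data, atol=1e-12)

    def test_symmetric_pair_unchanged(self):
        m = make_montage(32)
        data = np.zeros((32, 50))
        data[0] = 1.7
        data[1] = -1.7
        rec = make_recording(data, m)
        out = pp.rereference_average(rec)
        assert np.allclose(out.data, data)


class TestArtifactRejection:
    def test_exactly_the_spiked_window_is_removed(self, m32):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((32, 10 * 128)) * 5.0
        data[3, 4 * 128 + 10] = 200.0
        rec = make_recording(data, m32)
        out = pp.reject_artifact_segments(rec, 80.0, 1.0)
        assert out.n_samples == 9 * 128
        expected = np.hstack([data[:, : 4 * 128], data[:, 5 * 128 :]])
        assert np.array_equal(out.data, expected)
        assert list(out.segment_boundaries) == [4 * 128]

    def test_clean_data_identical(self, m32):
        rec = make_recording(np.random.default_rng(5).standard_normal((32, 640)), m32)
        assert pp.reject_artifact_segments(rec, 80.0, 1.0) is rec

    def test_zero_threshold_rejected(self, m32):
        rec = make_recording(np.zeros((32, 128)), m32)
        with pytest.raises(ValueError, match="positive"):
            pp.reject_artifact_segments(rec, 0.0, 1.0)


class TestOcularRemoval:
    @pytest.fixture()
    def blink(self):
        rng = np.random.default_rng(1)
        t = np.arange(2560)
        eog = np.zeros(2560)
        for c in rng.integers(100, 2460, 12):
            eog += np.exp(-0.5 * ((t - c) / 15.0) ** 2)
        return (eog - eog.mean()) / eog.std(), rng

    def test_planted_artifact_is_attenuated(self, m32, blink):
        eog, rng = blink
        clean = rng.standard_normal((32, 2560))
        mixed = clean.copy()
        mixed[:4] += 6 * eog
        rec = make_recording(mixed, m32)
        out = pp.remove_ocular_components(rec, eog, seed=0)
        before = abs(np.corrcoef(mixed[0], eog)[0, 1])
        after = abs(np.corrcoef(out.data[0], eog)[0, 1])
        assert after <= 0.5 * before

    def test_cutoff_one_is_identity(self, m32, blink):
        eog, rng = blink
        rec = make_recording(rng.standard_normal((32, 2560)), m32)
        out = pp.remove_ocular_components(rec, eog, cutoff=1.0, seed=0)
        assert np.array_equal(out.data, rec.data)


class TestMontageMapping:
    def test_downsample_64_to_32(self, montage64, montage32):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((64, 100))
        rec = make_recording(data, montage64)
        out = pp.map_to_common_montage(rec, montage32)
        assert out.montage.labels == montage32.labels
        for i, lab in enumerate(montage32.labels):
            assert np.array_equal(out.data[i], data[montage64.labels.index(lab)])

    def test_identity_mapping(self, montage32):
        rec = make_recording(np.zeros((32, 10)), montage32)
        assert pp.map_to_common_montage(rec, montage32) is rec

    def test_unknown_target_label_named(self, montage32):
        from neglect_eeg.montage import Montage

        bad = Montage(labels=["XX"], positions=np.array([[0.0, 0.0, 1.0]]))
        rec = make_recording(np.zeros((32, 10)), montage32)
        with pytest.raises(ValueError, match="channel XX not found"):
            pp.map_to_common_montage(rec, bad)


def test_full_chain_preserves_metadata_and_records_provenance(m32):
    rng = np.random.default_rng(7)
    data = rng.standard_normal((32, 256 * 30)) * 10.0
    data[5, 2000] = 500.0
    rec = make_recording(data, m32, rate=256.0, subject="P09", diagnosis="RHD")
    out = pp.preprocess_recording(rec)
    assert (out.subject, out.diagnosis, out.cohort) == ("P09", "RHD", "cohort1")
    assert out.rate == 128.0
    notes = " ".join(out.provenance)
    assert "bandpass" in notes and "resampled" in notes and "average" in notes
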