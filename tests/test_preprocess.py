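"""Filter design rule, referencing, resampling, band splitting, epoching."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from alphaffr import preprocess, synth
from alphaffr.preprocess import (
    FilterSpec,
    apply_fir,
    bandsplit,
    design_fir_bandpass,
    epoch,
    rereference,
    resample,
)


def _session(data, fs=5000.0, channels=None, events=None, condition="clear"):
    channels = channels or tuple(f"ch{i}" for i in range(data.shape[0]))
    if events is None:
        events = pd.DataFrame(
            {"onset_sample": [data.shape[1] // 2], "token": ["ba"],
             "polarity": [1], "block": [0]}
        )
    return synth.RecordingSession(
        data=np.asarray(data, dtype=np.float32), fs=fs,
        channel_labels=tuple(channels), events=events, condition=condition,
    )


class TestFilterDesign:
    @pytest.mark.parametrize(
        "band, n_taps, cutoffs",
        [
            ((100.0, 1000.0), 661, (87.5, 1125.0)),
            ((8.0, 12.0), 8251, (7.0, 13.5)),
            # floor rule does not bind at 18 Hz: transitions are 4.5/5.5 Hz
            ((18.0, 22.0), 3667, (15.75, 24.75)),
        ],
    )
    def test_printed_and_derived_designs(self, band, n_taps, cutoffs):
        spec = design_fir_bandpass(5000.0, *band)
        assert spec.n_taps == n_taps
        assert spec.minus6db_cutoffs == pytest.approx(cutoffs)
        assert spec.n_taps % 2 == 1

    def test_magnitude_response_claims(self):
        # unity passband center within the printed 0.02 dB ripple, and
        # >= 53 dB attenuation two transition widths outside the band
        spec = design_fir_bandpass(5000.0, 100.0, 1000.0)
        w, h = signal.freqz(spec.taps, worN=32768, fs=spec.fs)
        mag = np.abs(h)
        center = np.sqrt(100.0 * 1000.0)
        ripple_db = 20 * np.log10(mag[np.argmin(np.abs(w - center))])
        assert abs(ripple_db) < 0.02
        lo_probe = spec.band[0] - 2 * spec.transition_bw[0]
        hi_probe = spec.band[1] + 2 * spec.transition_bw[1]
        for probe in (lo_probe, hi_probe):
            att = -20 * np.log10(mag[np.argmin(np.abs(w - probe))] + 1e-300)
            assert att >= 53.0

    def test_minus6db_at_cutoffs(self):
        spec = design_fir_bandpass(5000.0, 8.0, 12.0)
        w, h = signal.freqz(spec.taps, worN=1 << 18, fs=spec.fs)
        for cut in spec.minus6db_cutoffs:
            mag = np.abs(h[np.argmin(np.abs(w - cut))])
            assert 20 * np.log10(mag) == pytest.approx(-6.02, abs=0.1)

    def test_design_is_pure(self):
        a = design_fir_bandpass(5000.0, 8.0, 12.0)
        b = design_fir_bandpass(5000.0, 8.0, 12.0)
        assert np.array_equal(a.taps, b.taps)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            design_fir_bandpass(5000.0, 100.0, 3000.0)
        with pytest.raises(ValueError):
            design_fir_bandpass(5000.0, 0.0, 100.0)

    def test_zero_phase_no_delay(self):
        # a 150 Hz tone passes the brainstem band with no phase shift
        spec = design_fir_bandpass(5000.0, 100.0, 1000.0)
        t = np.arange(5000) / 5000.0
        x = np.sin(2 * np.pi * 150 * t)
        y = apply_fir(x, spec)
        mid = slice(1000, 4000)
        assert np.corrcoef(x[mid], y[mid])[0, 1] > 0.99999


class TestRereference:
    def test_common_average_sums_to_zero(self):
        rng = np.random.default_rng(0)
        sess = _session(rng.normal(size=(4, 100)))
        out = rereference(sess, "common-average")
        assert np.abs(out.data.sum(axis=0)).max() < 1e-4

    def test_zero_mastoids_identity(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 50)).astype(np.float32)
        data[2:] = 0.0
        sess = _session(data, channels=("a", "b", "TP9", "TP10"))
        out = rereference(sess, "linked-mastoids")
        assert np.allclose(out.data, sess.data)

    def test_both_schemes_remove_common_offset(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(4, 64)).astype(np.float32)
        base -= base.mean(axis=0, keepdims=True)
        offset = rng.normal(size=64).astype(np.float32)
        sess = _session(base + offset, channels=("a", "b", "TP9", "TP10"))
        car = rereference(sess, "common-average")
        assert np.allclose(car.data, base, atol=1e-5)
        mast = rereference(sess, "linked-mastoids")
        ref = base[[2, 3]].mean(axis=0)
        assert np.allclose(mast.data, base - ref, atol=1e-5)

    def test_missing_mastoid_named(self):
        sess = _session(np.zeros((2, 10)), channels=("a", "TP9"))
        with pytest.raises(ValueError, match="TP10"):
            rereference(sess, "linked-mastoids")


class TestResample:
    def test_passband_tone_amplitude_preserved(self):
        fs = 20000.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 150 * t)[np.newaxis, :]
        sess = _session(x, fs=fs)
        out = resample(sess, 5000.0)
        amp = np.abs(out.data[0, 1000:-1000]).max()
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_event_index_rescaled(self):
        ev = pd.DataFrame({"onset_sample": [20000], "token": ["ba"],
                           "polarity": [1], "block": [0]})
        sess = _session(np.zeros((1, 40000)), fs=20000.0, events=ev)
        out = resample(sess, 5000.0)
        assert out.events["onset_sample"].iloc[0] == 5000

    def test_high_frequency_energy_removed(self):
        rng = np.random.default_rng(0)
        fs = 20000.0
        x = rng.normal(size=(1, int(fs)))
        sess = _session(x, fs=fs)
        out = resample(sess, 5000.0)
        f, pxx = signal.welch(out.data[0].astype(float), fs=5000.0, nperseg=1024)
        f0, pxx0 = signal.welch(x[0], fs=fs, nperseg=4096)
        hf_in = pxx0[(f0 > 2500)].sum() * (f0[1] - f0[0])
        hf_out = pxx[(f > 2450)].sum() * (f[1] - f[0])
        assert hf_out < 0.01 * hf_in

    def test_upsampling_refused(self):
        sess = _session(np.zeros((1, 100)), fs=5000.0)
        with pytest.raises(ValueError):
            resample(sess, 20000.0)


@pytest.fixture(scope="module")
def tone_session():
        fs = 5000.0
        t = np.arange(int(4 * fs)) / fs
        tone150 = np.sin(2 * np.pi * 150 * t)
        tone10 = np.sin(2 * np.pi * 10 * t)
        chans = list(synth.CHANNELS_32)
        data = np.zeros((32, t.size), dtype=np.float32)
        data[chans.index("Pz")] = tone150 + tone10
        data[chans.index("Oz")] = tone150 + tone10
        ev = pd.DataFrame({"onset_sample": [int(fs)], "token": ["ba"],
                           "polarity": [1], "block": [0]})
        return _session(data, fs=fs, channels=chans, events=ev)


class TestBandsplit:
    def test_band_selectivity(self, tone_session):
        streams = bandsplit(tone_session)
        mid = slice(5000, 15000)
        alpha = streams.alpha.data[0, mid].astype(float)

        def amp_at(x, f, fs=5000.0):
            t = np.arange(x.size) / fs
            return 2 * np.abs(np.mean(x * np.exp(-2j * np.pi * f * t)))

        assert amp_at(alpha, 10) > 0.95
        assert amp_at(alpha, 150) < 1e-3
        pz = list(synth.CHANNELS_32).index("Pz")
        ffr = streams.ffr.data[pz, mid].astype(float)
        assert amp_at(ffr, 150) > 0.9  # CAR subtracts 2/32 of the tone
        assert amp_at(ffr, 10) < 1e-3

    def test_opposite_poz_channels_cancel(self):
        fs = 5000.0
        t = np.arange(int(fs)) / fs
        s = np.sin(2 * np.pi * 10 * t)
        chans = list(synth.CHANNELS_32)
        data = np.zeros((32, t.size), dtype=np.float32)
        data[chans.index("Pz")] = s
        data[chans.index("Oz")] = -s
        sess = _session(data, fs=fs, channels=chans)
        streams = bandsplit(sess)
        assert np.abs(streams.alpha.data).max() < 1e-6


class TestEpoch:
    def test_sample_count_and_ta_exclusion(self, small_session):
        ep = epoch(small_session)
        assert ep.n_samples == 975  # 0.195 s at 5 kHz, half-open window
        assert not ep.metadata["token"].isin(["ta"]).any()
        n_frequent = (small_session.events["token"] != "ta").sum()
        assert ep.n_trials == n_frequent

    def test_impulse_alignment(self):
        fs = 5000.0
        data = np.zeros((1, 2000), dtype=np.float32)
        data[0, 1000] = 1.0
        ev = pd.DataFrame({"onset_sample": [1000], "token": ["pa"],
                           "polarity": [1], "block": [0]})
        sess = _session(data, fs=fs, events=ev)
        ep = epoch(sess)
        assert ep.data[0, 0, round(0.050 * fs)] == 1.0

    def test_constant_signal_lossless(self):
        fs = 5000.0
        data = np.full((1, 8000), 3.14, dtype=np.float32)
        ev = pd.DataFrame({"onset_sample": [1000, 3000, 5000],
                           "token": ["ba"] * 3, "polarity": [1, -1, 1],
                           "block": [0] * 3})
        sess = _session(data, fs=fs, events=ev)
        ep = epoch(sess)
        assert np.allclose(ep.data, 3.14)
        assert ep.n_trials == 3

    def test_edge_trials_dropped(self, caplog):
        fs = 5000.0
        data = np.zeros((1, 2000), dtype=np.float32)
        ev = pd.DataFrame({"onset_sample": [100, 1000, 1950],
                           "token": ["ba"] * 3, "polarity": [1, -1, 1],
                           "block": [0] * 3})
        sess = _session(data, fs=fs, events=ev)
        ep = epoch(sess)
        assert ep.n_trials == 1


class TestEpochsIO:
    def test_roundtrip(self, tmp_path):
        fs = 5000.0
        data = np.zeros((1, 4000), dtype=np.float32)
        ev = pd.DataFrame({"onset_sample": [1000, 2500], "token": ["ba", "pa"],
                           "polarity": [1, -1], "block": [0, 0]})
        sess = _session(data, fs=fs, events=ev)
        ep = epoch(sess)
        preprocess.save_epochs(ep, tmp_path / "epochs")
        back = preprocess.load_epochs(tmp_path / "epochs")
        assert np.array_equal(back.data, ep.data)
        assert back.fs == ep.fs and back.window == ep.window
        assert back.metadata["token"].tolist() == ep.metadata["token"].tolist()
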