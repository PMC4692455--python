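"""Filtering, epoching, spectral estimation and induced averaging."""

import json

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

from szdcm.forward import default_grid
from szdcm.preprocess import (EpochSequence, Recording, average_induced,
                              epoch_and_csd, filter_recording,
                              read_delimited, retained_fraction,
                              select_window_length, write_delimited)

FS = 512.0


def _sine(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilterRecording:
    def test_notch_attenuates_line_frequency(self):
        rec = Recording(_sine(50.0), FS)
        out = filter_recording(rec)
        spec_in = np.abs(rfft(rec.data[0]))
        spec_out = np.abs(rfft(out.data[0]))
        k = np.argmin(np.abs(rfftfreq(rec.data.shape[1], 1 / FS) - 50.0))
        atten_db = 20 * np.log10(spec_in[k] / spec_out[k])
        assert atten_db >= 20.0

    def test_passband_preserved(self):
        rec = Recording(_sine(10.0), FS)
        out = filter_recording(rec)
        mid = slice(1000, -1000)  # avoid edge transients
        ratio = np.std(out.data[0, mid]) / np.std(rec.data[0, mid])
        assert abs(ratio - 1.0) <= 0.05

    def test_dc_removed(self):
        rec = Recording(np.full(30 * int(FS), 3.0) + _sine(10.0, 30.0), FS)
        out = filter_recording(rec)
        interior = out.data[0, int(4 * FS):-int(4 * FS)]  # skip edge transients
        assert abs(np.mean(interior)) <= 1e-3 * 3.0

    def test_length_preserved(self):
        rec = Recording(_sine(5.0), FS)
        assert filter_recording(rec).data.shape == rec.data.shape

    def test_low_rate_rejected(self):
        rec = Recording(np.zeros(1000), 100.0)
        with pytest.raises(ValueError, match="140"):
            filter_recording(rec)


class TestEpochAndCsd:
    def test_fourteen_seconds_gives_seven_epochs(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal(int(14 * 256)), 256.0)
        seq = epoch_and_csd(rec)
        assert len(seq) == 7

    def test_trailing_partial_epoch_dropped(self):
        rec = Recording(np.random.default_rng(1).standard_normal(
            int(5.5 * FS)), FS)
        assert len(epoch_and_csd(rec)) == 2

    def test_auto_spectra_nonnegative(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.standard_normal(int(10 * FS)), FS)
        for ep in epoch_and_csd(rec):
            assert np.all(ep.csd.real >= 0)
            assert np.allclose(ep.csd.imag, 0)

    def test_white_noise_spectrum_flat(self):
        # average many epochs: the white-noise PSD is flat across the band
        rng = np.random.default_rng(3)
        rec = Recording(rng.standard_normal(int(200 * FS)), FS)
        seq = epoch_and_csd(rec)
        mean_psd = np.mean([ep.csd.real for ep in seq], axis=0)
        se = np.std([ep.csd.real for ep in seq], axis=0) / np.sqrt(len(seq))
        assert np.all(np.abs(mean_psd - mean_psd.mean()) <= 3 * se + 1e-12)

    def test_psd_scale_parseval(self):
        # band power from the CSD matches the brick-wall band variance
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(100 * FS))
        X = rfft(x)
        f = rfftfreq(x.size, 1 / FS)
        X[(f < 0.75) | (f > 40.25)] = 0.0
        var_t = np.var(np.fft.irfft(X, n=x.size))
        seq = epoch_and_csd(Recording(x, FS))
        psd = np.mean([ep.csd.real for ep in seq], axis=0)
        var_f = np.sum(psd) * 0.5  # df = 0.5 Hz
        assert abs(var_f - var_t) / var_t <= 0.10

    def test_multichannel_hermitian(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, int(6 * FS)))
        x[1] += 0.5 * x[0]
        seq = epoch_and_csd(Recording(x, FS))
        csd = seq[0].csd
        assert csd.shape == (79, 3, 3)
        assert np.allclose(csd, np.conj(np.swapaxes(csd, 1, 2)))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            epoch_and_csd(Recording(np.zeros(100), FS))

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        rec = Recording(rng.standard_normal(int(6 * FS)), FS)
        a = epoch_and_csd(rec)
        b = epoch_and_csd(Recording(rec.data.copy(), FS))
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.csd, eb.csd)


class TestWindowSelection:
    def _modulated(self, mod_hz=1.0, duration=16.0):
        t = np.arange(int(duration * FS)) / FS
        carrier = np.sin(2 * np.pi * 10 * t)
        env = 1.0 + 0.95 * np.sin(2 * np.pi * mod_hz * t)
        return Recording(env * carrier, FS)

    def test_stationary_signal_selects_largest(self):
        rec = Recording(_sine(10.0, duration=16.0), FS)
        L = select_window_length(rec, [500, 1000, 2000, 4000])
        assert L == 4000

    def test_modulated_signal_selects_short_window(self):
        L = select_window_length(self._modulated(), [250, 500, 1000, 2000, 4000])
        assert L <= 1000

    def test_retained_fraction_nonincreasing_in_window(self):
        rec = self._modulated()
        fracs = [retained_fraction(rec, L) for L in (250, 500, 1000, 2000, 4000)]
        assert all(a >= b - 0.02 for a, b in zip(fracs, fracs[1:]))

    def test_no_qualifying_candidate_falls_back(self, caplog):
        import logging
        rec = self._modulated()
        with caplog.at_level(logging.WARNING, logger="szdcm.preprocess"):
            L = select_window_length(rec, [2000, 4000], threshold=0.999)
        assert L == 2000.0
        assert any("falling back" in r.message for r in caplog.records)

    def test_unsorted_candidates_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            select_window_length(self._modulated(), [1000, 500])


class TestAverageInduced:
    def _noise_seq(self, seed, duration=8.0):
        rng = np.random.default_rng(seed)
        return epoch_and_csd(Recording(rng.standard_normal(int(duration * FS)), FS))

    def test_self_average_is_identity(self):
        seq = self._noise_seq(0)
        avg = average_induced([seq, seq])
        for a, b in zip(avg, seq):
            assert np.allclose(a.csd, b.csd)
            assert a.n_avg == 2

    def test_variance_shrinks_like_one_over_n(self):
        n = 20
        seqs = [self._noise_seq(100 + i) for i in range(n)]
        avg = average_induced(seqs)
        single_var = np.var([s[0].csd.real for s in seqs], axis=0).mean()
        resid = avg[0].csd.real - 2.0 / FS  # white-noise PSD level 2/fs
        # variance of the average ~ single-epoch variance / n
        assert np.var(resid) <= 3 * single_var / n

    def test_eleven_seizure_average_records_n(self):
        seqs = [self._noise_seq(i) for i in range(11)]
        avg = average_induced(seqs)
        assert avg.provenance["n_avg"] == 11
        assert all(ep.n_avg == 11 for ep in avg)

    def test_ragged_lengths(self):
        long, short = self._noise_seq(1, 8.0), self._noise_seq(2, 4.0)
        avg = average_induced([long, short])
        assert len(avg) == len(long)
        assert avg[0].n_avg == 2 and avg[-1].n_avg == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            average_induced([])


class TestIO:
    def test_delimited_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        rec = Recording(rng.standard_normal((2, 1000)), 256.0,
                        ch_names=["a", "b"],
                        annotations=[("seizure", 1.0, 3.0)])
        path = tmp_path / "rec.tsv"
        write_delimited(rec, path)
        back = read_delimited(path)
        assert np.allclose(back.data, rec.data)
        assert back.fs == 256.0
        assert back.ch_names == ["a", "b"]
        assert back.annotations == [("seizure", 1.0, 3.0)]

    def test_sequence_json_round_trip(self, tmp_path):
        seq = epoch_and_csd(Recording(
            np.random.default_rng(8).standard_normal(int(6 * FS)), FS))
        path = tmp_path / "seq.json"
        seq.to_json(path)
        back = EpochSequence.from_json(path)
        assert len(back) == len(seq)
        for a, b in zip(back, seq):
            assert np.allclose(a.csd, b.csd)
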