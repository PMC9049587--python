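"""Conditioning chain: decimation, wavelet sub-bands, slicing, balancing."""

import numpy as np
import pytest
import pywt

from ecgfusion.labels import ClassLabel
from ecgfusion.preprocess import (
    FoldAssignment,
    balance_subsets,
    downsample,
    preprocess_record,
    segment_starts,
    slice_record,
    wavelet_denoise,
    zscore,
)
from ecgfusion.record_io import ECGRecord


def record_from(signals, fs=500.0):
    return ECGRecord(signals=signals, fs=fs, labels=[ClassLabel.N],
                     record_id="t")


class TestDownsample:
    def test_factor_two_decimation(self):
        rec = record_from(np.random.default_rng(0).normal(size=(12, 5000)))
        out = downsample(rec, 250.0)
        assert out.fs == 250.0
        assert out.signals.shape == (12, 2500)

    def test_constant_signal_preserved(self):
        rec = record_from(np.full((12, 5000), 0.7))
        out = downsample(rec, 250.0)
        np.testing.assert_allclose(out.signals, 0.7, atol=1e-6)

    def test_sinusoid_amplitude_preserved(self):
        """A 10 Hz unit tone survives decimation within 1% (FFT oracle)."""
        t = np.arange(5000) / 500.0
        sig = np.tile(np.sin(2 * np.pi * 10.0 * t), (12, 1))
        out = downsample(record_from(sig), 250.0)
        spectrum = np.abs(np.fft.rfft(out.signals[0]))
        freqs = np.fft.rfftfreq(out.signals.shape[1], d=1 / 250.0)
        peak = freqs[spectrum.argmax()]
        amp = 2 * spectrum.max() / out.signals.shape[1]
        assert abs(peak - 10.0) < 0.2
        assert abs(amp - 1.0) < 0.01

    def test_upsampling_rejected(self):
        rec = record_from(np.zeros((12, 100)), fs=100.0)
        with pytest.raises(ValueError, match="below target"):
            downsample(rec, 250.0)


class TestWaveletDenoise:
    def test_perfect_reconstruction_without_zeroing(self):
        """The DWT itself is lossless: full-band inverse reproduces x."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        coeffs = pywt.wavedec(x, "db6", mode="symmetric", level=9)
        back = pywt.waverec(coeffs, "db6", mode="symmetric")[: len(x)]
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_baseline_wander_removed(self):
        """0.05 Hz drift lives in the discarded A9 band: <5% energy out."""
        t = np.arange(int(60 * 250)) / 250.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = wavelet_denoise(x, 250.0)
        assert np.sum(y ** 2) < 0.05 * np.sum(x ** 2)

    def test_qrs_band_retained(self):
        """10 Hz content sits in the retained D3..D9 bands: >=90% energy."""
        t = np.arange(int(60 * 250)) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = wavelet_denoise(x, 250.0)
        assert np.sum(y ** 2) >= 0.90 * np.sum(x ** 2)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 2048))
        a, b = 2.5, -1.3
        lhs = wavelet_denoise(a * x + b * y, 250.0)
        rhs = a * wavelet_denoise(x, 250.0) + b * wavelet_denoise(y, 250.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_too_short_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="512"):
            wavelet_denoise(np.zeros(100), 250.0)

    def test_output_length_matches_input(self):
        for n in (513, 1000, 1501):
            assert len(wavelet_denoise(np.random.default_rng(3).normal(size=n),
                                       250.0)) == n


class TestSlicing:
    def test_six_second_record_copied_ten_times(self):
        starts = segment_starts(1500, 1500)
        np.testing.assert_array_equal(starts, np.zeros(10, dtype=int))

    def test_sixty_second_record_disjoint(self):
        starts = segment_starts(15000, 1500)
        np.testing.assert_array_equal(starts, np.arange(10) * 1500)

    def test_intermediate_length_even_overlap(self):
        """33 s: starts i*750, adjacent slices overlap by half."""
        starts = segment_starts(8250, 1500)
        np.testing.assert_array_equal(starts, np.arange(10) * 750)

    def test_start_formula_general(self):
        n, seg = 4321, 1500
        expected = np.rint(np.arange(10) * (n - seg) / 9).astype(int)
        np.testing.assert_array_equal(segment_starts(n, seg), expected)

    def test_all_leads_share_starts(self):
        rng = np.random.default_rng(4)
        rec = record_from(rng.normal(size=(12, 2600)), fs=250.0)
        stacks = slice_record(rec)
        for s in stacks[1:]:
            np.testing.assert_array_equal(s.start_indices,
                                          stacks[0].start_indices)
        assert all(s.segments.shape == (10, 1500) for s in stacks)

    def test_short_record_zero_padded(self):
        rec = record_from(np.ones((12, 900)), fs=250.0)
        stacks = slice_record(rec, standardize=False)
        assert stacks[0].segments.shape == (10, 1500)
        np.testing.assert_array_equal(stacks[0].segments[0, 900:], 0.0)

    def test_wrong_rate_rejected(self):
        rec = record_from(np.zeros((12, 3000)), fs=500.0)
        with pytest.raises(ValueError, match="downsample"):
            slice_record(rec)


class TestZscore:
    def test_standardized_moments(self):
        out = zscore(np.array([1.0, 2.0, 3.0]))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_constant_segment_becomes_zeros(self):
        np.testing.assert_array_equal(zscore(np.full(100, 3.3)),
                                      np.zeros(100))

    @pytest.mark.parametrize("seed", range(5))
    def test_any_segment_standardized(self, seed):
        x = np.random.default_rng(seed).normal(5, 20, size=1500)
        out = zscore(x)
        assert abs(out.mean()) < 1e-9 and abs(out.std() - 1.0) < 1e-9


class TestChainDeterminism:
    def test_bit_identical_segment_stacks(self, normal_record):
        rec, _ = normal_record
        seg1, _ = preprocess_record(rec)
        seg2, _ = preprocess_record(rec)
        np.testing.assert_array_equal(seg1, seg2)
        assert seg1.shape == (12, 10, 1500)


class TestBalanceSubsets:
    @staticmethod
    def _mk(counts):
        recs = []
        for code, n in counts.items():
            cls = ClassLabel.from_code(code)
            recs += [(f"{code}{i}", cls) for i in range(n)]
        return recs

    def test_whole_replication_then_topup(self):
        """100 vs 40 in one subset: B doubled whole (80) + 20 random."""
        out = balance_subsets(self._mk({"N": 100, "AF": 40}), n_folds=1,
                              seed=0)
        by_cls = {c: [a for a in out if a.cls is c] for c in
                  (ClassLabel.N, ClassLabel.AF)}
        assert len(by_cls[ClassLabel.N]) == 100
        assert len(by_cls[ClassLabel.AF]) == 100
        af = by_cls[ClassLabel.AF]
        whole_replicas = [a for a in af if a.replica_of is not None]
        assert len(whole_replicas) == 60
        # every source appears at least twice (whole-set doubling)
        from collections import Counter
        src = Counter(a.source_id for a in af)
        assert min(src.values()) >= 2

    def test_random_topup_only_above_half(self):
        """100 vs 60: no whole replication, 40 random duplicates."""
        out = balance_subsets(self._mk({"N": 100, "AF": 60}), n_folds=1,
                              seed=0)
        af = [a for a in out if a.cls is ClassLabel.AF]
        assert len(af) == 100
        assert sum(a.replica_of is not None for a in af) == 40

    def test_balanced_input_unchanged(self):
        out = balance_subsets(self._mk({"N": 50, "AF": 50}), n_folds=1,
                              seed=0)
        assert all(a.replica_of is None for a in out)

    def test_per_fold_per_class_counts_equal(self):
        out = balance_subsets(self._mk({"N": 40, "AF": 25, "PVC": 10}),
                              n_folds=5, seed=1)
        for f in range(5):
            fold = [a for a in out if a.fold == f]
            counts = {c: sum(a.cls is c for a in fold)
                      for c in (ClassLabel.N, ClassLabel.AF, ClassLabel.PVC)}
            assert len(set(counts.values())) == 1

    def test_originals_partition_input(self):
        recs = self._mk({"N": 40, "AF": 25, "PVC": 10})
        out = balance_subsets(recs, n_folds=5, seed=1)
        originals = [a.record_id for a in out if a.replica_of is None]
        assert sorted(originals) == sorted(r for r, _ in recs)

    def test_replicas_stay_in_source_fold(self):
        out = balance_subsets(self._mk({"N": 40, "AF": 10}), n_folds=5,
                              seed=2)
        fold_of = {a.record_id: a.fold for a in out if a.replica_of is None}
        for a in out:
            if a.replica_of is not None:
                assert a.fold == fold_of[a.replica_of]

    def test_same_seed_same_assignment(self):
        recs = self._mk({"N": 20, "AF": 8})
        a = balance_subsets(recs, n_folds=2, seed=3)
        b = balance_subsets(recs, n_folds=2, seed=3)
        assert [(x.record_id, x.fold) for x in a] == \
               [(x.record_id, x.fold) for x in b]

    def test_assignments_serialize_to_table(self):
        from ecgfusion.preprocess import assignments_table

        out = balance_subsets(self._mk({"N": 10, "AF": 5}), n_folds=1, seed=0)
        table = assignments_table(out)
        assert list(table.columns) == ["record_id", "class", "fold",
                                       "replica_of"]
        assert len(table) == len(out)
        assert (table["replica_of"] != "").sum() == 5

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            balance_subsets(self._mk({"N": 20, "AF": 3}), n_folds=5, seed=0)
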