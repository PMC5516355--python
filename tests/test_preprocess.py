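"""Binning conventions, internal-standard normalization and QC, and the
replicate-averaged feature matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ladspectra as ls
from ladspectra.base import POSITIVE_LABEL, NEGATIVE_LABEL


def _rec(mz, inten, pid="p0", rep=0, label=POSITIVE_LABEL):
    return ls.SpectrumRecord(pid, rep, label, np.asarray(mz, float),
                             np.asarray(inten, float))


class TestBinning:
    def test_default_spec_has_5751_features(self):
        spec = ls.BinningSpec(low=500.0, high=12000.0, width=2.0)
        assert spec.n_features == 5751
        assert spec.bin_centers[0] == 500.0 and spec.bin_centers[-1] == 12000.0

    @given(low=st.floats(0, 1000), span=st.floats(10, 20000),
           width=st.floats(0.5, 50))
    @settings(max_examples=100, deadline=None)
    def test_length_law(self, low, span, width):
        spec = ls.BinningSpec(low=low, high=low + span, width=width)
        assert spec.n_features == int(np.floor((spec.high - spec.low) / spec.width)) + 1
        assert spec.bin_centers.size == spec.n_features

    def test_empty_peak_list_gives_zero_vector(self):
        out = ls.bin_spectrum(_rec([], []), ls.BinningSpec())
        assert out.shape == (5751,) and not out.any()

    def test_half_open_interval_convention(self):
        # bin centered at c covers [c-1, c+1): 500.9 -> 500, 501.1 -> 502
        spec = ls.BinningSpec(500.0, 12000.0, 2.0)
        out = ls.bin_spectrum(_rec([500.9, 501.1], [2.0, 3.0]), spec)
        assert out[0] == 2.0 and out[1] == 3.0 and out[2:].sum() == 0

    def test_peaks_in_same_bin_are_summed_and_out_of_range_dropped(self):
        spec = ls.BinningSpec(500.0, 600.0, 2.0)
        out = ls.bin_spectrum(_rec([100.0, 500.1, 500.3, 601.0, 5000.0],
                                   [9.0, 1.0, 2.0, 4.0, 9.0]), spec)
        assert out[0] == 3.0          # 500.1 + 500.3
        assert out.sum() == 3.0       # 601.0 >= 600+1 is outside; others dropped

    def test_mass_conservation_within_range(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(510, 590, 40))
        inten = rng.exponential(2.0, 40)
        spec = ls.BinningSpec(500.0, 600.0, 2.0)
        out = ls.bin_spectrum(_rec(mz, inten), spec)
        assert out.sum() == pytest.approx(inten.sum(), rel=1e-12)

    def test_unsorted_peaks_rejected_not_resorted(self):
        rec = _rec([500.0, 501.0], [1.0, 1.0])
        object.__setattr__(rec, "mz", np.array([501.0, 500.0]))
        with pytest.raises(ls.LADError, match="sorted"):
            ls.bin_spectrum(rec, ls.BinningSpec())


class TestNormalization:
    def test_divides_by_detected_standard(self):
        centers = np.array([5732.0, 5734.0, 5736.0])
        vec = np.array([1.0, 2.0, 0.5])
        out, det = ls.normalize_to_standard(vec, centers, 5734.5, window=10.0)
        assert det == (5734.0, 2.0)
        assert np.allclose(out, [0.5, 1.0, 0.25])

    def test_idempotent_when_standard_is_one(self):
        centers = np.array([5730.0, 5734.0, 5738.0])
        vec = np.array([0.3, 1.0, 0.7])
        out, _ = ls.normalize_to_standard(vec, centers, 5734.5)
        assert np.array_equal(out, vec)

    def test_mass_accuracy_qc_example(self):
        # detected 5,737.3 vs true 5,734.5: ~0.049%, inside the 0.06% bound
        err = ls.mass_error_pct(5737.3, 5734.5)
        assert err == pytest.approx(0.04883, abs=1e-4)
        assert err <= ls.MASS_ACCURACY_QC_PCT

    def test_no_bin_in_window_and_nonpositive_standard_raise(self):
        centers = np.array([100.0, 200.0])
        with pytest.raises(ls.NormalizationError, match="no bin"):
            ls.normalize_to_standard(np.ones(2), centers, 5734.5)
        with pytest.raises(ls.NormalizationError, match="<= 0"):
            ls.normalize_to_standard(np.zeros(2), np.array([5730.0, 5734.0]), 5734.5)


class TestFeatureMatrix:
    def test_cohort_shape_one_row_per_patient(self, recovery_cohort):
        matrix = recovery_cohort["matrix"]
        assert matrix.values.shape == (116, 201)
        assert len(set(matrix.patient_ids)) == 116

    def test_full_scale_shape_is_116_by_5751(self):
        cfg = ls.SyntheticConfig(seed=9, background_peak_count=40)
        matrix, _ = ls.build_feature_matrix(ls.generate_cohort(cfg))
        assert matrix.values.shape == (116, 5751)

    def test_identical_replicates_row_equals_replicate_and_r_one(self):
        mz = [500.5, 540.5, 5734.0]
        a = _rec(mz, [1.0, 3.0, 2.0], rep=0)
        b = _rec(mz, [1.0, 3.0, 2.0], rep=1)
        matrix, qc = ls.build_feature_matrix([a, b], ls.BinningSpec(500, 6000, 2))
        expect, _ = ls.normalize_to_standard(
            ls.bin_spectrum(a, ls.BinningSpec(500, 6000, 2)),
            ls.BinningSpec(500, 6000, 2).bin_centers, 5734.5)
        assert np.array_equal(matrix.values[0], expect)
        assert qc["per_patient"][0]["replicate_r"] == 1.0

    def test_scaled_replicates_identical_after_normalization(self):
        # replicate 2 = 2x replicate 1: normalization cancels the scale,
        # so the pre-averaging Pearson r is exactly 1
        mz = [500.5, 540.5, 5734.0]
        a = _rec(mz, [1.0, 3.0, 2.0], rep=0)
        b = _rec(mz, [2.0, 6.0, 4.0], rep=1)
        _, qc = ls.build_feature_matrix([a, b], ls.BinningSpec(500, 6000, 2))
        assert qc["per_patient"][0]["replicate_r"] == 1.0

    def test_conflicting_labels_rejected(self):
        a = _rec([5734.0], [1.0], rep=0, label=POSITIVE_LABEL)
        b = _rec([5734.0], [1.0], rep=1, label=NEGATIVE_LABEL)
        with pytest.raises(ls.LADError, match="conflicting labels"):
            ls.build_feature_matrix([a, b], ls.BinningSpec(500, 6000, 2))

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ls.ConfigError):
            ls.FeatureMatrix(["a"], [POSITIVE_LABEL], np.array([500.0]),
                             np.array([[-1.0]]))
        with pytest.raises(ls.ConfigError):
            ls.FeatureMatrix(["a", "b"], [POSITIVE_LABEL], np.array([500.0]),
                             np.array([[1.0]]))
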