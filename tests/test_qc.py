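"""Filtration, normalization and imputation cascade."""

import numpy as np
import pandas as pd
import pytest

from bloodvar.containers import BloodvarError
from bloodvar.qc import (
    filter_arrays,
    filter_probes,
    knn_impute,
    mask_flagged,
    qc_pipeline,
    quantile_normalize,
    resolve_replicates,
)

from conftest import make_annotations, make_expr


class TestMaskFlagged:
    def test_threshold_is_strict(self):
        expr = make_expr(np.ones((1, 3)), flags=[[9000, 8191, 0]])
        out = mask_flagged(expr)
        assert list(out.missing_mask.iloc[0]) == [True, False, False]

    def test_all_clear_is_identity(self):
        expr = make_expr(np.ones((2, 2)), flags=np.zeros((2, 2)))
        out = mask_flagged(expr)
        assert not out.missing_mask.to_numpy().any()

    def test_requires_flags(self):
        with pytest.raises(BloodvarError):
            mask_flagged(make_expr(np.ones((2, 2))))


class TestResolveReplicates:
    def _fixture(self, counts_per_array, n_probes=50):
        """Arrays with a prescribed number of probes at S/N > 3."""
        n = len(counts_per_array)
        snr = np.full((n_probes, n), 1.0)
        for j, c in enumerate(counts_per_array):
            snr[:c, j] = 5.0
        return make_expr(np.ones((n_probes, n)), snr=snr)

    def test_keeps_array_with_more_detected_probes(self):
        expr = self._fixture([12, 15])
        ann = make_annotations(subject="subj", subj=["A", "A"])
        out, report = resolve_replicates(expr, ann)
        assert list(out.sample_ids) == ["S001"]
        assert report.replicate_resolutions == [(("S000", "S001"), "S001")]

    def test_single_arrays_untouched(self):
        expr = self._fixture([10, 20])
        ann = make_annotations(subject="subj", subj=["A", "B"])
        out, report = resolve_replicates(expr, ann)
        assert out.n_samples == 2 and not report.excluded_arrays

    def test_triplicate_against_counting_oracle(self):
        counts = [10, 20, 30, 7]
        expr = self._fixture(counts)
        ann = make_annotations(subject="subj", subj=["A", "A", "A", "B"])
        out, _ = resolve_replicates(expr, ann)
        # oracle: count S/N>3 per array by brute force, keep argmax
        brute = [(expr.snr.iloc[:, j] > 3).sum() for j in range(3)]
        keep = f"S{int(np.argmax(brute)):03d}"
        assert keep in out.sample_ids and out.n_samples == 2

    def test_tie_broken_by_input_order(self):
        expr = self._fixture([15, 15])
        ann = make_annotations(subject="subj", subj=["A", "A"])
        out, _ = resolve_replicates(expr, ann)
        assert list(out.sample_ids) == ["S000"]


class TestArrayProbeFilters:
    def test_array_boundary_at_40_percent(self):
        # arrays at 39%, 40%, 100% detection of 100 probes
        snr = np.full((100, 3), 1.0)
        snr[:39, 0] = 3.0
        snr[:40, 1] = 3.0
        snr[:, 2] = 3.0  # >= 3 counts
        expr = make_expr(np.ones((100, 3)), snr=snr)
        out, report = filter_arrays(expr)
        assert [s for s, _ in report.excluded_arrays] == ["S000"]
        assert out.n_samples == 2

    def test_all_detected_identity(self):
        expr = make_expr(np.ones((10, 4)), snr=np.full((10, 4), 9.0))
        out, report = filter_arrays(expr)
        assert out.n_samples == 4 and not report.excluded_arrays

    def test_probe_boundary_at_50_percent(self):
        # 100 samples: probe detected in 49 vs 50 of them (strict > 3)
        snr = np.full((3, 100), 1.0)
        snr[0, :49] = 5.0
        snr[1, :50] = 5.0
        snr[2, :] = 5.0
        expr = make_expr(np.ones((3, 100)), snr=snr)
        out, report = filter_probes(expr)
        assert report.excluded_probes == ["P0000"]
        assert out.n_probes == 2

    def test_probe_kept_at_5_of_10(self):
        snr = np.full((1, 10), 1.0)
        snr[0, :5] = 4.0
        expr = make_expr(np.ones((1, 10)), snr=snr)
        out, _ = filter_probes(expr)
        assert out.n_probes == 1

    def test_snr_equal_3_not_detected_for_probe_rule(self):
        # probe rule uses strict "exceeds 3"
        snr = np.full((1, 10), 3.0)
        expr = make_expr(np.ones((1, 10)), snr=snr)
        out, _ = filter_probes(expr)
        assert out.n_probes == 0


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        expr = make_expr(np.array([[0.0, 2.0], [2.0, 4.0], [4.0, 6.0]]))
        out = quantile_normalize(expr)
        np.testing.assert_allclose(out.values.to_numpy(), [[1, 1], [3, 3], [5, 5]])

    def test_idempotent(self, rng):
        Y = rng.normal(7, 1, size=(50, 6))
        once = quantile_normalize(make_expr(Y))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
        )

    def test_column_distributions_identical_and_grand_mean_kept(self, rng):
        Y = rng.normal(7, 1, size=(80, 5))
        out = quantile_normalize(make_expr(Y)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-10)
        assert np.mean(out) == pytest.approx(np.mean(Y), abs=1e-10)

    def test_missing_aware_against_interpolation_oracle(self, rng):
        Y = rng.normal(0, 1, size=(30, 3))
        flags = np.zeros_like(Y)
        flags[4, 1] = 9000  # one missing cell
        expr = mask_flagged(make_expr(Y, flags=flags))
        out = quantile_normalize(expr)
        assert out.missing_mask.iloc[4, 1]  # missing preserved

        # oracle: build reference as mean of per-array quantile functions on
        # a common grid, then map each observed value through its rank
        G = Y.shape[0]
        grid = np.linspace(0, 1, G)
        qfuncs = []
        for j in range(3):
            obs = np.sort(Y[~expr.missing_mask.to_numpy()[:, j], j])
            qfuncs.append(np.interp(grid, np.linspace(0, 1, obs.size), obs))
        ref = np.mean(qfuncs, axis=0)
        col = Y[:, 0]
        ranks = np.argsort(np.argsort(col))
        expected = np.interp(ranks / (G - 1), grid, ref)
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], expected, atol=1e-10)

    def test_all_missing_array_rejected(self):
        Y = np.ones((3, 2))
        flags = np.zeros((3, 2))
        flags[:, 1] = 9999
        expr = mask_flagged(make_expr(Y, flags=flags))
        with pytest.raises(BloodvarError):
            quantile_normalize(expr)


class TestKnnImpute:
    def test_no_missing_is_identity(self, rng):
        expr = make_expr(rng.normal(size=(10, 5)))
        out, fb = knn_impute(expr)
        pd.testing.assert_frame_equal(out.values, expr.values)
        assert fb == []

    def test_duplicated_probe_exact_with_k1(self, rng):
        Y = rng.normal(size=(12, 6))
        Y[1] = Y[0]
        flags = np.zeros_like(Y)
        flags[0, 2] = 9000
        expr = mask_flagged(make_expr(Y, flags=flags))
        out, _ = knn_impute(expr, k=1)
        assert out.values.iloc[0, 2] == pytest.approx(Y[1, 2])

    def test_observed_cells_never_altered(self, rng):
        Y = rng.normal(size=(20, 8))
        flags = np.zeros_like(Y)
        flags[3, 1] = flags[7, 4] = 9000
        expr = mask_flagged(make_expr(Y, flags=flags))
        out, _ = knn_impute(expr)
        obs = ~expr.missing_mask.to_numpy()
        np.testing.assert_array_equal(
            out.values.to_numpy()[obs], expr.values.to_numpy()[obs]
        )
        assert not out.missing_mask.to_numpy().any()

    def test_fallback_to_probe_mean(self):
        # every other probe is missing at the target sample -> no neighbour
        Y = np.arange(12, dtype=float).reshape(3, 4)
        flags = np.zeros_like(Y)
        flags[:, 0] = 9000  # whole sample column unusable
        expr = mask_flagged(make_expr(Y, flags=flags))
        out, fallbacks = knn_impute(expr, k=2)
        assert fallbacks  # reported
        assert out.values.iloc[0, 0] == pytest.approx(np.mean(Y[0, 1:]))


class TestCascade:
    def test_order_and_reconciliation(self, rng):
        # planted violations: one flagged cell, one replicate pair, one
        # low-detection array, one low-detection probe
        G, n = 60, 12
        Y = rng.normal(7, 0.5, size=(G, n))
        snr = np.full((G, n), 9.0)
        flags = np.zeros((G, n))
        flags[0, 0] = 9000
        snr[:, 3] = 1.0
        snr[: int(0.39 * G), 3] = 3.0  # array at 39% (>=3 rule)
        snr[5, :] = 5.0
        snr[5, : n - 4] = 1.0  # probe detected in too few samples
        subj = [f"u{i}" for i in range(n)]
        subj[1] = subj[0]  # replicate pair
        snr[:, 1] = snr[:, 0]
        snr[10:, 1] = 1.0  # array 1 detects fewer probes than array 0
        ann = make_annotations(subject="subj", subj=subj)
        expr = make_expr(Y, snr=snr, flags=flags, sample_ids=list(ann.data.index))

        out, ann2, report = qc_pipeline(expr, ann)
        assert report.n_arrays_in == 12 and report.n_arrays_out == 10
        excluded = {s for s, _ in report.excluded_arrays}
        assert excluded == {"S001", "S003"}
        assert "P0005" in report.excluded_probes
        assert report.n_probes_out == report.n_probes_in - len(report.excluded_probes)
        assert not out.missing_mask.to_numpy().any()
        assert list(ann2.data.index) == list(out.sample_ids)
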