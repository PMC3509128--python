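"""Preprocessing chain: detection, background correction, normalization,
summarization, replicate QC."""

import numpy as np
import pandas as pd
import pytest

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.preprocess import (
    _normexp_correct,
    detection_calls,
    median_polish,
    median_polish_summarize,
    preprocess_pipeline,
    quantile_normalize,
    rma_background_correct,
    rolling_window_correlation,
    select_best_replicate,
)


def _spot_table(target_values, bg_values, feature="miR-x"):
    """One-array spot table with one target feature and one background probe pool."""
    rows = []
    for i, v in enumerate(target_values):
        rows.append((f"t-s{i}", "p-1", "arr1", v))
    for i, v in enumerate(bg_values):
        rows.append((f"b-s{i}", f"bg-{i}", "arr1", v))
    spots = pd.DataFrame(rows, columns=["spot_id", "probe_id", "array_id", "intensity"])
    annot = pd.DataFrame(
        [("p-1", feature, False, "gc1", "hsa")]
        + [(f"bg-{i}", "", True, "gc1", "none") for i in range(len(bg_values))],
        columns=["probe_id", "feature_id", "is_background", "gc_bin", "species"],
    )
    return spots, annot


class TestDetectionCalls:
    def test_clear_signal_called_present_with_exact_p(self):
        spots, annot = _spot_table([100.0, 101, 102, 103], list(np.linspace(1, 20, 20)))
        calls = detection_calls(spots, annot, alpha=0.05)
        p = calls.p_values.loc["miR-x", "arr1"]
        assert p == pytest.approx(1 / 10626, rel=1e-9)  # 1 / C(24, 4)
        assert bool(calls.present.loc["miR-x", "arr1"])

    def test_null_targets_rarely_present(self, rng):
        # target spots drawn from the background distribution: present
        # fraction over many features should approximate alpha
        n_feat, n_bg = 400, 20
        rows = []
        annot_rows = [(f"bg-{i}", "", True, "gc1", "none") for i in range(n_bg)]
        for i in range(n_bg):
            rows.append((f"b-{i}", f"bg-{i}", "arr1", rng.normal(50, 10)))
        for f in range(n_feat):
            annot_rows.append((f"p-{f}", f"feat-{f}", False, "gc1", "hsa"))
            for s in range(4):
                rows.append((f"t-{f}-{s}", f"p-{f}", "arr1", rng.normal(50, 10)))
        spots = pd.DataFrame(rows, columns=["spot_id", "probe_id", "array_id", "intensity"])
        annot = pd.DataFrame(
            annot_rows, columns=["probe_id", "feature_id", "is_background", "gc_bin", "species"]
        )
        frac = detection_calls(spots, annot, alpha=0.05).present.to_numpy().mean()
        assert 0.0 <= frac <= 0.12  # near alpha, discrete and conservative

    def test_monotone_in_target_intensity(self):
        bg = list(np.linspace(10, 40, 15))
        base = [20.0, 25, 30, 35]
        spots_lo, annot = _spot_table(base, bg)
        spots_hi, _ = _spot_table([v + 10 for v in base], bg)
        p_lo = detection_calls(spots_lo, annot).p_values.iloc[0, 0]
        p_hi = detection_calls(spots_hi, annot).p_values.iloc[0, 0]
        assert p_hi <= p_lo

    def test_orphan_gc_bin_rejected(self):
        spots, annot = _spot_table([1.0, 2, 3, 4], [1.5, 2.5])
        annot.loc[annot["probe_id"] == "p-1", "gc_bin"] = "gc9"
        with pytest.raises(ConfigurationError, match="gc9"):
            detection_calls(spots, annot)


class TestRmaBackgroundCorrect:
    def test_constant_array_stays_constant_positive(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": np.full(50, 7.0), "b": np.full(50, 3.0)}), scale="linear"
        )
        out = rma_background_correct(m)
        assert (out.values > 0).all()
        assert out.data["a"].nunique() == 1 and out.data["b"].nunique() == 1

    def test_subtracts_in_expectation_and_preserves_order(self, rng):
        x = np.clip(rng.exponential(30, 2000) + rng.normal(70, 15, 2000), 0.5, None)
        m = ExpressionMatrix(pd.DataFrame({"a": x}), scale="linear")
        out = rma_background_correct(m).data["a"].to_numpy()
        assert (out <= x + 1e-9).all()
        assert (out > 0).all()
        order = np.argsort(x)
        assert (np.diff(out[order]) >= -1e-9).all()

    def test_beats_naive_clipped_subtraction(self, rng):
        true = rng.exponential(30, 5000)
        x = np.clip(true + rng.normal(70, 15, 5000), 0.5, None)
        corrected = _normexp_correct(x)
        naive = np.clip(x - 70.0, 0.0, None)
        assert np.abs(corrected - true).mean() < np.abs(naive - true).mean()

    def test_rejects_nonpositive(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0, 2.0]}), scale="linear")
        m.data.iloc[0, 0] = -1.0
        with pytest.raises(ConfigurationError):
            rma_background_correct(m)


class TestQuantileNormalize:
    def test_hand_example(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": [2.0, 4, 6], "b": [1.0, 3, 5]}), scale="linear"
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.data["a"], [1.5, 3.5, 5.5])
        np.testing.assert_allclose(out.data["b"], [1.5, 3.5, 5.5])

    def test_identical_columns_unchanged_and_idempotent(self, rng):
        col = rng.normal(5, 2, 30)
        m = ExpressionMatrix(pd.DataFrame({"a": col, "b": col.copy()}), scale="linear")
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.data["a"], col)
        again = quantile_normalize(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-12)

    def test_columns_share_value_multiset_and_mean(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(rng.exponential(5, size=(40, 5)), columns=list("abcde")),
            scale="linear",
        )
        out = quantile_normalize(m)
        ref = np.sort(out.data["a"].to_numpy())
        for c in "bcde":
            np.testing.assert_allclose(np.sort(out.data[c].to_numpy()), ref, atol=1e-12)
        np.testing.assert_allclose(out.data.mean(), out.data.mean().iloc[0])

    def test_ties_share_spanned_quantile_mean(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]}), scale="linear"
        )
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out.data["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.data["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_sample_is_identity_with_warning(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0, 2.0]}), scale="linear")
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)


def _polish_oracle(x, tol=0.01, max_iter=10):
    """Straightforward re-implementation of iterative median polish used as
    an independent check of the library version."""
    z = [row[:] for row in x.tolist()]
    nr, nc = len(z), len(z[0])
    overall, rows, cols = 0.0, [0.0] * nr, [0.0] * nc
    import statistics

    old = 0.0
    for _ in range(max_iter):
        for i in range(nr):
            med = statistics.median(z[i])
            rows[i] += med
            for j in range(nc):
                z[i][j] -= med
        d = statistics.median(cols)
        overall += d
        cols = [c - d for c in cols]
        for j in range(nc):
            med = statistics.median(z[i][j] for i in range(nr))
            cols[j] += med
            for i in range(nr):
                z[i][j] -= med
        d = statistics.median(rows)
        overall += d
        rows = [r - d for r in rows]
        new = sum(abs(v) for row in z for v in row)
        if new == 0 or abs(new - old) < tol * new:
            break
        old = new
    return overall, rows, cols


class TestMedianPolish:
    def test_exactly_additive_matrix_recovered(self):
        overall, rows, cols, resid = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(overall + cols, [2.0, 3.0])
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_residual_medians_vanish(self, rng):
        x = rng.normal(size=(6, 9))
        _, _, _, resid = median_polish(x, tol=1e-9, max_iter=50)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6

    def test_matches_independent_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=(4, 6))
            overall, rows, cols, _ = median_polish(x)
            o2, r2, c2 = _polish_oracle(x)
            np.testing.assert_allclose(overall + cols, np.array(c2) + o2, atol=1e-8)

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=(5, 7))
        o1, _, c1, _ = median_polish(x)
        o2, _, c2, _ = median_polish(x + 3.5)
        np.testing.assert_allclose((o2 + c2) - (o1 + c1), 3.5, atol=1e-9)

    def test_single_spot_feature_degenerates_to_its_values(self):
        mat = pd.DataFrame({"a1": [1.0, 5.0], "a2": [2.0, 6.0]}, index=["s1", "s2"])
        feats = pd.Series({"s1": "fA", "s2": "fB"})
        out = median_polish_summarize(mat, feats)
        np.testing.assert_allclose(out.data.loc["fA"], [1.0, 2.0])
        np.testing.assert_allclose(out.data.loc["fB"], [5.0, 6.0])


class TestRollingWindow:
    def test_perfect_correlation_everywhere(self):
        x = np.arange(30.0)
        out = rolling_window_correlation(x, x, 5)
        np.testing.assert_allclose(out["r"], 1.0)
        assert len(out) == 26

    def test_window_equal_to_length_gives_single_point(self, rng):
        x = np.sort(rng.normal(size=99))
        y = rng.normal(size=99)
        out = rolling_window_correlation(x, y, 99)
        assert len(out) == 1
        assert out["abscissa"].iloc[0] == x[49]

    def test_matches_direct_recomputation_across_breakpoint(self, rng):
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.where(x < 5, rng.normal(size=60), x)  # noise then deterministic
        out = rolling_window_correlation(x, y, 11)
        for k in (0, 20, 49):
            expected = np.corrcoef(x[k : k + 11], y[k : k + 11])[0, 1]
            assert out["r"].iloc[k] == pytest.approx(expected, abs=1e-12)
        assert out["r"].iloc[-1] > out["r"].iloc[0]

    def test_invalid_width_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ConfigurationError):
            rolling_window_correlation(x, x, 4)
        with pytest.raises(ConfigurationError):
            rolling_window_correlation(x, x, 11)


class TestSelectBestReplicate:
    def test_identical_triplet_beats_noisy_fourth(self, rng):
        base = rng.normal(size=50)
        noisy = base + rng.normal(0, 5, 50)
        assert select_best_replicate([base, base.copy(), base.copy(), noisy]) < 3

    def test_two_replicates_tie_breaks_to_first(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert select_best_replicate([a, b]) == 0

    def test_hand_computed_argmax(self):
        t = np.linspace(0, 1, 40)
        reps = [np.sin(6 * t), np.sin(6 * t + 0.1), np.sin(6 * t + 0.9), np.cos(6 * t)]
        corr = np.corrcoef(np.vstack(reps))
        mean_r = (corr.sum(axis=1) - 1) / 3
        assert select_best_replicate(reps) == int(np.argmax(mean_r))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            select_best_replicate([np.arange(3.0), np.arange(4.0)])


class TestPreprocessPipeline:
    def test_replicates_collapse_to_one_column_per_sample(self):
        from conftest import small_design
        from mirpanel.synthetic import EffectSpec, simulate_panel

        design = small_design(n_replicate_samples=2, replicate_arrays=3)
        spots, annot, sheet, _ = simulate_panel(design, EffectSpec(), seed=3)
        assert sheet.shape[0] == 8 + 2 * 2  # 8 samples + 2 extra arrays x 2
        expr, calls, qc = preprocess_pipeline(spots, annot, sheet)
        assert expr.data.shape[1] == 8
        assert calls.p_values.shape[1] == 8
        assert set(qc["replicate_correlations"]) == set(
            sheet.groupby("sample_id").size()[lambda s: s > 1].index
        )

    def test_low_noise_replicates_highly_correlated(self):
        from conftest import small_design
        from mirpanel.synthetic import EffectSpec, simulate_panel

        design = small_design(n_replicate_samples=1, replicate_arrays=2)
        effects = EffectSpec(noise_sd=0.01, batch_sd=0.0, background_sd=1.0,
                             expressed_fraction=1.0, log2_expressed_range=(6.0, 10.0))
        spots, annot, sheet, _ = simulate_panel(design, effects, seed=5)
        _, _, qc = preprocess_pipeline(spots, annot, sheet)
        (info,) = qc["replicate_correlations"].values()
        assert min(info["pairwise_r"]) > 0.99

    def test_normalization_shrinks_batch_offsets(self):
        from conftest import small_design
        from mirpanel.synthetic import EffectSpec, simulate_panel

        design = small_design()
        effects = EffectSpec(batch_sd=1.0, expressed_fraction=1.0, log2_expressed_range=(4.0, 10.0))
        spots, annot, sheet, _ = simulate_panel(design, effects, seed=9)
        expr, _, _ = preprocess_pipeline(spots, annot, sheet)
        batch_of = sheet.set_index("sample_id")["batch"]
        # raw per-array mean log2 target-spot intensity, before any correction
        raw = spots.merge(sheet[["array_id", "sample_id"]], on="array_id")
        raw = raw[raw["probe_id"].str.startswith("p-")]
        raw_means = np.log2(raw.groupby("sample_id")["intensity"].mean())
        post_means = expr.data.mean()
        raw_spread = raw_means.groupby(batch_of).mean().std()
        post_spread = post_means.groupby(batch_of).mean().std()
        assert post_spread < raw_spread
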