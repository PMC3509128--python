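"""Clustering and moderated-t differential expression."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import random_log2_matrix
from mirpanel.groups import (
    EBHyperparams,
    cluster_samples,
    estimate_eb_hyperparameters,
    fit_moderated_t,
    mutation_de,
    one_vs_rest_de,
    top_k_by_p,
    uncentered_pearson_distance,
    z_scale_rows,
)
from mirpanel.matrix import ConfigurationError, ExpressionMatrix


class TestUncenteredDistance:
    def test_proportional_orthogonal_antiproportional(self):
        assert uncentered_pearson_distance([1, 2], [2, 4]) == pytest.approx(0.0)
        assert uncentered_pearson_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert uncentered_pearson_distance([1, 2], [-1, -2]) == pytest.approx(2.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ConfigurationError):
            uncentered_pearson_distance([0, 0], [1, 2])


class TestClusterSamples:
    def _two_group_matrix(self, rng, sep=6.0):
        g1 = rng.normal(5, 0.5, size=(30, 6))
        g2 = rng.normal(5, 0.5, size=(30, 6))
        g2[:15] += sep
        data = pd.DataFrame(
            np.hstack([g1, g2]),
            index=[f"f{i}" for i in range(30)],
            columns=[f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)],
        )
        return ExpressionMatrix(data, scale="log2")

    def test_planted_groups_recovered_exactly(self, rng):
        m = self._two_group_matrix(rng)
        dendro = cluster_samples(m)
        cut = dendro.cut(2)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, [cut[s] for s in m.samples]) == 1.0

    def test_duplicated_sample_merges_first_at_zero_height(self, rng):
        m = random_log2_matrix(rng, n=5)
        dup = m.data.copy()
        dup["s00b"] = dup["s00"]
        dendro = cluster_samples(ExpressionMatrix(dup, scale="log2"))
        assert dendro.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])}
        labels = list(dup.columns)
        assert {labels[i] for i in first} == {"s00", "s00b"}

    def test_three_sample_average_linkage_hand_trace(self):
        # distances chosen so (s1, s2) merge first, then s3 joins at the
        # average of its distances to s1 and s2
        data = pd.DataFrame(
            {"s1": [1.0, 0.0, 0.1], "s2": [1.0, 0.1, 0.0], "s3": [0.0, 1.0, 1.0]},
            index=["f1", "f2", "f3"],
        )
        m = ExpressionMatrix(data, scale="log2")
        d12 = uncentered_pearson_distance(data["s1"], data["s2"])
        d13 = uncentered_pearson_distance(data["s1"], data["s3"])
        d23 = uncentered_pearson_distance(data["s2"], data["s3"])
        dendro = cluster_samples(m, optimize_leaf_order=False)
        assert {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])} == {0, 1}
        assert dendro.linkage[0, 2] == pytest.approx(d12)
        assert dendro.linkage[1, 2] == pytest.approx((d13 + d23) / 2)

    def test_sample_order_invariant_topology(self, rng):
        m = self._two_group_matrix(rng)
        shuffled_cols = list(rng.permutation(m.data.columns))
        m2 = ExpressionMatrix(m.data[shuffled_cols], scale="log2")
        cut1 = cluster_samples(m).cut(2)
        cut2 = cluster_samples(m2).cut(2)
        labels = list(m.samples)
        assert adjusted_rand_score(
            [cut1[s] for s in labels], [cut2[s] for s in labels]
        ) == 1.0

    def test_newick_roundtrips_all_leaves(self, rng):
        m = random_log2_matrix(rng, n=6)
        newick = cluster_samples(m).to_newick()
        assert newick.endswith(";")
        for s in m.samples:
            assert s in newick


class TestModeratedT:
    def test_no_shrinkage_limit_equals_classic_t(self, rng):
        m = random_log2_matrix(rng, m=50, n=10)
        a, b = list(m.samples[:5]), list(m.samples[5:])
        records = fit_moderated_t(m, a, b, EBHyperparams(d0=0.0, s0_sq=1.0))
        classic = stats.ttest_ind(
            m.data[a], m.data[b], axis=1, equal_var=True
        )
        np.testing.assert_allclose(records["t"], classic.statistic, atol=1e-10)
        np.testing.assert_allclose(records["p"], classic.pvalue, atol=1e-10)

    def test_infinite_prior_fixes_variance_at_prior(self, rng):
        m = random_log2_matrix(rng, m=30, n=8)
        a, b = list(m.samples[:4]), list(m.samples[4:])
        records = fit_moderated_t(m, a, b, EBHyperparams(d0=np.inf, s0_sq=2.0))
        expected_se = np.sqrt(2.0 * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(
            records["t"], records["diff"] / expected_se, atol=1e-10
        )

    def test_null_rejection_rate_near_nominal(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = random_log2_matrix(rng, m=500, n=12)
            records = fit_moderated_t(m, list(m.samples[:6]), list(m.samples[6:]))
            fracs.append((records["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_sign_matches_mean_difference(self, rng):
        m = random_log2_matrix(rng, m=40, n=10)
        records = fit_moderated_t(m, list(m.samples[:5]), list(m.samples[5:]))
        assert (np.sign(records["t"]) == np.sign(records["diff"])).all()

    def test_group_overlap_and_small_groups_rejected(self, rng):
        m = random_log2_matrix(rng, n=6)
        with pytest.raises(ConfigurationError):
            fit_moderated_t(m, list(m.samples[:3]), list(m.samples[2:]))
        with pytest.raises(ConfigurationError):
            fit_moderated_t(m, [m.samples[0]], list(m.samples[1:]))

    def test_matches_limma_oracle(self, rng, tmp_path):
        """Dual-route check: our EB machinery against Bioconductor limma."""
        m, na, nb = 80, 5, 7
        x = rng.normal(5, 1, size=(m, na + nb))
        x[:10, :na] += 1.5
        cols = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
        df = pd.DataFrame(x, index=[f"f{i}" for i in range(m)], columns=cols)
        df.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))
            design <- cbind(Intercept=1, A=c(rep(1,{na}), rep(0,{nb})))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"],
                              d0=fit$df.prior, s0sq=fit$s2.prior)
            write.csv(out, "{tmp_path}/limma_out.csv")
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R")], check=True, capture_output=True
        )
        limma = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        ours = fit_moderated_t(ExpressionMatrix(df, "log2"), cols[:na], cols[na:])
        hyper = estimate_eb_hyperparameters(ours["s2"].to_numpy(), na + nb - 2)
        assert hyper.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-6)
        assert hyper.s0_sq == pytest.approx(limma["s0sq"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(ours["t"], limma["t"], atol=1e-9)
        np.testing.assert_allclose(ours["p"], limma["p"], atol=1e-9)


class TestEBHyperparameters:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        d0, s0sq, dg, m = 4.0, 1.0, 10, 5000
        true_var = s0sq * d0 / rng.chisquare(d0, size=m)
        s_sq = true_var * rng.chisquare(dg, size=m) / dg
        h = estimate_eb_hyperparameters(s_sq, dg)
        assert h.d0 == pytest.approx(d0, rel=0.25)
        assert h.s0_sq == pytest.approx(s0sq, rel=0.10)

    def test_zero_dispersion_gives_infinite_d0(self):
        h = estimate_eb_hyperparameters(np.full(50, 1.7), 8)
        assert np.isinf(h.d0)
        assert h.s0_sq > 0

    def test_too_few_features_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_eb_hyperparameters(np.array([1.0, 2.0]), 8)


class TestOneVsRest:
    def _sheet(self, samples, tissues):
        return pd.DataFrame(
            {"array_id": samples, "sample_id": samples, "cell_line": samples,
             "tissue": tissues, "day": 1, "batch": "b1"}
        )

    def test_complement_swap_flips_signs(self, rng):
        m = random_log2_matrix(rng, m=30, n=10)
        samples = list(m.samples)
        sheet = self._sheet(samples, ["X"] * 4 + ["Y"] * 6)
        res = one_vs_rest_de(m, sheet)
        np.testing.assert_allclose(
            res["X"]["diff"].to_numpy(), -res["Y"]["diff"].to_numpy(), atol=1e-12
        )

    def test_tiny_tissue_skipped_with_warning(self, rng):
        m = random_log2_matrix(rng, m=30, n=9)
        samples = list(m.samples)
        sheet = self._sheet(samples, ["X"] * 4 + ["Y"] * 4 + ["Z"])
        with pytest.warns(UserWarning, match="Z"):
            res = one_vs_rest_de(m, sheet)
        assert set(res) == {"X", "Y"}


class TestMutationDE:
    def _mutation_table(self, lines, mutants):
        return pd.DataFrame(
            {"cell_line": lines, "gene": "G", "status": [int(s in mutants) for s in lines]}
        )

    def test_below_min_mutants_refused_with_explanation(self, rng):
        m = random_log2_matrix(rng, n=10)
        lines = list(m.samples)
        muts = self._mutation_table(lines, set(lines[:3]))
        with pytest.raises(ConfigurationError, match="3 mutant"):
            mutation_de(m, muts, "G", min_mutants=10)

    def test_planted_effect_recovered_exactly(self):
        # two features shifted by 1.5x the noise SD between 30 mutant and
        # 29 wild-type lines should be the only discoveries in nearly
        # every seed
        hits, exact = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise_sd = 1.5  # matches the generator in random_log2_matrix
            m = random_log2_matrix(rng, m=300, n=59)
            lines = list(m.samples)
            mutants = set(lines[:30])
            m.data.loc[["f000", "f001"], list(mutants)] += 1.5 * noise_sd
            muts = self._mutation_table(lines, mutants)
            records = mutation_de(m, muts, "G", min_mutants=10)
            sig = set(records.loc[records["significant"], "feature"])
            if {"f000", "f001"} <= sig:
                hits += 1
            if sig == {"f000", "f001"}:
                exact += 1
        assert hits >= 9
        assert exact >= 8


class TestTopKAndZScale:
    def _records(self, ps, features=None):
        features = features or [f"f{i}" for i in range(len(ps))]
        return pd.DataFrame({"feature": features, "p": ps})

    def test_top_k_dominates_excluded(self, rng):
        records = self._records(list(rng.uniform(size=72)))
        top = top_k_by_p(records, 8)
        worst = records.set_index("feature").loc[top, "p"].max()
        rest = records[~records["feature"].isin(top)]["p"]
        assert (rest >= worst).all()

    def test_tie_breaks_lexicographically(self):
        records = self._records([0.5, 0.1, 0.5], features=["zz", "aa", "bb"])
        assert top_k_by_p(records, 2) == ["aa", "bb"]

    def test_overlong_k_warns_and_returns_all(self, rng):
        records = self._records([0.1, 0.2])
        with pytest.warns(UserWarning):
            assert len(top_k_by_p(records, 5)) == 2

    def test_matches_sort_oracle(self, rng):
        records = self._records(list(rng.uniform(size=40)))
        expected = records.sort_values(["p", "feature"]).head(7)["feature"].tolist()
        assert top_k_by_p(records, 7) == expected

    def test_z_scale_hand_example_and_affine_invariance(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=["a", "b", "c"]),
            scale="log2",
        )
        np.testing.assert_allclose(z_scale_rows(m).data.loc["f"], [-1, 0, 1])
        x = random_log2_matrix(rng)
        y = ExpressionMatrix(x.data.mul(3.0).add(2.0), scale="log2")
        pd.testing.assert_frame_equal(z_scale_rows(x).data, z_scale_rows(y).data)
        out = z_scale_rows(x)
        np.testing.assert_allclose(out.data.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_zero_variance_row_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"], columns=list("abc")),
            scale="log2",
        )
        with pytest.raises(ConfigurationError, match="flat"):
            z_scale_rows(m)
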