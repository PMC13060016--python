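import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphprot import diffabund
from dimorphprot.diffabund import (
    ModeratedTTest,
    bh_adjust,
    call_qualitative,
    call_quantitative,
    log2_transform,
    merge_bias,
    pca,
)

from conftest import make_matrix


def _design(n_a, n_e):
    rows = []
    for m, n in (("A", n_a), ("E", n_e)):
        for b in range(1, n + 1):
            rows.append({"run_id": f"r{m}{b}", "morph": m, "bio_rep": str(b), "tech_rep": "1"})
    return pd.DataFrame(rows)


class TestLog2:
    def test_values_and_missing_preserved(self):
        bio = make_matrix([[8.0, 1.0, np.nan]])
        out = log2_transform(bio)
        assert out.iloc[0, 0] == 3.0 and out.iloc[0, 1] == 0.0
        assert np.isnan(out.iloc[0, 2])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            log2_transform(make_matrix([[-1.0, 2.0]]))


def brute_force_bh(p):
    """Step-up definition computed literally: padj_i = min over p_j >= p_i
    of m*p_j/rank_j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    out = np.empty(m)
    for i in range(m):
        out[i] = min(min(m * ranked[j] / (j + 1) for j in range(m) if ranked[j] >= p[i] - 1e-300), 1.0)
    return out


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        padj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(padj[order]) >= -1e-15).all()
        assert (padj >= p - 1e-15).all()


class TestModeratedT:
    def _fixture(self, seed=0, n_feat=40, n0=5, n1=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n0 + n1, n_feat))
        X[n0:, : n_feat // 2] += 1.0
        y = np.array(["g0"] * n0 + ["g1"] * n1)
        return X, y

    def test_prior_df_zero_equals_pooled_t_test(self):
        X, y = self._fixture()
        est = ModeratedTTest(prior_df=0).fit(X, y)
        t_ref, p_ref = stats.ttest_ind(X[y == "g1"], X[y == "g0"], equal_var=True)
        assert np.allclose(est.t_, t_ref, atol=1e-10)
        assert np.allclose(est.p_, p_ref, atol=1e-10)

    def test_infinite_prior_df_shares_one_variance(self):
        X, y = self._fixture(seed=1)
        est = ModeratedTTest(prior_df=np.inf).fit(X, y)
        assert np.allclose(est.s2_posterior_, est.s2_posterior_[0])
        assert np.isinf(est.df_total_).all()

    def test_posterior_variance_interpolates(self):
        X, y = self._fixture(seed=2)
        est = ModeratedTTest().fit(X, y)
        lo = np.minimum(est.s2_, est.prior_s2_)
        hi = np.maximum(est.s2_, est.prior_s2_)
        assert ((est.s2_posterior_ >= lo - 1e-12) & (est.s2_posterior_ <= hi + 1e-12)).all()

    def test_moment_estimator_recovers_a_common_variance(self):
        # all proteins share sigma^2 = 0.49: d0 should blow up, s0^2 ~ truth
        rng = np.random.default_rng(3)
        X = rng.normal(0, 0.7, (11, 200))
        y = np.array(["g0"] * 5 + ["g1"] * 6)
        est = ModeratedTTest().fit(X, y)
        assert est.prior_s2_ == pytest.approx(0.49, rel=0.2)
        assert est.prior_df_ > 20

    def test_effect_is_group1_minus_group0(self):
        X = np.array([[0.0, 1.0], [0.1, 2.0], [3.0, 1.5], [3.1, 2.5]])
        y = np.array(["g0", "g0", "g1", "g1"])
        est = ModeratedTTest(prior_df=0).fit(X, y)
        assert est.effect_[0] == pytest.approx(3.0)

    def test_degenerate_all_zero_variance_rejected(self):
        X = np.tile([[1.0, 2.0]], (6, 1))
        y = np.array(["g0"] * 3 + ["g1"] * 3)
        with pytest.raises(ValueError, match="zero"):
            ModeratedTTest().fit(X, y)

    def test_missing_values_rejected(self):
        X, y = self._fixture()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            ModeratedTTest().fit(X, y)

    def test_wrapper_contrast_is_apyrene_minus_eupyrene(self):
        design = _design(3, 3)
        bio = make_matrix(
            np.column_stack([np.full(3, 9.0), np.full(3, 7.0)]).T.reshape(1, 6) +
            np.arange(6) * 0.0,
            proteins=["P0"],
            runs=[f"{m}_{b}" for m in "AE" for b in (1, 2, 3)],
        )
        # add a second protein so variance fitting has >=2 features
        bio.loc["P1"] = [5.0, 5.1, 4.9, 5.0, 5.2, 4.8]
        table = diffabund.moderated_ttest(bio, design, prior_df=0)
        assert table.at["P0", "log2fc"] == pytest.approx(2.0)


class TestCalls:
    def _table(self, padj, lfc):
        return pd.DataFrame({"log2fc": lfc, "p": padj, "padj": padj},
                            index=[f"P{i}" for i in range(len(lfc))])

    @pytest.mark.parametrize(
        "padj, lfc, expected",
        [
            (0.01, 1.0, "A_biased"),     # 2-fold up, significant
            (0.01, 0.3, "none"),         # 1.23-fold: below the 1.5-fold floor
            (0.20, 3.0, "none"),         # large but not significant
            (0.01, -0.9, "E_biased"),    # 1.87-fold down
            (0.049, np.log2(1.5), "A_biased"),  # boundary: exactly 1.5-fold counts
        ],
    )
    def test_quantitative_thresholds(self, padj, lfc, expected):
        out = call_quantitative(self._table([padj], [lfc]))
        assert out.at["P0", "quant_call"] == expected

    @pytest.mark.parametrize(
        "obs_a, obs_e, expected",
        [(5, 1, "A_only"), (4, 2, "none"), (0, 6, "E_only"),
         (4, 1, "A_only"), (3, 0, "none"), (1, 4, "E_only")],
    )
    def test_qualitative_presence_rule(self, obs_a, obs_e, expected):
        n_a, n_e = 5, 6
        row = ([10.0] * obs_a + [np.nan] * (n_a - obs_a)
               + [12.0] * obs_e + [np.nan] * (n_e - obs_e))
        bio = make_matrix([row], proteins=["P0"],
                          runs=[f"A_{i+1}" for i in range(n_a)] + [f"E_{i+1}" for i in range(n_e)])
        call = call_qualitative(bio, _design(n_a, n_e))
        assert call["P0"] == expected

    def test_qualitative_auto_scaling(self):
        # 8 replicates per morph: auto threshold = ceil(0.75*8) = 6
        n = 8
        row = [10.0] * 6 + [np.nan] * 2 + [np.nan] * 7 + [12.0]
        bio = make_matrix([row], proteins=["P0"],
                          runs=[f"A_{i+1}" for i in range(n)] + [f"E_{i+1}" for i in range(n)])
        assert call_qualitative(bio, _design(n, n), min_present="auto")["P0"] == "A_only"

    def test_merge_union_and_conflict(self):
        t = pd.DataFrame(
            {
                "quant_call": ["A_biased", "none", "none", "E_biased"],
                "qual_call": ["none", "E_only", "none", "E_only"],
            },
            index=["P0", "P1", "P2", "P3"],
        )
        out = merge_bias(t)
        assert out["bias"].tolist() == ["A_biased", "E_biased", "unbiased", "E_biased"]

        t.at["P3", "qual_call"] = "A_only"
        with pytest.raises(ValueError, match="P3"):
            merge_bias(t)


class TestPCA:
    def test_two_cluster_construction(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 0.01, (50, 8))
        base[:, 4:] += 5.0  # two groups of samples with distinct protein means
        mat = make_matrix(base)
        res = pca(mat)
        pc1 = res.scores["PC1"]
        assert (pc1.iloc[:4] * pc1.iloc[4:].mean() < 0).all()  # groups on opposite sides
        assert res.variance_explained[0] > 0.95

    def test_identical_samples_give_zero_eigenvalues(self):
        mat = make_matrix(np.tile([[1.0], [2.0], [3.0]], (1, 5)))
        res = pca(mat)
        assert np.allclose(res.scores.to_numpy(), 0.0, atol=1e-12)

    def test_variance_fractions_sorted_and_bounded(self, small_bundle):
        from dimorphprot import analyze

        res = analyze(small_bundle.abundance, small_bundle.design)
        ve = res.pca.variance_explained
        assert (np.diff(ve) <= 1e-12).all() and 0 < ve.sum() <= 1 + 1e-9

    def test_top_n_restricts_to_most_variable(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.1, (30, 6))
        X[:3] += rng.normal(0, 10, (3, 6))
        full = pca(make_matrix(X))
        top = pca(make_matrix(X), top_n=3)
        assert top.scores.shape == (6, 3)  # components bounded by protein count
        assert full.scores.shape == (6, 5)
        # the high-variance proteins dominate: leading scores barely change
        assert abs(np.corrcoef(top.scores["PC1"], full.scores["PC1"])[0, 1]) > 0.999

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca(make_matrix([[1.0, 2.0]]))
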