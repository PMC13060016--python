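import numpy as np
import pandas as pd
import pytest

from dimorphprot.missingness import (
    ImputationParams,
    MinDetImputer,
    MLEImputer,
    classify_missingness,
    filter_sporadic,
    impute_mindet,
    impute_mle,
    mixed_impute,
)

from conftest import make_matrix


def _design(n_a, n_e):
    rows = []
    for m, n in (("A", n_a), ("E", n_e)):
        for b in range(1, n + 1):
            rows.append({"run_id": f"r{m}{b}", "morph": m, "bio_rep": str(b), "tech_rep": "1"})
    return pd.DataFrame(rows)


def _bio_with_counts(obs_a, obs_e, n_a=5, n_e=6):
    """One-protein bio matrix with the requested observation pattern."""
    row = [10.0] * obs_a + [np.nan] * (n_a - obs_a) + [12.0] * obs_e + [np.nan] * (n_e - obs_e)
    cols = [f"A_{i+1}" for i in range(n_a)] + [f"E_{i+1}" for i in range(n_e)]
    return make_matrix([row], proteins=["P0"], runs=cols)


DESIGN_5_6 = _design(5, 6)


class TestFilterAndClassify:
    @pytest.mark.parametrize(
        "obs_a, obs_e, retained, mclass",
        [
            (2, 3, False, None),        # miss 3 and 3: removed
            (2, 0, False, None),        # sporadic in both
            (5, 0, True, "MNAR"),       # solid in one morph is kept
            (5, 6, True, "COMPLETE"),
            (2, 5, True, "MAR"),        # >=2 obs in both morphs
            (3, 4, True, "MAR"),
            (1, 5, True, "MNAR"),       # <=1 in one, >=3 in the other
            (0, 4, True, "MNAR"),
            (4, 1, True, "MNAR"),
            (3, 6, True, "MAR"),
        ],
    )
    def test_filter_and_classification_rules(self, obs_a, obs_e, retained, mclass):
        bio = _bio_with_counts(obs_a, obs_e)
        rep = classify_missingness(filter_sporadic(bio, DESIGN_5_6))
        assert bool(rep.at["P0", "retained"]) is retained
        if retained:
            assert rep.at["P0", "mclass"] == mclass
        assert rep.at["P0", "obs_A"] == obs_a and rep.at["P0", "miss_E"] == 6 - obs_e

    def test_every_retained_incomplete_pattern_is_classified_in_5v6_design(self):
        """Case enumeration: with 5 apyrene and 6 eupyrene replicates the
        MAR/MNAR rules cover every retained, incomplete protein."""
        for obs_a in range(6):
            for obs_e in range(7):
                bio = _bio_with_counts(obs_a, obs_e)
                rep = classify_missingness(filter_sporadic(bio, DESIGN_5_6))
                if rep.at["P0", "retained"] and (obs_a, obs_e) != (5, 6):
                    assert rep.at["P0", "mclass"] in {"MAR", "MNAR"}, (obs_a, obs_e)


class TestMinDet:
    def test_fill_is_the_low_quantile_of_the_sample(self):
        col = np.arange(1.0, 101.0)  # observed values 1..100
        X = np.column_stack([col, col])
        X2 = X.copy()
        X2[0, 0] = np.nan
        imp = MinDetImputer(quantile=0.01).fit(X2)
        # 1st percentile of the 99 observed values {2..100}: 2 + 0.01*98
        assert imp.fill_values_[0] == pytest.approx(2.98)
        out = imp.transform(X2)
        assert out[0, 0] == pytest.approx(2.98)

    def test_imputed_below_sample_median(self):
        rng = np.random.default_rng(2)
        X = rng.normal(20, 3, (200, 6))
        X[rng.random(X.shape) < 0.1] = np.nan
        out = MinDetImputer(quantile=0.01).fit(X).transform(X)
        med = np.nanmedian(X, axis=0)
        assert (out[np.isnan(X)] <= np.take(med, np.nonzero(np.isnan(X))[1])).all()

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (150, 5))
        mask = rng.random(X.shape) < 0.15
        X[mask] = np.nan
        prev = None
        for q in (0.01, 0.05, 0.2, 0.5):
            out = MinDetImputer(quantile=q).fit(X).transform(X)
            if prev is not None:
                assert (out[mask] >= prev[mask] - 1e-12).all()
            prev = out

    def test_untouched_without_missing_and_targets_respected(self):
        bio = make_matrix([[1.0, 2.0], [np.nan, 3.0]], proteins=["P0", "P1"])
        out = impute_mindet(bio, targets=["P0"], q=0.1)
        assert out.equals(bio)  # P0 has no missing; P1 not targeted

    def test_all_missing_column_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="no observed values"):
            MinDetImputer().fit(X)


class TestMLE:
    def test_perfectly_correlated_samples_recover_the_regression_line(self):
        # complete cases lie exactly on y = 2x + 1
        x = np.linspace(0, 10, 30)
        X = np.column_stack([x, 2 * x + 1]).astype(float)
        target = np.array([[4.0, np.nan]])
        est = MLEImputer(tol=1e-10).fit(np.vstack([X, target]))
        out = est.transform(target)
        assert out[0, 1] == pytest.approx(2 * 4.0 + 1, abs=1e-6)

    def test_uncorrelated_samples_impute_the_column_mean(self):
        # sample covariance is exactly diagonal by construction
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [2.0, -1.0], [-2.0, -1.0]])
        est = MLEImputer().fit(X)
        out = est.transform(np.array([[5.0, np.nan]]))
        assert out[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_loglikelihood_is_nondecreasing(self):
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        X = rng.multivariate_normal([0, 0, 0], cov, size=300)
        X[rng.random(X.shape) < 0.2] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        est = MLEImputer(tol=1e-8, max_iter=200).fit(X)
        assert est.converged_
        assert (np.diff(est.loglik_path_) >= -1e-6).all()

    def test_mcar_recovery_error_shrinks_with_noise(self):
        """Columns share a strong common factor; as idiosyncratic noise
        vanishes the conditional-mean imputations approach the truth."""
        rng = np.random.default_rng(9)
        rmse = []
        for noise in (1.0, 0.1, 0.01):
            factor = rng.normal(0, 3, 400)
            X_true = np.column_stack([factor + rng.normal(0, noise, 400) for _ in range(5)])
            X = X_true.copy()
            mask = rng.random(X.shape) < 0.1
            mask[np.arange(400) % 7 == 0] = False  # keep complete rows for init
            X[mask] = np.nan
            out = MLEImputer(tol=1e-8, max_iter=300).fit(X).transform(X)
            rmse.append(float(np.sqrt(np.mean((out[mask] - X_true[mask]) ** 2))))
        assert rmse[0] > rmse[1] > rmse[2]
        assert rmse[2] < 0.05

    def test_no_missing_targets_is_identity(self):
        bio = make_matrix(np.arange(12, dtype=float).reshape(4, 3))
        assert impute_mle(bio, targets=["P0", "P1"]).equals(bio)

    def test_nonconvergence_warns_and_returns_last_iterate(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (50, 4))
        X[rng.random(X.shape) < 0.2] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        with pytest.warns(RuntimeWarning, match="did not converge"):
            est = MLEImputer(tol=1e-12, max_iter=2).fit(X)
        assert est.mean_.shape == (4,)


class TestMixedImpute:
    def _setup(self, seed=13):
        from dimorphprot.diffabund import log2_transform
        from dimorphprot.qc import consolidate_tech_reps
        from dimorphprot.synthetic import SyntheticConfig, generate_bundle

        bundle = generate_bundle(SyntheticConfig(n_proteins=500, seed=seed))
        bio, _ = consolidate_tech_reps(bundle.abundance, bundle.design)
        report = classify_missingness(filter_sporadic(bio, bundle.design))
        retained = report.index[report["retained"]]
        return log2_transform(bio.loc[retained]), report, bundle

    def test_imputers_cover_disjoint_sets_and_fill_everything(self):
        bio_log2, report, _ = self._setup()
        out = mixed_impute(bio_log2, report)
        assert not out.isna().any().any()
        classes = report.loc[out.index, "mclass"]
        assert {"MAR", "MNAR"} <= set(classes.unique())

    def test_present_values_never_altered(self):
        bio_log2, report, _ = self._setup(seed=14)
        out = mixed_impute(bio_log2, report)
        obs = bio_log2.notna().to_numpy()
        assert np.array_equal(out.to_numpy()[obs], bio_log2.to_numpy()[obs])

    def test_all_complete_is_identity(self):
        bio = make_matrix(np.arange(1.0, 13.0).reshape(2, 6),
                          runs=[f"{m}_{b}" for m in "AE" for b in (1, 2, 3)])
        design = _design(3, 3)
        report = classify_missingness(filter_sporadic(bio, design))
        assert mixed_impute(bio, report).equals(bio)

    def test_mindet_fills_lie_below_sample_medians(self):
        bio_log2, report, _ = self._setup(seed=15)
        out = mixed_impute(bio_log2, report)
        mnar = report.index[(report["mclass"] == "MNAR") & report["retained"]]
        med = bio_log2.median(axis=0, skipna=True)
        for p in mnar:
            filled = bio_log2.loc[p].isna()
            assert (out.loc[p, filled] < med[filled]).all()

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ImputationParams(mindet_quantile=0.0)
        with pytest.raises(ValueError):
            ImputationParams(em_max_iter=0)
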