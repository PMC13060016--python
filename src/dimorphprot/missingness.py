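"""Detection filtering, MAR/MNAR classification, and mixed imputation.

Label-free proteomics matrices are missing values for two distinct reasons:
stochastic detection failure (missing at random, MAR) and genuine absence or
sub-detection-limit abundance (missing not at random, MNAR).  The two demand
different treatment.  Here the classification is operational, driven by the
per-morph observation counts:

* a protein is *retained* unless it has more than ``max_missing`` (default 2)
  missing biological replicates in **both** morphs;
* a retained, incomplete protein is MAR when it is observed at least twice in
  both morphs, MNAR when it is observed at most once in one morph and at
  least three times in the other, and UNCLASSIFIED otherwise (possible only
  in designs other than 5-vs-6 replicates; such proteins fall back to the
  MAR imputer, the less aggressive assumption).

Imputation operates on log2-transformed abundances.  MNAR values are filled
deterministically with a low per-sample quantile of the observed values
(MinDet); MAR values by the conditional expectation under a multivariate
normal across samples fitted by expectation–maximisation (MLE).  Both
imputers are sklearn-style transformers over a proteins × samples frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .qc import bio_sample_morphs

__all__ = [
    "ImputationParams",
    "filter_sporadic",
    "classify_missingness",
    "MinDetImputer",
    "MLEImputer",
    "impute_mindet",
    "impute_mle",
    "mixed_impute",
]

MCLASS_COMPLETE = "COMPLETE"
MCLASS_MAR = "MAR"
MCLASS_MNAR = "MNAR"
MCLASS_UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class ImputationParams:
    """Knobs of the mixed imputation.

    mindet_quantile : per-sample quantile of observed log2 values used as the
        MNAR fill (0 < q ≤ 0.5).  0.01 keeps imputed values at the very left
        tail, where censored values must lie.
    em_tol, em_max_iter : EM convergence controls for the MAR imputer.
    """

    mindet_quantile: float = 0.01
    em_tol: float = 1e-4
    em_max_iter: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.mindet_quantile <= 0.5):
            raise ValueError("mindet_quantile must be in (0, 0.5]")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("em_tol must be > 0 and em_max_iter >= 1")


def _obs_counts(bio: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    morphs = bio_sample_morphs(design, bio.columns)
    cols_a = [c for c in bio.columns if morphs[c] == "A"]
    cols_e = [c for c in bio.columns if morphs[c] == "E"]
    if not cols_a or not cols_e:
        raise ValueError("both morphs must be present among the biological samples")
    rep = pd.DataFrame(index=bio.index)
    rep["obs_A"] = bio[cols_a].notna().sum(axis=1)
    rep["obs_E"] = bio[cols_e].notna().sum(axis=1)
    rep["miss_A"] = len(cols_a) - rep["obs_A"]
    rep["miss_E"] = len(cols_e) - rep["obs_E"]
    return rep


def filter_sporadic(
    bio: pd.DataFrame, design: pd.DataFrame, max_missing: int = 2
) -> pd.DataFrame:
    """Apply the sporadic-detection filter.

    A protein is removed only when it exceeds ``max_missing`` missing
    biological replicates in *both* morphs; a protein solidly observed in one
    morph is kept no matter how absent it is from the other (those are
    exactly the biologically interesting presence/absence candidates).

    Returns the missingness report with per-morph observed/missing counts,
    a ``retained`` flag, and ``mclass`` initialised (COMPLETE for fully
    observed proteins, UNCLASSIFIED otherwise) pending
    :func:`classify_missingness`.
    """
    rep = _obs_counts(bio, design)
    rep["retained"] = ~((rep["miss_A"] > max_missing) & (rep["miss_E"] > max_missing))
    rep["mclass"] = np.where(
        (rep["miss_A"] == 0) & (rep["miss_E"] == 0), MCLASS_COMPLETE, MCLASS_UNCLASSIFIED
    )
    return rep


def classify_missingness(report: pd.DataFrame) -> pd.DataFrame:
    """Assign MAR/MNAR classes to retained, incomplete proteins.

    MAR requires at least two observations in both morphs; MNAR requires at
    most one observation in one morph and at least three in the other.
    Retained proteins matching neither (possible only off the 5-vs-6 design)
    stay UNCLASSIFIED and are imputed as MAR downstream.
    """
    rep = report.copy()
    incomplete = rep["retained"] & ((rep["miss_A"] > 0) | (rep["miss_E"] > 0))
    mar = incomplete & (rep["obs_A"] >= 2) & (rep["obs_E"] >= 2)
    mnar = incomplete & (
        ((rep["obs_A"] <= 1) & (rep["obs_E"] >= 3))
        | ((rep["obs_E"] <= 1) & (rep["obs_A"] >= 3))
    )
    rep.loc[incomplete, "mclass"] = MCLASS_UNCLASSIFIED
    rep.loc[mar, "mclass"] = MCLASS_MAR
    rep.loc[mnar, "mclass"] = MCLASS_MNAR
    rep.loc[rep["retained"] & ~incomplete, "mclass"] = MCLASS_COMPLETE
    return rep


class MinDetImputer(BaseEstimator, TransformerMixin):
    """Deterministic left-censored imputation.

    Fills each missing cell with the ``quantile``-quantile of the *observed*
    values of its sample column, mirroring the assumption that the value was
    censored below the detection limit.  Rows are proteins, columns are
    biological samples (features, in sklearn terms).

    Attributes
    ----------
    fill_values_ : ndarray of shape (n_samples_columns,)
        Per-column fill value learned by :meth:`fit`.
    """

    def __init__(self, quantile: float = 0.01):
        self.quantile = quantile

    def fit(self, X, y=None):
        if not (0 < self.quantile <= 0.5):
            raise ValueError("quantile must be in (0, 0.5]")
        X = self._to_array(X)
        if np.all(np.isnan(X), axis=0).any():
            bad = np.flatnonzero(np.all(np.isnan(X), axis=0)).tolist()
            raise ValueError(f"sample column(s) {bad} have no observed values")
        self.n_features_in_ = X.shape[1]
        self.fill_values_ = np.nanquantile(X, self.quantile, axis=0)
        return self

    def transform(self, X):
        arr = self._to_array(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        filled = np.where(np.isnan(arr), self.fill_values_, arr)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(filled, index=X.index, columns=X.columns)
        return filled

    @staticmethod
    def _to_array(X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D proteins × samples array")
        return arr


class MLEImputer(BaseEstimator, TransformerMixin):
    """Maximum-likelihood imputation under a multivariate normal.

    Samples (columns) are the variables of a joint Gaussian; proteins (rows)
    are i.i.d. cases.  :meth:`fit` runs EM: the E-step replaces each case's
    missing coordinates by their conditional expectation given the observed
    ones (plus the conditional covariance in the sufficient statistics), the
    M-step re-estimates the mean vector and covariance matrix.
    :meth:`transform` fills missing cells with the conditional expectation
    under the fitted Gaussian.  Deterministic: no randomness anywhere.

    Parameters
    ----------
    tol : maximum absolute change of any mean/covariance entry accepted as
        convergence.
    max_iter : EM iteration cap; hitting it raises a warning and keeps the
        last iterate.
    ridge : added to the covariance diagonal whenever it becomes numerically
        singular.

    Attributes
    ----------
    mean_, covariance_ : fitted Gaussian parameters.
    n_iter_, converged_ : EM diagnostics.
    loglik_path_ : observed-data log-likelihood per iteration (non-decreasing
        up to numerical noise — a standard EM self-check).
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 100, ridge: float = 1e-6):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        X = MinDetImputer._to_array(X)
        n, p = X.shape
        obs = ~np.isnan(X)
        if not obs.any(axis=1).all():
            raise ValueError("every protein must be observed in at least one sample")

        complete = obs.all(axis=1)
        if complete.sum() >= p + 1:
            mu = X[complete].mean(axis=0)
            sigma = np.cov(X[complete], rowvar=False, bias=True)
        else:  # degenerate fixture: moment start ignoring missingness
            mu = np.nanmean(X, axis=0)
            var = np.nanvar(X, axis=0)
            sigma = np.diag(np.where(var > 0, var, 1.0))

        patterns = self._group_patterns(obs)
        loglik_path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            sigma = self._regularise(sigma)
            ex = np.array(X)  # E[x]
            exx_corr = np.zeros((p, p))  # sum of conditional covariances
            loglik = 0.0
            for key, rows in patterns.items():
                o = np.array(key)
                m = ~o
                xo = X[np.ix_(rows, np.flatnonzero(o))]
                if m.any():
                    soo = sigma[np.ix_(o, o)]
                    som = sigma[np.ix_(o, m)]
                    b = np.linalg.solve(soo, som)  # (|o|, |m|)
                    cond_mean = mu[m] + (xo - mu[o]) @ b
                    ex[np.ix_(rows, np.flatnonzero(m))] = cond_mean
                    cond_cov = sigma[np.ix_(m, m)] - som.T @ b
                    exx_corr[np.ix_(m, m)] += len(rows) * cond_cov
                loglik += self._block_loglik(xo, mu[o], sigma[np.ix_(o, o)])
            loglik_path.append(loglik)
            mu_new = ex.mean(axis=0)
            centered = ex - mu_new
            sigma_new = (centered.T @ centered + exx_corr) / n
            delta = max(
                float(np.max(np.abs(mu_new - mu))),
                float(np.max(np.abs(sigma_new - sigma))),
            )
            mu, sigma = mu_new, sigma_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations; using last iterate",
                RuntimeWarning,
            )
        self.mean_ = mu
        self.covariance_ = self._regularise(sigma)
        self.n_iter_ = it
        self.converged_ = converged
        self.loglik_path_ = np.array(loglik_path)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        arr = MinDetImputer._to_array(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        out = np.array(arr)
        mu, sigma = self.mean_, self.covariance_
        for key, rows in self._group_patterns(~np.isnan(arr)).items():
            o = np.array(key)
            m = ~o
            if not m.any():
                continue
            if not o.any():
                out[np.ix_(rows, np.flatnonzero(m))] = mu[m]
                continue
            b = np.linalg.solve(sigma[np.ix_(o, o)], sigma[np.ix_(o, m)])
            xo = arr[np.ix_(rows, np.flatnonzero(o))]
            out[np.ix_(rows, np.flatnonzero(m))] = mu[m] + (xo - mu[o]) @ b
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _group_patterns(obs: np.ndarray) -> dict[tuple, np.ndarray]:
        patterns: dict[tuple, list[int]] = {}
        for i, row in enumerate(obs):
            patterns.setdefault(tuple(row.tolist()), []).append(i)
        return {k: np.array(v) for k, v in patterns.items()}

    def _regularise(self, sigma: np.ndarray) -> np.ndarray:
        sigma = 0.5 * (sigma + sigma.T)
        try:
            np.linalg.cholesky(sigma + 0.0)
            return sigma
        except np.linalg.LinAlgError:
            return sigma + self.ridge * np.eye(sigma.shape[0])

    @staticmethod
    def _block_loglik(xo: np.ndarray, mu_o: np.ndarray, soo: np.ndarray) -> float:
        k = soo.shape[0]
        sign, logdet = np.linalg.slogdet(soo)
        if sign <= 0:
            return -np.inf
        dev = xo - mu_o
        maha = np.einsum("ij,ij->i", dev @ np.linalg.inv(soo), dev)
        return float(-0.5 * (len(xo) * (k * np.log(2 * np.pi) + logdet) + maha.sum()))


# -- functional wrappers over the estimators --------------------------------


def impute_mindet(bio: pd.DataFrame, targets, q: float = 0.01) -> pd.DataFrame:
    """MinDet-impute the missing cells of ``targets`` proteins only.

    The per-sample fill quantile is computed over the observed values of the
    *whole* matrix, not just the targets.
    """
    targets = [t for t in targets if t in bio.index]
    imputer = MinDetImputer(quantile=q).fit(bio)
    out = bio.copy()
    if targets:
        out.loc[targets] = imputer.transform(bio.loc[targets])
    return out


def impute_mle(
    bio: pd.DataFrame, targets, params: ImputationParams | None = None
) -> pd.DataFrame:
    """MLE-impute the missing cells of ``targets`` proteins.

    The Gaussian is fitted on the target rows together with all fully
    observed rows (which anchor the covariance structure).
    """
    params = params or ImputationParams()
    targets = [t for t in targets if t in bio.index]
    out = bio.copy()
    if not targets:
        return out
    complete = bio.index[bio.notna().all(axis=1)]
    fit_rows = list(dict.fromkeys(list(complete) + list(targets)))
    est = MLEImputer(tol=params.em_tol, max_iter=params.em_max_iter).fit(bio.loc[fit_rows])
    out.loc[targets] = est.transform(bio.loc[targets])
    return out


def mixed_impute(
    bio: pd.DataFrame,
    report: pd.DataFrame,
    params: ImputationParams | None = None,
) -> pd.DataFrame:
    """Impute MNAR proteins by MinDet and MAR (plus UNCLASSIFIED) by MLE.

    ``bio`` must already be log2-scale and restricted (or restrictable) to
    retained proteins; COMPLETE proteins pass through untouched and no
    present value is ever altered.  The result has no missing cells among
    retained proteins.
    """
    params = params or ImputationParams()
    retained = report.index[report["retained"]]
    sub = bio.loc[[p for p in bio.index if p in set(retained)]]
    mnar = [p for p in sub.index if report.at[p, "mclass"] == MCLASS_MNAR]
    mar = [
        p for p in sub.index
        if report.at[p, "mclass"] in (MCLASS_MAR, MCLASS_UNCLASSIFIED)
        and sub.loc[p].isna().any()
    ]
    # both imputers see the pristine observed matrix; results are merged
    out = sub.copy()
    if mnar:
        out.loc[mnar] = impute_mindet(sub, mnar, q=params.mindet_quantile).loc[mnar]
    if mar:
        out.loc[mar] = impute_mle(sub, mar, params).loc[mar]
    assert not out.isna().any().any(), "mixed imputation left missing cells"
    # imputation must never touch an observed value
    observed = sub.notna()
    assert (out[observed] == sub[observed]).all().all() or np.allclose(
        out.to_numpy()[observed.to_numpy()], sub.to_numpy()[observed.to_numpy()]
    )
    return out
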