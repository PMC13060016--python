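"""Quantitative and qualitative differential abundance between sperm morphs.

The quantitative test is an empirical-Bayes moderated two-sample t-test: the
per-protein residual variance :math:`s_g^2` (pooled over the two morphs,
:math:`d_g = n_A + n_E - 2` df) is shrunk toward a prior variance
:math:`s_0^2` carrying :math:`d_0` prior degrees of freedom,

.. math::

    \\tilde{s}_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},
    \\qquad
    t_g = \\frac{\\bar{x}_{A,g} - \\bar{x}_{E,g}}
               {\\tilde{s}_g\\sqrt{1/n_A + 1/n_E}},

with p-values from a t distribution on :math:`d_0 + d_g` degrees of freedom.
The hyperparameters :math:`(d_0, s_0^2)` are estimated by the method of
moments on :math:`\\log s_g^2`, whose marginal distribution under the
hierarchical model is a shifted log-F: matching its mean and variance via
digamma/trigamma functions yields closed-form moment equations (a trigamma
inverse is solved by Newton iteration).  :math:`d_0 = 0` recovers the
ordinary pooled t-test; :math:`d_0 = \\infty` pools all proteins to a single
variance.

A protein is called quantitatively biased when its BH-adjusted p-value is
below ``alpha`` *and* its estimated fold difference reaches ``fc_min``
(default 1.5-fold).  Qualitative presence/absence calls are made on the
non-imputed matrix: detection in at least ``min_present`` replicates of one
morph and at most ``max_other`` of the other.  The two call sets merge into
a single per-protein bias category; the sign convention throughout is
apyrene minus eupyrene (positive log2fc = apyrene-biased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

from .missingness import _obs_counts
from .qc import bio_sample_morphs

__all__ = [
    "ModeratedTTest",
    "PCAResult",
    "log2_transform",
    "moderated_ttest",
    "bh_adjust",
    "call_quantitative",
    "call_qualitative",
    "merge_bias",
    "pca",
]

CALL_A = "A_biased"
CALL_E = "E_biased"
CALL_NONE = "none"
QUAL_A = "A_only"
QUAL_E = "E_only"
BIAS_UNBIASED = "unbiased"


def log2_transform(bio: pd.DataFrame) -> pd.DataFrame:
    """log2 the present values; missing cells stay missing."""
    vals = bio.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        bad = bio.index[(bio <= 0).any(axis=1)].tolist()
        raise ValueError(f"nonpositive abundance(s) in protein(s) {bad[:5]}")
    with np.errstate(invalid="ignore"):
        return pd.DataFrame(np.log2(vals), index=bio.index, columns=bio.columns)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y; trigamma is convex decreasing.
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0²).

    Under the hierarchical model ``s2 | sigma2 ~ sigma2 * chi2(df)/df`` with
    ``1/sigma2 ~ chi2(d0)/(d0 s0²)``, the statistic
    ``e = log s2 - digamma(df/2) + log(df/2)`` has mean
    ``log s0² + digamma(d0/2) - log(d0/2)`` and variance
    ``trigamma(df/2) + trigamma(d0/2)``.  Solving the two moment equations
    gives the estimates; a non-positive excess variance means no detectable
    inter-protein variance spread and returns ``d0 = inf``.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances to fit the prior")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(((e - e_mean) ** 2 * len(e) / (len(e) - 1)).mean()) - float(
        np.mean(special.polygamma(1, df / 2.0))
    )
    if excess <= 0:
        return math.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + np.log(d0 / 2.0) - special.digamma(d0 / 2.0)))
    return d0, s0_sq


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-group t-test, sklearn style.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_proteins) and a binary
    group label vector ``y``; the contrast is group ``groups_[1]`` minus
    group ``groups_[0]``.  Per-feature results land in trailing-underscore
    attributes.

    Parameters
    ----------
    prior_df : None to estimate ``d0`` by moments (the default), ``0`` to pin
        the ordinary pooled t-test, ``numpy.inf`` for complete shrinkage to a
        single common variance.

    Attributes
    ----------
    effect_ : per-feature mean difference (log2 fold change on log2 data).
    s2_, df_residual_ : per-feature residual variance and its df.
    prior_df_, prior_s2_ : fitted (or pinned) hyperparameters.
    s2_posterior_, t_, p_, df_total_ : moderated results.
    """

    def __init__(self, prior_df: float | None = None):
        self.prior_df = prior_df

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if np.isnan(X).any():
            raise ValueError("moderated t-test requires a fully imputed matrix")
        self.groups_ = sorted(pd.unique(y).tolist())
        if len(self.groups_) != 2:
            raise ValueError(f"need exactly two groups, got {self.groups_}")
        g0, g1 = self.groups_
        x0, x1 = X[y == g0], X[y == g1]
        n0, n1 = len(x0), len(x1)
        if min(n0, n1) < 2:
            raise ValueError("each group needs at least 2 samples")

        self.effect_ = x1.mean(axis=0) - x0.mean(axis=0)
        d_g = n0 + n1 - 2
        ss = ((x0 - x0.mean(axis=0)) ** 2).sum(axis=0) + ((x1 - x1.mean(axis=0)) ** 2).sum(axis=0)
        self.s2_ = ss / d_g
        self.df_residual_ = np.full(X.shape[1], float(d_g))
        if not np.any(self.s2_ > 0):
            raise ValueError("all residual variances are zero; degenerate input")

        if self.prior_df is None:
            d0, s0_sq = fit_variance_prior(self.s2_, self.df_residual_)
        else:
            d0 = float(self.prior_df)
            if d0 < 0:
                raise ValueError("prior_df must be >= 0")
            # s0² from the mean moment equation at the pinned d0
            e = (
                np.log(self.s2_[self.s2_ > 0])
                - special.digamma(d_g / 2.0)
                + np.log(d_g / 2.0)
            )
            if math.isinf(d0) or d0 == 0:
                s0_sq = float(np.exp(e.mean()))
            else:
                s0_sq = float(
                    np.exp(e.mean() + np.log(d0 / 2.0) - special.digamma(d0 / 2.0))
                )
        self.prior_df_ = d0
        self.prior_s2_ = s0_sq

        if math.isinf(d0):
            self.s2_posterior_ = np.full_like(self.s2_, s0_sq)
            self.df_total_ = np.full_like(self.s2_, np.inf)
        elif d0 == 0:
            self.s2_posterior_ = self.s2_.copy()
            self.df_total_ = self.df_residual_.copy()
        else:
            self.s2_posterior_ = (d0 * s0_sq + d_g * self.s2_) / (d0 + d_g)
            self.df_total_ = self.df_residual_ + d0

        se = np.sqrt(self.s2_posterior_ * (1.0 / n0 + 1.0 / n1))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.t_ = np.where(se > 0, self.effect_ / se, np.where(self.effect_ == 0, 0.0, np.inf * np.sign(self.effect_)))
        finite_df = np.where(np.isinf(self.df_total_), 1e12, self.df_total_)
        self.p_ = 2.0 * stats.t.sf(np.abs(self.t_), finite_df)
        if np.isinf(self.df_total_).any():
            self.p_ = np.where(
                np.isinf(self.df_total_), 2.0 * stats.norm.sf(np.abs(self.t_)), self.p_
            )
        return self


def moderated_ttest(
    imputed: pd.DataFrame, design: pd.DataFrame, prior_df: float | None = None
) -> pd.DataFrame:
    """Run the moderated t-test on an imputed proteins × samples frame.

    The contrast is apyrene minus eupyrene.  Returns the differential table
    with ``log2fc``, ``t_mod`` and ``p`` columns.
    """
    morphs = bio_sample_morphs(design, imputed.columns)
    # contrast A - E: make "E" the baseline group (sorted order puts A first,
    # so encode labels to force groups_ = [E, A])
    y = np.where(morphs.values == "A", "b_A", "a_E")
    est = ModeratedTTest(prior_df=prior_df).fit(imputed.to_numpy().T, y)
    table = pd.DataFrame(index=imputed.index)
    table["log2fc"] = est.effect_
    table["t_mod"] = est.t_
    table["p"] = est.p_
    table.attrs["prior_df"] = est.prior_df_
    table.attrs["prior_s2"] = est.prior_s2_
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_quantitative(
    table: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Apply the significance and fold-change thresholds.

    A call requires BH-adjusted p < ``alpha`` and an estimated fold
    difference of at least ``fc_min`` on the model coefficient
    (|log2fc| >= log2 fc_min).
    """
    out = table.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["p"].to_numpy())
    lfc_min = math.log2(fc_min)
    sig = out["padj"] < alpha
    out["quant_call"] = CALL_NONE
    out.loc[sig & (out["log2fc"] >= lfc_min), "quant_call"] = CALL_A
    out.loc[sig & (out["log2fc"] <= -lfc_min), "quant_call"] = CALL_E
    return out


def call_qualitative(
    bio_prefilter: pd.DataFrame,
    design: pd.DataFrame,
    min_present: int | str = 4,
    max_other: int = 1,
) -> pd.Series:
    """Presence/absence calls on the non-imputed, filtered matrix.

    ``min_present="auto"`` scales the presence threshold to
    ``ceil(0.75 * n_morph)`` per morph for designs with other replicate
    counts; the default 4 is the fixed threshold appropriate to 5-or-6
    replicate designs.
    """
    counts = _obs_counts(bio_prefilter, design)
    morphs = bio_sample_morphs(design, bio_prefilter.columns)
    n_a = int((morphs == "A").sum())
    n_e = int((morphs == "E").sum())
    if min_present == "auto":
        thr_a, thr_e = math.ceil(0.75 * n_a), math.ceil(0.75 * n_e)
    else:
        thr_a = thr_e = int(min_present)
    call = pd.Series(CALL_NONE, index=bio_prefilter.index, name="qual_call")
    call[(counts["obs_A"] >= thr_a) & (counts["obs_E"] <= max_other)] = QUAL_A
    call[(counts["obs_E"] >= thr_e) & (counts["obs_A"] <= max_other)] = QUAL_E
    return call


def merge_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Union the quantitative and qualitative calls into one bias category.

    A protein quantitatively biased toward one morph but qualitatively
    exclusive to the other would be self-contradictory; such proteins abort
    the merge with an error naming them.
    """
    for col in ("quant_call", "qual_call"):
        if col not in table.columns:
            raise ValueError(f"merge_bias requires column {col!r}")
    conflict = (
        ((table["quant_call"] == CALL_A) & (table["qual_call"] == QUAL_E))
        | ((table["quant_call"] == CALL_E) & (table["qual_call"] == QUAL_A))
    )
    if conflict.any():
        raise ValueError(
            "conflicting quantitative/qualitative directions for protein(s): "
            f"{table.index[conflict].tolist()}"
        )
    out = table.copy()
    out["bias"] = BIAS_UNBIASED
    out.loc[(out["quant_call"] == CALL_A) | (out["qual_call"] == QUAL_A), "bias"] = CALL_A
    out.loc[(out["quant_call"] == CALL_E) | (out["qual_call"] == QUAL_E), "bias"] = CALL_E
    return out


@dataclass
class PCAResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples × components
    variance_explained: np.ndarray  # fractions, non-increasing

    def __post_init__(self) -> None:
        ve = self.variance_explained
        assert np.all(np.diff(ve) <= 1e-12) and ve.sum() <= 1 + 1e-9


def pca(imputed: pd.DataFrame, top_n: int | None = None) -> PCAResult:
    """PCA of biological samples over (optionally the most variable) proteins.

    Proteins are mean-centred; components are those of the sample × protein
    matrix.  ``top_n`` restricts to the ``top_n`` highest-variance proteins
    first, mirroring the common expression-analysis convention.
    """
    if imputed.isna().any().any():
        raise ValueError("PCA requires a fully imputed matrix")
    if imputed.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    mat = imputed
    if top_n is not None and top_n < len(mat):
        order = mat.var(axis=1).sort_values(ascending=False).index[:top_n]
        mat = mat.loc[order]
    X = mat.to_numpy().T  # samples × proteins
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if X.var(axis=0, ddof=1).sum() == 0:  # all samples identical
        scores = np.zeros((X.shape[0], n_comp))
        frac = np.zeros(n_comp)
    else:
        model = _SkPCA(n_components=n_comp, svd_solver="full")
        scores = model.fit_transform(X)
        frac = model.explained_variance_ratio_
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=imputed.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
        ),
        variance_explained=frac,
    )
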