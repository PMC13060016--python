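"""Technical-replicate consolidation and biological-sample quality control.

Repeated MS injections of the same biological sample carry no biological
information of their own; they only sharpen the abundance estimate.  This
module collapses them to one value per biological replicate (mean of the
detected injections), reports pairwise technical-replicate correlations as a
sanity check on that collapse, and flags biological replicates whose
detection count or abundance distribution is aberrant.  Flags are advisory:
exclusion is always an explicit, recorded decision (`drop_samples`), never
automatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "bio_sample_id",
    "bio_sample_morphs",
    "consolidate_tech_reps",
    "flag_outlier_samples",
    "drop_samples",
]

#: minimum jointly detected proteins for a correlation to be reported
MIN_SHARED_FOR_CORR = 10


def bio_sample_id(morph: str, bio_rep: str) -> str:
    return f"{morph}_{bio_rep}"


def bio_sample_morphs(design: pd.DataFrame, columns) -> pd.Series:
    """Morph label for each biological-sample column id."""
    mapping = {
        bio_sample_id(m, b): m
        for (m, b), _ in design.groupby(["morph", "bio_rep"], sort=False)
    }
    unknown = [c for c in columns if c not in mapping]
    if unknown:
        raise ValueError(f"biological sample(s) {unknown} not described by the design")
    return pd.Series({c: mapping[c] for c in columns}, name="morph")


@dataclass
class QCReport:
    """Per-biological-sample QC summary.

    Attributes
    ----------
    sample_stats : DataFrame indexed by biological sample with columns
        ``n_proteins_detected``, ``median_log2_abundance``, ``outlier_flag``,
        ``flag_reasons``.
    tech_correlations : DataFrame with one row per technical-replicate pair
        (``bio_sample``, ``run_i``, ``run_j``, ``n_shared``, ``pearson_r``);
        correlations are computed on log2 abundances over jointly detected
        proteins and reported as NaN when fewer than
        ``MIN_SHARED_FOR_CORR`` proteins are shared.
    """

    sample_stats: pd.DataFrame
    tech_correlations: pd.DataFrame
    correlation_scale: str = "log2"

    def min_tech_correlation(self) -> float:
        r = self.tech_correlations["pearson_r"].dropna()
        return float(r.min()) if len(r) else float("nan")


def _sample_stats(bio: pd.DataFrame) -> pd.DataFrame:
    stats = pd.DataFrame(index=bio.columns)
    stats["n_proteins_detected"] = bio.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        stats["median_log2_abundance"] = np.log2(bio).median(axis=0, skipna=True)
    stats["outlier_flag"] = False
    stats["flag_reasons"] = [[] for _ in range(len(stats))]
    return stats


def consolidate_tech_reps(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, QCReport]:
    """Average technical replicates into one column per biological replicate.

    Each consolidated cell is the arithmetic mean of the *detected*
    technical-replicate values; a protein is missing in a biological
    replicate only when every injection missed it.  Averaging over detected
    injections only keeps technical dropout from masquerading as biology.
    """
    unmapped = [c for c in matrix.columns if c not in set(design["run_id"])]
    if unmapped:
        raise ValueError(f"run(s) {unmapped} in matrix are absent from the sample design")

    cols: dict[str, pd.Series] = {}
    corr_rows = []
    for (morph, bio_rep), grp in design.groupby(["morph", "bio_rep"], sort=False):
        runs = [r for r in grp["run_id"] if r in matrix.columns]
        if not runs:
            raise ValueError(
                f"biological sample {bio_sample_id(morph, bio_rep)!r} has no runs in the matrix"
            )
        block = matrix[runs]
        cols[bio_sample_id(morph, bio_rep)] = block.mean(axis=1, skipna=True)
        log2_block = np.log2(block)
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                x, y = log2_block[runs[i]], log2_block[runs[j]]
                shared = x.notna() & y.notna()
                n_shared = int(shared.sum())
                r = (
                    float(np.corrcoef(x[shared], y[shared])[0, 1])
                    if n_shared >= MIN_SHARED_FOR_CORR
                    else np.nan
                )
                corr_rows.append(
                    {
                        "bio_sample": bio_sample_id(morph, bio_rep),
                        "run_i": runs[i],
                        "run_j": runs[j],
                        "n_shared": n_shared,
                        "pearson_r": r,
                    }
                )

    bio = pd.DataFrame(cols, index=matrix.index)
    bio.index.name = "protein_id"
    report = QCReport(
        sample_stats=_sample_stats(bio),
        tech_correlations=pd.DataFrame(
            corr_rows, columns=["bio_sample", "run_i", "run_j", "n_shared", "pearson_r"]
        ),
    )
    return bio, report


def flag_outlier_samples(
    bio: pd.DataFrame, count_frac: float = 0.6, abundance_z: float = 3.0
) -> QCReport:
    """Flag biological replicates with aberrant detection counts or abundances.

    A sample is flagged when its detected-protein count falls below
    ``count_frac`` of the median count across samples ("count" reason), or
    when its median log2 abundance deviates from the median of sample medians
    by more than ``abundance_z`` robust standard deviations
    (1.4826 × MAD) ("abundance" reason).  Degenerate spread (MAD = 0) flags
    any sample whose median differs at all.
    """
    if bio.shape[1] < 3:
        raise ValueError("outlier flagging needs at least 3 biological samples")
    stats = _sample_stats(bio)

    median_count = stats["n_proteins_detected"].median()
    medians = stats["median_log2_abundance"]
    center = medians.median()
    mad = float((medians - center).abs().median())

    for s in stats.index:
        reasons = []
        if stats.at[s, "n_proteins_detected"] < count_frac * median_count:
            reasons.append("count")
        dev = abs(stats.at[s, "median_log2_abundance"] - center)
        z = 0.0 if dev == 0 else (dev / (1.4826 * mad) if mad > 0 else np.inf)
        if z > abundance_z:
            reasons.append("abundance")
        stats.at[s, "flag_reasons"] = reasons
        stats.at[s, "outlier_flag"] = bool(reasons)

    return QCReport(sample_stats=stats, tech_correlations=pd.DataFrame(
        columns=["bio_sample", "run_i", "run_j", "n_shared", "pearson_r"]))


def drop_samples(bio: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    """Remove biological-sample columns by explicit id list."""
    unknown = [s for s in ids if s not in bio.columns]
    if unknown:
        raise ValueError(f"cannot drop unknown sample(s) {unknown}")
    return bio.drop(columns=list(ids))
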