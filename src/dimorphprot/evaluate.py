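"""Truth-based evaluation of pipeline output on synthetic bundles.

Utilities for benchmarking the differential-abundance pipeline against the
generator's ground truth: per-run false-discovery proportions under a null
generator, fold-change floors over the called set, and effect-size recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffabund
from .pipeline import AnalysisResult, PipelineConfig, analyze
from .synthetic import SyntheticConfig, SyntheticTruth, generate_bundle

__all__ = [
    "quantitative_fdp",
    "null_fdr_experiment",
    "fold_change_floor",
    "recovery_stats",
]

_TRUE_OF_CALL = {diffabund.CALL_A: "A_biased", diffabund.CALL_E: "E_biased"}


def quantitative_fdp(result: AnalysisResult, truth: SyntheticTruth) -> float:
    """False-discovery proportion of the quantitative calls of one run.

    A call is false when the protein is truly unbiased or truly biased in
    the opposite direction.  Runs with no calls score 0 (nothing was
    discovered, so nothing falsely).
    """
    table = result.table
    called = table.index[table["quant_call"] != diffabund.CALL_NONE]
    if len(called) == 0:
        return 0.0
    true_bias = truth.protein_truth["true_bias"]
    n_false = sum(
        1 for p in called if true_bias[p] != _TRUE_OF_CALL[table.at[p, "quant_call"]]
    )
    return n_false / len(called)


def null_fdr_experiment(
    n_runs: int = 200,
    base_seed: int = 1,
    config: PipelineConfig | None = None,
    **generator_overrides,
) -> tuple[float, float, np.ndarray]:
    """Mean FDP of the full quantitative pipeline over null bundles.

    Generates ``n_runs`` bundles with no true morph effect
    (``frac_biased=0``) at seeds ``base_seed .. base_seed+n_runs-1``, runs
    the complete pipeline on each, and returns (mean FDP, Monte-Carlo
    standard error of the mean, per-run FDPs).
    """
    generator_overrides.setdefault("frac_biased", 0.0)
    fdps = np.empty(n_runs)
    for i in range(n_runs):
        bundle = generate_bundle(SyntheticConfig(seed=base_seed + i, **generator_overrides))
        result = analyze(bundle.abundance, bundle.design, config)
        fdps[i] = quantitative_fdp(result, bundle.truth)
    mc_se = float(fdps.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else float("nan")
    return float(fdps.mean()), mc_se, fdps


def fold_change_floor(result: AnalysisResult) -> float:
    """Smallest estimated fold difference among quantitatively called
    proteins (``inf`` when nothing is called)."""
    table = result.table
    called = table["quant_call"] != diffabund.CALL_NONE
    if not called.any():
        return float("inf")
    return float(np.exp2(table.loc[called, "log2fc"].abs()).min())


def recovery_stats(result: AnalysisResult, truth: SyntheticTruth) -> dict[str, float]:
    """Effect-size recovery against truth.

    Returns the mean log2fc estimation error over truly biased proteins that
    survived the filter (``bias``), and the fraction of all truly biased
    proteins assigned the correct bias category (``sensitivity``; proteins
    lost to the filter count as misses).
    """
    table = result.table
    true_tab = truth.protein_truth
    biased = true_tab.index[true_tab["true_bias"] != "unbiased"]
    kept = [p for p in biased if p in table.index]
    errors = table.loc[kept, "log2fc"] - true_tab.loc[kept, "true_log2fc"]
    correct = sum(1 for p in kept if table.at[p, "bias"] == true_tab.at[p, "true_bias"])
    return {
        "bias": float(errors.mean()) if kept else float("nan"),
        "mean_abs_error": float(errors.abs().mean()) if kept else float("nan"),
        "sensitivity": correct / len(biased) if len(biased) else float("nan"),
        "n_true_biased": int(len(biased)),
    }
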