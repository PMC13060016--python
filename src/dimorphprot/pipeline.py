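"""End-to-end orchestration: raw run-level matrix to results bundle.

Stage order: consolidate technical replicates → QC/outlier flags → explicit
sample exclusion → sporadic-detection filter → log2 → MAR/MNAR
classification → mixed imputation → moderated t + BH + fold threshold →
qualitative presence/absence calls → bias merge → PCA → annotation
chi-squares → GO enrichment → cross-species homology.  Every intermediate
is kept (and written, when running from files) so each summary number can be
re-derived from the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diffabund, enrich, homology, ingest, missingness, qc

logger = logging.getLogger("dimorphprot")

__all__ = ["PipelineConfig", "AnalysisResult", "analyze", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    File paths may be None when a stage's inputs are unavailable; dependent
    stages are then skipped (the summary records which ran).
    """

    abundance: str | None = None
    design: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    obo: str | None = None
    gene2go: str | None = None
    orthologs: str | None = None
    sperm_lists: dict[str, str] = field(default_factory=dict)  # species -> id-list path

    exclude_samples: list[str] = field(default_factory=list)
    max_missing: int = 2
    alpha: float = 0.05
    fc_min: float = 1.5
    min_present: int | str = 4
    max_other: int = 1
    mindet_quantile: float = 0.01
    em_tol: float = 1e-4
    em_max_iter: int = 100
    p_cutoff: float = 0.05
    min_size: int = 3
    top_n: int | None = None
    focal_species: str = "focal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Intermediates and results of the statistical core."""

    bio: pd.DataFrame  # consolidated, post-exclusion
    qc_report: qc.QCReport
    missingness_report: pd.DataFrame
    bio_log2_filtered: pd.DataFrame  # retained proteins, non-imputed, log2
    imputed: pd.DataFrame
    table: pd.DataFrame  # differential table (retained proteins)
    pca: diffabund.PCAResult
    summary: dict[str, Any]


def analyze(
    abundance: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the statistical core on in-memory frames."""
    cfg = config or PipelineConfig()

    bio, qc_report = qc.consolidate_tech_reps(abundance, design)
    flags = qc.flag_outlier_samples(bio)
    qc_report.sample_stats = flags.sample_stats
    if cfg.exclude_samples:
        bio = qc.drop_samples(bio, cfg.exclude_samples)
    logger.info("consolidated %d proteins x %d biological samples", *bio.shape)

    report = missingness.filter_sporadic(bio, design, max_missing=cfg.max_missing)
    report = missingness.classify_missingness(report)
    retained = report.index[report["retained"]]
    logger.info(
        "filter: %d/%d proteins retained (classes: %s)",
        len(retained), len(report),
        report.loc[retained, "mclass"].value_counts().to_dict(),
    )

    bio_log2 = diffabund.log2_transform(bio.loc[retained])
    params = missingness.ImputationParams(
        mindet_quantile=cfg.mindet_quantile, em_tol=cfg.em_tol, em_max_iter=cfg.em_max_iter
    )
    imputed = missingness.mixed_impute(bio_log2, report, params)

    table = diffabund.moderated_ttest(imputed, design)
    table["padj"] = diffabund.bh_adjust(table["p"].to_numpy())
    table = diffabund.call_quantitative(table, alpha=cfg.alpha, fc_min=cfg.fc_min)
    table["qual_call"] = diffabund.call_qualitative(
        bio_log2, design, min_present=cfg.min_present, max_other=cfg.max_other
    )
    table = diffabund.merge_bias(table)
    pca_res = diffabund.pca(imputed, top_n=cfg.top_n)

    bias_counts = table["bias"].value_counts().to_dict()
    quant = table["quant_call"].value_counts().to_dict()
    qual = table["qual_call"].value_counts().to_dict()
    summary = {
        "n_proteins_input": int(len(report)),
        "n_retained": int(len(retained)),
        "n_excluded_samples": len(cfg.exclude_samples),
        "mclass_counts": report.loc[retained, "mclass"].value_counts().to_dict(),
        "n_quant_A": int(quant.get(diffabund.CALL_A, 0)),
        "n_quant_E": int(quant.get(diffabund.CALL_E, 0)),
        "n_qual_A": int(qual.get(diffabund.QUAL_A, 0)),
        "n_qual_E": int(qual.get(diffabund.QUAL_E, 0)),
        "n_quant_and_qual": int(
            ((table["quant_call"] != diffabund.CALL_NONE)
             & (table["qual_call"] != diffabund.CALL_NONE)).sum()
        ),
        "n_A_biased": int(bias_counts.get(diffabund.CALL_A, 0)),
        "n_E_biased": int(bias_counts.get(diffabund.CALL_E, 0)),
        "n_unbiased": int(bias_counts.get(diffabund.BIAS_UNBIASED, 0)),
        "pc_variance_explained": [round(float(v), 6) for v in pca_res.variance_explained[:2]],
        "moderation_prior_df": float(table.attrs.get("prior_df", float("nan"))),
    }
    return AnalysisResult(
        bio=bio,
        qc_report=qc_report,
        missingness_report=report,
        bio_log2_filtered=bio_log2,
        imputed=imputed,
        table=table,
        pca=pca_res,
        summary=summary,
    )


def _functional_stage(
    cfg: PipelineConfig, result: AnalysisResult, outdir: Path
) -> dict[str, Any]:
    """Annotation chi-squares, GO enrichment and homology, where inputs exist."""
    out: dict[str, Any] = {}
    gene_map = None
    if cfg.fasta:
        records = ingest.dedupe_protein_db(ingest.read_protein_fasta(cfg.fasta), seed=cfg.seed)
        gene_map = ingest.longest_isoform(records)
    protein_to_gene = (
        {pid: g for g, pid in gene_map.items()} if gene_map else {p: p for p in result.table.index}
    )
    subsets = {
        name: {
            protein_to_gene.get(p, p)
            for p in result.table.index[result.table["bias"] == name]
        }
        for name in (diffabund.CALL_A, diffabund.CALL_E, diffabund.BIAS_UNBIASED)
    }
    universe = set().union(*subsets.values())

    if cfg.annotations:
        ann = ingest.read_annotation_table(cfg.annotations)
        chis = {}
        for feature in ("has_mito_target", "has_signal_peptide", "tm_domain_count", "annotated"):
            counts = enrich.annotation_subset_counts(ann, subsets, feature)
            counts.to_csv(outdir / f"counts_{feature}.tsv", sep="\t")
            chi2, df, p = enrich.chisq_homogeneity(counts)
            chis[feature] = {"chi2": round(chi2, 4), "df": df, "p": p}
        out["annotation_chisq"] = chis

    if cfg.obo and cfg.gene2go:
        dag = enrich.GoDag.from_obo(cfg.obo).load_annotations(cfg.gene2go)
        dag = enrich.propagate_annotations(dag)
        n_sig = {}
        for ns in ("BP", "CC", "MF"):
            for name, genes in subsets.items():
                res = enrich.conditional_enrich(
                    dag, genes & universe, universe, ns,
                    p_cutoff=cfg.p_cutoff, min_size=cfg.min_size,
                )
                res.to_csv(outdir / f"go_{ns}_{name}.tsv", sep="\t", index=False)
                n_sig[f"{ns}:{name}"] = int((res["p"] < cfg.p_cutoff).sum())
        out["go_significant_terms"] = n_sig

    if cfg.orthologs and cfg.sperm_lists:
        orthomap = ingest.read_ortholog_table(cfg.orthologs)
        sharing = {}
        for sp, path in cfg.sperm_lists.items():
            table = homology.cross_reference(
                subsets, orthomap, cfg.focal_species, sp, ingest.read_id_list(path)
            )
            table.to_csv(outdir / f"sharing_{sp}.tsv", sep="\t")
            chi2, df, p = homology.sharing_chisq(table)
            sharing[sp] = {
                "proportions": {k: round(float(v), 4) for k, v in table["proportion"].items()},
                "chi2": round(chi2, 4), "df": df, "p": p,
            }
        out["homology"] = sharing
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """File-based full pipeline; writes intermediates, log and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "ingest"
    try:
        if not config.abundance or not config.design:
            raise ValueError("config must provide 'abundance' and 'design' paths")
        logger.info("config digest %s, seed %d", config.digest(), config.seed)
        abundance = ingest.read_abundance_matrix(config.abundance)
        design = ingest.read_sample_design(config.design)

        stage = "analysis"
        result = analyze(abundance, design, config)
        result.bio.to_csv(outdir / "bio_abundance.tsv", sep="\t")
        result.qc_report.sample_stats.to_csv(outdir / "qc_samples.tsv", sep="\t")
        result.qc_report.tech_correlations.to_csv(
            outdir / "qc_tech_correlations.tsv", sep="\t", index=False
        )
        result.missingness_report.to_csv(outdir / "missingness.tsv", sep="\t")
        result.imputed.to_csv(outdir / "imputed_log2.tsv", sep="\t")
        result.table.to_csv(outdir / "differential.tsv", sep="\t")
        result.pca.scores.assign().to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.Series(
            result.pca.variance_explained,
            index=result.pca.scores.columns,
            name="variance_fraction",
        ).to_csv(outdir / "pca_variance.tsv", sep="\t")

        stage = "functional"
        summary = dict(result.summary)
        summary.update(_functional_stage(config, result, outdir))
        summary["config_digest"] = config.digest()
        summary["seed"] = config.seed
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        logger.info("pipeline complete: %d biased proteins",
                    summary["n_A_biased"] + summary["n_E_biased"])
        return summary
    except Exception as e:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        logger.error("pipeline failed at stage %s: %s", stage, e)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    finally:
        logger.removeHandler(handler)
        handler.close()
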