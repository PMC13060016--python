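"""Ground-truthed synthetic input bundles.

Emulates the statistical structure of a dimorphic-sperm LFQ experiment so
every pipeline stage can be exercised, with known truth, on data generated
in memory.  The generative model, on the log2 scale:

.. math::

    y_{g,s,t} = \\mu_g + \\mathbb{1}[m(s) = A]\\,\\beta_g + b_{g,s}
                + \\varepsilon_{g,s,t}

with protein baselines :math:`\\mu_g \\sim N(20, 3^2)`, biological noise
:math:`b_{g,s} \\sim N(0, \\sigma_{bio}^2)` and technical noise
:math:`\\varepsilon \\sim N(0, \\sigma_{tech}^2)`.  A fraction of proteins is
morph-biased with effect :math:`|\\beta_g|` drawn from a configured normal,
signed eupyrene-biased with probability ``frac_e_biased`` (defaults echo the
mild eupyrene excess typical of these proteomes).  Missingness has two
planted mechanisms kept disjoint per cell: left-censoring of each run's
lowest-quantile values (MNAR) and uniform dropout (MAR).  Optionally one
apyrene replicate is degraded into an outlier (extra dropout plus a global
abundance shift).  Values are exported on the raw :math:`2^y` scale, so the
pipeline's own log2 step is exercised.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import GoDag
from .ingest import OrthologMap, ProteinRecord, write_abundance_matrix, write_protein_fasta
from .qc import bio_sample_id

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "Bundle",
    "PlantedTerm",
    "generate_bundle",
    "generate_protein_db",
    "generate_annotation_fixture",
    "generate_go_fixture",
    "generate_ortholog_fixture",
    "write_bundle",
]

FOCAL_SPECIES = "focal"
COMPARISON_SPECIES = ("species_X", "species_Y")


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the emulated study conditions.

    n_bio biological replicates per morph are measured in ``n_tech``
    technical injections each, except the last replicate of each morph which
    gets one fewer when ``duplicate_last_bio`` is set (instrument-time
    constraints commonly shave the final sample).
    """

    n_proteins: int = 1700
    n_bio: int = 6
    n_tech: int = 3
    duplicate_last_bio: bool = True
    frac_biased: float = 0.15
    frac_e_biased: float = 0.55
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5
    base_mu_mean: float = 20.0
    base_mu_sd: float = 3.0
    sigma_bio: float = 0.5
    sigma_tech: float = 0.05
    mnar_threshold_quantile: float = 0.05
    mar_dropout_rate: float = 0.02
    outlier_sample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_biased", "frac_e_biased", "mnar_threshold_quantile", "mar_dropout_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("log2fc_sd", "base_mu_sd", "sigma_bio", "sigma_tech"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_proteins < 1 or self.n_bio < 2 or self.n_tech < 1:
            raise ValueError("need n_proteins >= 1, n_bio >= 2, n_tech >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated bundle.

    protein_truth : per-protein ``true_log2fc`` (apyrene minus eupyrene) and
        ``true_bias`` category.
    censor_mask / dropout_mask : protein × run booleans, disjoint per cell.
    outlier_sample : degraded biological-sample id, or None.
    """

    protein_truth: pd.DataFrame
    censor_mask: pd.DataFrame
    dropout_mask: pd.DataFrame
    outlier_sample: str | None
    config: SyntheticConfig

    def genes_by_bias(self) -> dict[str, set[str]]:
        return {
            b: set(self.protein_truth.index[self.protein_truth["true_bias"] == b])
            for b in ("A_biased", "E_biased", "unbiased")
        }


class Bundle(NamedTuple):
    abundance: pd.DataFrame
    design: pd.DataFrame
    truth: SyntheticTruth


def _make_design(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for morph in ("A", "E"):
        for b in range(1, cfg.n_bio + 1):
            n_t = cfg.n_tech
            if cfg.duplicate_last_bio and b == cfg.n_bio:
                n_t = max(cfg.n_tech - 1, 1)
            for t in range(1, n_t + 1):
                rows.append(
                    {
                        "run_id": f"run_{morph}{b}_t{t}",
                        "morph": morph,
                        "bio_rep": str(b),
                        "tech_rep": str(t),
                    }
                )
    return pd.DataFrame(rows)


def generate_bundle(config: SyntheticConfig) -> Bundle:
    """Draw one complete abundance matrix + design + truth bundle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    proteins = [f"P{i:05d}" for i in range(1, cfg.n_proteins + 1)]

    mu = rng.normal(cfg.base_mu_mean, cfg.base_mu_sd, cfg.n_proteins)
    biased = rng.random(cfg.n_proteins) < cfg.frac_biased
    e_signed = rng.random(cfg.n_proteins) < cfg.frac_e_biased
    magnitude = np.abs(rng.normal(cfg.log2fc_mean, cfg.log2fc_sd, cfg.n_proteins))
    beta = np.where(biased, np.where(e_signed, -magnitude, magnitude), 0.0)

    bio_ids = [bio_sample_id(m, str(b)) for m in ("A", "E") for b in range(1, cfg.n_bio + 1)]
    bio_effect = rng.normal(0.0, cfg.sigma_bio, (cfg.n_proteins, len(bio_ids)))
    bio_log2 = {
        s: mu + (beta if s.startswith("A") else 0.0) + bio_effect[:, j]
        for j, s in enumerate(bio_ids)
    }

    run_ids = design["run_id"].tolist()
    log2_vals = np.empty((cfg.n_proteins, len(run_ids)))
    for j, (_, row) in enumerate(design.iterrows()):
        s = bio_sample_id(row["morph"], row["bio_rep"])
        log2_vals[:, j] = bio_log2[s] + rng.normal(0.0, cfg.sigma_tech, cfg.n_proteins)

    outlier_id = None
    if cfg.outlier_sample:
        # degrade one apyrene replicate: +2 global shift, heavy extra dropout
        out_rep = "4" if cfg.n_bio >= 4 else str(cfg.n_bio)
        outlier_id = bio_sample_id("A", out_rep)
        out_cols = design.index[(design["morph"] == "A") & (design["bio_rep"] == out_rep)].to_numpy()
        log2_vals[:, out_cols] += 2.0

    censor = np.zeros_like(log2_vals, dtype=bool)
    if cfg.mnar_threshold_quantile > 0:
        thresh = np.quantile(log2_vals, cfg.mnar_threshold_quantile, axis=0)
        censor = log2_vals < thresh
    dropout = (~censor) & (rng.random(log2_vals.shape) < cfg.mar_dropout_rate)
    if outlier_id is not None:
        extra = (~censor) & (rng.random(log2_vals.shape) < 0.5)
        extra[:, [j for j in range(len(run_ids)) if j not in set(out_cols)]] = False
        dropout |= extra

    values = np.exp2(log2_vals)
    values[censor | dropout] = np.nan
    abundance = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=run_ids)

    truth = SyntheticTruth(
        protein_truth=pd.DataFrame(
            {
                "true_log2fc": beta,
                "true_bias": np.where(
                    biased, np.where(e_signed, "E_biased", "A_biased"), "unbiased"
                ),
            },
            index=abundance.index,
        ),
        censor_mask=pd.DataFrame(censor, index=abundance.index, columns=run_ids),
        dropout_mask=pd.DataFrame(dropout, index=abundance.index, columns=run_ids),
        outlier_sample=outlier_id,
        config=cfg,
    )
    return Bundle(abundance, design, truth)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_protein_db(truth: SyntheticTruth, seed: int = 0) -> list[ProteinRecord]:
    """One random-sequence isoform per protein, gene G##### for protein P#####."""
    rng = np.random.default_rng(seed)
    records = []
    for pid in truth.protein_truth.index:
        length = int(rng.integers(50, 70))
        seq = "".join(rng.choice(_AA, length))
        records.append(ProteinRecord(pid, "G" + pid[1:], seq))
    return records


def gene_of(protein_id: str) -> str:
    return "G" + protein_id[1:]


def generate_annotation_fixture(
    truth: SyntheticTruth,
    enrich_mito_in_A: float = 0.5,
    enrich_signal_in_E: float = 0.5,
    base_mito: float = 0.1,
    base_signal: float = 0.1,
    annotated_rate: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene annotation table with planted feature enrichment.

    Mitochondrial-targeting flags are drawn at ``enrich_mito_in_A`` for truly
    apyrene-biased proteins and ``base_mito`` otherwise; signal peptides
    analogously for eupyrene-biased proteins.
    """
    for r in (enrich_mito_in_A, enrich_signal_in_E, base_mito, base_signal, annotated_rate):
        if not (0 <= r <= 1):
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bias = truth.protein_truth["true_bias"]
    rows = []
    for pid, b in bias.items():
        p_mito = enrich_mito_in_A if b == "A_biased" else base_mito
        p_sig = enrich_signal_in_E if b == "E_biased" else base_signal
        has_ann = rng.random() < annotated_rate
        rows.append(
            {
                "gene_id": gene_of(pid),
                "has_signal_peptide": bool(rng.random() < p_sig),
                "has_mito_target": bool(rng.random() < p_mito),
                "tm_domain_count": int(rng.poisson(0.5)),
                "description": f"synthetic protein {pid}" if has_ann else "",
                "blast_hit": f"sp|{pid}|SYN" if has_ann else "",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class PlantedTerm:
    """A GO term whose genes over-sample one bias subset."""

    namespace: str = "BP"
    n_genes: int = 10
    subset: str = "A_biased"
    odds_ratio: float = 8.0


def generate_go_fixture(
    n_terms: int,
    truth: SyntheticTruth,
    planted: PlantedTerm | None = None,
    mean_annotations_per_gene: float = 2.0,
    seed: int = 0,
) -> GoDag:
    """Random small GO DAG (three namespaces) with gene annotations.

    Each namespace gets a root and a random child→parent DAG; genes receive
    Poisson-many random direct annotations.  If ``planted`` is given, one
    extra term is attached whose ``n_genes`` annotated genes are drawn with
    weight ``odds_ratio`` for the chosen true-bias subset and 1 elsewhere.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms (one per namespace)")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    per_ns = {"BP": [], "CC": [], "MF": []}
    counter = 0
    for ns in per_ns:
        root = f"GO:{counter:07d}"
        counter += 1
        g.add_node(root, name=f"{ns} root", namespace=ns)
        per_ns[ns].append(root)
    for i in range(n_terms - 3):
        ns = ("BP", "CC", "MF")[i % 3]
        tid = f"GO:{counter:07d}"
        counter += 1
        g.add_node(tid, name=f"synthetic term {tid}", namespace=ns)
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(len(per_ns[ns]), size=min(n_parents, len(per_ns[ns])), replace=False)
        for pi in parents:
            g.add_edge(tid, per_ns[ns][int(pi)])
        per_ns[ns].append(tid)

    dag = GoDag(graph=g)
    genes = [gene_of(p) for p in truth.protein_truth.index]
    non_roots = [t for ns in per_ns for t in per_ns[ns][1:]] or [t for ns in per_ns for t in per_ns[ns]]
    for gene in genes:
        k = rng.poisson(mean_annotations_per_gene)
        for ti in rng.choice(len(non_roots), size=min(k, len(non_roots)), replace=False):
            dag.annotate(gene, non_roots[int(ti)])

    if planted is not None:
        tid = f"GO:{counter:07d}"
        g.add_node(tid, name="planted term", namespace=planted.namespace)
        g.add_edge(tid, per_ns[planted.namespace][0])
        in_subset = np.array([
            truth.protein_truth.at["P" + gn[1:], "true_bias"] == planted.subset for gn in genes
        ])
        w = np.where(in_subset, planted.odds_ratio, 1.0)
        w = w / w.sum()
        pick = rng.choice(len(genes), size=min(planted.n_genes, len(genes)), replace=False, p=w)
        for gi in pick:
            dag.annotate(genes[int(gi)], tid)
        dag.graph.nodes[tid]["planted"] = True
    return dag


def generate_ortholog_fixture(
    truth: SyntheticTruth,
    share_rates: dict[str, float],
    seed: int = 0,
) -> tuple[OrthologMap, dict[str, set[str]]]:
    """Ortholog map to two pseudo-species with subset-specific sperm sharing.

    Every focal gene gets exactly one ortholog in each comparison species;
    the ortholog lands inside that species' sperm-protein set with the
    ``share_rates`` probability of the focal gene's true-bias subset.
    """
    for k, v in share_rates.items():
        if not (0 <= v <= 1):
            raise ValueError(f"share rate {k}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    groups = []
    sperm_sets: dict[str, set[str]] = {sp: set() for sp in COMPARISON_SPECIES}
    for pid, b in truth.protein_truth["true_bias"].items():
        gene = gene_of(pid)
        members = {(FOCAL_SPECIES, gene)}
        rate = share_rates.get(b, 0.0)
        for sp in COMPARISON_SPECIES:
            og = f"{sp}_{gene}"
            members.add((sp, og))
            if rng.random() < rate:
                sperm_sets[sp].add(og)
        groups.append(frozenset(members))
    return (
        OrthologMap(species=[FOCAL_SPECIES, *COMPARISON_SPECIES], groups=groups),
        sperm_sets,
    )


def write_bundle(bundle: Bundle, outdir: str | Path, with_fixtures: bool = True) -> None:
    """Materialise a bundle as the text formats the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_matrix(bundle.abundance, outdir / "abundance.tsv")
    bundle.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    truth = bundle.truth
    truth.protein_truth.to_csv(outdir / "truth_proteins.tsv", sep="\t")
    truth.censor_mask.astype(int).to_csv(outdir / "truth_censor_mask.tsv", sep="\t")
    truth.dropout_mask.astype(int).to_csv(outdir / "truth_dropout_mask.tsv", sep="\t")
    manifest = {"outlier_sample": truth.outlier_sample, "config": asdict(truth.config)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if not with_fixtures:
        return
    cfg = truth.config
    write_protein_fasta(generate_protein_db(truth, seed=cfg.seed), outdir / "proteins.fasta")
    generate_annotation_fixture(truth, seed=cfg.seed).to_csv(outdir / "annotations.tsv", sep="\t")
    dag = generate_go_fixture(60, truth, planted=PlantedTerm(), seed=cfg.seed)
    with open(outdir / "gene2go.tsv", "w", encoding="utf-8") as fh:
        for gene, terms in sorted(dag.annotations.items()):
            for t in sorted(terms):
                fh.write(f"{gene}\t{t}\n")
    _write_obo(dag, outdir / "ontology.obo")
    orthomap, sperm_sets = generate_ortholog_fixture(
        bundle.truth, {"A_biased": 0.4, "E_biased": 0.7, "unbiased": 0.45}, seed=cfg.seed
    )
    _write_proteinortho(orthomap, outdir / "orthologs.tsv")
    for sp, genes in sperm_sets.items():
        (outdir / f"sperm_{sp}.txt").write_text("\n".join(sorted(genes)) + "\n")


def _write_obo(dag: GoDag, path: Path) -> None:
    ns_long = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for node, data in dag.graph.nodes(data=True):
            fh.write(f"\n[Term]\nid: {node}\nname: {data.get('name', node)}\n")
            fh.write(f"namespace: {ns_long.get(data.get('namespace'), 'biological_process')}\n")
            for parent in dag.graph.successors(node):
                fh.write(f"is_a: {parent} ! parent\n")


def _write_proteinortho(orthomap: OrthologMap, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Species\tGenes\tAlg.-Conn.\t" + "\t".join(orthomap.species) + "\n")
        for grp in orthomap.groups:
            by_sp: dict[str, list[str]] = {}
            for sp, gene in sorted(grp):
                by_sp.setdefault(sp, []).append(gene)
            n_sp = len(by_sp)
            n_genes = sum(len(v) for v in by_sp.values())
            cells = [",".join(sorted(by_sp.get(sp, []))) or "*" for sp in orthomap.species]
            fh.write(f"{n_sp}\t{n_genes}\t1\t" + "\t".join(cells) + "\n")
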