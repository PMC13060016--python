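"""Annotation-proportion tests and conditional GO-term enrichment.

Two functional questions are asked of the bias subsets (apyrene-biased,
eupyrene-biased, unbiased):

1. Do annotation features (signal peptide, mitochondrial targeting,
   transmembrane domains, any functional annotation) occur at different
   rates across the three subsets?  Tested by a Pearson chi-square of
   homogeneity on the 3 × 2 count table.
2. Which GO terms are over-represented in each subset against the universe
   of all detected sperm proteins?  Tested per term with the hypergeometric
   upper tail; the *conditional* variant walks the ontology children before
   parents and, whenever a term is significant, removes its annotated genes
   from every ancestor before the ancestor is tested — so a parent is only
   called when it carries signal beyond its significant children.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats

__all__ = [
    "GoDag",
    "chisq_homogeneity",
    "propagate_annotations",
    "hypergeom_enrich",
    "conditional_enrich",
]

NAMESPACES = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
_NS_SHORT = {v: k for k, v in NAMESPACES.items()}


@dataclass
class GoDag:
    """A GO ontology fragment plus gene → term annotations.

    ``graph`` is a directed graph with edges child → parent (``is_a``, and by
    default ``part_of`` treated alike); node attributes carry ``name`` and
    ``namespace`` ('BP' | 'CC' | 'MF').  ``annotations`` maps each gene to
    the set of terms it is directly annotated to.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]] = field(default_factory=dict)
    propagated: bool = False

    @classmethod
    def from_obo(cls, path: str | Path, include_part_of: bool = True) -> "GoDag":
        multi = obonet.read_obo(str(path))
        g = nx.DiGraph()
        for node, data in multi.nodes(data=True):
            ns = data.get("namespace", "")
            g.add_node(node, name=data.get("name", node), namespace=_NS_SHORT.get(ns, ns))
        keep = {"is_a"} | ({"part_of"} if include_part_of else set())
        for child, parent, key in multi.edges(keys=True):
            if key in keep:
                g.add_edge(child, parent)
        return cls(graph=g)

    def load_annotations(self, path: str | Path) -> "GoDag":
        """Two-column TSV: gene_id, GO term id."""
        df = pd.read_csv(Path(path), sep="\t", header=None, names=["gene_id", "term"],
                         dtype=str, comment="#", encoding="utf-8")
        for gene, term in df.itertuples(index=False):
            self.annotate(gene, term)
        return self

    def annotate(self, gene: str, term: str) -> None:
        if term not in self.graph:
            raise ValueError(f"annotation to unknown GO term {term!r}")
        self.annotations.setdefault(gene, set()).add(term)

    def terms_in(self, namespace: str) -> list[str]:
        return [t for t, d in self.graph.nodes(data=True) if d.get("namespace") == namespace]

    def genes_of(self, term: str) -> set[str]:
        return {g for g, ts in self.annotations.items() if term in ts}


def chisq_homogeneity(counts: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity on a subsets × (feature, no-feature)
    table.

    ``counts`` needs columns ``n_with_feature`` and ``n_total`` with one row
    per subset.  No continuity correction (the study's 3 × 2 tables have
    df = 2, where Yates is inapplicable anyway).  Warns when any expected
    cell is below 5.
    """
    if (counts["n_total"] <= 0).any():
        bad = counts.index[counts["n_total"] <= 0].tolist()
        raise ValueError(f"subset(s) {bad} have zero total proteins")
    if (counts["n_with_feature"] > counts["n_total"]).any():
        raise ValueError("n_with_feature exceeds n_total")
    table = np.column_stack(
        [counts["n_with_feature"], counts["n_total"] - counts["n_with_feature"]]
    )
    if table.sum(axis=0).min() == 0:
        # a column of zeros (feature never/always present) → no heterogeneity
        return 0.0, int(len(counts) - 1), 1.0
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected cell count below 5; p-value approximate")
    return float(chi2), int(df), float(p)


def _check_acyclic(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"GO graph contains a cycle: {cycle}")


def propagate_annotations(dag: GoDag) -> GoDag:
    """Apply the true-path rule: every gene annotated to a term is also
    annotated to all ancestors of that term (within its namespace, which
    edges never leave).  Idempotent."""
    _check_acyclic(dag.graph)
    ancestors: dict[str, set[str]] = {}
    for term in reversed(list(nx.topological_sort(dag.graph))):  # parents first
        anc = set()
        for parent in dag.graph.successors(term):
            anc.add(parent)
            anc |= ancestors[parent]
        ancestors[term] = anc
    new_ann = {
        gene: set().union(*({t} | ancestors[t] for t in terms)) if terms else set()
        for gene, terms in dag.annotations.items()
    }
    return GoDag(graph=dag.graph, annotations=new_ann, propagated=True)


def _term_universe_genes(dag: GoDag, universe: set[str]) -> dict[str, set[str]]:
    per_term: dict[str, set[str]] = {}
    for gene, terms in dag.annotations.items():
        if gene in universe:
            for t in terms:
                per_term.setdefault(t, set()).add(gene)
    return per_term


def _result_row(term: str, dag: GoDag, genes_u: set[str], subset: set[str],
                n: int, N: int, conditioned: bool) -> dict:
    K = len(genes_u)
    k = len(genes_u & subset)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return {
        "term": term,
        "name": dag.graph.nodes[term].get("name", term),
        "namespace": dag.graph.nodes[term].get("namespace", ""),
        "k": k, "K": K, "n": n, "N": N,
        "p": min(p, 1.0),
        "conditioned": conditioned,
    }


def _validate_sets(dag: GoDag, subset: set, universe: set) -> None:
    if not dag.propagated:
        raise ValueError("annotations must be propagated before enrichment")
    extra = set(subset) - set(universe)
    if extra:
        raise ValueError(f"subset gene(s) outside the universe: {sorted(extra)[:5]}")


def hypergeom_enrich(
    dag: GoDag,
    subset: set[str],
    universe: set[str],
    namespace: str,
    min_size: int = 3,
) -> pd.DataFrame:
    """Unconditional per-term over-representation test.

    For each term of ``namespace`` with at least ``min_size`` annotated genes
    in the universe: ``p = P[X >= k]`` with
    ``X ~ Hypergeometric(N=len(universe), K, n=len(subset))``.
    """
    _validate_sets(dag, subset, universe)
    subset, universe = set(subset), set(universe)
    per_term = _term_universe_genes(dag, universe)
    n, N = len(subset), len(universe)
    rows = [
        _result_row(t, dag, per_term[t], subset, n, N, conditioned=False)
        for t in dag.terms_in(namespace)
        if len(per_term.get(t, ())) >= min_size
    ]
    return _as_frame(rows)


def conditional_enrich(
    dag: GoDag,
    subset: set[str],
    universe: set[str],
    namespace: str,
    p_cutoff: float = 0.05,
    min_size: int = 3,
) -> pd.DataFrame:
    """Conditional hypergeometric enrichment over the GO DAG.

    Terms are visited children before parents.  When a term's p-value falls
    below ``p_cutoff``, its universe-annotated genes are removed from the
    annotation sets of all its ancestors before those are tested, so
    ancestors must show enrichment beyond what their significant descendants
    already explain.  With nothing significant the output equals the
    unconditional test.
    """
    _validate_sets(dag, subset, universe)
    _check_acyclic(dag.graph)
    subset, universe = set(subset), set(universe)
    per_term = _term_universe_genes(dag, universe)
    n, N = len(subset), len(universe)

    removed: dict[str, set[str]] = {}
    ancestors_cache: dict[str, set[str]] = {}
    rows = []
    ns_terms = set(dag.terms_in(namespace))
    for term in nx.topological_sort(dag.graph):  # children before parents
        if term not in ns_terms:
            continue
        genes_full = per_term.get(term, set())
        if len(genes_full) < min_size:
            continue
        cut = removed.get(term, set())
        genes = genes_full - cut
        row = _result_row(term, dag, genes, subset, n, N, conditioned=bool(cut))
        rows.append(row)
        if row["p"] < p_cutoff:
            anc = ancestors_cache.get(term)
            if anc is None:
                anc = nx.descendants(dag.graph, term)  # ancestors in child→parent orientation
                ancestors_cache[term] = anc
            for a in anc:
                removed.setdefault(a, set()).update(genes_full)
    return _as_frame(rows)


def _as_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["term", "name", "namespace", "k", "K", "n", "N", "p", "conditioned"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["p", "term"], kind="mergesort")
        .reset_index(drop=True)
    )


def annotation_subset_counts(
    annotations: pd.DataFrame, subsets: dict[str, set[str]], feature: str
) -> pd.DataFrame:
    """Count annotation-feature carriers per bias subset.

    ``feature`` is a boolean column of the annotation table, or
    ``tm_domain_count`` (counted as carrier when > 0), or ``annotated``
    (non-empty description or BLAST hit).  Genes missing from the annotation
    table count as non-carriers.
    """
    rows = {}
    for name, genes in subsets.items():
        present = [g for g in genes if g in annotations.index]
        if feature == "tm_domain_count":
            carriers = int((annotations.loc[present, "tm_domain_count"] > 0).sum())
        elif feature == "annotated":
            sub = annotations.loc[present]
            carriers = int(((sub["description"] != "") | (sub["blast_hit"] != "")).sum())
        else:
            carriers = int(annotations.loc[present, feature].astype(bool).sum())
        rows[name] = {"n_with_feature": carriers, "n_total": len(genes)}
    return pd.DataFrame.from_dict(rows, orient="index")
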