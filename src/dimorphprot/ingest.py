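"""Readers, writers and protein-database curation.

All tabular inputs are plain UTF-8 text (TSV canonical, CSV accepted).
Abundance matrices are held as :class:`pandas.DataFrame` objects with protein
IDs on the index, MS-run IDs on the columns, and ``NaN`` marking a
non-detection.  A cell of ``0`` in a label-free export is not a measurement
— quantification engines use blank and zero interchangeably for "feature not
found" — so zeros are mapped to missing on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "OrthologMap",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_sample_design",
    "read_protein_fasta",
    "dedupe_protein_db",
    "longest_isoform",
    "read_ortholog_table",
    "read_annotation_table",
    "read_id_list",
]

#: tokens interpreted as "not detected" in abundance exports
MISSING_TOKENS = {"", "na", "nan", "0", "0.0"}

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of a predicted-protein database."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r} contains non-amino-acid symbols {sorted(bad)}"
            )


@dataclass
class OrthologMap:
    """Ortholog groups across species, as produced by a reciprocal-best-hit
    graph pipeline (ProteinOrtho-style table).

    Each group is a set of ``(species, gene_id)`` pairs; a pair belongs to at
    most one group.
    """

    species: list[str]
    groups: list[frozenset[tuple[str, str]]] = field(default_factory=list)

    def groups_of(self, species: str, gene_id: str) -> list[frozenset]:
        return [g for g in self.groups if (species, gene_id) in g]

    def members(self, species: str) -> set[str]:
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}; have {self.species}")
        return {g for grp in self.groups for (sp, g) in grp if sp == species}


def _sep_for(path: Path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "generic_tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_abundance_matrix(path: str | Path, dialect: str = "generic_tsv") -> pd.DataFrame:
    """Read a proteins × runs abundance table.

    First column holds protein IDs, the header row holds run IDs.  Blank,
    ``NA``, ``NaN`` and ``0`` cells become missing (``NaN``); every other cell
    must parse as a positive real.

    Raises
    ------
    ValueError
        on duplicate protein IDs (naming the ID), on non-numeric cells
        (naming row and column), or on negative values.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=_sep_for(path, dialect), index_col=0, dtype=str,
        keep_default_na=False, encoding="utf-8",
    )
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate protein ID(s) in {path.name}: {dup}")
    dup_runs = raw.columns[raw.columns.duplicated()].unique().tolist()
    if dup_runs:
        raise ValueError(f"duplicate run ID(s) in {path.name}: {dup_runs}")

    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            token = cell.strip()
            if token.lower() in MISSING_TOKENS:
                continue
            try:
                v = float(token)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at protein {raw.index[i]!r}, run {col!r}"
                ) from None
            if v == 0:
                continue
            if v < 0 or not np.isfinite(v):
                raise ValueError(
                    f"invalid abundance {v!r} at protein {raw.index[i]!r}, run {col!r}"
                )
            values[i, j] = v
    out = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    out.index.name = "protein_id"
    return out


def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path, dialect: str = "generic_tsv") -> None:
    """Write a matrix so that :func:`read_abundance_matrix` round-trips it
    bit-exactly (``repr`` floats, blanks for missing)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id" + sep + sep.join(map(str, matrix.columns)) + "\n")
        for pid, row in matrix.iterrows():
            cells = ["" if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(pid) + sep + sep.join(cells) + "\n")


_MORPH_ALIASES = {
    "a": "A", "apyrene": "A", "A": "A",
    "e": "E", "eupyrene": "E", "E": "E",
}


def read_sample_design(path: str | Path, dialect: str = "generic_tsv") -> pd.DataFrame:
    """Read the run → (morph, biological replicate, technical replicate) map.

    Expected columns: ``run_id``, ``morph`` (apyrene/eupyrene or A/E),
    ``bio_rep``, ``tech_rep``.  Run IDs are opaque strings; no structure is
    ever parsed out of them.
    """
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path), dialect), dtype=str, encoding="utf-8")
    return validate_sample_design(df)


def validate_sample_design(df: pd.DataFrame) -> pd.DataFrame:
    required = ["run_id", "morph", "bio_rep", "tech_rep"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"sample design lacks column(s) {missing_cols}")
    df = df[required].astype(str).copy()
    try:
        df["morph"] = [_MORPH_ALIASES[m.strip().lower() if m.strip().lower() in _MORPH_ALIASES else m] for m in df["morph"]]
    except KeyError as e:
        raise ValueError(f"unknown morph label {e.args[0]!r} (expected apyrene/eupyrene or A/E)") from None
    if df["run_id"].duplicated().any():
        raise ValueError("duplicate run_id in sample design")
    trip = df[["morph", "bio_rep", "tech_rep"]].apply(tuple, axis=1)
    if trip.duplicated().any():
        raise ValueError("duplicate (morph, bio_rep, tech_rep) triple in sample design")
    for morph, sub in df.groupby("morph"):
        if sub["bio_rep"].nunique() < 2:
            raise ValueError(f"morph {morph!r} has fewer than 2 biological replicates")
    return df


def read_protein_fasta(path: str | Path, gene_pattern: str = r"gene=(\S+)") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The gene ID is taken from the header description via ``gene_pattern``
    (default ``gene=<id>``); records without a match use the protein ID as
    their own gene.
    """
    pat = re.compile(gene_pattern)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein ID {rec.id!r} in {path}")
        seen.add(rec.id)
        m = pat.search(rec.description)
        gene = m.group(1) if m else rec.id
        records.append(ProteinRecord(rec.id, gene, str(rec.seq)))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.protein_id} gene={r.gene_id}\n{r.sequence}\n")


def dedupe_protein_db(records: list[ProteinRecord], seed: int) -> list[ProteinRecord]:
    """Collapse redundant transcripts of a predicted-protein set.

    Within each gene, transcripts encoding an identical protein sequence are
    reduced to a single representative chosen by a seeded RNG, so that every
    distinct isoform sequence per gene survives exactly once.  Deterministic
    for a given seed, and idempotent.
    """
    rng = np.random.default_rng(seed)
    # representative per (gene, sequence), chosen among sorted candidates
    chosen: dict[tuple[str, str], str] = {}
    by_key: dict[tuple[str, str], list[str]] = {}
    for r in records:
        by_key.setdefault((r.gene_id, r.sequence), []).append(r.protein_id)
    for key in sorted(by_key):
        cands = sorted(by_key[key])
        chosen[key] = cands[int(rng.integers(len(cands)))]
    return [r for r in records if chosen[(r.gene_id, r.sequence)] == r.protein_id]


def longest_isoform(records: list[ProteinRecord]) -> dict[str, str]:
    """Map each gene to its longest protein isoform.

    Length ties break lexicographically by protein ID, which makes the choice
    reproducible across runs and platforms.
    """
    if not records:
        raise ValueError("longest_isoform requires a non-empty record list")
    best: dict[str, ProteinRecord] = {}
    for r in records:
        cur = best.get(r.gene_id)
        if (
            cur is None
            or len(r.sequence) > len(cur.sequence)
            or (len(r.sequence) == len(cur.sequence) and r.protein_id < cur.protein_id)
        ):
            best[r.gene_id] = r
    return {g: r.protein_id for g, r in best.items()}


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Parse a ProteinOrtho result table.

    Layout: three leading columns (``# Species``, ``Genes``, ``Alg.-Conn.``)
    then one column per species holding comma-separated gene IDs or ``*`` for
    "no member".  Each gene may appear in at most one group.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = [c.lstrip("#").strip().lower() for c in header[:3]]
        if len(header) < 4 or cols[0] != "species" or cols[1] != "genes" or not cols[2].startswith("alg"):
            raise ValueError(
                f"{path.name}: malformed ProteinOrtho header {header[:3]!r} "
                "(expected '# Species', 'Genes', 'Alg.-Conn.', then species columns)"
            )
        species = [c.strip() for c in header[3:]]
        groups: list[frozenset[tuple[str, str]]] = []
        seen: dict[tuple[str, str], int] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            members: set[tuple[str, str]] = set()
            for sp, cell in zip(species, fields[3:]):
                cell = cell.strip()
                if cell in {"*", ""}:
                    continue
                for gene in cell.split(","):
                    gene = gene.strip()
                    if not gene:
                        continue
                    key = (sp, gene)
                    if key in seen:
                        raise ValueError(
                            f"{path.name}: gene {gene!r} of species {sp!r} appears in "
                            f"rows {seen[key]} and {lineno}"
                        )
                    seen[key] = lineno
                    members.add(key)
            if members:
                groups.append(frozenset(members))
    return OrthologMap(species=species, groups=groups)


_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False,
                "yes": True, "no": False, "y": True, "n": False}


def read_annotation_table(path: str | Path, dialect: str = "generic_tsv") -> pd.DataFrame:
    """Read the per-gene functional annotation table.

    Columns: ``gene_id``, ``has_signal_peptide``, ``has_mito_target``,
    ``tm_domain_count``, ``description``, ``blast_hit`` (last two optional /
    may be empty).  These are consumed as the tabular outputs of upstream
    sequence-feature predictors; the predictors themselves are never run here.
    """
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path), dialect), dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if "gene_id" not in df.columns:
        raise ValueError("annotation table lacks 'gene_id' column")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id(s) in annotation table: {dups}")
    out = pd.DataFrame(index=pd.Index(df["gene_id"], name="gene_id"))
    for col in ("has_signal_peptide", "has_mito_target"):
        out[col] = [_parse_bool(v, col) for v in df[col]]
    out["tm_domain_count"] = [_parse_count(v) for v in df["tm_domain_count"]]
    out["description"] = df.get("description", pd.Series([""] * len(df))).values
    out["blast_hit"] = df.get("blast_hit", pd.Series([""] * len(df))).values
    return out


def _parse_bool(v: str, col: str) -> bool:
    try:
        return _BOOL_TOKENS[v.strip().lower()]
    except KeyError:
        raise ValueError(f"cannot parse {v!r} as boolean in column {col!r}") from None


def _parse_count(v: str) -> int:
    n = int(v)
    if n < 0:
        raise ValueError(f"negative transmembrane-domain count {n}")
    return n


def read_id_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out
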