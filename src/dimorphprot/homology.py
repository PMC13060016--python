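"""Cross-species sperm-proteome sharing through ortholog groups.

A focal sperm gene is "shared" with a comparison species when some ortholog
group contains both the focal gene and at least one gene of that species
that itself belongs to the species' sperm-protein set — orthology alone is
not enough; the ortholog must have been detected in sperm.  Many-to-many
groups count as shared if any co-member qualifies.  Sharing proportions are
tabulated per bias subset and compared with a chi-square of homogeneity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .enrich import chisq_homogeneity
from .ingest import OrthologMap

__all__ = ["cross_reference", "sharing_chisq"]


def cross_reference(
    focal_genes: dict[str, set[str]],
    orthomap: OrthologMap,
    focal_species: str,
    other_species: str,
    other_sperm: set[str],
) -> pd.DataFrame:
    """Tabulate sperm-proteome sharing with one comparison species.

    Parameters
    ----------
    focal_genes : bias subset name → set of focal-species gene IDs.
    other_sperm : sperm-protein gene IDs of the comparison species.

    Returns a frame indexed by subset with ``n_shared``, ``n_total`` and
    ``proportion``; empty subsets are excluded with a warning.
    """
    for sp in (focal_species, other_species):
        if sp not in orthomap.species:
            raise ValueError(f"species {sp!r} not in ortholog table ({orthomap.species})")

    # genes of the focal species whose group contains a sperm ortholog
    shared_focal: set[str] = set()
    for group in orthomap.groups:
        if any(sp == other_species and g in other_sperm for sp, g in group):
            shared_focal.update(g for sp, g in group if sp == focal_species)

    rows = {}
    for name, genes in focal_genes.items():
        if not genes:
            warnings.warn(f"subset {name!r} is empty; excluded from sharing table")
            continue
        n_shared = len(set(genes) & shared_focal)
        rows[name] = {
            "n_shared": n_shared,
            "n_total": len(genes),
            "proportion": n_shared / len(genes),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subset"
    out.attrs["other_species"] = other_species
    return out


def sharing_chisq(table: pd.DataFrame) -> tuple[float, int, float]:
    """Chi-square of homogeneity of sharing proportions across subsets."""
    counts = pd.DataFrame(
        {"n_with_feature": table["n_shared"], "n_total": table["n_total"]}
    )
    return chisq_homogeneity(counts)
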