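import numpy as np
import pandas as pd
import pytest

from dimorphprot.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A modest default-structure bundle shared by read-only tests."""
    return generate_bundle(SyntheticConfig(n_proteins=400, seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size bundle at study-scale defaults."""
    return generate_bundle(SyntheticConfig(seed=7))


@pytest.fixture
def tiny_design():
    """2 morphs x 2 bio reps x 2 tech reps."""
    rows = []
    for m in ("A", "E"):
        for b in ("1", "2"):
            for t in ("1", "2"):
                rows.append({"run_id": f"r{m}{b}{t}", "morph": m, "bio_rep": b, "tech_rep": t})
    return pd.DataFrame(rows)


def make_matrix(values, proteins=None, runs=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    runs = runs or [f"r{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=runs)
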