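import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stimskew as sk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_matrix(counts, groups, gene_ids=None, lengths=None, study=None):
    """Build a CountMatrix from a plain array and group labels."""
    counts = np.asarray(counts)
    genes = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame({"group": groups}, index=samples)
    if study is not None:
        meta["study"] = study
    gl = None if lengths is None else pd.Series(lengths, index=genes)
    return sk.CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta, gl)


@pytest.fixture(scope="session")
def null_three_group():
    """A seeded all-null three-group dataset shared across tests."""
    cfg = sk.SimulationConfig(seed=11, n_genes=600, category_fractions={})
    return sk.simulate_three_group(cfg)


@pytest.fixture(scope="session")
def planted_three_group():
    """A seeded dataset with planted core/skewed categories."""
    cfg = sk.SimulationConfig(seed=5, n_genes=1200)
    return sk.simulate_three_group(cfg)
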