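import numpy as np
import pandas as pd
import pytest

import urchintx as ux


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    """3 genes x 5 stages with the housekeeping trio whose geometric mean
    is exactly 1000 at every stage."""
    stages = list(ux.UNIFIED_STAGES)
    values = pd.DataFrame(
        {
            s: [500.0, 1000.0, 2000.0, 100.0 * (i + 1), 3.0]
            for i, s in enumerate(stages)
        },
        index=["GAPDH", "ODC", "HPRT", "geneA", "geneB"],
    )
    return ux.ExpressionTable("S. purpuratus", ux.Unit.RPM, values)


def random_table(rng, n_genes=50, n_stages=5, species="S. purpuratus"):
    """Random positive table including the housekeeping trio."""
    stages = list(ux.UNIFIED_STAGES)[:n_stages]
    hk = rng.uniform(100.0, 10000.0, size=(3, n_stages))
    body = rng.uniform(0.0, 5000.0, size=(n_genes, n_stages))
    values = pd.DataFrame(
        np.vstack([hk, body]),
        index=["GAPDH", "ODC", "HPRT"] + [f"g{i}" for i in range(n_genes)],
        columns=stages,
    )
    return ux.ExpressionTable(species, ux.Unit.FPKM, values)


@pytest.fixture
def sp_cohort():
    """Default synthetic cohort on the S. purpuratus grid (500 genes)."""
    config = ux.GeneratorConfig(seed=42)
    return ux.generate_bulk_dataset(config, "S. purpuratus")
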