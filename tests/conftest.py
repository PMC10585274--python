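import numpy as np
import pandas as pd
import pytest

from mrmediate.io import CANONICAL_COLUMNS


def make_frame(rows):
    """Build a canonical summary-statistics DataFrame from compact dicts.

    Unspecified fields get innocuous defaults; ``rows`` may override any
    canonical column.
    """
    defaults = {
        "chrom": "1",
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "se": 0.01,
        "pval": 1e-8,
        "n": 10_000.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"snp_id": f"rs{i+1}", "pos": 1_000_000 + i * 1000, "beta": 0.1, **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out, columns=list(CANONICAL_COLUMNS))


@pytest.fixture
def small_study():
    """A compact simulated three-trait study used across tests."""
    from mrmediate import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(n_snps=80, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
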