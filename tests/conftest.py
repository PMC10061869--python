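import numpy as np
import pandas as pd
import pytest

import evarseq as ev


@pytest.fixture(scope="session")
def small_sim():
    """Small trend-only dataset: one dose, three groups, no planted effects."""
    cfg = ev.SimConfig(
        n_genes=400,
        samples_per_group=12,
        doses=("0",),
        frac_hyper=0.0,
        frac_hypo=0.0,
        frac_bimodal=0.0,
        frac_de=0.0,
        seed=7,
    )
    counts, metadata, truth = ev.simulate_counts(cfg)
    return cfg, counts, metadata, truth


@pytest.fixture(scope="session")
def small_size_factors(small_sim):
    _, counts, _, _ = small_sim
    return ev.compute_size_factors(counts)


@pytest.fixture()
def tiny_counts():
    """3x3 integer matrix with readable ids."""
    return pd.DataFrame(
        np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=np.int64),
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3"],
    )
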