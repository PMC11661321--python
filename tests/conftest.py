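import numpy as np
import pandas as pd
import pytest

from tgvis import SimConfig, simulate_locus


def make_sumstats_frame(ids, a1, a2, beta, se=None, n=1000.0,
                        chrom="1", pos=None):
    m = len(ids)
    return pd.DataFrame({
        "id": list(ids), "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "a1": list(a1), "a2": list(a2),
        "beta": np.asarray(beta, float),
        "se": np.ones(m) if se is None else np.asarray(se, float),
        "n": n,
    })


@pytest.fixture(scope="session")
def small_locus():
    """A small synthetic locus (4 genes x 2 tissues, M=60) for fast
    pipeline-level tests."""
    cfg = SimConfig(n_genes=4, n_tissues=2, M=60, block_size=20,
                    causal_pairs=(0, 7), shared_pool_size=10,
                    scenario="none", seed=11)
    return simulate_locus(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
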