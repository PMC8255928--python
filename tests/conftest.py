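import numpy as np
import pandas as pd
import pytest

from lncnet.io import ExpressionMatrix
from lncnet.simulate import SimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_cfg():
    """Small cohort: 6 vs 6 samples, 300 genes, one planted module."""
    return SimConfig(
        n_genes=225,
        n_lnc=75,
        de_fraction=0.1,
        log2fc_effect=2.0,
        module_spec=((10, 0.9),),
        seed=7,
        noise_sd=0.3,
        n_cis_pairs=6,
        n_duplex_pairs=6,
        tx_len_range=(300, 900),
        genome_len=60_000_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_expression(small_cfg)


def toy_matrix(values, samples=None, n_control=None):
    """Build an ExpressionMatrix from a 2-D array; first half of the
    columns are controls unless n_control is given."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if samples is None:
        samples = [f"X{i}" for i in range(n)]
    if n_control is None:
        n_control = n // 2
    groups = {
        s: ("control" if i < n_control else "case") for i, s in enumerate(samples)
    }
    df = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples
    )
    return ExpressionMatrix(df, groups)
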