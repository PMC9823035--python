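import numpy as np
import pytest

import pecknet as pn
from pecknet import simulate as sim


@pytest.fixture
def small_cfg():
    """A small but fully featured cohort configuration."""
    return pn.SimConfig(
        seed=11,
        n_samples=150,
        n_chromosomes=3,
        n_variants_per_chrom=50,
        n_chip_per_chrom=60,
        n_genes=20,
        n_expr_samples=100,
        tf_hub=(0, tuple(range(1, 8)), 0.8),
        qtl_spec=((70, 0.047),),
        n_background_genes=30,
        n_sv_truth=40,
    )


@pytest.fixture
def small_cohort(small_cfg):
    return sim.simulate_cohort(small_cfg)


def ols_scan(x, y, w):
    """Independent per-variant OLS oracle: regress y on [w, x] column-wise."""
    import numpy.linalg as la

    betas = []
    for j in range(x.shape[1]):
        design = np.column_stack([w, x[:, j]])
        coef, *_ = la.lstsq(design, y, rcond=None)
        betas.append(coef[-1])
    return np.array(betas)
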