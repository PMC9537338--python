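import numpy as np
import pytest

from avcycle.simulate import SimConfig, make_gene_panel, simulate_single_cells


def scaled_config(**overrides) -> SimConfig:
    """A ratio-preserving scaled-down study configuration for fast tests.

    Keeps the default panel fractions (2% state-signature genes per state,
    1% arterial/venous, 0.4% TGF/BMP) at 500 cells x 1500 genes.
    """
    base = dict(
        n_cells=500,
        n_genes=1500,
        n_state_genes_per_state=30,
        n_arterial_genes=15,
        n_venous_genes=15,
        n_tgf_genes=6,
        n_bmp_genes=6,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One shared scaled dataset with default (coupled) parameters."""
    cfg = scaled_config(seed=1)
    panel = make_gene_panel(cfg)
    return cfg, panel, simulate_single_cells(cfg, panel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
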