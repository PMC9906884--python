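import numpy as np
import pytest

from twaskit import RankedList, simulate_ld_block, simulate_weight_panel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ranked():
    """Five genes ranked 5..1, ids a..e."""
    return RankedList(np.array(list("abcde"), dtype=object), np.array([5.0, 4, 3, 2, 1]))


@pytest.fixture(scope="session")
def null_twas_table():
    """A 2000-gene TWAS scan on null GWAS data (no causal genes).

    Session-scoped: shared by calibration tests across modules.
    """
    from twaskit import simulate_gwas_z, twas_scan

    panels = simulate_weight_panel(2000, 5, seed=42)
    ld = {p.gene: simulate_ld_block(5, 0.5) for p in panels}
    gwas = simulate_gwas_z(panels, ld, causal_genes=None, effect_size=0.0, seed=42)
    return twas_scan(panels, gwas, ld, ridge=0.0)


def make_ranked(n, seed, ties=False):
    """Random ranked list of n genes with standard-normal statistics."""
    r = np.random.default_rng(seed)
    stats = r.standard_normal(n)
    if ties:
        stats = np.round(stats, 1)
    genes = np.array([f"g{i:04d}" for i in range(n)], dtype=object)
    return RankedList(genes, stats)
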