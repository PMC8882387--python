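import numpy as np
import pytest

from mkomega import (
    FitOptions,
    GeneRecord,
    SiteFrequencySpectrum,
    SyntheticConfig,
    simulate_dataset,
)
from mkomega.sfs import NONSYNONYMOUS, SYNONYMOUS


def make_gene(
    gene_id="g0",
    n=6,
    L_syn=100.0,
    L_nonsyn=300.0,
    sfs_syn=None,
    sfs_nonsyn=None,
    D_syn=2.0,
    D_nonsyn=3.0,
    **kwargs,
):
    """Small hand-built gene record for structural tests."""
    if sfs_syn is None:
        sfs_syn = np.zeros(n - 1)
    if sfs_nonsyn is None:
        sfs_nonsyn = np.zeros(n - 1)
    return GeneRecord(
        gene_id=gene_id,
        L_syn=L_syn,
        L_nonsyn=L_nonsyn,
        sfs_syn=SiteFrequencySpectrum(n, np.asarray(sfs_syn, float), site_class=SYNONYMOUS),
        sfs_nonsyn=SiteFrequencySpectrum(n, np.asarray(sfs_nonsyn, float), site_class=NONSYNONYMOUS),
        D_syn=D_syn,
        D_nonsyn=D_nonsyn,
        **kwargs,
    )


@pytest.fixture(scope="session")
def fast_opts():
    """Reduced multi-start for bulk fitting in tests; the profiled
    2-D likelihood is smooth, so two starts locate the same optimum."""
    return FitOptions(n_starts=2)


@pytest.fixture(scope="session")
def small_world():
    """A modest default-structure synthetic world shared across tests."""
    cfg = SyntheticConfig(n_genes=1200, n_go_categories=8, go_membership_mean=1.5, seed=101)
    return simulate_dataset(cfg)
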