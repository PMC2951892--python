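import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None)
settings.load_profile("default")

from eesnet import NetworkConfig, build_synthetic_network, fit_ees, knockout_panel
from eesnet.affine import random_stable_affine


@pytest.fixture(scope="session")
def default_net():
    return build_synthetic_network(NetworkConfig(seed=0))


@pytest.fixture(scope="session")
def affine12():
    """Small affine surrogate: exactly linear ground truth, N=12."""
    return random_stable_affine(12, np.random.default_rng(42))


@pytest.fixture(scope="session")
def affine12_ees(affine12):
    """EES fitted on the affine surrogate's exact knockout equilibria
    (internal genes 0..3)."""
    internal = [0, 1, 2, 3]
    kos = np.array([affine12.clamped_equilibrium({g: 0.0}) for g in internal])
    return fit_ees(affine12.x_star, kos, internal, gene_ids=affine12.gene_ids)


@pytest.fixture(scope="session")
def net_ees(default_net):
    """EES on the default synthetic network, 6 viable internal genes."""
    from eesnet.pipeline import select_internal_genes

    panel = knockout_panel(default_net, range(default_net.n_genes))
    internal = select_internal_genes(default_net, panel, 6)
    by_gene = {next(iter(st.mutant.clamps)): st for st in panel}
    ees = fit_ees(
        default_net.x_star,
        np.array([by_gene[g].x for g in internal]),
        [default_net.gene_ids[g] for g in internal],
        gene_ids=default_net.gene_ids,
    )
    return default_net, ees, internal
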