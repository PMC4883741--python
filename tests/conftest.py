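import dendropy
import numpy as np
import pytest

from pglspatial.covariance import build_covariance_set
from pglspatial.simulate import make_fixture, simulate_sites, simulate_tree
from pglspatial.tree_io import PhyloTree


@pytest.fixture
def hand_tree():
    """((A:1,B:1):1,C:2); — the worked example used across modules."""
    return PhyloTree(dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick"))


@pytest.fixture(scope="session")
def toy_cov():
    """A 60-site CovarianceSet with mild spatial-phylogenetic confounding."""
    tree = simulate_tree(60, seed=101, unit_height=True)
    sites, aug = simulate_sites(tree, spatial_phylo_correlation=0.3, seed=102)
    return build_covariance_set(aug, sites["primary_taxon"], sites["lat"], sites["lon"],
                                labels=sites["site_id"].tolist())


@pytest.fixture(scope="session")
def pacific_fixture():
    """One pacific80 synthetic study dataset shared by the slower tests."""
    return make_fixture(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
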