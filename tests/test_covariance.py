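import dendropy
import numpy as np
import pytest
from scipy import stats

from pglspatial.covariance import (
    CovarianceSet,
    VarianceParams,
    combined_variance,
    empirical_variogram,
    haversine_matrix,
    lambda_transform,
    phylo_vcv,
    spatial_similarity,
)
from pglspatial.tree_io import PhyloTree

R = 6371.0


def test_phylo_vcv_hand_example(hand_tree):
    sigma, h = phylo_vcv(hand_tree, taxon_order=["A", "B", "C"], normalize=False)
    np.testing.assert_allclose(sigma, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])
    np.testing.assert_allclose(h, [2, 2, 2])
    sigma_n, h_n = phylo_vcv(hand_tree, taxon_order=["A", "B", "C"])
    np.testing.assert_allclose(sigma_n, np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]]) / 2)
    assert h_n.max() == pytest.approx(1.0)


def test_phylo_vcv_star_tree():
    star = PhyloTree(dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick"))
    sigma, _ = phylo_vcv(star, normalize=False)
    off = sigma[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 0.0)


def test_phylo_vcv_matches_brownian_motion_simulation(hand_tree):
    """Independent oracle: trait covariance from edge-wise BM simulation matches Sigma."""
    n_sims = 50_000
    rng = np.random.default_rng(99)
    order = ["A", "B", "C"]
    # simulate BM increment per edge and accumulate along root-to-tip paths
    tree = hand_tree.tree
    vals = {tree.seed_node: np.zeros(n_sims)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        step = rng.normal(scale=np.sqrt(node.edge.length), size=n_sims)
        vals[node] = vals[node.parent_node] + step
    tips = {leaf.taxon.label: vals[leaf] for leaf in tree.leaf_node_iter()}
    traits = np.vstack([tips[o] for o in order])
    emp = traits @ traits.T / n_sims
    sigma, _ = phylo_vcv(hand_tree, taxon_order=order, normalize=False)
    # entrywise MC standard error of a covariance of Gaussians
    mc_se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n_sims)
    assert np.all(np.abs(emp - sigma) < 3 * mc_se + 1e-9)


@pytest.mark.parametrize("lam,expected_off", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
def test_lambda_transform_scales_off_diagonals(hand_tree, lam, expected_off):
    sigma, _ = phylo_vcv(hand_tree, taxon_order=["A", "B", "C"], normalize=False)
    out = lambda_transform(sigma, lam)
    assert out[0, 1] == pytest.approx(expected_off * sigma[0, 1])
    np.testing.assert_allclose(np.diag(out), np.diag(sigma))


def test_lambda_transform_domain_error(hand_tree):
    sigma, _ = phylo_vcv(hand_tree)
    with pytest.raises(ValueError, match="lambda"):
        lambda_transform(sigma, 1.5)


def test_haversine_closed_forms():
    d = haversine_matrix([0.0, 0.0, 0.0], [0.0, 180.0, 90.0])
    assert d[0, 1] == pytest.approx(np.pi * R)
    assert d[0, 2] == pytest.approx(np.pi / 2 * R)
    assert d[0, 0] == 0.0
    assert np.allclose(d, d.T)


def test_haversine_out_of_range_names_site():
    with pytest.raises(ValueError, match="badsite"):
        haversine_matrix([95.0, 0.0], [0.0, 0.0], site_ids=["badsite", "ok"])


def test_haversine_triangle_inequality(rng):
    lat = rng.uniform(-90, 90, size=30)
    lon = rng.uniform(-180, 180, size=30)
    d = haversine_matrix(lat, lon)
    for _ in range(200):
        i, j, k = rng.choice(30, size=3, replace=False)
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_spatial_similarity_extremes():
    d = haversine_matrix([0.0, 0.0, 10.0], [0.0, 0.0, 0.0])
    w = spatial_similarity(d)
    assert w[0, 1] == pytest.approx(1.0)  # co-located pair
    far = np.unravel_index(np.argmax(d), d.shape)
    assert w[far] == pytest.approx(0.0)  # farthest pair
    np.testing.assert_allclose(np.diag(w), 1.0)


def test_spatial_similarity_equidistant_sites():
    # three points on an equilateral spherical triangle around the equator
    d = haversine_matrix([0.0, 0.0, 0.0], [0.0, 120.0, -120.0])
    w = spatial_similarity(d)
    off = w[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, off[0], atol=1e-12)


def test_spatial_similarity_all_colocated_errors():
    with pytest.raises(ValueError, match="co-located"):
        spatial_similarity(np.zeros((3, 3)))


def _toy_covset(n=25, seed=3):
    from pglspatial.covariance import build_covariance_set
    from pglspatial.simulate import simulate_sites, simulate_tree

    tree = simulate_tree(n, seed=seed, unit_height=True)
    sites, aug = simulate_sites(tree, 0.4, seed=seed + 1)
    return build_covariance_set(aug, sites["primary_taxon"], sites["lat"], sites["lon"],
                                labels=sites["site_id"].tolist())


@pytest.mark.parametrize(
    "lam,phi,component", [(0.0, 0.0, "h"), (1.0, 0.0, "sigma"), (0.0, 1.0, "w")]
)
def test_combined_variance_pure_cases(lam, phi, component):
    cov = _toy_covset()
    v = combined_variance(cov, VarianceParams(lam=lam, phi=phi))
    expected = {"h": np.diag(cov.h), "sigma": cov.sigma, "w": cov.w}[component]
    np.testing.assert_allclose(v, expected, atol=1e-12)


def test_combined_variance_psd_over_grid():
    cov = _toy_covset()
    for lam in np.linspace(0, 1, 11):
        for phi in np.linspace(0, 1, 11):
            v = combined_variance(cov, VarianceParams(lam=lam, phi=phi))
            assert np.allclose(v, v.T)
            assert np.linalg.eigvalsh(v).min() >= -1e-8


def test_combined_variance_proportions_sum_to_one_on_diagonal():
    cov = _toy_covset()
    p = VarianceParams(lam=0.6, phi=0.3)
    assert p.gamma + p.lam_prime + p.phi == pytest.approx(1.0)
    v = combined_variance(cov, p)
    np.testing.assert_allclose(np.diag(v), 1.0, atol=1e-10)


def test_reordering_permutes_consistently():
    cov = _toy_covset()
    p = VarianceParams(lam=0.5, phi=0.2)
    v = combined_variance(cov, p)
    perm = np.random.default_rng(0).permutation(cov.n)
    cov_p = cov.subset(perm)
    v_p = combined_variance(cov_p, p)
    np.testing.assert_allclose(v_p, v[np.ix_(perm, perm)])


def test_variogram_constant_trait_warns_and_zeroes():
    d = haversine_matrix([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="constant"):
        vg = empirical_variogram(np.ones(4), d, n_bins=2)
    assert (vg["semivariance"].dropna() == 0).all()


def test_variogram_definitional_semivariance():
    d = haversine_matrix([0.0, 0.0, 40.0], [0.0, 1.0, 0.0])
    y = np.array([0.0, 2.0, 10.0])
    vg = empirical_variogram(y, d, n_bins=2)
    # nearest pair (sites 0,1) alone in the first bin: gamma = (0-2)^2 / 2
    assert vg.loc[0, "semivariance"] == pytest.approx(2.0)
    assert vg["n_pairs"].sum() == 3


def test_variogram_detects_spatial_structure(toy_cov, rng):
    # trait with covariance W is spatially autocorrelated: semivariance rises with distance
    L = np.linalg.cholesky(toy_cov.w + 1e-8 * np.eye(toy_cov.n))
    y = L @ rng.normal(size=toy_cov.n)
    vg = empirical_variogram(y, toy_cov.dist, n_bins=6).dropna(subset=["semivariance"])
    r, _ = stats.spearmanr(vg["mean_dist"], vg["semivariance"])
    assert r > 0
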