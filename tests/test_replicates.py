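import numpy as np
import pandas as pd
import pytest

from pglspatial.gls import pagel_lambda_signal
from pglspatial.covariance import phylo_vcv
from pglspatial.replicates import AggregateResult, ReplicateSpec, run_replicates, sample_site_languages
from pglspatial.simulate import simulate_sites, simulate_tree
from pglspatial.tree_io import TreeSample, PhyloTree


@pytest.fixture(scope="module")
def dialect_setup():
    tree = simulate_tree(20, seed=31, unit_height=True)
    sites, aug = simulate_sites(tree, 0.2, seed=32, multi_language_fraction=0.4)
    return sites, aug


def test_single_candidate_always_chosen(dialect_setup):
    sites, aug = dialect_setup
    single = sites[sites["candidate_taxa"].map(len) == 1]
    rng = np.random.default_rng(0)
    chosen = sample_site_languages(sites, rng, tree_tips=aug.tips)
    for idx in single.index:
        assert chosen[idx] == sites.loc[idx, "candidate_taxa"][0]


def test_uniform_selection_frequencies():
    table = pd.DataFrame({"site_id": ["isabel"], "candidate_taxa": [[f"L{i}" for i in range(5)]]})
    rng = np.random.default_rng(1)
    counts = {f"L{i}": 0 for i in range(5)}
    n_draws = 10_000
    for _ in range(n_draws):
        counts[sample_site_languages(table, rng)[0]] += 1
    freqs = np.array(list(counts.values())) / n_draws
    np.testing.assert_allclose(freqs, 0.2, atol=0.015)


def test_same_rng_state_gives_identical_assignment(dialect_setup):
    sites, aug = dialect_setup
    a = sample_site_languages(sites, np.random.default_rng(42), tree_tips=aug.tips)
    b = sample_site_languages(sites, np.random.default_rng(42), tree_tips=aug.tips)
    assert a == b


def test_missing_candidate_names_site():
    table = pd.DataFrame({"site_id": ["lost"], "candidate_taxa": [["nowhere"]]})
    with pytest.raises(ValueError, match="lost"):
        sample_site_languages(table, np.random.default_rng(0), tree_tips=["other"])


def _signal_analysis(y):
    def analysis(site_table, tree, rng):
        sigma, _ = phylo_vcv(tree, normalize=True)
        pos = {lbl: i for i, lbl in enumerate(tree.tips)}
        idx = np.array([pos[t] for t in site_table["taxon"]])
        sig = sigma[np.ix_(idx, idx)]
        res = pagel_lambda_signal(y, sig, np.diag(sig))
        return {"lambda_hat": res.lam_hat, "n": res.n}

    return analysis


def test_single_replicate_identity(dialect_setup):
    sites, aug = dialect_setup
    y = np.random.default_rng(5).normal(size=len(sites))
    sample = TreeSample(trees=[aug])
    spec = ReplicateSpec(tree_source=sample, site_table=sites, n_replicates=1, seed=9)
    agg = run_replicates(spec, _signal_analysis(y))
    assert agg.n_effective == 1
    assert agg.means == pytest.approx(agg.per_replicate[0])


def test_no_stochastic_input_means_zero_variance():
    tree = simulate_tree(15, seed=33, unit_height=True)
    sites, aug = simulate_sites(tree, 0.2, seed=34, multi_language_fraction=0.0)
    y = np.random.default_rng(6).normal(size=len(sites))
    sample = TreeSample(trees=[aug])
    spec = ReplicateSpec(tree_source=sample, site_table=sites, n_replicates=4, seed=10)
    agg = run_replicates(spec, _signal_analysis(y))
    vals = [r["lambda_hat"] for r in agg.per_replicate]
    assert np.std(vals) == 0.0


def test_tree_perturbation_propagates(dialect_setup):
    sites, aug = dialect_setup
    rng = np.random.default_rng(7)
    trees = []
    for _ in range(6):
        clone = PhyloTree(aug.tree.clone(depth=1))
        for e in clone.tree.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * rng.lognormal(0, 0.3)
        trees.append(clone)
    y = rng.normal(size=len(sites))
    # partially structured trait (BM plus noise) so lambda-hat sits in the
    # interior and responds to branch-length perturbation and language draws
    sigma, _ = phylo_vcv(aug, normalize=True)
    pos = {lbl: i for i, lbl in enumerate(aug.tips)}
    idx = np.array([pos[t] for t in sites["primary_taxon"]])
    y = np.linalg.cholesky(sigma[np.ix_(idx, idx)] + 1e-8 * np.eye(len(sites))) @ y
    y = y + 0.7 * rng.normal(size=len(sites))
    spec = ReplicateSpec(tree_source=TreeSample(trees=trees), site_table=sites,
                         n_replicates=6, seed=11)
    agg = run_replicates(spec, _signal_analysis(y))
    vals = [r["lambda_hat"] for r in agg.per_replicate]
    assert np.std(vals) > 0


def test_aggregate_mean_within_replicate_range(dialect_setup):
    sites, aug = dialect_setup
    y = np.random.default_rng(8).normal(size=len(sites))
    spec = ReplicateSpec(tree_source=TreeSample(trees=[aug]), site_table=sites,
                         n_replicates=5, seed=12)
    agg = run_replicates(spec, _signal_analysis(y))
    vals = [r["lambda_hat"] for r in agg.per_replicate]
    assert min(vals) <= agg.means["lambda_hat"] <= max(vals)


def test_failures_skipped_and_capped(dialect_setup):
    sites, aug = dialect_setup
    calls = {"n": 0}

    def flaky(site_table, tree, rng):
        calls["n"] += 1
        if calls["n"] % 10 == 0:
            raise RuntimeError("boom")
        return {"value": 1.0}

    spec = ReplicateSpec(tree_source=TreeSample(trees=[aug]), site_table=sites,
                         n_replicates=10, seed=13)
    agg = run_replicates(spec, flaky)
    assert agg.n_effective == 9
    assert len(agg.failures) == 1

    def always_fail(site_table, tree, rng):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="replicates failed"):
        run_replicates(spec, always_fail)


def test_full_replication_is_seed_reproducible(dialect_setup):
    sites, aug = dialect_setup
    y = np.random.default_rng(14).normal(size=len(sites))
    spec = ReplicateSpec(tree_source=TreeSample(trees=[aug]), site_table=sites,
                         n_replicates=3, seed=21)
    a = run_replicates(spec, _signal_analysis(y))
    b = run_replicates(spec, _signal_analysis(y))
    assert a.means == b.means
    assert a.per_replicate == b.per_replicate
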