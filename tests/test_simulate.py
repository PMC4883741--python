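import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pglspatial.covariance import build_covariance_set, haversine_matrix
from pglspatial.gls import pagel_lambda_signal
from pglspatial.simulate import (
    SimulationTruth,
    make_fixture,
    simulate_outcome,
    simulate_predictors,
    simulate_sites,
    simulate_tree,
    write_fixture,
)


def test_yule_tree_tip_count_and_determinism():
    t1 = simulate_tree(5, seed=1)
    assert t1.n_tips == 5
    assert len(set(t1.tips)) == 5
    t2 = simulate_tree(5, seed=1)
    assert t1.as_newick() == t2.as_newick()
    assert simulate_tree(5, seed=2).as_newick() != t1.as_newick()


def test_yule_height_matches_closed_form_expectation():
    """Mean height over replicates vs the pure-birth expectation sum_{k=2..n} 1/(b k)."""
    n, birth = 200, 1.0
    expected = sum(1.0 / (birth * k) for k in range(2, n + 1))
    heights = [simulate_tree(n, seed=s, birth_rate=birth).max_height() for s in range(40)]
    assert abs(np.mean(heights) - expected) / expected < 0.10


def test_yule_trees_are_ultrametric():
    tree = simulate_tree(30, seed=3)
    depths = np.array(list(tree.root_distances().values()))
    np.testing.assert_allclose(depths, depths[0], rtol=1e-9)


def _patristic_vs_geographic(rho, n=100, seed=50):
    tree = simulate_tree(n, seed=seed, unit_height=True)
    sites, aug = simulate_sites(tree, spatial_phylo_correlation=rho, seed=seed + 1)
    pat = aug.path_length_matrix(sites["primary_taxon"].tolist())
    geo = haversine_matrix(sites["lat"], sites["lon"])
    iu = np.triu_indices(n, k=1)
    r, _ = stats.spearmanr(pat[iu], geo[iu])
    return r


def test_no_confound_when_rho_zero():
    assert abs(_patristic_vs_geographic(0.0)) < 0.1


def test_strong_confound_when_rho_high():
    assert _patristic_vs_geographic(0.9) > 0.3


def test_multi_language_fraction_zero_gives_single_candidates():
    tree = simulate_tree(20, seed=4)
    sites, aug = simulate_sites(tree, 0.1, seed=5, multi_language_fraction=0.0)
    assert (sites["candidate_taxa"].map(len) == 1).all()
    assert aug.n_tips == 20


def test_dialect_tips_extend_tree_and_sites():
    tree = simulate_tree(20, seed=6, unit_height=True)
    sites, aug = simulate_sites(tree, 0.1, seed=7, multi_language_fraction=0.5,
                                multi_language_range=(2, 3))
    multi = sites[sites["candidate_taxa"].map(len) > 1]
    assert len(multi) == 10
    tips = set(aug.tips)
    for cands in sites["candidate_taxa"]:
        assert set(cands) <= tips


def test_predictor_signal_recovery(toy_cov):
    """Latent lambda_signal of 0 vs 1 is recoverable from the generated columns."""
    spec0 = {"flat": {"type": "continuous", "lambda_signal": 0.0}}
    spec1 = {"deep": {"type": "continuous", "lambda_signal": 1.0}}
    lam0, lam1 = [], []
    rng = np.random.default_rng(80)
    for _ in range(50):
        x0 = simulate_predictors(toy_cov.sigma, spec0, seed=rng)["flat"].to_numpy()
        x1 = simulate_predictors(toy_cov.sigma, spec1, seed=rng)["deep"].to_numpy()
        lam0.append(pagel_lambda_signal(x0, toy_cov.sigma, toy_cov.h).lam_hat)
        lam1.append(pagel_lambda_signal(x1, toy_cov.sigma, toy_cov.h).lam_hat)
    assert np.median(lam0) <= 0.1
    assert np.median(lam1) >= 0.9


def test_predictor_types_and_missingness(toy_cov):
    spec = {
        "f": {"type": "factor", "lambda_signal": 0.3, "levels": ["lo", "mid", "hi"]},
        "b": {"type": "binary", "lambda_signal": 0.2, "prevalence": 0.3},
        "c": {"type": "continuous", "lambda_signal": 0.5, "missing_rate": 0.2},
    }
    cols = simulate_predictors(toy_cov.sigma, spec, seed=9)
    assert set(cols["f"].dropna()) <= {"lo", "mid", "hi"}
    assert set(cols["b"].dropna()) <= {0, 1}
    assert cols["c"].isna().sum() > 0


def test_outcome_discretization_range(toy_cov, rng):
    X = np.ones((toy_cov.n, 1))
    truth = SimulationTruth(0.3, 0.2, 1.0, {"i": 2.0}, {"levels": 5}, 0)
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    assert set(np.unique(y)) <= {1.0, 2.0, 3.0, 4.0, 5.0}


def test_outcome_pure_noise_is_unstructured(toy_cov, rng):
    truth = SimulationTruth(0.0, 0.0, 1.0, {"i": 0.0}, None, 0)
    y = simulate_outcome(np.ones((toy_cov.n, 1)), truth, toy_cov, seed=rng)
    # no phylogenetic structure should be detectable
    assert stats.shapiro(y).pvalue > 1e-4


def test_fixture_shape_and_invariants(pacific_fixture):
    sample, table, truths = pacific_fixture
    assert len(table) == 80
    assert table["site_id"].is_unique
    assert table["lat"].between(-90, 90).all()
    assert table["lon"].between(-180, 180).all()
    assert len(sample) == 10
    tips = set(sample[0].tips)
    for cands in table["candidate_taxa"]:
        assert set(cands) <= tips
    # >= 15 design columns after dummy expansion of the two 3-level factors
    base_predictors = ["rainfall", "elevation", "area", "isolation", "abs_latitude",
                       "makatea_pct", "dust", "wet", "dry", "arboriculture",
                       "individual_ownership", "elite_ownership"]
    n_design = len(base_predictors) + 2 + 2  # tephra and age dummies
    assert n_design >= 15
    for col in base_predictors + ["tephra", "age", "deforestation", "replacement"]:
        assert col in table.columns
    assert table["treeless"].sum() == 2
    for truth in truths.values():
        assert truth.seed == 7


def test_fixture_write_is_deterministic(tmp_path):
    for d in ("a", "b"):
        sample, table, truths = make_fixture(seed=3)
        write_fixture(tmp_path / d, sample, table, truths)
    for name in ("trees.nwk", "sites.csv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_fixture_missingness_present(pacific_fixture):
    _, table, _ = pacific_fixture
    assert table[["dust", "age"]].isna().any().any()


def test_full_pipeline_recovers_strong_effect_signs(pacific_fixture):
    """Generating coefficient signs survive the whole averaging pipeline.

    Checked for every predictor whose standardized effect magnitude is at
    least 0.5 in the deforestation truth (rainfall, dust, latitude).
    """
    from pglspatial.evaluation import PACIFIC80_RUN_CONFIG
    from pglspatial.pipeline import RunConfig, run_analysis

    sample, table, truths = pacific_fixture
    cfg = RunConfig(**PACIFIC80_RUN_CONFIG, n_replicates=2, seed=17)
    report = run_analysis(cfg, trees=sample, site_table=table, write=False)
    tab = report["predictor_table"].set_index("predictor")
    beta_true = truths["deforestation"].beta
    assert np.sign(tab.loc["rainfall", "beta"]) == np.sign(beta_true["log_rainfall"])
    assert np.sign(tab.loc["dust", "beta"]) == np.sign(beta_true["dust"])
    assert np.sign(tab.loc["abs_latitude", "beta"]) == np.sign(beta_true["abs_latitude"])
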