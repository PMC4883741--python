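"""Synthetic trees, site coordinates, predictors and outcomes with known truth.

The generator emulates the structural features of an island-scale
cross-cultural dataset: a pure-birth language phylogeny with dialect tips
attached to some sites (so sites can carry several candidate languages), site
coordinates that are spatially confounded with phylogeny (close relatives tend
to be geographic neighbours), predictors carrying tunable phylogenetic signal,
and outcomes drawn from the generative model y = X beta + eps with
eps ~ N(0, sigma^2 V(lambda, phi)). Every dataset records its SimulationTruth
so recovery can be checked end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from pglspatial.covariance import CovarianceSet, build_covariance_set, combined_variance, lambda_transform, VarianceParams
from pglspatial.tree_io import PhyloTree, TreeSample

__all__ = [
    "SimulationTruth",
    "simulate_tree",
    "simulate_sites",
    "simulate_predictors",
    "simulate_outcome",
    "make_fixture",
    "write_fixture",
    "read_fixture",
]

# default geographic window: a Pacific-like band, decimal degrees (S/W negative)
LAT_WINDOW = (-30.0, 10.0)
LON_WINDOW = (140.0, 179.9)


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside every generated dataset."""

    lam: float
    phi: float
    sigma2: float
    beta: dict[str, float]
    discretization: dict | None
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


def simulate_tree(n_tips: int, model: str = "yule", seed: int | np.random.Generator = 0,
                  birth_rate: float = 1.0, unit_height: bool = False) -> PhyloTree:
    """Simulate a pure-birth (Yule) tree with exponential waiting times.

    Starting from two lineages, at k extant lineages the next split waits
    Exp(k * birth_rate); after the n-th lineage appears one final waiting time
    Exp(n * birth_rate) elapses before sampling, so the expected height is
    sum_{k=2..n} 1 / (birth_rate * k). Tips are labeled T001, T002, ...
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if model != "yule":
        raise ValueError(f"unknown model {model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node, born = active.pop(int(rng.integers(k)))
        node.edge.length = t - born
        for _ in range(2):
            child = node.new_child()
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node, born in active:
        node.edge.length = t - born
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"T{i:0{width}d}")
    out = PhyloTree(tree)
    if unit_height:
        out = out.scaled(1.0 / out.max_height())
    return out


def _latlon_to_unit(lat, lon):
    phi_r, lam_r = np.radians(lat), np.radians(lon)
    return np.array([np.cos(phi_r) * np.cos(lam_r), np.cos(phi_r) * np.sin(lam_r), np.sin(phi_r)])

def _unit_to_latlon(v):
    v = v / np.linalg.norm(v)
    return float(np.degrees(np.arcsin(np.clip(v[2], -1, 1)))), float(np.degrees(np.arctan2(v[1], v[0])))

def _random_tangent(v, rng):
    r = rng.normal(size=3)
    r -= (r @ v) * v
    return r / np.linalg.norm(r)

def _rotate_towards(v, u, theta):
    return np.cos(theta) * v + np.sin(theta) * u

def _slerp(a, b, frac):
    dot = float(np.clip(a @ b, -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        return b
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def simulate_sites(
    tree: PhyloTree,
    spatial_phylo_correlation: float = 0.0,
    seed: int | np.random.Generator = 0,
    multi_language_fraction: float = 0.0,
    multi_language_range: tuple[int, int] = (2, 5),
    angular_sd: float = 0.35,
    dialect_depth: float = 0.02,
    lat_window: tuple[float, float] = LAT_WINDOW,
    lon_window: tuple[float, float] = LON_WINDOW,
) -> tuple[pd.DataFrame, PhyloTree]:
    """Place one site per tree tip, optionally confounding geography with phylogeny.

    Coordinates come from a diffusion on the sphere along the tree (each child
    rotates away from its parent by an angle ~ N(0, angular_sd^2 * branch
    length)); with confound strength rho the final coordinate is the
    great-circle interpolation between an independent uniform draw in the
    window (rho = 0) and the pure diffusion endpoint (rho = 1), so the expected
    geographic distance between sites increases with patristic distance when
    rho > 0. A fraction of sites receives 2-5 candidate dialect tips attached
    near the site's tip with short terminal branches.

    Returns a site table (site_id, lat, lon, candidate_taxa, primary_taxon) and
    the tree augmented with the dialect tips.
    """
    rho = float(spatial_phylo_correlation)
    if not (0.0 <= rho <= 1.0):
        raise ValueError("spatial_phylo_correlation must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    work = PhyloTree(tree.tree.clone(depth=1))
    base_tips = work.tips
    n = len(base_tips)
    center = _latlon_to_unit(np.mean(lat_window), np.mean(lon_window))

    # diffusion endpoints per tip
    vecs: dict = {work.tree.seed_node: center}
    for node in work.tree.preorder_node_iter():
        if node is work.tree.seed_node:
            continue
        parent = vecs[node.parent_node]
        bl = node.edge.length or 0.0
        theta = angular_sd * np.sqrt(bl) * rng.normal()
        vecs[node] = _rotate_towards(parent, _random_tangent(parent, rng), theta)
    diffused = {leaf.taxon.label: vecs[leaf] for leaf in work.tree.leaf_node_iter()}

    lats, lons = [], []
    for lbl in base_tips:
        uni = _latlon_to_unit(rng.uniform(*lat_window), rng.uniform(*lon_window))
        lat, lon = _unit_to_latlon(_slerp(uni, diffused[lbl], rho))
        lats.append(lat)
        lons.append(lon)

    # attach dialect tips to a subset of sites
    candidates: dict[str, list[str]] = {lbl: [lbl] for lbl in base_tips}
    n_multi = int(round(multi_language_fraction * n))
    multi_sites = [base_tips[i] for i in rng.choice(n, size=n_multi, replace=False)] if n_multi else []
    if multi_sites:
        ns = work.tree.taxon_namespace
        leaf_by_label = {leaf.taxon.label: leaf for leaf in work.tree.leaf_node_iter()}
        height = work.max_height()
        for lbl in multi_sites:
            k = int(rng.integers(multi_language_range[0], multi_language_range[1] + 1))
            leaf = leaf_by_label[lbl]
            delta = min(dialect_depth * height, 0.5 * (leaf.edge.length or dialect_depth * height))
            leaf.edge.length = (leaf.edge.length or 0.0) - delta
            leaf.taxon = None  # becomes the dialect-group ancestor
            group = []
            for d in range(1, k + 1):
                child = leaf.new_child()
                child.edge.length = delta
                child.taxon = ns.new_taxon(label=f"{lbl}_d{d}")
                group.append(child.taxon.label)
            candidates[lbl] = group
    augmented = PhyloTree(work.tree)

    width = len(str(n))
    table = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "lat": lats,
            "lon": lons,
            "candidate_taxa": [candidates[lbl] for lbl in base_tips],
            "primary_taxon": [candidates[lbl][0] for lbl in base_tips],
        }
    )
    return table, augmented


def simulate_predictors(
    sigma: np.ndarray,
    spec: dict[str, dict],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw predictor columns with per-predictor phylogenetic signal.

    ``sigma`` is the (normalized) phylogenetic VCV for the sites; each entry of
    ``spec`` maps a predictor name to a dict with keys:

    - ``type``: "continuous" | "factor" | "binary"
    - ``lambda_signal``: target Pagel's lambda of the latent draw (in [0, 1])
    - ``levels`` (factor): list of level labels, split at equal quantiles
    - ``prevalence`` (binary): probability of 1 (default 0.5)
    - ``loc``/``scale`` (continuous): affine transform of the latent draw
    - ``positive`` (continuous): exponentiate, for log-scale variables
    - ``missing_rate``: MCAR missingness fraction (default 0)
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = sigma.shape[0]
    cols = {}
    for name, cfg in spec.items():
        lam = float(cfg.get("lambda_signal", 0.0))
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda_signal for {name} must lie in [0, 1], got {lam}")
        V = lambda_transform(sigma, lam)
        latent = np.linalg.cholesky(V + 1e-12 * np.eye(n)) @ rng.normal(size=n)
        z = (latent - latent.mean()) / latent.std()
        kind = cfg.get("type", "continuous")
        if kind == "continuous":
            x = cfg.get("loc", 0.0) + cfg.get("scale", 1.0) * z
            col = pd.Series(np.exp(x) if cfg.get("positive") else x, dtype=float)
        elif kind == "factor":
            levels = cfg["levels"]
            cuts = np.quantile(z, np.linspace(0, 1, len(levels) + 1)[1:-1])
            col = pd.Series(np.asarray(levels, dtype=object)[np.digitize(z, cuts)])
        elif kind == "binary":
            prev = cfg.get("prevalence", 0.5)
            col = pd.Series((z > np.quantile(z, 1.0 - prev)).astype(int))
        else:
            raise ValueError(f"unknown predictor type {kind!r} for {name}")
        miss = float(cfg.get("missing_rate", 0.0))
        if miss > 0:
            mask = rng.random(n) < miss
            col = col.astype(object) if kind != "continuous" else col
            col[mask] = np.nan if kind == "continuous" else None
        cols[name] = col
    return pd.DataFrame(cols)


def simulate_outcome(
    X,
    truth: SimulationTruth,
    cov: CovarianceSet,
    seed: int | np.random.Generator = 0,
    discretize: dict | None = None,
) -> np.ndarray:
    """Draw y = X beta + eps with eps ~ N(0, sigma^2 V(lambda, phi)).

    ``X`` is a DataFrame whose columns match ``truth.beta`` keys (an intercept
    key "intercept" is honored if present), or an array conformable with the
    beta vector. ``discretize`` maps the continuous draw to ordinal scores,
    e.g. {"levels": 5} (equal marginal proportions) or
    {"levels": 4, "probs": [...]}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(X, pd.DataFrame):
        beta = np.array([truth.beta.get(c, 0.0) for c in X.columns], dtype=float)
        mu = X.to_numpy(dtype=float) @ beta + truth.beta.get("intercept", 0.0)
    else:
        X = np.asarray(X, dtype=float)
        beta = np.asarray([truth.beta[k] for k in truth.beta], dtype=float)
        if X.shape[1] != beta.size:
            raise ValueError(f"design has {X.shape[1]} columns but truth lists {beta.size} betas")
        mu = X @ beta
    n = mu.size
    if cov.n != n:
        raise ValueError("covariance set and design sizes differ")
    V = combined_variance(cov, VarianceParams(lam=truth.lam, phi=truth.phi))
    eps = np.linalg.cholesky(V + 1e-12 * np.eye(n)) @ rng.normal(size=n)
    y = mu + np.sqrt(truth.sigma2) * eps
    rule = discretize if discretize is not None else truth.discretization
    if rule:
        levels = int(rule["levels"])
        probs = rule.get("probs") or [1.0 / levels] * levels
        cuts = np.quantile(y, np.cumsum(probs)[:-1])
        y = (np.digitize(y, cuts) + 1).astype(float)
    return y


# predictor specification mirroring the study's variable types: four log-scale
# continuous ecological variables, a latitude-like gradient, a percentage, a
# continuous deposition variable, two 3-level factors, five binary cultural traits
PACIFIC80_PREDICTORS: dict[str, dict] = {
    "rainfall": {"type": "continuous", "lambda_signal": 0.7, "loc": 7.6, "scale": 0.4, "positive": True},
    "elevation": {"type": "continuous", "lambda_signal": 0.6, "loc": 5.5, "scale": 1.0, "positive": True},
    "area": {"type": "continuous", "lambda_signal": 0.6, "loc": 4.5, "scale": 1.5, "positive": True},
    "isolation": {"type": "continuous", "lambda_signal": 0.5, "loc": 5.0, "scale": 0.8, "positive": True},
    "makatea_pct": {"type": "continuous", "lambda_signal": 0.3, "loc": 20.0, "scale": 15.0},
    "dust": {"type": "continuous", "lambda_signal": 0.2, "loc": 1.0, "scale": 0.5, "missing_rate": 0.05},
    "tephra": {"type": "factor", "lambda_signal": 0.5, "levels": [1, 2, 3]},
    "age": {"type": "factor", "lambda_signal": 0.4, "levels": ["young", "medium", "old"], "missing_rate": 0.05},
    "wet": {"type": "binary", "lambda_signal": 0.8, "prevalence": 0.45},
    "dry": {"type": "binary", "lambda_signal": 0.8, "prevalence": 0.35},
    "arboriculture": {"type": "binary", "lambda_signal": 0.7, "prevalence": 0.5},
    "individual_ownership": {"type": "binary", "lambda_signal": 0.6, "prevalence": 0.4},
    "elite_ownership": {"type": "binary", "lambda_signal": 0.6, "prevalence": 0.3},
}

# generating coefficients on the analysis (log-transformed) scale; intercepts
# offset the predictor means so the outcomes sit on score-like ranges
PACIFIC80_BETA_DEFORESTATION = {
    "intercept": 14.0,
    "log_rainfall": -1.5,
    "abs_latitude": 0.08,
    "makatea_pct": 0.03,
    "dust": -1.0,
}
PACIFIC80_BETA_REPLACEMENT = {
    "intercept": 6.0,
    "log_isolation": -0.9,
    "log_area": 0.2,
    "wet": 0.8,
}


def make_fixture(profile: str = "pacific80", seed: int = 0, n_sites: int = 80,
                 n_trees: int = 10, discretize: bool = False):
    """Generate a complete synthetic study dataset with recorded ground truth.

    The ``pacific80`` profile produces 80 sites on a ~120-tip tree (dialect
    tips give some sites 2-5 candidate languages), a posterior-like sample of
    ``n_trees`` branch-length-jittered copies of the base tree, ten ecological
    predictors (log-scale continuous, latitude, percentage and deposition
    variables, two 3-level factors) plus five binary cultural predictors with a
    few percent missingness, geographic coordinates confounded with phylogeny,
    and two outcomes (deforestation-like, replacement-like) generated under
    V(lambda, phi) with known coefficients. Two sites are flagged treeless for
    row-filter exercises.

    Returns ``(TreeSample, site_table, truths)`` with one SimulationTruth per
    outcome.
    """
    if profile != "pacific80":
        raise ValueError(f"unknown profile {profile!r}")
    root_ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root_ss.spawn(6)]

    base = simulate_tree(n_sites, seed=rngs[0], unit_height=True)
    sites, aug = simulate_sites(
        base, spatial_phylo_correlation=0.6, seed=rngs[1],
        multi_language_fraction=0.2, multi_language_range=(2, 5),
    )

    # posterior-like sample: branch-length jitter of the augmented tree
    trees = []
    for _ in range(n_trees):
        clone = PhyloTree(aug.tree.clone(depth=1))
        for edge in clone.tree.preorder_edge_iter():
            if edge.length is not None and edge.head_node is not clone.tree.seed_node:
                edge.length = edge.length * rngs[2].lognormal(mean=0.0, sigma=0.1)
        trees.append(clone)
    sample = TreeSample(trees=trees, source=f"pacific80 synthetic posterior (seed={seed})")

    cov = build_covariance_set(aug, sites["primary_taxon"], sites["lat"], sites["lon"],
                               labels=sites["site_id"].tolist())
    predictors = simulate_predictors(cov.sigma, PACIFIC80_PREDICTORS, seed=rngs[3])
    table = pd.concat([sites, predictors], axis=1)
    table["abs_latitude"] = table["lat"].abs()

    design = pd.DataFrame(
        {
            "log_rainfall": np.log(table["rainfall"]),
            "log_isolation": np.log(table["isolation"]),
            "log_area": np.log(table["area"]),
            "abs_latitude": table["abs_latitude"],
            "makatea_pct": table["makatea_pct"].fillna(table["makatea_pct"].mean()),
            "dust": table["dust"].fillna(table["dust"].mean()),
            "wet": table["wet"].astype(float),
        }
    )
    disc_def = {"levels": 5} if discretize else None
    disc_rep = {"levels": 4} if discretize else None
    truth_def = SimulationTruth(
        lam=0.5, phi=0.2, sigma2=1.0, beta=PACIFIC80_BETA_DEFORESTATION,
        discretization=disc_def, seed=seed, extras={"outcome": "deforestation"},
    )
    truth_rep = SimulationTruth(
        lam=0.9, phi=0.1, sigma2=1.0, beta=PACIFIC80_BETA_REPLACEMENT,
        discretization=disc_rep, seed=seed, extras={"outcome": "replacement"},
    )
    table["deforestation"] = simulate_outcome(design, truth_def, cov, seed=rngs[4])
    table["replacement"] = simulate_outcome(design, truth_rep, cov, seed=rngs[5])

    treeless = table.nsmallest(2, "area").index
    table["treeless"] = False
    table.loc[treeless, "treeless"] = True
    return sample, table, {"deforestation": truth_def, "replacement": truth_rep}


def write_fixture(outdir: str | Path, sample: TreeSample, table: pd.DataFrame, truths: dict) -> None:
    """Write a fixture as plain text: newick trees, a sites CSV, truth JSON."""
    from pglspatial.tree_io import write_trees

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trees(sample, outdir / "trees.nwk")
    flat = table.copy()
    flat["candidate_taxa"] = flat["candidate_taxa"].map(";".join)
    flat.to_csv(outdir / "sites.csv", index=False)
    payload = {k: json.loads(v.to_json()) for k, v in truths.items()}
    (outdir / "truth.json").write_text(json.dumps(payload, sort_keys=True, indent=2))


def read_fixture(indir: str | Path):
    """Read back a fixture written by :func:`write_fixture`."""
    from pglspatial.tree_io import read_trees

    indir = Path(indir)
    sample = read_trees(indir / "trees.nwk", format="newick")
    table = pd.read_csv(indir / "sites.csv")
    table["candidate_taxa"] = table["candidate_taxa"].str.split(";")
    return sample, table
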