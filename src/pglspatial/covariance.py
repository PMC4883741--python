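"""Variance-structure building blocks: phylogenetic VCV, spatial similarity, and their mixture.

The combined error covariance of the regression is

    V(lambda, phi) = (1 - phi) * [(1 - lambda) * diag(h) + lambda * Sigma] + phi * W
                   = gamma * diag(h) + lambda' * Sigma + phi * W

where Sigma holds shared root-to-tip path lengths (the Brownian-motion trait
covariance), h = diag(Sigma), and W is a spatial similarity matrix derived from
great-circle distances. Sigma is normalized to unit maximum root-to-tip height
and W has a unit diagonal, so for an ultrametric tree the mixture weights
gamma = (1-phi)(1-lambda), lambda' = (1-phi)lambda and phi are variance
proportions that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pglspatial.tree_io import PhyloTree

__all__ = [
    "CovarianceSet",
    "VarianceParams",
    "phylo_vcv",
    "lambda_transform",
    "haversine_matrix",
    "spatial_similarity",
    "combined_variance",
    "empirical_variogram",
    "build_covariance_set",
]

EARTH_RADIUS_KM = 6371.0
PSD_TOL = 1e-8


@dataclass(frozen=True)
class VarianceParams:
    """Dependence parameters (lambda, phi) and their proportional reparameterization."""

    lam: float
    phi: float

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")

    @property
    def lam_prime(self) -> float:
        """Proportional contribution of phylogeny to variance, (1 - phi) * lambda."""
        return (1.0 - self.phi) * self.lam

    @property
    def gamma(self) -> float:
        """Proportion of variance independent of phylogeny and space, (1 - phi)(1 - lambda)."""
        return (1.0 - self.phi) * (1.0 - self.lam)


@dataclass
class CovarianceSet:
    """Aligned covariance ingredients for one analysis: Sigma, h, D (km) and W.

    All matrices are indexed identically by ``taxon_order`` (one entry per
    analysis site). ``sigma`` is normalized so max(h) = 1 unless built otherwise.
    """

    sigma: np.ndarray
    h: np.ndarray
    dist: np.ndarray
    w: np.ndarray
    taxon_order: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.sigma.shape[0]

    def validate(self) -> None:
        n = self.n
        for name, m in (("sigma", self.sigma), ("dist", self.dist), ("w", self.w)):
            if m.shape != (n, n):
                raise ValueError(f"{name} has shape {m.shape}, expected {(n, n)}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(self.sigma), self.h):
            raise ValueError("h must equal diag(sigma)")
        if np.any(np.diag(self.dist) != 0) or np.any(self.dist < 0):
            raise ValueError("dist must be nonnegative with zero diagonal")
        if not np.allclose(np.diag(self.w), 1.0) or self.w.min() < -1e-10 or self.w.max() > 1 + 1e-10:
            raise ValueError("w must have unit diagonal and entries in [0, 1]")
        if self.taxon_order and len(self.taxon_order) != n:
            raise ValueError("taxon_order length mismatch")

    def subset(self, idx: np.ndarray) -> "CovarianceSet":
        """Row/column subset (e.g. after listwise deletion), preserving alignment."""
        order = [self.taxon_order[i] for i in idx] if self.taxon_order else []
        return CovarianceSet(
            sigma=self.sigma[np.ix_(idx, idx)],
            h=self.h[idx],
            dist=self.dist[np.ix_(idx, idx)],
            w=self.w[np.ix_(idx, idx)],
            taxon_order=order,
        )


def phylo_vcv(tree: PhyloTree, taxon_order=None, normalize: bool = True):
    """Phylogenetic variance-covariance matrix of shared root-to-tip path lengths.

    Sigma_ij is the branch length shared by the root-to-tip paths of tips i and
    j (the depth of their most recent common ancestor); h = diag(Sigma) is the
    root-to-tip distance. With ``normalize`` the matrix is scaled so
    max(h) = 1, making lambda/phi mixture weights interpretable as proportions.

    Returns ``(sigma, h)`` ordered by ``taxon_order`` (default: tree tip order).
    """
    tips = tree.tips
    if len(tips) < 2:
        raise ValueError("need at least 2 taxa")
    order = list(taxon_order) if taxon_order is not None else tips
    if sorted(order) != sorted(tips):
        raise ValueError("taxon_order must be a permutation of the tree's tips")
    pos = {lbl: i for i, lbl in enumerate(order)}
    n = len(order)
    sigma = np.zeros((n, n))

    # depth-first pass: each internal node contributes its depth as the shared
    # path length for every tip pair split across its children
    root = tree.tree.seed_node
    depth = {root: root.edge.length or 0.0}
    leaves_below: dict = {}
    for node in tree.tree.preorder_node_iter():
        if node is not root:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            leaves_below[node] = [pos[node.taxon.label]]
            sigma[leaves_below[node][0], leaves_below[node][0]] = depth[node]
        else:
            child_sets = [leaves_below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.asarray(child_sets[a])
                    ib = np.asarray(child_sets[b])
                    sigma[np.ix_(ia, ib)] = d
                    sigma[np.ix_(ib, ia)] = d
            leaves_below[node] = [i for s in child_sets for i in s]
    h = np.diag(sigma).copy()
    if normalize:
        scale = h.max()
        if scale <= 0:
            raise ValueError("tree has zero height; cannot normalize")
        sigma = sigma / scale
        h = h / scale
    return sigma, h


def lambda_transform(sigma: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by lambda, diagonal kept.

    Equivalently (1 - lambda) * diag(h) + lambda * Sigma. lambda = 1 returns
    Sigma unchanged (Brownian motion); lambda = 0 removes all phylogenetic
    covariance.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * np.asarray(sigma, dtype=float)
    np.fill_diagonal(out, np.diag(sigma))
    return out


def haversine_matrix(lat, lon, radius_km: float = EARTH_RADIUS_KM, site_ids=None) -> np.ndarray:
    """Pairwise great-circle distances (km) from decimal-degree coordinates.

    Uses the haversine formula with a spherical Earth of radius ``radius_km``
    (default: mean radius 6371 km).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    bad_lat = np.where((lat < -90) | (lat > 90))[0]
    bad_lon = np.where((lon < -180) | (lon > 180))[0]
    if bad_lat.size or bad_lon.size:
        bad = sorted(set(bad_lat) | set(bad_lon))
        names = [site_ids[i] for i in bad] if site_ids is not None else bad
        raise ValueError(f"coordinates out of range for sites {names}")
    phi_r = np.radians(lat)
    lam_r = np.radians(lon)
    dphi = phi_r[:, None] - phi_r[None, :]
    dlam = lam_r[:, None] - lam_r[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi_r)[:, None] * np.cos(phi_r)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def spatial_similarity(dist: np.ndarray) -> np.ndarray:
    """Convert a distance matrix to a covariance-compatible similarity matrix.

    W_ij = 1 - D_ij / max(D), so the farthest pair has similarity 0 and
    co-located sites similarity 1. If the result is not positive semidefinite
    it is repaired by eigenvalue clipping (negative eigenvalues set to zero,
    matrix reconstituted, diagonal restored to 1) with a warning.
    """
    dist = np.asarray(dist, dtype=float)
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("all sites are co-located; spatial similarity undefined")
    w = 1.0 - dist / dmax
    np.fill_diagonal(w, 1.0)
    eigvals = np.linalg.eigvalsh(w)
    if eigvals.min() < -PSD_TOL:
        warnings.warn(
            f"spatial similarity matrix not PSD (min eigenvalue {eigvals.min():.3g}); "
            "applying eigenvalue clipping",
            stacklevel=2,
        )
        vals, vecs = np.linalg.eigh(w)
        vals = np.clip(vals, 0.0, None)
        w = (vecs * vals) @ vecs.T
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def combined_variance(cov: CovarianceSet, params: VarianceParams) -> np.ndarray:
    """Assemble V = gamma * diag(h) + lambda' * Sigma + phi * W.

    For an ultrametric normalized tree the diagonal is identically 1, so the
    three weights partition the variance.
    """
    if cov.sigma.shape != cov.w.shape:
        raise ValueError(f"sigma {cov.sigma.shape} and w {cov.w.shape} dimension mismatch")
    v = params.gamma * np.diag(cov.h) + params.lam_prime * cov.sigma + params.phi * cov.w
    return (v + v.T) / 2


def empirical_variogram(y, dist: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Binned empirical semivariogram: semivariance of trait differences by distance.

    Pairs (i < j) are assigned to ``n_bins`` equal-width distance bins; per bin
    the semivariance is mean((y_i - y_j)^2) / 2. Bins with no pairs get NaN.
    An increasing semivariance with distance diagnoses spatial autocorrelation.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if np.ptp(y) == 0:
        warnings.warn("constant trait: all semivariances are zero", stacklevel=2)
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    sq = 0.5 * (y[iu] - y[ju]) ** 2
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rows.append(
            {
                "bin": b,
                "dist_lo": edges[b],
                "dist_hi": edges[b + 1],
                "mean_dist": d[mask].mean() if mask.any() else np.nan,
                "semivariance": sq[mask].mean() if mask.any() else np.nan,
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def build_covariance_set(
    tree: PhyloTree,
    taxa,
    lat,
    lon,
    labels=None,
    radius_km: float = EARTH_RADIUS_KM,
) -> CovarianceSet:
    """Build an aligned CovarianceSet for sites mapped to tree tips.

    ``taxa`` gives the tree tip assigned to each site (one per site, in site
    order); ``lat``/``lon`` are the site coordinates. The tree is pruned is the
    caller's responsibility — here ``taxa`` must all exist on ``tree``.
    """
    taxa = list(taxa)
    sigma_full, _ = phylo_vcv(tree, normalize=True)
    tip_pos = {lbl: i for i, lbl in enumerate(tree.tips)}
    missing = [t for t in taxa if t not in tip_pos]
    if missing:
        raise ValueError(f"taxa not on tree: {sorted(set(missing))}")
    idx = np.array([tip_pos[t] for t in taxa])
    sigma = sigma_full[np.ix_(idx, idx)]
    h = np.diag(sigma).copy()
    ids = list(labels) if labels is not None else taxa
    dist = haversine_matrix(lat, lon, radius_km=radius_km, site_ids=ids)
    w = spatial_similarity(dist)
    cs = CovarianceSet(sigma=sigma, h=h, dist=dist, w=w, taxon_order=ids)
    cs.validate()
    return cs
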