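"""Replication over posterior tree samples and per-site language assignments.

Sites can carry several candidate languages (dialect chains, multilingual
islands); using all of them would double-count societies. Each replicate
therefore draws one tree from the posterior sample and one language per site,
prunes the tree to the drawn languages, rebuilds the covariance structures and
reruns the full analysis. Aggregates are arithmetic means across replicates,
which integrates the results over phylogenetic and assignment uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from pglspatial.tree_io import PhyloTree, TreeSample, prune_to_taxa

__all__ = ["ReplicateSpec", "AggregateResult", "sample_site_languages", "run_replicates"]

MAX_FAILURE_FRACTION = 0.2


@dataclass
class ReplicateSpec:
    """Configuration of one replication run."""

    tree_source: TreeSample
    site_table: pd.DataFrame
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class AggregateResult:
    """Across-replicate means plus the raw per-replicate records for audit."""

    means: dict[str, float]
    per_replicate: list[dict[str, float]]
    replicate_log: pd.DataFrame
    n_requested: int
    n_effective: int
    seed: int
    failures: list[tuple[int, str]] = field(default_factory=list)


def sample_site_languages(site_table: pd.DataFrame, rng: np.random.Generator,
                          tree_tips: Sequence[str] | None = None) -> list[str]:
    """Draw one candidate taxon per site, uniformly among its candidates.

    ``site_table`` must carry a ``candidate_taxa`` column (list of tip labels
    per site). When ``tree_tips`` is given, candidates are first restricted to
    tips present on the current tree; a site with no remaining candidate is an
    error naming the site.
    """
    tips = set(tree_tips) if tree_tips is not None else None
    chosen = []
    for _, row in site_table.iterrows():
        cands = list(row["candidate_taxa"])
        if tips is not None:
            cands = [c for c in cands if c in tips]
        if not cands:
            raise ValueError(f"site {row['site_id']} has no candidate taxon on the tree")
        chosen.append(cands[int(rng.integers(len(cands)))])
    return chosen


def run_replicates(
    spec: ReplicateSpec,
    analysis: Callable[[pd.DataFrame, PhyloTree, np.random.Generator], dict[str, float]],
    p_aggregate: str = "mean",
) -> AggregateResult:
    """Run the configured analysis across replicates and aggregate.

    Per replicate: draw a tree (without replacement when the sample holds at
    least ``n_replicates`` trees, else with replacement), draw one language per
    site, prune the tree to the drawn languages, and call
    ``analysis(site_table_with_taxon, pruned_tree, rng)``, which must return a
    flat dict of scalars. Aggregates are arithmetic means; keys that look like
    p-values (``p_`` prefix after the last dot) follow ``p_aggregate``
    ("mean", the default, or "median"). Failed replicates are recorded and
    skipped; more than 20% failures aborts the run.
    """
    if p_aggregate not in ("mean", "median"):
        raise ValueError("p_aggregate must be 'mean' or 'median'")
    n_rep = spec.n_replicates
    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    substreams = ss.spawn(n_rep + 1)[1:]

    n_trees = len(spec.tree_source)
    if n_trees >= n_rep:
        tree_indices = master.permutation(n_trees)[:n_rep]
    else:
        tree_indices = master.integers(n_trees, size=n_rep)

    records: list[dict[str, float]] = []
    log_rows = []
    failures: list[tuple[int, str]] = []
    for r in range(n_rep):
        rng = np.random.default_rng(substreams[r])
        tree = spec.tree_source[int(tree_indices[r])]
        try:
            taxa = sample_site_languages(spec.site_table, rng, tree_tips=tree.tips)
            pruned = prune_to_taxa(tree, set(taxa))
            table = spec.site_table.copy()
            table["taxon"] = taxa
            rec = analysis(table, pruned, rng)
        except Exception as exc:  # noqa: BLE001 — any replicate failure is logged, not fatal
            failures.append((r, f"{type(exc).__name__}: {exc}"))
            continue
        rec = {k: float(v) for k, v in rec.items()}
        records.append(rec)
        log_rows.append(
            {
                "replicate": r,
                "tree_index": int(tree_indices[r]),
                "n_sites_used": rec.get("n", np.nan),
                "loglik": rec.get("loglik", np.nan),
                "lambda_prime": rec.get("dependence.lambda_prime", np.nan),
                "phi": rec.get("dependence.phi", np.nan),
                "gamma": rec.get("dependence.gamma", np.nan),
            }
        )
    if len(failures) > MAX_FAILURE_FRACTION * n_rep:
        detail = "; ".join(f"rep {i}: {msg}" for i, msg in failures[:5])
        raise RuntimeError(f"{len(failures)}/{n_rep} replicates failed ({detail} ...)")
    if not records:
        raise RuntimeError("no successful replicates")

    keys = sorted({k for rec in records for k in rec})
    means: dict[str, float] = {}
    for k in keys:
        vals = np.array([rec[k] for rec in records if k in rec], dtype=float)
        is_p = k.rsplit(".", 1)[-1].startswith("p_")
        if is_p and p_aggregate == "median":
            means[k] = float(np.nanmedian(vals))
        else:
            means[k] = float(np.nanmean(vals))
    return AggregateResult(
        means=means,
        per_replicate=records,
        replicate_log=pd.DataFrame(log_rows),
        n_requested=n_rep,
        n_effective=len(records),
        seed=spec.seed,
        failures=failures,
    )
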