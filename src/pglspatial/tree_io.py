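"""Reading, validating, pruning and writing phylogenetic trees.

Trees serve as the ancestry proxy for the analysis: what matters downstream is
the matrix of shared root-to-tip path lengths, so every operation here is
contracted in terms of path lengths. Parsing and pruning are delegated to
dendropy; this module adds validation (unique tip labels, non-negative branch
lengths, rootedness) and a stable tip-ordered interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = ["PhyloTree", "TreeSample", "read_trees", "write_trees", "prune_to_taxa"]


class TreeFormatError(ValueError):
    """Raised when a tree file cannot be parsed in the named dialect."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates an invariant (duplicate tips, negative branches)."""


@dataclass
class PhyloTree:
    """A rooted phylogenetic tree with branch lengths.

    Wraps a :class:`dendropy.Tree`. Tip labels are unique, branch lengths are
    non-negative (missing lengths are rejected), and polytomies are accepted
    as-is. Zero-length terminal branches are legal — they arise when dialects
    are attached to a language — but are reported with a warning because the
    corresponding tips are perfectly correlated under Brownian motion.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon is not None]
        if len(labels) != len(self.tree.leaf_nodes()):
            raise TreeValidationError("tree contains unlabeled tips")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        zero_terminals = []
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # root edge may legitimately lack a length
            if edge.length is None:
                raise TreeValidationError("tree has an edge with no branch length")
            if edge.length < 0:
                raise TreeValidationError(f"negative branch length {edge.length}")
            if edge.length == 0 and edge.head_node.is_leaf():
                zero_terminals.append(edge.head_node.taxon.label)
        if zero_terminals:
            warnings.warn(
                f"zero-length terminal branches at tips {sorted(zero_terminals)}: "
                "these tips are perfectly correlated under Brownian motion",
                stacklevel=3,
            )

    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (preorder leaf) order."""
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def root_distances(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return {leaf.taxon.label: leaf.root_distance for leaf in self.tree.leaf_node_iter()}

    def path_length_matrix(self, order: Sequence[str] | None = None):
        """Pairwise patristic distance matrix (numpy array) in the given tip order."""
        import numpy as np

        order = list(order) if order is not None else self.tips
        pdm = self.tree.phylogenetic_distance_matrix()
        ns = self.tree.taxon_namespace
        taxa = [ns.get_taxon(lbl) for lbl in order]
        missing = [lbl for lbl, t in zip(order, taxa) if t is None]
        if missing:
            raise TreeValidationError(f"labels not on tree: {missing}")
        n = len(taxa)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return out

    def max_height(self) -> float:
        return max(self.root_distances().values())

    def scaled(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(clone)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class TreeSample:
    """An ordered collection of trees, e.g. draws from a Bayesian posterior."""

    trees: list[PhyloTree]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeValidationError("TreeSample must contain at least one tree")
        tip_sets = [frozenset(t.tips) for t in self.trees]
        if len(set(tip_sets)) > 1:
            raise TreeValidationError("all trees in a TreeSample must share the same tip-label set")

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)


def read_trees(path: str | Path, format: str = "newick") -> TreeSample:
    """Read one or more trees from a Newick or Nexus file.

    Trees are returned in file order with branch lengths preserved as written.
    Nexus translate tables are honored and quoted labels with spaces are
    supported (dendropy semantics).

    Raises
    ------
    TreeFormatError
        If the file does not parse in the named dialect.
    TreeValidationError
        On duplicate tip labels or negative branch lengths.
    """
    path = Path(path)
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # separate namespaces so duplicate labels surface per-tree, not cross-tree
        tree_list = dendropy.TreeList.get(
            path=str(path), schema=format, taxon_namespace=dendropy.TaxonNamespace()
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        msg = str(exc)
        if "Multiple occurrences of the same taxa" in msg or "duplicate" in msg.lower():
            raise TreeValidationError(f"duplicate tip label in {path.name}: {msg}") from exc
        raise TreeFormatError(f"cannot parse {path.name} as {format}: {msg}") from exc
    if len(tree_list) == 0:
        raise TreeFormatError(f"{path.name} contains no trees")
    trees = []
    for idx, t in enumerate(tree_list):
        try:
            trees.append(PhyloTree(t))
        except TreeValidationError as exc:
            raise TreeValidationError(f"tree {idx} in {path.name}: {exc}") from exc
    return TreeSample(trees=trees, source=str(path))


def write_trees(sample: TreeSample | PhyloTree | Iterable[PhyloTree], path: str | Path) -> None:
    """Write trees as one newick string per line."""
    if isinstance(sample, PhyloTree):
        trees: Iterable[PhyloTree] = [sample]
    elif isinstance(sample, TreeSample):
        trees = sample.trees
    else:
        trees = list(sample)
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick() + "\n")


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Prune a tree down to the given tip labels.

    Path lengths between kept tips are unchanged; unary internal nodes created
    by pruning are suppressed with their branch lengths summed.
    """
    keep = set(keep)
    tips = set(tree.tips)
    missing = sorted(keep - tips)
    if missing:
        raise TreeValidationError(f"labels not on tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    with warnings.catch_warnings():
        # dialect tips already warned about at construction
        warnings.simplefilter("ignore")
        pruned = tree.tree.extract_tree_with_taxa_labels(keep)
        return PhyloTree(pruned)
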