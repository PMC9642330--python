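"""Neighbour-joining trees, nonparametric bootstrap and species monophyly.

The tree stage is a distance-based surrogate for likelihood tree inference:
the acceptance surface of a barcode survey is whether species form
well-supported exclusive clades, which NJ on the same distance matrix
answers at desk scale.  Trees are built unrooted; an outgroup can root them
for display only.

Bootstrap proceeds by resampling alignment columns with replacement,
recomputing the distance matrix and NJ tree per replicate, and scoring each
internal bipartition of the original tree by the percentage of replicates
containing it.  Replicates producing undefined distances are dropped and
logged.  A species is monophyletic when some bipartition of the unrooted
tree isolates exactly its members, which makes the verdict invariant under
rerooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .distances import (
    DistanceMatrix,
    _distances_from_patterns,
    _pattern_matrices,
)
from .seqio import BarcodeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SupportedTree",
    "MonophylyReport",
    "nj_tree",
    "bootstrap_support",
    "monophyly",
    "write_newick",
    "read_newick",
]


@dataclass
class SupportedTree:
    """An NJ tree with per-bipartition bootstrap supports (percent)."""

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    replicates: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class MonophylyReport:
    """Per-species category: monophyletic / non-monophyletic / trivial."""

    categories: dict[str, str]
    supports: dict[str, float]  # species -> support of its clade, if scored


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Standard neighbour-joining on a fully defined distance matrix.

    Negative branch lengths are clamped to zero.  Raises when any pairwise
    distance is undefined — remove or impute those records first.
    """
    if len(matrix.ids) < 3:
        raise ValueError("NJ requires at least 3 records")
    if matrix.n_undefined_pairs:
        raise ValueError(
            "distance matrix has undefined entries; remove the affected "
            "records or impute before tree building"
        )
    dm = _SkbioDM(matrix.data, ids=matrix.ids)
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _splits(tree: TreeNode, leaf_names: frozenset) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions keyed by the side excluding an anchor leaf."""
    anchor = min(leaf_names)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(clade) > len(leaf_names) - 2:
            continue
        key = clade if anchor not in clade else leaf_names - clade
        out[key] = node
    return out


def _matrix_from_codes(codes: np.ndarray, ids: Sequence[str], model: str,
                       gc: float | None) -> DistanceMatrix:
    d = _distances_from_patterns(*_pattern_matrices(codes), model, gc)
    return DistanceMatrix(list(ids), d, model)


def bootstrap_support(
    dataset: BarcodeDataset,
    model: str = "k2p",
    replicates: int = 100,
    seed: int | None = None,
    gc: float | None = None,
) -> SupportedTree:
    """NJ tree of the dataset with column-resampling bootstrap supports.

    Deterministic under a fixed seed; the seed is recorded in the result.
    Internal nodes of the returned tree are labelled with their integer
    support percentage.
    """
    if replicates < 1:
        raise ValueError("at least one bootstrap replicate is required")
    from .distances import distance_matrix

    if model == "t92" and gc is None:
        from .seqio import composition

        gc = composition(dataset).gc_content
    base = distance_matrix(dataset, model, gc=gc)
    tree = nj_tree(base)
    leaf_names = frozenset(dataset.ids)
    rng = np.random.default_rng(seed)
    codes = dataset.codes()
    L = dataset.length
    counts: dict[frozenset, int] = {}
    valid = 0
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        rep = _matrix_from_codes(codes[:, idx], dataset.ids, model, gc)
        if rep.n_undefined_pairs:
            logger.warning("bootstrap replicate dropped: undefined distances")
            continue
        valid += 1
        for key in _splits(nj_tree(rep), leaf_names):
            counts[key] = counts.get(key, 0) + 1
    if valid == 0:
        raise ValueError("all bootstrap replicates had undefined distances")
    supports: dict[frozenset, float] = {}
    for key, node in _splits(tree, leaf_names).items():
        supports[key] = 100.0 * counts.get(key, 0) / valid
        node.name = f"{supports[key]:.0f}"
    return SupportedTree(tree=tree, supports=supports, replicates=valid,
                         seed=seed)


def monophyly(
    tree: TreeNode | SupportedTree, labels: Mapping[str, str]
) -> MonophylyReport:
    """Categorise each species by whether a bipartition isolates it."""
    supports: dict[frozenset, float] = {}
    if isinstance(tree, SupportedTree):
        supports = tree.supports
        tree = tree.tree
    leaf_names = frozenset(t.name for t in tree.tips())
    missing = leaf_names - set(labels)
    if missing:
        raise ValueError(f"labels missing for leaves: {sorted(missing)}")
    anchor = min(leaf_names)
    split_keys = set(_splits(tree, leaf_names))
    members: dict[str, set[str]] = {}
    for leaf in leaf_names:
        members.setdefault(labels[leaf], set()).add(leaf)
    categories: dict[str, str] = {}
    sp_support: dict[str, float] = {}
    for sp, mem in members.items():
        if len(mem) == 1:
            categories[sp] = "trivial"
            continue
        mem = frozenset(mem)
        key = mem if anchor not in mem else leaf_names - mem
        # a species covering all but one leaf is monophyletic by convention
        if len(mem) >= len(leaf_names) - 1 or key in split_keys:
            categories[sp] = "monophyletic"
            if key in supports:
                sp_support[sp] = supports[key]
        else:
            categories[sp] = "non-monophyletic"
    return MonophylyReport(categories, sp_support)


def write_newick(tree: TreeNode | SupportedTree, path: str | Path) -> None:
    if isinstance(tree, SupportedTree):
        tree = tree.tree
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
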