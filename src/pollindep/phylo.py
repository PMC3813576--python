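"""Phylogenetic trees and the among-species correlation used by GEE.

Under a Brownian-motion model of trait evolution, the covariance between two
tips equals the shared path length from the root to their most recent common
ancestor.  The correlation passed to the regression stage normalizes this by
the root-to-tip distances, ``corr(i, k) = depth(mrca(i, k)) / sqrt(t_i *
t_k)``, which handles non-ultrametric trees and yields a unit diagonal.

Polytomies (nodes with more than two children) are resolved into random
bifurcations joined by zero-length edges; because inserted edges have zero
length, resolution leaves the correlation matrix unchanged.

Branch lengths missing from the input default to 1 — community trees pruned
from family-level megatrees frequently carry topology only.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np

PhyloTree = dendropy.Tree


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string; missing branch lengths become 1."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"invalid newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip label(s): {', '.join(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
        elif edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def to_newick(tree: PhyloTree) -> str:
    """Serialize with labels kept verbatim (spaces quoted, not underscored)."""
    return tree.as_string(schema="newick", preserve_spaces=True)


def resolve_polytomies(tree: PhyloTree, seed: int) -> PhyloTree:
    """Return a strictly bifurcating copy; inserted edges get length 0.

    The order in which polytomy children are paired is drawn uniformly from
    the seeded generator, so the output topology is reproducible.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, update_bipartitions=False, rng=random.Random(seed))
    for edge in out.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return out


def _tip_map(tree: PhyloTree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def root_to_tip_distances(tree: PhyloTree, species: list[str]) -> np.ndarray:
    tips = _tip_map(tree)
    return np.array([tips[s].distance_from_root() for s in species])


def phylo_correlation(tree: PhyloTree, species: list[str]) -> np.ndarray:
    """Brownian-motion correlation matrix among ``species`` (in that order)."""
    tips = _tip_map(tree)
    missing = [s for s in species if s not in tips]
    if missing:
        raise ValueError(f"species missing from tree: {', '.join(missing)}")
    n = len(species)
    depth = {}  # node -> distance from root, memoized over the traversal
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    t = np.array([depth[tips[s]] for s in species])
    if np.any(t <= 0):
        raise ValueError("zero root-to-tip distance: correlation undefined")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {s: tips[s].taxon for s in species}
    corr = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[k]])
            cov = (t[i] + t[k] - d) / 2.0
            corr[i, k] = corr[k, i] = cov / np.sqrt(t[i] * t[k])
    return corr


def phylogenetic_df(tree: PhyloTree, species: list[str] | None = None) -> float:
    """Effective sample size discounting phylogenetic non-independence.

    ``dfP = n * (total branch length) / (sum of root-to-tip distances)``
    over the ``n`` analysis species.  A star tree (all tips attached at the
    root with equal branches) gives ``dfP = n``; shared internal branches
    shrink it toward 1.
    """
    if species is None:
        species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    t = root_to_tip_distances(tree, species)
    total = tree.length()
    return len(species) * total / t.sum()
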