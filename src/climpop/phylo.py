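"""Brownian-motion phylogenetic correlation from a newick tree.

Under Brownian trait evolution the covariance of two tips is proportional to
the length of the root-to-MRCA path they share.  Dividing by the root-to-tip
depth of an ultrametric tree gives a correlation matrix V with unit diagonal,
the quantity the meta-regression consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MissingTaxonError

__all__ = ["PhyloCorrelation", "read_newick", "brownian_correlation",
           "match_species", "load_synonym_map"]


@dataclass
class PhyloCorrelation:
    """Species-order-indexed Brownian correlation matrix."""

    species_order: list
    V: np.ndarray

    def index_of(self, name: str) -> int:
        return self.species_order.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.species_order,
                            columns=self.species_order)

    def to_csv(self, path):
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, index_col=0)
        return cls(species_order=list(df.index), V=df.to_numpy(dtype=float))


def read_newick(path) -> dendropy.Tree:
    """Parse a newick tree with branch lengths.

    Polytomies are accepted; a missing branch length on any non-root edge is a
    parse error.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise InvalidArgumentError(f"cannot parse newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise InvalidArgumentError(
                f"newick tree {path} has an edge without a branch length")
    return tree


def _tip_depths_and_ancestry(tree, taxa):
    """Per-taxon root distance and ancestor->depth maps for MRCA lookup."""
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        label_to_leaf[leaf.taxon.label] = leaf
    missing = [t for t in taxa if t not in label_to_leaf]
    if missing:
        raise MissingTaxonError(missing)
    depths = {}   # node id -> distance from root
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[id(node)] = 0.0
        else:
            depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
    anc = {}
    tip_depth = {}
    for t in taxa:
        node = label_to_leaf[t]
        tip_depth[t] = depths[id(node)]
        chain = {}
        cur = node.parent_node
        while cur is not None:
            chain[id(cur)] = depths[id(cur)]
            cur = cur.parent_node
        anc[t] = chain
    return tip_depth, anc


def brownian_correlation(tree, taxa=None) -> PhyloCorrelation:
    """Brownian correlation V over ``taxa`` (default: all tips, sorted).

    V[i, j] is the root-to-MRCA shared path length of tips i and j divided by
    the maximum root-to-tip depth; the diagonal is exactly 1.  For a
    non-ultrametric tree the off-diagonal normalization uses the maximum depth
    and a warning is emitted.
    """
    if taxa is None:
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = list(taxa)
    if len(taxa) < 1:
        raise InvalidArgumentError("need at least one taxon")
    tip_depth, anc = _tip_depths_and_ancestry(tree, taxa)
    depth = max(tip_depth.values())
    if depth <= 0:
        raise InvalidArgumentError("tree has zero depth")
    spread = max(tip_depth.values()) - min(tip_depth.values())
    if spread > 1e-6 * depth:
        warnings.warn("tree is not ultrametric; normalizing by maximum "
                      "root-to-tip depth", stacklevel=2)
    n = len(taxa)
    V = np.eye(n)
    for i in range(n):
        ai = anc[taxa[i]]
        for j in range(i + 1, n):
            aj = anc[taxa[j]]
            shared = ai.keys() & aj.keys()
            mrca_depth = max(ai[k] for k in shared) if shared else 0.0
            V[i, j] = V[j, i] = mrca_depth / depth
    return PhyloCorrelation(species_order=taxa, V=V)


def match_species(names, phylo: PhyloCorrelation, synonym_map=None):
    """Map data species names to indices into ``phylo.species_order``.

    ``synonym_map`` maps data-side names to tree-side names (e.g. Loxodonta
    cyclotis -> Loxodonta africana).  All unmatched names are reported at once.
    """
    synonym_map = synonym_map or {}
    pos = {name: i for i, name in enumerate(phylo.species_order)}
    idx = np.empty(len(names), dtype=int)
    missing = []
    for k, name in enumerate(names):
        resolved = synonym_map.get(name, name)
        if resolved in pos:
            idx[k] = pos[resolved]
        else:
            missing.append(name)
            idx[k] = -1
    if missing:
        raise MissingTaxonError(sorted(set(missing)))
    return idx


def load_synonym_map(path) -> dict:
    """Two-column CSV (data_name, tree_name) -> dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidArgumentError("synonym map needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
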