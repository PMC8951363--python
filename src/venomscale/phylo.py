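"""Phylogeny handling for the "animal" random term.

The mixed model controls for shared ancestry through a species-by-species
covariance matrix whose (i, j) entry is the branch length shared between
the root-to-i and root-to-j paths. This module parses Newick trees
(via dendropy), repairs missing branch lengths with Grafen's method,
prunes to the analyzed species, and builds that covariance matrix scaled
to unit tree height so variance components are comparable across trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, PhylogenyError
from .ingest import normalize_species_name

logger = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """A rooted tree with optional branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` carrying a flag for whether
    the source provided branch lengths (Open Tree synthetic topologies
    usually do not).
    """

    tree: dendropy.Tree
    has_lengths: bool = True

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(tree=self.tree.clone(depth=1), has_lengths=self.has_lengths)


@dataclass
class PhyloCovariance:
    """Species-ordered shared-branch-length matrix (the animal term's structure).

    ``matrix[i, j]`` is the depth of the most recent common ancestor of
    species i and j (total shared root-path length); the diagonal holds
    root-to-tip path lengths. When ``scaled`` the matrix has been divided
    by its maximum diagonal entry, so an ultrametric tree has unit
    diagonal.
    """

    species_order: list[str]
    matrix: np.ndarray
    scaled: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        q = len(self.species_order)
        if self.matrix.shape != (q, q):
            raise PhylogenyError(
                f"covariance shape {self.matrix.shape} does not match {q} species"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise PhylogenyError("covariance matrix is not symmetric")

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.matrix, index=self.species_order, columns=self.species_order
        ).to_csv(path, sep="\t")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement into a :class:`Phylogeny`.

    Topology, labels and any branch lengths are preserved exactly. Trees
    with no branch lengths at all are flagged (``has_lengths=False``) so
    downstream code can assign Grafen lengths. Unbalanced parentheses,
    duplicate tips and empty input raise :class:`NewickParseError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    depth = 0
    for pos, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in Newick input")
    try:
        tree = dendropy.Tree.get(
            data=stripped, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    if not labels:
        raise NewickParseError("tree has no tips")
    lengths = [e.length for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    has_lengths = any(l is not None for l in lengths)
    if has_lengths:
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None and e.length is None:
                e.length = 0.0
            if e.length is not None and e.length < 0:
                raise NewickParseError(f"negative branch length {e.length}")
    return Phylogeny(tree=tree, has_lengths=has_lengths)


def read_newick(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text(encoding="utf-8"))


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n", encoding="utf-8")


def assign_grafen_lengths(phy: Phylogeny, keep_existing: bool = False) -> Phylogeny:
    """Assign branch lengths by Grafen's method and scale to unit depth.

    Each internal node's height is (number of descendant tips − 1), tips
    sit at height 0, heights are divided by the root height, and each
    branch length is parent height − child height. The result is
    ultrametric with depth 1. With ``keep_existing`` a tree that already
    has branch lengths is returned unchanged.
    """
    if keep_existing and phy.has_lengths:
        return phy
    out = phy.copy()
    tree = out.tree
    n_tips = out.n_tips
    if n_tips < 2:
        raise PhylogenyError("Grafen lengths require at least 2 tips")
    root_height = float(n_tips - 1)
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[id(node)] = 0.0
        else:
            k = sum(1 for _ in node.leaf_iter())
            heights[id(node)] = (k - 1) / root_height
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None
    out.has_lengths = True
    return out


def assign_unit_lengths(phy: Phylogeny) -> Phylogeny:
    """Alternative repair policy: every branch length 1 (no depth scaling)."""
    out = phy.copy()
    for e in out.tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = 1.0
    out.has_lengths = True
    return out


def prune_to_tips(phy: Phylogeny, names: Iterable[str]) -> Phylogeny:
    """Restrict the tree to the named tips (induced subtree).

    Unbranched internal nodes left by the pruning are suppressed with
    their branch lengths summed, so root-to-tip distances among retained
    tips are preserved. Names absent from the tree raise an error listing
    every absentee.
    """
    wanted = list(dict.fromkeys(names))
    have = set(phy.tip_labels)
    missing = sorted(set(wanted) - have)
    if missing:
        raise PhylogenyError(f"tips not in tree: {missing}")
    out = phy.copy()
    out.tree.retain_taxa_with_labels(wanted)
    return out


def match_tree_to_species(phy: Phylogeny, species: Sequence[str]) -> tuple[Phylogeny, dict[str, str]]:
    """Prune the tree to the analysis species using normalized name matching.

    Returns the pruned tree and a mapping from analysis species name to
    the matching tip label. Species absent from the tree abort with a
    named list — silent fuzzy matching would be irreproducible.
    """
    by_norm: dict[str, str] = {}
    for label in phy.tip_labels:
        by_norm.setdefault(normalize_species_name(label), label)
    mapping = {}
    missing = []
    for sp in species:
        label = by_norm.get(normalize_species_name(sp))
        if label is None:
            missing.append(sp)
        else:
            mapping[sp] = label
    if missing:
        raise PhylogenyError(f"species not found among tree tips: {sorted(missing)}")
    return prune_to_tips(phy, mapping.values()), mapping


def phylo_covariance(
    phy: Phylogeny, species_order: Sequence[str], scale: bool = True
) -> PhyloCovariance:
    """Build the shared-branch-length covariance matrix in a given species order.

    For every branch, its length is added to all entries (i, j) whose two
    tips both descend from the branch — which accumulates exactly the
    depth of each pair's most recent common ancestor. With ``scale`` the
    matrix is divided by its maximum diagonal (unit tree height).
    """
    if not phy.has_lengths:
        raise PhylogenyError("tree has no branch lengths; assign Grafen lengths first")
    labels = phy.tip_labels
    by_norm = {}
    for lab in labels:
        by_norm.setdefault(normalize_species_name(lab), lab)
    order_labels = []
    missing = []
    for sp in species_order:
        lab = by_norm.get(normalize_species_name(sp))
        if lab is None:
            missing.append(sp)
        else:
            order_labels.append(lab)
    if missing:
        raise PhylogenyError(f"species not found among tree tips: {sorted(missing)}")
    idx = {lab: i for i, lab in enumerate(order_labels)}
    q = len(order_labels)
    cov = np.zeros((q, q))
    for node in phy.tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        if length < 0:
            raise PhylogenyError(f"negative branch length {length}")
        below = [idx[lf.taxon.label] for lf in node.leaf_iter() if lf.taxon.label in idx]
        if below:
            sel = np.array(below)
            cov[np.ix_(sel, sel)] += length
    if scale:
        top = cov.diagonal().max()
        if top <= 0:
            raise PhylogenyError("tree has zero total depth; cannot scale")
        cov = cov / top
    return PhyloCovariance(species_order=list(species_order), matrix=cov, scaled=scale)
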