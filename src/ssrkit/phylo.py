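"""UPGMA dendrograms with locus-bootstrap supports and Newick serialization.

UPGMA repeatedly merges the closest pair of clusters; the distance from a
merged cluster to any other is the size-weighted arithmetic mean of its
members' distances, and the merge node sits at height d/2, producing a
rooted ultrametric tree.  Ties are broken by the smallest (row, column)
index pair in cluster-creation order, which makes the tree byte-
reproducible.  Bootstrap supports resample loci (columns of the genotype
table) with replacement; the support of an internal node is the percentage
of replicate trees containing the same leaf set under some clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .popgen import (
    DistanceMatrix,
    GenotypeTable,
    NoSharedAllelesError,
    distance_matrix,
)


@dataclass
class TreeNode:
    """A node of a rooted ultrametric tree.

    Leaves have height 0 and a name; internal nodes carry the merge height
    (merge distance / 2) and optionally a bootstrap support in [0, 100].
    """

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes below (and including) this one."""
        return {
            n.leaf_names() for n in self.walk() if not n.is_leaf
        }


@dataclass
class UltrametricTree:
    """A rooted binary ultrametric dendrogram."""

    root: TreeNode

    def __post_init__(self) -> None:
        # heights non-decreasing toward the root and leaves at 0 make every
        # root-to-leaf path length equal to root.height (ultrametric)
        for node in self.root.walk():
            for child in node.children:
                if child.height > node.height + 1e-9:
                    raise ValueError("child above parent: tree is not ultrametric")
            if node.is_leaf and abs(node.height) > 1e-9:
                raise ValueError("leaf not at height 0")

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def clades(self) -> set[frozenset[str]]:
        return self.root.clades()

    def cophenetic(self, a: str, b: str) -> float:
        """Tree distance between two leaves: twice their lowest common
        ancestor's height."""
        node = self.root
        while True:
            nxt = None
            for child in node.children:
                names = child.leaf_names()
                if a in names and b in names:
                    nxt = child
                    break
            if nxt is None:
                return 2.0 * node.height
            node = nxt


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """Build the UPGMA tree for a symmetric, finite distance matrix.

    At each step the minimum-distance cluster pair is merged; ties break on
    the smallest (i, j) pair in cluster-creation order.
    """
    ids = dist.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    d = dist.data.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")

    # active clusters in creation order
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    sizes: list[int] = [1] * len(ids)
    dists: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))
    }
    active = list(range(len(ids)))
    next_idx = len(ids)
    store: dict[int, TreeNode] = {i: n for i, n in enumerate(nodes)}
    size_of: dict[int, int] = {i: s for i, s in enumerate(sizes)}

    def dget(i: int, j: int) -> float:
        return dists[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (dget(i, j), i, j)
                if best is None or key < best:
                    best = key
        dmin, i, j = best
        merged = TreeNode(
            height=dmin / 2.0, children=[store[i], store[j]]
        )
        si, sj = size_of[i], size_of[j]
        for k in active:
            if k in (i, j):
                continue
            dnew = (si * dget(i, k) + sj * dget(j, k)) / (si + sj)
            dists[(k, next_idx) if k < next_idx else (next_idx, k)] = dnew
        store[next_idx] = merged
        size_of[next_idx] = si + sj
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1
    return UltrametricTree(store[active[0]])


def bootstrap_upgma(
    table: GenotypeTable,
    n_reps: int = 1000,
    seed: int | None = None,
    variant: str = "nei1972",
    on_zero_identity: str = "error",
) -> tuple[UltrametricTree, dict[str, int]]:
    """UPGMA tree from the full table, with locus-bootstrap clade supports.

    Each replicate resamples loci with replacement, rebuilds the distance
    matrix and tree, and every internal node of the reference tree gets the
    percentage of replicates containing its leaf set as a clade.
    Replicates whose distances are undefined (no shared alleles in the
    resampled loci) are skipped and counted; ``on_zero_identity="cap"``
    instead replaces undefined distances with a large finite stand-in,
    keeping every replicate.  Deterministic for fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reference = upgma(
        distance_matrix(table, variant=variant, on_zero_identity=on_zero_identity)
    )
    rng = np.random.default_rng(seed)
    loci = table.loci
    counts: dict[frozenset[str], int] = {c: 0 for c in reference.clades()}
    n_used = 0
    n_skipped = 0
    for _ in range(n_reps):
        sample = list(rng.choice(loci, size=len(loci), replace=True))
        sub = table.subset_loci(sample)
        try:
            rep_tree = upgma(
                distance_matrix(sub, variant=variant,
                                on_zero_identity=on_zero_identity)
            )
        except (NoSharedAllelesError, ValueError, ZeroDivisionError):
            n_skipped += 1
            continue
        n_used += 1
        rep_clades = rep_tree.clades()
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    if n_used == 0:
        raise RuntimeError("every bootstrap replicate failed")
    for node in reference.root.walk():
        if not node.is_leaf:
            node.support = round(100.0 * counts[node.leaf_names()] / n_used)
    return reference, {"replicates_used": n_used, "replicates_skipped": n_skipped}


def _sorted_children(node: TreeNode) -> list[TreeNode]:
    # deterministic rendering: smaller subtree first, then lexicographic
    return sorted(
        node.children,
        key=lambda c: (len(c.leaves()), min(l.name for l in c.leaves())),
    )


def write_newick(
    tree: UltrametricTree,
    with_supports: bool = True,
    with_branch_lengths: bool = True,
) -> str:
    """Serialize to Newick.  A node's branch length is its parent's height
    minus its own height; supports render as internal node labels."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            label = node.name
        else:
            inner = ",".join(
                render(c, node.height) for c in _sorted_children(node)
            )
            sup = (
                f"{node.support:g}"
                if with_supports and node.support is not None
                else ""
            )
            label = f"({inner}){sup}"
        if with_branch_lengths and parent_height is not None:
            label += f":{parent_height - node.height:.10g}"
        return label

    return render(tree.root, None) + ";"


def parse_newick(text: str) -> UltrametricTree:
    """Parse the Newick subset produced by :func:`write_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> tuple[TreeNode, float | None]:
        nonlocal pos
        children: list[TreeNode] = []
        child_info: list[tuple[TreeNode, float | None]] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child, blen = parse_node()
                child_info.append((child, blen))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        blen = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            blen = float(s[start:pos])
        node = TreeNode()
        if child_info:
            node.children = [c for c, _ in child_info]
            if label:
                node.support = float(label)
            node._child_blens = [b for _, b in child_info]  # type: ignore[attr-defined]
        else:
            node.name = label or None
        return node, blen

    root, _ = parse_node()

    # convert branch lengths to heights (leaves at height 0)
    def fix_heights(node: TreeNode) -> float:
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        blens = getattr(node, "_child_blens")
        heights = []
        for child, blen in zip(node.children, blens):
            ch = fix_heights(child)
            heights.append(ch + (blen if blen is not None else 0.0))
        node.height = heights[0]
        return node.height

    fix_heights(root)
    return UltrametricTree(root)


def cut_tree(tree: UltrametricTree, height: float) -> dict[str, int]:
    """Cluster membership at a height cut: leaf name → cluster index.

    Clusters are the maximal clades whose node height is at most the cut;
    indices follow the deterministic rendering order.
    """
    clusters: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf or node.height <= height:
            clusters.append(sorted(l.name for l in node.leaves()))
            return
        for child in _sorted_children(node):
            walk(child)

    walk(tree.root)
    return {
        name: idx for idx, names in enumerate(clusters) for name in names
    }
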