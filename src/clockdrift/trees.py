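"""Dated phylogenetic trees, the fixed simulation-tree builders, and newick I/O.

A :class:`DatedTree` is a rooted tree in which every node carries an age in
millions of years (tips at 0, ages increasing root-ward) and every non-root
branch carries an expected number of substitutions per site. Branch
attributes are stored on the child node. For clock-true simulation trees the
identity ``length = rate * time_span`` holds exactly by construction.

The per-branch *rate* used throughout the package is the branch length
(substitutions/site) divided by the branch's time span (Myr).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np


class DatedTree:
    """Rooted tree with node ages (Myr) and branch lengths (subs/site).

    Nodes are integers ``0..n_nodes-1``; ``parent[i]`` is -1 for the root.
    ``lengths`` may be ``None`` when the source newick carried no branch
    lengths (absent is distinct from zero).
    """

    def __init__(
        self,
        parent: Sequence[int],
        labels: Sequence[Optional[str]],
        ages: Optional[Sequence[float]] = None,
        lengths: Optional[Sequence[float]] = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.labels = list(labels)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        self.lengths = None if lengths is None else np.asarray(lengths, dtype=float)
        # optional annotations set by builders
        self.clade_of: dict[int, str] = {}
        self.branch_depths: dict[int, int] = {}

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    @property
    def time_spans(self) -> np.ndarray:
        """Per-branch duration in Myr (parent age minus child age); nan at root."""
        if self.ages is None:
            raise ValueError("tree has no node ages")
        spans = np.full(self.n_nodes, np.nan)
        for i, p in enumerate(self.parent):
            if p >= 0:
                spans[i] = self.ages[p] - self.ages[i]
        return spans

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        if self.ages is None:
            raise ValueError("tree has no node ages")
        return bool(np.all(np.abs(self.ages[self.tips]) <= tol))

    def root_to_tip_lengths(self) -> dict[int, float]:
        """Total substitutions/site from root to each tip."""
        if self.lengths is None:
            raise ValueError("tree has no branch lengths")
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.lengths[node]
        return {t: depth[t] for t in self.tips}

    def with_lengths(self, lengths: Sequence[float]) -> "DatedTree":
        out = DatedTree(self.parent, self.labels, self.ages, np.asarray(lengths, float))
        out.clade_of = dict(self.clade_of)
        out.branch_depths = dict(self.branch_depths)
        return out

    def total_time(self) -> float:
        """Sum of all branch time spans (Myr)."""
        spans = self.time_spans
        return float(np.nansum(spans))

    def total_length(self) -> float:
        if self.lengths is None:
            raise ValueError("tree has no branch lengths")
        return float(np.nansum([self.lengths[i] for i in range(self.n_nodes) if self.parent[i] >= 0]))

    # ------------------------------------------------------------------
    def _tag_root_clades(self) -> None:
        """Tag the two root subtrees as clades A and B (binary root only)."""
        if len(self.children[self.root]) != 2:
            return
        for tag, top in zip("AB", self.children[self.root]):
            stack = [top]
            while stack:
                node = stack.pop()
                self.clade_of[node] = tag
                stack.extend(self.children[node])

    def __repr__(self) -> str:  # pragma: no cover
        return f"DatedTree(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


@dataclass(frozen=True)
class UnrootedBranch:
    """One branch of the unrooted view of a rooted tree.

    For a binary root the two root-child branches merge into a single
    *central* branch whose length and time span are the sums of the two
    rooted halves; ``child`` then holds both child nodes.
    """

    index: int
    child: tuple[int, ...]
    length: float
    time_span: float
    is_central: bool
    depth: Optional[int]
    clade: Optional[str]


def unrooted_branches(tree: DatedTree) -> list[UnrootedBranch]:
    """Enumerate the 2n-3 branches of the unrooted view of ``tree``.

    The central branch carries no depth tag and no single clade tag (it
    spans both root subtrees).
    """
    spans = tree.time_spans if tree.ages is not None else None
    lengths = tree.lengths
    branches: list[UnrootedBranch] = []
    root_children = tree.children[tree.root]
    merge = len(root_children) == 2
    idx = 0
    for node in tree.preorder():
        if node == tree.root or (merge and node in root_children):
            continue
        branches.append(
            UnrootedBranch(
                index=idx,
                child=(node,),
                length=float(lengths[node]) if lengths is not None else np.nan,
                time_span=float(spans[node]) if spans is not None else np.nan,
                is_central=False,
                depth=tree.branch_depths.get(node),
                clade=tree.clade_of.get(node),
            )
        )
        idx += 1
    if merge:
        c1, c2 = root_children
        branches.append(
            UnrootedBranch(
                index=idx,
                child=(c1, c2),
                length=float(lengths[c1] + lengths[c2]) if lengths is not None else np.nan,
                time_span=float(spans[c1] + spans[c2]) if spans is not None else np.nan,
                is_central=True,
                depth=None,
                clade=None,
            )
        )
    return branches


# ----------------------------------------------------------------------
# builders


def build_8taxon_tree(per_branch_length: float) -> DatedTree:
    """The balanced 8-taxon ultrametric simulation tree.

    Topology (((t1,t2),(t3,t4)),((t5,t6),(t7,t8))): cherry ancestors at
    1 Myr, their parents at 2 Myr, root at 3 Myr. Every rooted branch spans
    1 Myr and carries ``per_branch_length`` substitutions/site, so the true
    rate is ``per_branch_length`` per Myr on every branch. The unrooted view
    has 13 branches; the central one spans 2 Myr with twice the length.

    Branch depth tags: the 8 terminal branches are depth 1, the 4
    cherry-to-parent branches are depth 2; the central branch has no depth.
    """
    L = float(per_branch_length)
    if L <= 0:
        raise ValueError("per_branch_length must be > 0")
    # tips 0..7, cherries 8..11, depth-2 nodes 12..13, root 14
    parent = [8, 8, 9, 9, 10, 10, 11, 11, 12, 12, 13, 13, 14, 14, -1]
    labels: list[Optional[str]] = [f"t{i+1}" for i in range(8)] + [None] * 7
    ages = [0.0] * 8 + [1.0] * 4 + [2.0] * 2 + [3.0]
    lengths = [L] * 14 + [np.nan]
    tree = DatedTree(parent, labels, ages, lengths)
    tree._tag_root_clades()
    tree.branch_depths = {i: 1 for i in range(8)}
    tree.branch_depths.update({i: 2 for i in range(8, 12)})
    return tree


def build_dated_tree(time_tree, mean_rate: float) -> DatedTree:
    """Scale a time-calibrated tree into substitutions/site at a clock rate.

    ``time_tree`` is a newick string/path (edge lengths in Myr, ultrametric)
    or a :class:`DatedTree` with ages set. Every branch gets
    ``length = mean_rate * time_span``; the two root subtrees are tagged as
    clades A and B.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be > 0")
    if isinstance(time_tree, DatedTree):
        tree = time_tree
        if tree.ages is None:
            raise ValueError("tree has no node ages")
    else:
        tree = read_newick(time_tree)
        if tree.lengths is None:
            raise ValueError("time tree must carry branch lengths (in Myr)")
        # edge lengths are durations; convert to ages (tips at 0)
        dist = np.zeros(tree.n_nodes)
        for node in tree.preorder():
            if node != tree.root:
                dist[node] = dist[tree.parent[node]] + tree.lengths[node]
        height = max(dist[t] for t in tree.tips)
        ages = height - dist
        ages[tree.tips] = np.where(np.abs(ages[tree.tips]) < 1e-6, 0.0, ages[tree.tips])
        if np.any(ages[tree.tips] != 0.0):
            raise ValueError("time tree is not ultrametric: tips not contemporaneous")
        tree.ages = ages
    spans = tree.time_spans
    if np.any(spans[np.array(tree.parent) >= 0] <= 0):
        raise ValueError("non-positive time span implied by node ages")
    lengths = mean_rate * spans
    out = tree.with_lengths(lengths)
    if not out.clade_of:
        out._tag_root_clades()
    return out


# ----------------------------------------------------------------------
# newick I/O (dendropy-backed)


def _looks_like_newick(s: str) -> bool:
    return s.lstrip().startswith("(")


def read_newick(source: str) -> DatedTree:
    """Parse a newick string or file into a :class:`DatedTree` (no ages).

    Branch lengths are kept when present; a newick without lengths yields
    ``lengths=None`` rather than zeros. Malformed input raises ValueError
    with the parser's location message.
    """
    text = source if _looks_like_newick(source) else open(source).read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValueError(f"newick parse failure: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = [-1] * len(nodes)
    labels: list[Optional[str]] = [None] * len(nodes)
    lengths = np.full(len(nodes), np.nan)
    any_length = False
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                lengths[i] = nd.edge.length
                any_length = True
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return DatedTree(parent, labels, ages=None, lengths=lengths if any_length else None)


def write_newick(tree: DatedTree, path: Optional[str] = None, precision: int = 10) -> str:
    """Serialise to newick; returns the string, optionally writing ``path``."""

    def render(node: int) -> str:
        if not tree.children[node]:
            s = tree.labels[node] or f"n{node}"
        else:
            s = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
            if tree.labels[node]:
                s += tree.labels[node]
        if tree.parent[node] >= 0 and tree.lengths is not None and np.isfinite(tree.lengths[node]):
            s += f":{tree.lengths[node]:.{precision}g}"
        return s

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
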