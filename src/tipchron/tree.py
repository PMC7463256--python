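"""Rooted binary time-trees with node ages in years before the youngest tip.

The tree is stored in flat arrays for fast traversal inside the MCMC
sampler: node indices ``0 .. n_tips-1`` are tips (in label order),
``n_tips .. 2*n_tips-2`` are internal nodes.  Ages increase toward the
root; every parent is strictly older than both of its children.  A tree
is ultrametric only if all tips have age 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "TreeError"]


class TreeError(ValueError):
    """Raised for structurally invalid trees (polytomies, bad ages...)."""


@dataclass
class TimeTree:
    labels: list[str]
    parent: np.ndarray      # (2n-1,) int, -1 at the root
    children: np.ndarray    # (2n-1, 2) int, -1 rows for tips
    ages: np.ndarray        # (2n-1,) float, years before youngest tip
    _postorder: np.ndarray = field(default=None, repr=False)

    # -- construction -------------------------------------------------

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.ages = np.asarray(self.ages, dtype=float)
        self.validate()

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeError("a time-tree needs at least 2 tips")
        if len(set(self.labels)) != n:
            raise TreeError("tip labels must be unique")
        if self.parent.shape != (2 * n - 1,) or self.children.shape != (2 * n - 1, 2):
            raise TreeError("array shapes inconsistent with n_tips")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        for node in range(n, 2 * n - 1):
            l, r = self.children[node]
            if l < 0 or r < 0:
                raise TreeError(f"internal node {node} is not binary")
            for c in (l, r):
                if not self.ages[node] > self.ages[c]:
                    raise TreeError(
                        f"node {node} (age {self.ages[node]:g}) is not older "
                        f"than child {c} (age {self.ages[c]:g})"
                    )
        if np.any(self.ages < 0):
            raise TreeError("negative node age")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> np.ndarray:
        """Internal nodes ordered children-before-parent (cached)."""
        if self._postorder is None:
            order, stack, seen = [], [self.root], set()
            while stack:
                node = stack.pop()
                if node < self.n_tips:
                    continue
                if node in seen:
                    order.append(node)
                    continue
                seen.add(node)
                stack.append(node)
                stack.extend(int(c) for c in self.children[node])
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.ages[p] - self.ages[node])

    def path_to_root(self, node: int) -> list[int]:
        out = []
        p = int(self.parent[node])
        while p != -1:
            out.append(p)
            p = int(self.parent[p])
        return out

    def mrca(self, labels) -> int:
        """Index of the most recent common ancestor of a set of tip labels."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        want = {idx[l] for l in labels}
        if not want:
            raise TreeError("empty label set")
        # climb from one member, keep the first ancestor covering all of them
        cover = {min(want)}
        node = min(want)
        while not want <= cover:
            node = int(self.parent[node])
            if node == -1:
                raise TreeError("labels do not share an ancestor")
            cover = set(self._subtree_tips(node))
        return node

    def _subtree_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(int(c) for c in self.children[v])
        return out

    def tip_ages(self) -> np.ndarray:
        return self.ages[: self.n_tips].copy()

    def copy(self) -> "TimeTree":
        return TimeTree(
            list(self.labels), self.parent.copy(), self.children.copy(), self.ages.copy()
        )

    # -- sub-trees -----------------------------------------------------

    def induced_subtree(self, keep_labels) -> "TimeTree":
        """Subtree spanned by a subset of tips, unary nodes suppressed.

        Node ages are preserved, so branch durations along retained
        paths are unchanged.
        """
        keep = [l for l in self.labels if l in set(keep_labels)]
        if len(keep) < 2:
            raise TreeError("need at least 2 retained tips")
        idx = {lab: i for i, lab in enumerate(self.labels)}
        n_new = len(keep)
        new_parent = np.full(2 * n_new - 1, -1, dtype=np.int64)
        new_children = np.full((2 * n_new - 1, 2), -1, dtype=np.int64)
        new_ages = np.zeros(2 * n_new - 1)

        # bottom-up: map each old node to a new node id, or pass a single
        # retained child through (unary suppression)
        mapping: dict[int, int] = {}
        for i, lab in enumerate(keep):
            mapping[idx[lab]] = i
            new_ages[i] = self.ages[idx[lab]]
        next_id = n_new
        for node in self.postorder():
            kids = [mapping[int(c)] for c in self.children[node] if int(c) in mapping]
            if len(kids) == 2:
                mapping[int(node)] = next_id
                new_children[next_id] = kids
                new_parent[kids[0]] = next_id
                new_parent[kids[1]] = next_id
                new_ages[next_id] = self.ages[node]
                next_id += 1
            elif len(kids) == 1:
                mapping[int(node)] = kids[0]  # suppress unary node
        return TimeTree(keep, new_parent, new_children, new_ages)

    # -- interop -------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with branch lengths in years."""

        def rec(node: int) -> str:
            if node < self.n_tips:
                return f"{self.labels[node]}:{self.branch_length(node):.12g}"
            l, r = self.children[node]
            inner = f"({rec(int(l))},{rec(int(r))})"
            if self.parent[node] == -1:
                return inner
            return f"{inner}:{self.branch_length(node):.12g}"

        return rec(self.root) + ";"

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, tip_ages: dict | None = None) -> "TimeTree":
        """Build from a dendropy tree with edge lengths in years.

        Node ages are recomputed from root-to-tip path lengths; if
        ``tip_ages`` (label -> years before youngest tip) is given they
        override the path-derived tip ages, otherwise the deepest tip is
        placed at age 0.
        """
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        leaves = [lf for lf in dtree.leaf_node_iter()]
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None and len(nd.child_nodes()) not in (0, 2):
                raise TreeError("polytomies are not supported; resolve the tree first")
            if nd.parent_node is None and len(nd.child_nodes()) != 2:
                raise TreeError("root must be bifurcating")
        labels = sorted(lf.taxon.label for lf in leaves)
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        n = len(labels)
        lab_to_i = {l: i for i, l in enumerate(labels)}

        # root-to-node depths
        depth = {}
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        max_depth = max(depth[lf] for lf in leaves)

        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
        ages = np.zeros(2 * n - 1)
        node_id = {}
        next_internal = n
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                i = lab_to_i[nd.taxon.label]
            else:
                i = next_internal
                next_internal += 1
            node_id[nd] = i
            ages[i] = max_depth - depth[nd]
            if tip_ages is not None and nd.is_leaf():
                ages[i] = float(tip_ages[nd.taxon.label])
            if not nd.is_leaf():
                kids = [node_id[c] for c in nd.child_nodes()]
                children[i] = kids
                for c in kids:
                    parent[c] = i
        if tip_ages is not None:
            # internal age = child age + edge length, so branch durations
            # stay consistent with the supplied tip dates
            for nd in dtree.postorder_node_iter():
                if nd.is_leaf():
                    continue
                c = nd.child_nodes()[0]
                ages[node_id[nd]] = ages[node_id[c]] + (c.edge.length or 0.0)
        return cls(labels, parent, children, ages)

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict | None = None) -> "TimeTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree, tip_ages=tip_ages)

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")
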