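"""Rooted ultrametric time trees (node ages in Myr, tips at age 0).

Every non-root node defines the branch above it; branch ids are child
node ids.  Tips are ids ``0..n-1``; internal nodes ``n..2n-2``.
"""

from __future__ import annotations

import dendropy
import numpy as np


class ChronoTree:
    def __init__(self, labels: list[str], parent: list[int], ages: list[float]):
        self.labels = list(labels)
        self.n_tips = len(labels)
        self.parent = np.asarray(parent, dtype=int)
        self.ages = np.asarray(ages, dtype=float)
        n_nodes = len(self.parent)
        if n_nodes != 2 * self.n_tips - 1:
            raise ValueError("not a binary rooted tree")
        roots = [i for i in range(n_nodes) if self.parent[i] < 0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i in range(n_nodes):
            if self.parent[i] >= 0:
                self.children[self.parent[i]].append(i)
        for i in range(n_nodes):
            nchild = len(self.children[i])
            if (i < self.n_tips and nchild != 0) or (i >= self.n_tips and nchild != 2):
                raise ValueError("tips must have 0 children, internals 2")
            if self.parent[i] >= 0 and not self.ages[self.parent[i]] > self.ages[i]:
                raise ValueError("node ages must strictly decrease root -> tip")

    # -- structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def internal_nodes(self) -> list[int]:
        return list(range(self.n_tips, self.n_nodes))

    def branches(self) -> list[int]:
        """Branch ids = every non-root node (the branch above it)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def branch_duration(self, child: int) -> float:
        return float(self.ages[self.parent[child]] - self.ages[child])

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def tips_below(self, node: int) -> frozenset[int]:
        out, stack = set(), [node]
        while stack:
            x = stack.pop()
            if x < self.n_tips:
                out.add(x)
            stack.extend(self.children[x])
        return frozenset(out)

    def labels_below(self, node: int) -> frozenset[str]:
        return frozenset(self.labels[i] for i in self.tips_below(node))

    def mrca(self, labels) -> int:
        want = set(labels)
        unknown = want - set(self.labels)
        if unknown:
            raise ValueError(f"unknown tips: {sorted(unknown)}")
        for node in self.postorder():
            if want <= {self.labels[i] for i in self.tips_below(node)}:
                return node
        return self.root

    def copy(self) -> "ChronoTree":
        return ChronoTree(self.labels, self.parent.tolist(), self.ages.tolist())

    def with_ages(self, ages) -> "ChronoTree":
        return ChronoTree(self.labels, self.parent.tolist(), list(ages))

    # -- io -----------------------------------------------------------

    def newick(self, precision: int = 10) -> str:
        def sub(node: int) -> str:
            if node < self.n_tips:
                body = self.labels[node]
            else:
                body = "(" + ",".join(sub(c) for c in self.children[node]) + ")"
            if node == self.root:
                return body
            length = self.ages[self.parent[node]] - self.ages[node]
            return f"{body}:{length:.{precision}g}"

        return sub(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "ChronoTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        nodes = list(dt.preorder_node_iter())
        depth = {dt.seed_node: 0.0}
        for nd in nodes[1:]:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        max_depth = max(depth[lf] for lf in dt.leaf_node_iter())
        leaves = [lf for lf in dt.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        ids = {lf: i for i, lf in enumerate(leaves)}
        nxt = len(labels)
        for nd in nodes:
            if nd not in ids:
                ids[nd] = nxt
                nxt += 1
        parent = [-1] * len(nodes)
        ages = [0.0] * len(nodes)
        for nd in nodes:
            i = ids[nd]
            parent[i] = ids[nd.parent_node] if nd.parent_node else -1
            ages[i] = max_depth - depth[nd]
            if nd.is_leaf():
                ages[i] = 0.0
        return cls(labels, parent, ages)

    def to_unrooted(self, branch_scale=None) -> "object":
        """Unrooted copy with branch lengths = durations, optionally scaled
        by ``branch_scale`` (a scalar rate, or a per-branch mapping keyed by
        child node id, e.g. clock rate times UGAM multipliers)."""
        from .treespace import UnrootedTree

        def blen(child: int) -> float:
            d = self.branch_duration(child)
            if branch_scale is not None:
                if np.isscalar(branch_scale):
                    d *= branch_scale
                else:
                    d *= branch_scale[child]
            return d

        def sub(node: int) -> str:
            if node < self.n_tips:
                return f"{self.labels[node]}:{blen(node):.12g}"
            inner = ",".join(sub(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{blen(node):.12g}"

        return UnrootedTree.from_newick(sub(self.root) + ";", labels=self.labels)
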