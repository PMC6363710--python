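"""Unrooted binary trees for topology MCMC.

Tips are node ids ``0..n-1`` (carrying labels), internal nodes
``n..2n-3`` with degree 3.  Branch lengths live on unordered node pairs.
The representation supports the moves the samplers need (NNI, SPR with
branch-length split), split extraction for constraint checking and
consensus building, and Newick round-trips via dendropy.
"""

from __future__ import annotations


import dendropy
import numpy as np


class UnrootedTree:
    def __init__(self, labels: list[str]):
        if len(labels) < 2:
            raise ValueError("need at least 2 tips")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        self.labels = list(labels)
        self.n_tips = len(labels)
        self.nbrs: list[dict[int, float]] = []

    # -- construction -------------------------------------------------

    @classmethod
    def star3(cls, labels: list[str], brlens=1.0) -> "UnrootedTree":
        t = cls(labels[:3])
        t.nbrs = [dict() for _ in range(4)]
        for tip in range(3):
            t._connect(tip, 3, brlens if np.isscalar(brlens) else brlens[tip])
        return t

    @classmethod
    def random(
        cls,
        labels: list[str],
        rng: np.random.Generator,
        mean_brlen: float = 0.1,
    ) -> "UnrootedTree":
        """Random topology by sequential addition, Exp(mean) branch lengths."""
        n = len(labels)
        if n == 2:
            t = cls(labels)
            t.nbrs = [dict(), dict()]
            t._connect(0, 1, rng.exponential(mean_brlen))
            return t
        t = cls.star3(labels, rng.exponential(mean_brlen, size=3))
        full = cls(labels)
        full.nbrs = [dict() for _ in range(2 * n - 2)]
        # copy the 3-tip star into the full-size container
        for tip in range(3):
            full._connect(tip, n, t.nbrs[tip][3])
        next_internal = n + 1
        for tip in range(3, n):
            edges = full.edge_list()
            u, v = edges[rng.integers(len(edges))]
            length = full.nbrs[u][v]
            r = rng.uniform()
            full._disconnect(u, v)
            mid = next_internal
            next_internal += 1
            full._connect(u, mid, r * length)
            full._connect(mid, v, (1 - r) * length)
            full._connect(tip, mid, rng.exponential(mean_brlen))
        return full

    @classmethod
    def constrained_random(
        cls,
        labels: list[str],
        clauses: list[frozenset[str]],
        rng: np.random.Generator,
        mean_brlen: float = 0.1,
    ) -> "UnrootedTree":
        """Random topology in which every clause tip set is monophyletic.

        Clauses must be laminar (pairwise nested or disjoint); violations
        raise ValueError naming the conflicting pair.
        """
        label_set = set(labels)
        for c in clauses:
            missing = c - label_set
            if missing:
                raise ValueError(f"clause references unknown tips {sorted(missing)}")
        for i, a in enumerate(clauses):
            for b in clauses[i + 1 :]:
                if a & b and not (a <= b or b <= a):
                    raise ValueError(
                        f"incompatible constraint clauses {sorted(a)} vs {sorted(b)}"
                    )

        def build(tip_set: frozenset[str]) -> str:
            inner = [c for c in clauses if c < tip_set]
            maximal = [
                c for c in inner if not any(c < d for d in inner if d is not c)
            ]
            covered = set().union(*maximal) if maximal else set()
            units = [build(c) for c in maximal] + [
                t for t in sorted(tip_set) if t not in covered
            ]
            rng.shuffle(units)
            while len(units) > 1:  # random sequential pairing
                i, j = sorted(rng.choice(len(units), size=2, replace=False))
                merged = f"({units[i]},{units[j]})"
                units = [u for k, u in enumerate(units) if k not in (i, j)]
                units.append(merged)
            return units[0]

        newick = build(frozenset(labels)) + ";"
        tree = cls.from_newick(newick, labels=labels)
        for u in range(len(tree.nbrs)):
            for v in list(tree.nbrs[u]):
                if u < v:
                    length = rng.exponential(mean_brlen)
                    tree.nbrs[u][v] = length
                    tree.nbrs[v][u] = length
        return tree

    @classmethod
    def from_newick(cls, newick: str, labels: list[str] | None = None) -> "UnrootedTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        dt.is_rooted = False
        dt.update_bipartitions(suppress_unifurcations=True)
        tip_labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if labels is None:
            labels = sorted(tip_labels)
        if set(labels) != set(tip_labels):
            raise ValueError("newick tips do not match expected labels")
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        t = cls(labels)
        t.nbrs = [dict() for _ in range(2 * n - 2)]
        next_internal = [n]
        node_id: dict = {}

        def assign(node):
            if node.is_leaf():
                node_id[node] = index[node.taxon.label]
            else:
                node_id[node] = next_internal[0]
                next_internal[0] += 1
            for ch in node.child_nodes():
                assign(ch)

        def wire(node):
            for ch in node.child_nodes():
                t._connect(
                    node_id[node],
                    node_id[ch],
                    ch.edge.length if ch.edge.length is not None else 1.0,
                )
                wire(ch)

        seed = dt.seed_node
        children = seed.child_nodes()
        if n == 2:
            t._connect(0, 1, merged := sum(
                c.edge.length if c.edge.length is not None else 1.0
                for c in children
            ))
            return t
        if len(children) == 2 and n > 2:
            # suppress a degree-2 seed node by merging its two incident edges
            keep = children[0] if not children[0].is_leaf() else children[1]
            other = children[1] if keep is children[0] else children[0]
            merged_len = sum(
                e.edge.length if e.edge.length is not None else 1.0
                for e in (keep, other)
            )
            assign(keep)
            assign(other)
            wire(keep)
            wire(other)
            t._connect(node_id[keep], node_id[other], merged_len)
        else:
            assign(seed)
            wire(seed)
        if any(len(d) not in (1, 3) for d in t.nbrs if d) or any(
            not d for d in t.nbrs
        ):
            raise ValueError("tree is not an unrooted binary tree")
        return t

    # -- basic ops ----------------------------------------------------

    def _connect(self, u: int, v: int, length: float) -> None:
        self.nbrs[u][v] = length
        self.nbrs[v][u] = length

    def _disconnect(self, u: int, v: int) -> None:
        del self.nbrs[u][v]
        del self.nbrs[v][u]

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree(self.labels)
        t.nbrs = [dict(d) for d in self.nbrs]
        return t

    def edge_list(self) -> list[tuple[int, int]]:
        return [(u, v) for u in range(len(self.nbrs)) for v in self.nbrs[u] if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for (u, v) in self.edge_list()
            if u >= self.n_tips and v >= self.n_tips
        ]

    def branch_lengths(self) -> np.ndarray:
        return np.array([self.nbrs[u][v] for u, v in self.edge_list()])

    def set_length(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValueError("negative branch length")
        self.nbrs[u][v] = length
        self.nbrs[v][u] = length

    def total_length(self) -> float:
        return float(sum(self.nbrs[u][v] for u, v in self.edge_list()))

    # -- traversal ----------------------------------------------------

    def postorder(self, root: int | None = None):
        """(node, parent, brlen) postorder triples from a virtual root.

        Default root: the internal node adjacent to tip 0 (tip 0 itself
        for a 2-taxon tree).
        """
        if root is None:
            root = next(iter(self.nbrs[0])) if self.n_tips > 2 else 0
        order = []
        stack = [(root, -1, 0.0, False)]
        while stack:
            node, parent, length, done = stack.pop()
            if done:
                order.append((node, parent, length))
                continue
            stack.append((node, parent, length, True))
            for nb, ln in self.nbrs[node].items():
                if nb != parent:
                    stack.append((nb, node, ln, False))
        return order, root

    def side_tips(self, u: int, v: int) -> frozenset[int]:
        """Tip ids on the v side of edge (u, v)."""
        seen = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node < self.n_tips:
                seen.add(node)
            for nb in self.nbrs[node]:
                if nb != parent:
                    stack.append((nb, node))
        return frozenset(seen)

    def splits(self) -> dict[frozenset[int], tuple[int, int]]:
        """Nontrivial splits, keyed by the side not containing tip 0."""
        order, _root = self.postorder()
        below: dict[int, frozenset[int]] = {}
        out: dict[frozenset[int], tuple[int, int]] = {}
        for node, parent, _length in order:
            tips = frozenset([node]) if node < self.n_tips else frozenset()
            for nb in self.nbrs[node]:
                if nb != parent and nb in below:
                    tips |= below[nb]
            below[node] = tips
            if parent >= 0 and 1 < len(tips) < self.n_tips - 1:
                out[tips] = (parent, node)
        return out

    def label_splits(self) -> set[frozenset[str]]:
        return {
            frozenset(self.labels[i] for i in s) for s in self.splits()
        }

    def satisfies(self, clauses: list[frozenset[str]]) -> bool:
        """Each clause tip set must be one side of some branch (monophyly)."""
        all_tips = frozenset(self.labels)
        splits = None
        for clause in clauses:
            if len(clause) <= 1 or clause == all_tips:
                continue
            if len(clause) == self.n_tips - 1:
                continue  # trivially a split around the excluded tip's branch
            if splits is None:
                splits = self.label_splits()
                splits = splits | {all_tips - s for s in splits}
            if frozenset(clause) not in splits:
                return False
        return True

    # -- moves (in place; callers copy first) -------------------------

    def nni(self, u: int, v: int, variant: int) -> None:
        """Swap one subtree across internal edge (u, v)."""
        others_u = [x for x in self.nbrs[u] if x != v]
        others_v = [x for x in self.nbrs[v] if x != u]
        b = others_u[1]
        c = others_v[variant % 2]
        lb, lc = self.nbrs[u][b], self.nbrs[v][c]
        self._disconnect(u, b)
        self._disconnect(v, c)
        self._connect(u, c, lc)
        self._connect(v, b, lb)

    def spr(self, prune_u: int, prune_v: int, target: tuple[int, int], r: float) -> float:
        """Prune subtree on the ``prune_v`` side of (prune_u, prune_v), then
        regraft into ``target`` edge at relative position ``r``.

        Returns the log-Hastings correction (branch-length split Jacobian).
        """
        u, v = prune_u, prune_v
        if u < self.n_tips:
            raise ValueError("prune attachment node must be internal")
        keep_len = self.nbrs[u][v]
        x, y = [w for w in self.nbrs[u] if w != v]
        lx, ly = self.nbrs[u][x], self.nbrs[u][y]
        a, b = target
        lab = self.nbrs[a][b]
        self._disconnect(u, v)
        self._disconnect(u, x)
        self._disconnect(u, y)
        self._connect(x, y, lx + ly)
        self._disconnect(a, b)
        self._connect(a, u, r * lab)
        self._connect(u, b, (1 - r) * lab)
        self._connect(u, v, keep_len)
        return float(np.log(lab) - np.log(lx + ly))

    # -- newick -------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        if self.n_tips == 2:
            ln = self.nbrs[0][1]
            return f"({self.labels[0]}:{ln:.{precision}g},{self.labels[1]}:0);"

        def sub(node: int, parent: int) -> str:
            length = self.nbrs[node][parent]
            if node < self.n_tips:
                return f"{self.labels[node]}:{length:.{precision}g}"
            kids = [sub(nb, node) for nb in sorted(self.nbrs[node]) if nb != parent]
            return f"({','.join(kids)}):{length:.{precision}g}"

        root = next(iter(self.nbrs[0]))
        kids = [sub(nb, root) for nb in sorted(self.nbrs[root])]
        return f"({','.join(kids)});"

    def topology_key(self) -> frozenset[frozenset[str]]:
        return frozenset(self.label_splits())
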