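"""Ortholog delimitation: similarity scores, neighbor joining against
brute-force oracles, contour grouping and true/uncertain calls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picoevo.alignment import Alignment
from picoevo.ortholog_contour import (
    BlastHit,
    NJTree,
    apply_pair_exclusion,
    build_nj_tree,
    classify_orthologs,
    draw_contours,
    identical_fraction,
    pairwise_distance,
)
from picoevo.treespace import UnrootedTree


class TestIdenticalFraction:
    @pytest.mark.parametrize(
        "pct,aln_len,qlen,expected",
        [(100.0, 100, 100, 1.0), (50.0, 50, 100, 0.25), (95.0, 120, 100, 1.14)],
    )
    def test_formula(self, pct, aln_len, qlen, expected):
        hit = BlastHit("q", "s", pct, aln_len, 1e-20)
        assert identical_fraction(hit, qlen) == pytest.approx(expected)

    def test_zero_query_length_rejected(self):
        with pytest.raises(ValueError):
            identical_fraction(BlastHit("q", "s", 50.0, 10, 0.0), 0)


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        aln = Alignment({"a": "ACGT", "b": "ACGT"})
        assert pairwise_distance(aln).loc["a", "b"] == 0.0

    def test_single_mismatch(self):
        aln = Alignment({"a": "AAAA", "b": "AAAT"})
        assert pairwise_distance(aln).loc["a", "b"] == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        aln = Alignment({"a": "AC-GT", "b": "AT--T"})
        # shared ungapped columns: 0, 1, 4; one mismatch at column 1
        assert pairwise_distance(aln).loc["a", "b"] == pytest.approx(1 / 3)

    def test_no_shared_columns_rejected_with_ids(self):
        aln = Alignment({"x": "A--", "y": "-CC", "z": "ACC"})
        with pytest.raises(ValueError, match="x.*y"):
            pairwise_distance(aln)


def tree_distances(tree: UnrootedTree) -> pd.DataFrame:
    """Path-length matrix of a tree (test helper for additivity checks)."""
    import networkx as nx

    g = nx.Graph()
    for u, v in tree.edge_list():
        g.add_edge(u, v, weight=tree.nbrs[u][v])
    n = tree.n_tips
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = nx.shortest_path_length(g, i, j, weight="weight")
    return pd.DataFrame(D, index=tree.labels, columns=tree.labels)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        nj = build_nj_tree(D)
        t = nj.tree
        hub = next(iter(t.nbrs[t.labels.index("A")]))
        lengths = {lab: t.nbrs[t.labels.index(lab)][hub] for lab in "ABC"}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa, rng):
        labels = [f"t{i}" for i in range(n_taxa)]
        truth = UnrootedTree.random(labels, rng, mean_brlen=1.0)
        D = tree_distances(truth)
        nj = build_nj_tree(D)
        assert nj.tree.label_splits() == truth.label_splits()
        back = tree_distances(nj.tree).loc[labels, labels]
        assert np.allclose(back.values, D.loc[labels, labels].values, atol=1e-9)

    def test_least_squares_oracle_on_four_taxa(self, rng):
        """NJ's topology matches the brute-force least-squares fit over
        all three unrooted four-taxon topologies."""
        labels = list("abcd")
        truth = UnrootedTree.random(labels, rng, mean_brlen=1.0)
        D = tree_distances(truth)
        nj_splits = build_nj_tree(D).tree.label_splits()

        # brute force: every 4-taxon topology is defined by its single split
        best, best_rss = None, np.inf
        for pair in combinations(labels, 2):
            split = frozenset(pair)
            # design matrix for the 5 branch lengths of ((a,b),(c,d))
            grouped = [list(pair), [l for l in labels if l not in pair]]
            order = grouped[0] + grouped[1]
            rows, y = [], []
            for i, j in combinations(range(4), 2):
                row = [0.0] * 5
                row[i] = 1.0
                row[j] = 1.0
                same_side = (i < 2) == (j < 2)
                if not same_side:
                    row[4] = 1.0
                rows.append(row)
                y.append(D.loc[order[i], order[j]])
            sol, rss, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
            resid = np.array(rows) @ sol - np.array(y)
            rss = float(resid @ resid)
            if rss < best_rss:
                best_rss, best = rss, split
        expected = {best, frozenset(labels) - best}
        assert nj_splits and next(iter(nj_splits)) in expected

    def test_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = [f"t{i}" for i in range(6)]
        truth = UnrootedTree.random(labels, rng, mean_brlen=1.0)
        D = tree_distances(truth)
        ours = build_nj_tree(D).tree.label_splits()
        sk_tree = skbio_nj(DistanceMatrix(D.values, ids=labels))
        sk_splits = set()
        for node in sk_tree.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels) - 1:
                sk_splits.add(tips)
        norm = lambda ss: {min(s, frozenset(labels) - s, key=sorted) for s in ss}
        assert norm(ours) == norm(sk_splits)

    def test_equal_distances_deterministic(self):
        labels = list("abcd")
        D = pd.DataFrame(
            np.ones((4, 4)) - np.eye(4), index=labels, columns=labels
        )
        a = build_nj_tree(D).tree.to_newick()
        b = build_nj_tree(D).tree.to_newick()
        assert a == b

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame(
            [[0, np.nan], [np.nan, 0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError):
            build_nj_tree(bad)


def scored_tree(newick, scores):
    t = UnrootedTree.from_newick(newick, labels=sorted(scores))
    return NJTree(tree=t, scores=scores)


class TestContours:
    def test_uniform_scores_single_group(self):
        nj = scored_tree(
            "((q:1,a:1):1,(b:1,c:1):1);", {"q": 1.0, "a": 1.0, "b": 1.0, "c": 1.0}
        )
        cs = draw_contours(nj, [0.9, 0.5])
        for level in (0.9, 0.5):
            assert cs.groups[level] == [frozenset("abcq")]

    def test_direct_rule_on_three_tips(self):
        nj = scored_tree("(q:1,a:1,b:1);", {"q": 1.0, "a": 0.8, "b": 0.2})
        cs = draw_contours(nj, [0.5])
        assert frozenset({"q", "a"}) in cs.groups[0.5]
        assert all("b" not in g for g in cs.groups[0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nesting_across_levels(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(6)]
        tree = UnrootedTree.random(labels, rng)
        scores = {lab: float(rng.uniform(0, 1)) for lab in labels}
        nj = NJTree(tree=tree, scores=scores)
        cs = draw_contours(nj, [0.8, 0.4])
        for hi_group in cs.groups[0.8]:
            assert any(hi_group <= lo for lo in cs.groups[0.4])
        # laminarity within each level
        for level in (0.8, 0.4):
            for g1, g2 in combinations(cs.groups[level], 2):
                assert not (g1 & g2)

    def test_unscored_tip_rejected(self):
        t = UnrootedTree.from_newick("(q:1,a:1,b:1);", labels=["a", "b", "q"])
        with pytest.raises(ValueError):
            draw_contours(NJTree(tree=t, scores={"q": 1.0}), [0.5])


class TestClassifyOrthologs:
    def bimodal_fixture(self):
        newick = "(((q:1,a:1):1,b:1):1,(x:1,y:1):1);"
        scores = {"q": 1.0, "a": 0.9, "b": 0.8, "x": 0.3, "y": 0.2}
        return scored_tree(newick, scores)

    def test_clean_bimodal_split(self):
        nj = self.bimodal_fixture()
        cs = draw_contours(nj, [0.8, 0.5, 0.2])
        calls = classify_orthologs(nj, cs, "q", gap_min=0.2)
        assert {s for s, c in calls.items() if c.verdict == "true_ortholog"} == {
            "q", "a", "b",
        }
        assert {s for s, c in calls.items() if c.verdict == "non_ortholog"} == {
            "x", "y",
        }

    def test_boundary_tip_uncertain(self):
        newick = "((((q:1,a:1):1,b:1):1,m:1):1,(x:1,y:1):1);"
        scores = {"q": 1.0, "a": 0.9, "b": 0.85, "m": 0.55, "x": 0.25, "y": 0.2}
        nj = scored_tree(newick, scores)
        cs = draw_contours(nj, [0.8, 0.5, 0.2])
        calls = classify_orthologs(nj, cs, "q", monophyly_tolerance=0.25, gap_min=0.3)
        assert calls["m"].verdict == "uncertain"
        assert calls["a"].verdict == "true_ortholog"
        assert calls["x"].verdict == "non_ortholog"

    def test_query_alone(self):
        nj = scored_tree("(q:1,a:1,b:1);", {"q": 1.0, "a": 0.1, "b": 0.05})
        cs = draw_contours(nj, [0.9, 0.5])
        calls = classify_orthologs(nj, cs, "q", gap_min=0.2)
        assert calls["q"].verdict == "true_ortholog"
        assert calls["a"].verdict == "non_ortholog"

    def test_no_gap_all_uncertain(self):
        nj = scored_tree(
            "((q:1,a:1):1,(b:1,c:1):1);",
            {"q": 1.0, "a": 0.62, "b": 0.60, "c": 0.58},
        )
        cs = draw_contours(nj, [0.9, 0.6])
        calls = classify_orthologs(nj, cs, "q", gap_min=0.5)
        non_query = {s: c for s, c in calls.items() if s != "q"}
        assert all(c.verdict == "uncertain" for c in non_query.values())
        assert all(c.evidence.get("no_well_defined_contour") for c in non_query.values())

    def test_order_invariance(self, rng):
        labels = [f"g{i}" for i in range(7)]
        tree = UnrootedTree.random(labels, rng)
        scores = {lab: float(rng.uniform(0, 1)) for lab in labels}
        scores[labels[0]] = 1.0
        nj = NJTree(tree=tree, scores=scores)
        cs = draw_contours(nj)
        base = {
            s: c.verdict for s, c in classify_orthologs(nj, cs, labels[0]).items()
        }
        shuffled = NJTree(
            tree=tree, scores={k: scores[k] for k in reversed(list(scores))}
        )
        cs2 = draw_contours(shuffled)
        again = {
            s: c.verdict
            for s, c in classify_orthologs(shuffled, cs2, labels[0]).items()
        }
        assert base == again


class TestPairExclusion:
    def make_calls(self, verdicts):
        from picoevo.ortholog_contour import OrthologCall

        return {s: OrthologCall(s, v) for s, v in verdicts.items()}

    def test_uncertain_alpha_drops_beta(self):
        alpha = self.make_calls({"G_a": "uncertain", "H_a": "true_ortholog"})
        beta = self.make_calls({"G_b": "true_ortholog", "H_b": "true_ortholog"})
        gmap = {"G_a": "G", "G_b": "G", "H_a": "H", "H_b": "H"}
        fa, fb, excluded = apply_pair_exclusion(alpha, beta, gmap)
        assert excluded == {"G"}
        assert set(fa) == {"H_a"} and set(fb) == {"H_b"}

    def test_symmetric_default_and_asymmetric_option(self):
        alpha = self.make_calls({"K_a": "true_ortholog"})
        beta = self.make_calls({"K_b": "uncertain"})
        gmap = {"K_a": "K", "K_b": "K"}
        fa, fb, excluded = apply_pair_exclusion(alpha, beta, gmap)
        assert excluded == {"K"} and not fa and not fb
        fa2, fb2, excluded2 = apply_pair_exclusion(alpha, beta, gmap, symmetric=False)
        assert excluded2 == set() and set(fa2) == {"K_a"} and not fb2

    def test_uncovered_subject_rejected(self):
        alpha = self.make_calls({"G_a": "true_ortholog"})
        with pytest.raises(ValueError):
            apply_pair_exclusion(alpha, {}, {})
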