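"""Likelihood engine vs enumeration oracles, sampler contracts, split
diagnostics, consensus construction and rooting."""

from itertools import product

import numpy as np
import pytest

from picoevo.alignment import AA_ALPHABET, Alignment, concatenate
from picoevo.models import empirical_aa, gtr, jc_like
from picoevo.phylo_engine import (
    PosteriorSample,
    Priors,
    asdsf,
    consensus_tree,
    log_likelihood,
    mcmc_sample,
    root_on_split,
)
from picoevo.treespace import UnrootedTree


def brute_force_loglik(aln: Alignment, tree: UnrootedTree, model) -> float:
    """Sum over all internal-state assignments (oracle for pruning)."""
    enc = aln.encode(taxa_order=tree.labels)
    K = model.K
    rates = model.category_rates()
    order, root = tree.postorder()
    internals = sorted({n for n, _, _ in order if n >= tree.n_tips})
    total = 0.0
    for site in range(aln.n_sites):
        cat_likes = []
        for r in rates:
            site_like = 0.0
            for assign in product(range(K), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                prob = model.frequencies[amap[root]]
                for node, parent, _l in order:
                    if parent == -1:
                        continue
                    P = model.transition_matrix(tree.nbrs[node][parent] * r)
                    sp = amap[parent]
                    if node >= tree.n_tips:
                        prob *= P[sp, amap[node]]
                    else:
                        obs = enc[node, site]
                        prob *= 1.0 if obs < 0 else P[sp, obs]
                site_like += prob
            cat_likes.append(site_like)
        var = float(np.mean(cat_likes))
        seen = enc[:, site][enc[:, site] >= 0]
        if seen.size == 0:
            inv = 1.0
        elif np.all(seen == seen[0]):
            inv = float(model.frequencies[seen[0]])
        else:
            inv = 0.0
        total += np.log((1 - model.p_inv) * var + model.p_inv * inv)
    return total


class TestLogLikelihood:
    def test_single_identical_site_t0_closed_form(self):
        t = UnrootedTree(["a", "b"])
        t.nbrs = [{1: 0.0}, {0: 0.0}]
        aln = Alignment({"a": "A", "b": "A"}, AA_ALPHABET)
        ll = log_likelihood(aln, t, jc_like(AA_ALPHABET))
        assert ll == pytest.approx(np.log(1 / 20))

    @pytest.mark.parametrize("t", [0.1, 1.0])
    def test_identical_column_transition_closed_form(self, t):
        tree = UnrootedTree(["a", "b"])
        tree.nbrs = [{1: t}, {0: t}]
        aln = Alignment({"a": "A", "b": "A"}, AA_ALPHABET)
        ll = log_likelihood(aln, tree, jc_like(AA_ALPHABET))
        expect = (1 / 20) * (1 / 20 + (19 / 20) * np.exp(-20 * t / 19))
        assert ll == pytest.approx(np.log(expect), abs=1e-12)

    @pytest.mark.parametrize(
        "model",
        [
            jc_like("ACGT"),
            jc_like("ACGT", alpha=0.6, p_inv=0.25),
            gtr(
                [[0, 1, 2, 1], [1, 0, 1, 3], [2, 1, 0, 1], [1, 3, 1, 0]],
                [0.35, 0.25, 0.2, 0.2],
                alpha=1.2,
            ),
        ],
        ids=["poisson", "poisson+I+G", "gtr+G"],
    )
    def test_matches_enumeration_oracle(self, model, rng):
        tree = UnrootedTree.random(list("abcd"), rng)
        aln = Alignment(
            {"a": "ACGTA", "b": "ACGTC", "c": "AAGTA", "d": "TCG-A"}, "ACGT"
        )
        fast = log_likelihood(aln, tree, model)
        slow = brute_force_loglik(aln, tree, model)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_empirical_matrix_oracle_five_taxa(self, rng):
        model = empirical_aa("LG", alpha=0.9)
        tree = UnrootedTree.random(list("abcde"), rng, mean_brlen=0.3)
        seqs = {"a": "AR", "b": "AK", "c": "RR", "d": "A-", "e": "AR"}
        aln = Alignment(seqs, AA_ALPHABET)
        fast = log_likelihood(aln, tree, model)
        slow = brute_force_loglik(aln, tree, model)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_taxon_mismatch_rejected(self, rng):
        tree = UnrootedTree.random(list("abc"), rng)
        aln = Alignment({"a": "A", "b": "A", "z": "A"}, "ACGT")
        with pytest.raises(ValueError):
            log_likelihood(aln, tree, jc_like("ACGT"))


class TestMcmc:
    def test_prior_only_branch_length_moments(self):
        aln = Alignment({t: "A" for t in "abcd"}, "ACGT")
        runs = mcmc_sample(
            aln,
            priors=Priors(brlen_mean=0.1),
            n_gens=20_000,
            n_runs=1,
            thin=10,
            seed=3,
            likelihood_power=0.0,
            sample_alpha=False,
            sample_pinv=False,
        )
        lens = np.concatenate([s.tree.branch_lengths() for s in runs[0]])
        # generous 3-sigma bands using a conservative effective sample size
        ess = 300
        assert abs(lens.mean() - 0.1) < 3 * 0.1 / np.sqrt(ess)
        assert abs(lens.var() - 0.01) < 3 * 0.03 / np.sqrt(ess)

    def test_constraint_always_satisfied(self):
        rng = np.random.default_rng(0)
        labels = list("abcdef")
        seqs = {
            lab: "".join(rng.choice(list("ACGT"), size=60)) for lab in labels
        }
        aln = Alignment(seqs, "ACGT")
        clause = frozenset({"a", "b"})
        runs = mcmc_sample(
            aln,
            constraints=[clause],
            n_gens=3000,
            n_runs=1,
            thin=10,
            seed=5,
            sample_alpha=False,
            sample_pinv=False,
        )
        for s in runs[0]:
            assert s.tree.satisfies([clause])

    def test_unsatisfiable_constraints_rejected_before_sampling(self):
        aln = Alignment({t: "ACGT" for t in "abcd"}, "ACGT")
        with pytest.raises(ValueError):
            mcmc_sample(
                aln,
                constraints=[frozenset("ab"), frozenset("bc")],
                n_gens=100,
                n_runs=1,
                seed=1,
            )

    def test_same_seed_identical_chains(self):
        aln = Alignment(
            {"a": "ACGTACGT", "b": "ACGTACGA", "c": "ACCTACGT", "d": "TCGTACGT"},
            "ACGT",
        )
        r1 = mcmc_sample(aln, n_gens=500, n_runs=1, thin=10, seed=9,
                         sample_alpha=False, sample_pinv=False)
        r2 = mcmc_sample(aln, n_gens=500, n_runs=1, thin=10, seed=9,
                         sample_alpha=False, sample_pinv=False)
        assert [s.log_likelihood for s in r1[0]] == [
            s.log_likelihood for s in r2[0]
        ]
        assert [s.tree.to_newick() for s in r1[0]] == [
            s.tree.to_newick() for s in r2[0]
        ]


def samples_from_newicks(newicks):
    out = []
    labels = sorted(
        UnrootedTree.from_newick(newicks[0]).labels
    )
    for i, nwk in enumerate(newicks):
        tree = UnrootedTree.from_newick(nwk, labels=labels)
        out.append(
            PosteriorSample(iteration=i, tree=tree, log_likelihood=0.0, log_prior=0.0)
        )
    return out


T1 = "((a:1,b:1):1,(c:1,d:1):1,e:1);"
T2 = "((a:1,c:1):1,(b:1,d:1):1,e:1);"


class TestAsdsf:
    def test_identical_runs_zero(self):
        runs = [samples_from_newicks([T1] * 10), samples_from_newicks([T1] * 10)]
        assert asdsf(runs) == 0.0

    def test_full_disagreement(self):
        runs = [samples_from_newicks([T1] * 10), samples_from_newicks([T2] * 10)]
        # four splits each at frequencies (1, 0): sd = 0.7071 each
        assert asdsf(runs) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_hand_computed_partial_disagreement(self):
        runs = [
            samples_from_newicks([T1] * 8 + [T2] * 2),
            samples_from_newicks([T1] * 6 + [T2] * 4),
        ]
        # every qualifying split has frequencies {0.8, 0.6} or {0.2, 0.4}
        assert asdsf(runs) == pytest.approx(0.1414, abs=1e-3)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            asdsf([samples_from_newicks([T1])])


class TestConsensus:
    def test_identical_samples_fully_resolved(self):
        samples = samples_from_newicks([T1] * 20)
        cons = consensus_tree(samples, collapse_pp=0.75)
        assert all(pp == 1.0 for pp in cons.split_pp.values())
        assert len([s for s in cons.split_pp if 1 < len(s) < 4]) >= 2

    @pytest.mark.parametrize("k,retained", [(74, False), (76, True)])
    def test_collapse_threshold_boundary(self, k, retained):
        samples = samples_from_newicks([T1] * k + [T2] * (100 - k))
        cons = consensus_tree(samples, collapse_pp=0.75)
        ab = frozenset({"a", "b"})
        full = frozenset("abcde")
        clades = set()
        for nd in cons.tree.preorder_node_iter():
            tips = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if 1 < len(tips) < len(full):
                clades.add(tips)
                clades.add(full - tips)
        # the (a,b) split survives in the consensus iff its PP >= 0.75
        assert (ab in clades) == retained

    def test_pp_equal_split_counting_oracle(self):
        rng = np.random.default_rng(7)
        labels = list("abcdef")
        newicks = []
        trees = []
        for _ in range(200):
            t = UnrootedTree.random(labels, rng)
            trees.append(t)
            newicks.append(t.to_newick())
        samples = samples_from_newicks(newicks)
        cons = consensus_tree(samples, collapse_pp=0.5)
        # brute-force counting
        full = frozenset(labels)
        counts = {}
        for t in trees:
            for s in t.label_splits():
                key = min(s, full - s, key=sorted)
                counts[key] = counts.get(key, 0) + 1
        for split, pp in cons.split_pp.items():
            key = min(split, full - split, key=sorted)
            assert pp == pytest.approx(counts.get(key, 0) / 200)


class TestRootOnSplit:
    def test_four_tip_cherry_root(self):
        tree = UnrootedTree.from_newick(
            "((a1:1,a2:1):1,(b1:1,b2:1):1);", labels=["a1", "a2", "b1", "b2"]
        )
        rooted = root_on_split(tree, {"a1", "a2"}, {"b1", "b2"})
        kids = rooted.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in k.leaf_iter()} for k in kids
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }

    def test_subunit_fixture_root_separates_families(self):
        newick = "(((cpeA_x:1,mpeA_x:1):1,cpeA_y:1):2,((cpeB_x:1,mpeB_x:1):1,cpeB_y:1):2);"
        labels = ["cpeA_x", "mpeA_x", "cpeA_y", "cpeB_x", "mpeB_x", "cpeB_y"]
        tree = UnrootedTree.from_newick(newick, labels=labels)
        alpha = {t for t in labels if "A_" in t}
        beta = set(labels) - alpha
        rooted = root_on_split(tree, alpha, beta)
        sides = [
            frozenset(lf.taxon.label for lf in k.leaf_iter())
            for k in rooted.seed_node.child_nodes()
        ]
        assert frozenset(alpha) in sides and frozenset(beta) in sides

    def test_missing_split_errors_and_leaves_tree_unchanged(self):
        tree = UnrootedTree.from_newick(
            "((a:1,b:1):1,(c:1,d:1):1);", labels=list("abcd")
        )
        before = tree.to_newick()
        with pytest.raises(ValueError, match="nearest"):
            root_on_split(tree, {"a", "c"}, {"b", "d"})
        assert tree.to_newick() == before


class TestConcatenate:
    def test_total_length_and_partition_map(self):
        a = Alignment({"x": "ACGT", "y": "ACGA"})
        b = Alignment({"x": "GG", "y": "GC"})
        cat = concatenate({"p1": a, "p2": b})
        assert cat.alignment.n_sites == 6
        assert [p.name for p in cat.partitions] == ["p1", "p2"]

    def test_missing_taxon_padded_with_gaps(self):
        a = Alignment({"x": "ACGT", "y": "ACGA"})
        b = Alignment({"x": "GG"})
        cat = concatenate({"p1": a, "p2": b})
        assert cat.alignment.sequences["y"][4:] == "--"

    def test_many_partition_shape_identity(self, rng):
        names = {}
        total = 0
        for i in range(30):
            n = int(rng.integers(3, 12))
            total += n
            names[f"g{i}"] = Alignment(
                {"x": "A" * n, "y": "C" * n}
            )
        cat = concatenate(names)
        assert cat.alignment.n_sites == total
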