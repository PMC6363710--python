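"""Desk-scale Bayesian phylogenetics: pruning likelihood, topology MCMC,
convergence diagnostics, consensus trees and rooting.

The likelihood is the standard postorder (pruning) recursion under a
reversible substitution model with invariant sites and discrete-gamma
rate variation, summed over partitions whose branch lengths are scaled
by per-partition rate multipliers.  The sampler is plain
Metropolis-Hastings over topology (NNI and SPR), branch lengths and
model parameters; monophyly constraints are enforced by rejecting any
proposal whose topology violates a clause.  Topology convergence is
summarised by the average standard deviation of split frequencies
(ASDSF) across independent runs, and posterior topologies by a
majority-rule-extended consensus in which splits below a posterior
probability threshold are collapsed into polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import (
    Alignment,
    PartitionedAlignment,
    compress_patterns,
    concatenate,  # noqa: F401  (re-exported: partition plumbing lives here)
    single_partition,
)
from .models import AA_MODEL_NAMES, SubstitutionModel, empirical_aa
from .treespace import UnrootedTree

__all__ = [
    "Priors",
    "PosteriorSample",
    "ConsensusTree",
    "log_likelihood",
    "mcmc_sample",
    "asdsf",
    "consensus_tree",
    "root_on_split",
    "concatenate",
]


# ---------------------------------------------------------------------------
# likelihood


class LikelihoodEngine:
    """Pattern-compressed likelihood with cached tip indicators.

    Encoding, pattern compression and the invariant-site bookkeeping are
    done once per alignment; repeated evaluations (as in MCMC) only pay
    for the pruning recursion itself.
    """

    def __init__(self, aln: PartitionedAlignment, tip_order: list[str]):
        if set(aln.taxa) != set(tip_order):
            raise ValueError("alignment taxa do not match tree tips")
        self.parts = []
        for part in aln.partitions:
            sub = aln.partition_alignment(part.name)
            enc = sub.encode(taxa_order=tip_order)
            patterns, weights = compress_patterns(enc)
            K = len(part.alphabet)
            npat = patterns.shape[1]
            tip_ind = []
            for row in patterns:
                ind = np.ones((K, npat))
                mask = row >= 0
                if mask.any():
                    cols = np.zeros((K, mask.sum()))
                    cols[row[mask], np.arange(mask.sum())] = 1.0
                    ind[:, mask] = cols
                tip_ind.append(ind)
            # invariant-site component: state index of a constant column,
            # -2 for all-missing (likelihood 1), -1 for variable (0)
            inv_state = np.full(npat, -1, dtype=int)
            for p in range(npat):
                seen = patterns[:, p][patterns[:, p] >= 0]
                if seen.size == 0:
                    inv_state[p] = -2
                elif np.all(seen == seen[0]):
                    inv_state[p] = seen[0]
            self.parts.append(
                {
                    "name": part.name,
                    "patterns": patterns,
                    "weights": weights,
                    "tip_ind": tip_ind,
                    "inv_state": inv_state,
                }
            )

    def loglik(
        self,
        tree: UnrootedTree,
        models: dict[str, SubstitutionModel],
        multipliers: dict[str, float] | None = None,
    ) -> float:
        total = 0.0
        for part in self.parts:
            scale = (multipliers or {}).get(part["name"], 1.0)
            total += _pruned_loglik(tree, models[part["name"]], scale, part)
            if total == -np.inf:
                break
        return float(total)


def _pruned_loglik(tree: UnrootedTree, model: SubstitutionModel, scale, part) -> float:
    rates = model.category_rates()
    ncat = len(rates)
    K = model.K
    weights = part["weights"]
    npat = len(weights)
    if npat == 0:
        return 0.0
    tip_ind = part["tip_ind"]
    order, root = tree.postorder()
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(npat)
    single = ncat == 1

    # one batched eigen-exponential for every (branch, rate category)
    edge_ts = []
    edge_idx: dict[tuple[int, int], int] = {}
    for node, parent, _length in order:
        for child in tree.nbrs[node]:
            if child != parent and (node, child) not in edge_idx:
                edge_idx[(node, child)] = len(edge_ts)
                edge_ts.append(tree.nbrs[node][child] * scale)
    ts = np.asarray(edge_ts)[:, None] * rates[None, :]
    P_all = model.transition_matrices(ts.ravel()).reshape(
        len(edge_ts), ncat, K, K
    )

    for node, parent, _length in order:
        children = [nb for nb in tree.nbrs[node] if nb != parent]
        if not children:
            partials[node] = tip_ind[node]  # (K, npat); shared across cats
            continue
        prod = None
        for child in children:
            cp = partials.pop(child)
            P_edge = P_all[edge_idx[(node, child)]]
            if single:
                contrib = P_edge[0] @ (cp if cp.ndim == 2 else cp[0])
                if prod is None:
                    prod = contrib
                else:
                    prod *= contrib
                continue
            if cp.ndim == 2:
                contrib = P_edge @ cp
            else:
                contrib = np.einsum("ckj,cjp->ckp", P_edge, cp)
            prod = contrib if prod is None else prod * contrib
        if single:
            if node < tree.n_tips:
                prod = prod * tip_ind[node]
            mx = prod.max(axis=0)
            if mx.min() < 1e-120:
                mx = np.where(mx > 0, mx, 1.0)
                prod /= mx[None, :]
                log_scale += np.log(mx)
            partials[node] = prod
            continue
        if node < tree.n_tips:  # 2-taxon tree rooted at a tip
            prod = prod * tip_ind[node][None, :, :]
        mx = prod.max(axis=(0, 1))
        if mx.min() < 1e-120:  # rescale only when drifting toward underflow
            mx = np.where(mx > 0, mx, 1.0)
            prod /= mx[None, None, :]
            log_scale += np.log(mx)
        partials[node] = prod
    root_part = partials[root]
    if root_part.ndim == 2:
        root_part = root_part[None, :, :]
    site = np.einsum("k,ckp->cp", model.frequencies, root_part).mean(axis=0)
    if model.p_inv > 0:
        inv_state = part["inv_state"]
        inv = np.where(
            inv_state == -2,
            1.0,
            np.where(inv_state >= 0, model.frequencies[np.clip(inv_state, 0, None)], 0.0),
        )
        site = (1 - model.p_inv) * site + model.p_inv * inv * np.exp(-log_scale)
    if np.any(site <= 0):
        return -np.inf
    return float(np.dot(weights, np.log(site) + log_scale))


def log_likelihood(
    aln: PartitionedAlignment | Alignment,
    tree: UnrootedTree,
    models: dict[str, SubstitutionModel] | SubstitutionModel,
) -> float:
    """Summed partition log likelihoods under +I+Gamma mixtures.

    Partition ``p``'s branch lengths are scaled by its rate multiplier.
    """
    if isinstance(aln, Alignment):
        aln = single_partition(aln)
    if isinstance(models, SubstitutionModel):
        models = {p.name: models for p in aln.partitions}
    engine = LikelihoodEngine(aln, tree.labels)
    return engine.loglik(tree, models, aln.rate_multipliers)


# ---------------------------------------------------------------------------
# priors and MCMC


@dataclass
class Priors:
    """Priors for the topology/branch-length/model sampler.

    branch lengths ~ Exp(mean ``brlen_mean``); gamma shape ~ Exp(1);
    p_inv ~ Uniform[0,1); frequencies ~ flat Dirichlet; partition rate
    multipliers ~ mean-1 Dirichlet-weighted; topology uniform over the
    (constrained) space; amino-acid model indicator uniform over
    {LG, WAG, JTT}.
    """

    brlen_mean: float = 0.1
    alpha_mean: float = 1.0

    def log_brlens(self, tree: UnrootedTree) -> float:
        lens = tree.branch_lengths()
        if np.any(lens < 0):
            return -np.inf
        return float(-np.log(self.brlen_mean) * lens.size - lens.sum() / self.brlen_mean)

    def log_alpha(self, alpha: float) -> float:
        if np.isinf(alpha):
            return 0.0
        if alpha <= 0:
            return -np.inf
        return float(-np.log(self.alpha_mean) - alpha / self.alpha_mean)


@dataclass
class PosteriorSample:
    iteration: int
    tree: UnrootedTree
    log_likelihood: float
    log_prior: float
    params: dict = field(default_factory=dict)

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior


@dataclass
class _McmcState:
    tree: UnrootedTree
    models: dict[str, SubstitutionModel]
    multipliers: dict[str, float]
    log_like: float
    log_prior: float


def _state_loglike(engine, state, power):
    if power == 0.0 or engine is None:
        return 0.0
    return engine.loglik(state.tree, state.models, state.multipliers)


def _state_logprior(priors: Priors, state: _McmcState) -> float:
    lp = priors.log_brlens(state.tree)
    for m in state.models.values():
        lp += priors.log_alpha(m.alpha)
        if not 0.0 <= m.p_inv < 1.0:
            return -np.inf
    return lp


def mcmc_sample(
    aln: PartitionedAlignment | Alignment,
    priors: Priors | None = None,
    constraints: list[frozenset[str]] | None = None,
    n_gens: int = 50_000,
    n_runs: int = 2,
    thin: int = 50,
    seed: int = 0,
    models: dict[str, SubstitutionModel] | SubstitutionModel | None = None,
    burn_in: float = 0.25,
    likelihood_power: float = 1.0,
    sample_topology: bool = True,
    sample_alpha: bool = None,
    sample_pinv: bool = None,
    sample_freqs: bool = False,
    sample_model_id: bool = False,
    start_tree: UnrootedTree | None = None,
    return_final_state: bool = False,
):
    """Metropolis-Hastings sampling of trees and model parameters.

    Returns a list of ``n_runs`` lists of :class:`PosteriorSample`
    (post-burn-in, thinned).  ``likelihood_power`` tempers the likelihood
    (0 = prior-only), which is what the stepping-stone estimator needs.
    Constraints are monophyly clauses on tip labels; unsatisfiable or
    incompatible clause sets are rejected before sampling starts.
    """
    if isinstance(aln, Alignment):
        aln = single_partition(aln)
    priors = priors or Priors()
    constraints = [frozenset(c) for c in (constraints or [])]
    taxa = aln.taxa
    rng_master = np.random.default_rng(seed)
    engine = LikelihoodEngine(aln, taxa)

    if models is None:
        models = {
            p.name: SubstitutionModel(alphabet=p.alphabet) for p in aln.partitions
        }
    elif isinstance(models, SubstitutionModel):
        models = {p.name: models.with_params() for p in aln.partitions}
    if sample_alpha is None:
        sample_alpha = any(np.isfinite(m.alpha) for m in models.values())
    if sample_pinv is None:
        sample_pinv = any(m.p_inv > 0 for m in models.values())

    runs_out = []
    final_states = []
    for run in range(n_runs):
        rng = np.random.default_rng(rng_master.integers(2**31))
        if start_tree is not None:
            if start_tree.labels == taxa:
                tree = start_tree.copy()
            else:
                # reindex the start tree's tips to this alignment's order
                tree = UnrootedTree.from_newick(start_tree.to_newick(), labels=taxa)
        elif constraints:
            tree = UnrootedTree.constrained_random(
                taxa, constraints, rng, priors.brlen_mean
            )
        else:
            tree = UnrootedTree.random(taxa, rng, priors.brlen_mean)
        if not tree.satisfies(constraints):
            raise ValueError("could not construct a constraint-satisfying tree")
        state = _McmcState(
            tree=tree,
            models={k: m.with_params() for k, m in models.items()},
            multipliers={p.name: 1.0 for p in aln.partitions},
            log_like=0.0,
            log_prior=0.0,
        )
        state.log_like = _state_loglike(engine, state, likelihood_power)
        state.log_prior = _state_logprior(priors, state)

        moves = _build_moves(
            aln,
            len(taxa),
            sample_topology,
            sample_alpha,
            sample_pinv,
            sample_freqs,
            sample_model_id,
        )
        samples = []
        keep_from = int(burn_in * n_gens)
        for it in range(1, n_gens + 1):
            name, mover = moves[rng.integers(len(moves))]
            prop, log_hastings = mover(state, rng)
            if prop is not None:
                ok = True
                if name in ("nni", "spr") and constraints:
                    ok = prop.tree.satisfies(constraints)
                if ok:
                    lp = _state_logprior(priors, prop)
                    if np.isfinite(lp):
                        ll = _state_loglike(engine, prop, likelihood_power)
                        delta = (
                            likelihood_power * (ll - state.log_like)
                            + lp
                            - state.log_prior
                            + log_hastings
                        )
                        if delta >= 0 or np.log(rng.uniform()) < delta:
                            prop.log_like = ll
                            prop.log_prior = lp
                            state = prop
            if it > keep_from and it % thin == 0:
                # under a prior-only run the chain never evaluates the
                # likelihood; recorded samples still carry the true lnL
                ll_rec = (
                    state.log_like
                    if likelihood_power > 0.0
                    else _state_loglike(engine, state, 1.0)
                )
                samples.append(
                    PosteriorSample(
                        iteration=it,
                        tree=state.tree.copy(),
                        log_likelihood=ll_rec,
                        log_prior=state.log_prior,
                        params={
                            k: {
                                "alpha": m.alpha,
                                "p_inv": m.p_inv,
                                "model_id": m.model_id,
                                "multiplier": state.multipliers[k],
                            }
                            for k, m in state.models.items()
                        },
                    )
                )
        runs_out.append(samples)
        final_states.append(state)
    if return_final_state:
        return runs_out, final_states
    return runs_out


def _build_moves(aln, n_tips, topo, alpha, pinv, freqs, model_id):
    part_names = [p.name for p in aln.partitions]
    moves = []

    def brlen_move(state, rng):
        prop = _clone(state)
        edges = prop.tree.edge_list()
        u, v = edges[rng.integers(len(edges))]
        old = prop.tree.nbrs[u][v]
        factor = np.exp(1.0 * (rng.uniform() - 0.5))
        prop.tree.set_length(u, v, old * factor)
        return prop, np.log(factor)

    moves.append(("brlen", brlen_move))

    if topo and n_tips > 3:

        def nni_move(state, rng):
            prop = _clone(state)
            internal = prop.tree.internal_edges()
            if not internal:
                return None, 0.0
            u, v = internal[rng.integers(len(internal))]
            prop.tree.nni(u, v, int(rng.integers(2)))
            return prop, 0.0

        moves.append(("nni", nni_move))
        moves.append(("nni", nni_move))  # weight topology moves up

    if topo and n_tips > 4:

        def spr_move(state, rng):
            prop = _clone(state)
            tree = prop.tree
            edges = tree.edge_list()
            u, v = edges[rng.integers(len(edges))]
            if rng.uniform() < 0.5:
                u, v = v, u
            if u < tree.n_tips:
                u, v = v, u
            if u < tree.n_tips:
                return None, 0.0
            sub_nodes = set()
            stack = [(v, u)]
            while stack:
                node, parent = stack.pop()
                sub_nodes.add(node)
                stack.extend((nb, node) for nb in tree.nbrs[node] if nb != parent)
            targets = [
                (a, b)
                for a, b in edges
                if a not in sub_nodes
                and b not in sub_nodes
                and a != u
                and b != u
            ]
            if not targets:
                return None, 0.0
            a, b = targets[rng.integers(len(targets))]
            lh = tree.spr(u, v, (a, b), rng.uniform())
            return prop, lh

        moves.append(("spr", spr_move))

    if alpha:

        def alpha_move(state, rng):
            prop = _clone(state)
            name = part_names[rng.integers(len(part_names))]
            m = prop.models[name]
            if np.isinf(m.alpha):
                return None, 0.0
            factor = np.exp(0.5 * (rng.uniform() - 0.5))
            prop.models[name] = m.with_params(alpha=m.alpha * factor)
            return prop, np.log(factor)

        moves.append(("alpha", alpha_move))

    if pinv:

        def pinv_move(state, rng):
            prop = _clone(state)
            name = part_names[rng.integers(len(part_names))]
            m = prop.models[name]
            x = m.p_inv + 0.1 * (rng.uniform() - 0.5)
            hi = 1.0 - 1e-9
            while x < 0 or x > hi:  # reflect
                x = -x if x < 0 else 2 * hi - x
            prop.models[name] = m.with_params(p_inv=x)
            return prop, 0.0

        moves.append(("pinv", pinv_move))

    if freqs:

        def freq_move(state, rng):
            from scipy.stats import dirichlet

            prop = _clone(state)
            name = part_names[rng.integers(len(part_names))]
            m = prop.models[name]
            conc = 200.0
            cur = np.clip(m.frequencies, 1e-6, None)
            cur /= cur.sum()
            new = rng.dirichlet(conc * cur)
            new = np.clip(new, 1e-8, None)
            new /= new.sum()
            lh = dirichlet.logpdf(cur, conc * new) - dirichlet.logpdf(new, conc * cur)
            prop.models[name] = m.with_params(frequencies=new)
            return prop, float(lh)

        moves.append(("freqs", freq_move))

    if model_id:

        def model_move(state, rng):
            prop = _clone(state)
            name = part_names[rng.integers(len(part_names))]
            m = prop.models[name]
            choice = AA_MODEL_NAMES[rng.integers(len(AA_MODEL_NAMES))]
            if choice == m.model_id:
                return None, 0.0
            prop.models[name] = empirical_aa(choice, p_inv=m.p_inv, alpha=m.alpha)
            return prop, 0.0

        moves.append(("model", model_move))

    if len(part_names) > 1:

        def mult_move(state, rng):
            from scipy.stats import dirichlet

            prop = _clone(state)
            P = len(part_names)
            conc = 200.0
            cur = np.array([state.multipliers[k] for k in part_names]) / P
            cur = np.clip(cur, 1e-8, None)
            cur /= cur.sum()
            new = rng.dirichlet(conc * cur)
            new = np.clip(new, 1e-8, None)
            new /= new.sum()
            lh = dirichlet.logpdf(cur, conc * new) - dirichlet.logpdf(new, conc * cur)
            prop.multipliers = {k: float(P * w) for k, w in zip(part_names, new)}
            return prop, float(lh)

        moves.append(("multipliers", mult_move))

    return moves


def _clone(state: _McmcState) -> _McmcState:
    return _McmcState(
        tree=state.tree.copy(),
        models=dict(state.models),
        multipliers=dict(state.multipliers),
        log_like=state.log_like,
        log_prior=state.log_prior,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries


def split_frequencies(samples: list[PosteriorSample]) -> dict[frozenset[str], float]:
    counts: dict[frozenset[str], int] = {}
    for s in samples:
        for split in s.tree.label_splits():
            counts[split] = counts.get(split, 0) + 1
    n = len(samples)
    return {k: v / n for k, v in counts.items()}


def asdsf(runs: list[list[PosteriorSample]], min_freq: float = 0.1) -> float:
    """Average (across qualifying splits) standard deviation of split
    frequencies across independent runs; qualifying = frequency >=
    ``min_freq`` in at least one run."""
    if len(runs) < 2:
        raise ValueError("ASDSF needs at least two runs")
    freqs = [split_frequencies(r) for r in runs]
    all_splits = set().union(*[set(f) for f in freqs])
    sds = []
    for split in all_splits:
        vals = np.array([f.get(split, 0.0) for f in freqs])
        if vals.max() >= min_freq:
            sds.append(vals.std(ddof=1))
    return float(np.mean(sds)) if sds else 0.0


@dataclass
class ConsensusTree:
    tree: dendropy.Tree
    split_pp: dict[frozenset[str], float]
    collapse_pp: float

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def consensus_tree(
    samples: list[PosteriorSample], collapse_pp: float = 0.75
) -> ConsensusTree:
    """Majority-rule-extended consensus with low-support splits collapsed.

    Posterior probability of a split is exactly its sample frequency.
    Compatible splits are accepted greedily in frequency order
    (ties: higher mean branch length, then lexicographic), then any
    accepted split with PP below ``collapse_pp`` is removed, which
    collapses the corresponding node into a polytomy.
    """
    if not samples:
        raise ValueError("no samples")
    labels = samples[0].tree.labels
    anchor = labels[0]
    full = frozenset(labels)
    freqs = split_frequencies(samples)

    # mean branch length per split for tie-breaking
    mean_len: dict[frozenset[str], float] = {}
    for split in freqs:
        tot, cnt = 0.0, 0
        for s in samples:
            spl = s.tree.splits()
            key = frozenset(s.tree.labels[i] for i in range(s.tree.n_tips))
            for side, (u, v) in spl.items():
                lab_side = frozenset(s.tree.labels[i] for i in side)
                if lab_side == split or full - lab_side == split:
                    tot += s.tree.nbrs[u][v]
                    cnt += 1
        mean_len[split] = tot / cnt if cnt else 0.0

    def canon(split: frozenset[str]) -> frozenset[str]:
        return split if anchor not in split else full - split

    ordered = sorted(
        freqs,
        key=lambda s: (-freqs[s], -mean_len[s], tuple(sorted(s))),
    )
    accepted: list[frozenset[str]] = []
    for split in ordered:
        c = canon(split)
        if all(_compatible(c, other) for other in accepted):
            accepted.append(c)
    kept = [s for s in accepted if freqs_of(freqs, s, full) >= collapse_pp]

    # build the tree from the laminar family of kept clades (anchor outside)
    rest = sorted(set(labels) - {anchor})
    kept_sorted = sorted(kept, key=len)

    children: dict[frozenset[str], list] = {frozenset(rest): []}
    for clade in kept_sorted:
        if clade not in children:
            children[frozenset(clade)] = []

    def newick_for(clade: frozenset[str]) -> str:
        inner = [c for c in kept_sorted if c < clade]
        maximal = [c for c in inner if not any(c < d for d in inner if d is not c)]
        covered = set().union(*maximal) if maximal else set()
        parts = [newick_for(c) for c in maximal] + sorted(clade - covered)
        pp = freqs_of(freqs, clade, full)
        label = f"{pp:.4f}" if clade != frozenset(rest) else ""
        return "(" + ",".join(parts) + ")" + label

    newick = f"({anchor},{newick_for(frozenset(rest))});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return ConsensusTree(
        tree=tree,
        split_pp={s: freqs_of(freqs, s, full) for s in accepted},
        collapse_pp=collapse_pp,
    )


def freqs_of(freqs, split, full):
    return max(freqs.get(split, 0.0), freqs.get(full - split, 0.0))


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return not (a & b) or a <= b or b <= a


def root_on_split(
    tree: UnrootedTree, side_a: set[str], side_b: set[str]
) -> dendropy.Tree:
    """Root on the branch inducing the bipartition side_a | side_b."""
    side_a, side_b = frozenset(side_a), frozenset(side_b)
    full = frozenset(tree.labels)
    if side_a | side_b != full or side_a & side_b:
        raise ValueError("sides must partition the tip set")
    target_edge = None
    for u, v in tree.edge_list():
        side = frozenset(tree.labels[i] for i in tree.side_tips(u, v))
        if side == side_a or side == side_b:
            target_edge = (u, v)
            break
    if target_edge is None:
        best, best_d = None, None
        for s in tree.label_splits():
            d = min(len(s ^ side_a), len(s ^ side_b))
            if best_d is None or d < best_d:
                best, best_d = s, d
        raise ValueError(
            f"bipartition not present in tree; nearest compatible split: {sorted(best) if best else None}"
        )
    u, v = target_edge
    half = tree.nbrs[u][v] / 2.0

    def sub(node: int, parent: int) -> str:
        if node < tree.n_tips:
            return f"{tree.labels[node]}:{tree.nbrs[node][parent]:.10g}"
        kids = [sub(nb, node) for nb in sorted(tree.nbrs[node]) if nb != parent]
        return f"({','.join(kids)}):{tree.nbrs[node][parent]:.10g}"

    def side_newick(node: int, other: int) -> str:
        if node < tree.n_tips:
            return f"{tree.labels[node]}:{half:.10g}"
        kids = [sub(nb, node) for nb in sorted(tree.nbrs[node]) if nb != other]
        return f"({','.join(kids)}):{half:.10g}"

    newick = f"({side_newick(u, v)},{side_newick(v, u)});"
    rooted = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    rooted.is_rooted = True
    return rooted
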