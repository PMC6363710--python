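"""Constrained-topology hypothesis testing by stepping-stone Bayes factors.

Three hypotheses for the origin of the phycoerythrin-II genes (mpeBA)
relative to phycoerythrin-I (cpeBA) are encoded as monophyly constraint
sets: an ancient duplication/transfer predating cyanobacteria (A: all
cpe sequences monophyletic, excluding mpe), a duplication in the common
ancestor of the picocyanobacteria and their sponge-symbiont sister
(B: mpe clades sister to the picocyanobacterial cpe clades), and a
lateral transfer from a crown-group cyanobacterium (C: only mpe
monophyly is constrained).  Each hypothesis's marginal likelihood is
estimated by stepping-stone sampling along a ladder of power posteriors
prior -> posterior, and hypotheses are compared by log Bayes factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PartitionedAlignment, single_partition
from .models import SubstitutionModel
from .phylo_engine import Priors, mcmc_sample
from .treespace import UnrootedTree

HYPOTHESES = ("A", "B", "C")


@dataclass
class TopologyConstraint:
    """Named monophyly clauses; clauses must be pairwise nested or disjoint."""

    clauses: dict[str, frozenset[str]]
    hypothesis: str = "custom"

    def __post_init__(self) -> None:
        items = list(self.clauses.items())
        for name, tips in items:
            if len(tips) < 2:
                raise ValueError(f"clause {name!r} needs at least 2 tips")
        for i, (n1, c1) in enumerate(items):
            for n2, c2 in items[i + 1 :]:
                if c1 & c2 and not (c1 <= c2 or c2 <= c1):
                    raise ValueError(
                        f"incompatible clauses {n1!r} and {n2!r}: overlapping but not nested"
                    )

    def clause_list(self) -> list[frozenset[str]]:
        return list(self.clauses.values())

    def satisfied_by(self, tree: UnrootedTree) -> bool:
        return tree.satisfies(self.clause_list())


def build_hypothesis_constraint(
    hypothesis: str, tip_groups: dict[str, set[str]]
) -> TopologyConstraint:
    """Constraint sets for the duplication-vs-LGT hypotheses.

    A (ancient duplication/transfer): cpeA and cpeB each monophyletic,
    excluding mpeA/mpeB.  B (duplication on the picocyanobacterial stem):
    mpeA, mpeB, the picocyanobacterial cpeA and cpeB clades, and each
    mpe+cpe(pico) pairing monophyletic.  C (lateral transfer): only
    mpeA and mpeB monophyly.
    """
    g = {k: frozenset(v) for k, v in tip_groups.items()}
    required = {"cpeA_all", "cpeB_all", "mpeA", "mpeB", "cpeA_synpro", "cpeB_synpro"}
    missing = required - set(g)
    if missing:
        raise ValueError(f"tip_groups missing {sorted(missing)}")
    if not g["cpeA_synpro"] <= g["cpeA_all"] or not g["cpeB_synpro"] <= g["cpeB_all"]:
        raise ValueError("picocyanobacterial cpe groups must nest inside cpe_all")
    if hypothesis == "A":
        clauses = {"cpeA_all": g["cpeA_all"], "cpeB_all": g["cpeB_all"]}
    elif hypothesis == "B":
        clauses = {
            "mpeA": g["mpeA"],
            "mpeB": g["mpeB"],
            "cpeA_synpro": g["cpeA_synpro"],
            "cpeB_synpro": g["cpeB_synpro"],
            "mpeA+cpeA_synpro": g["mpeA"] | g["cpeA_synpro"],
            "mpeB+cpeB_synpro": g["mpeB"] | g["cpeB_synpro"],
        }
    elif hypothesis == "C":
        clauses = {"mpeA": g["mpeA"], "mpeB": g["mpeB"]}
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    return TopologyConstraint(clauses=clauses, hypothesis=hypothesis)


# ---------------------------------------------------------------------------
# stepping-stone sampling


@dataclass
class SteppingStoneSchedule:
    """Powers beta_K=0 < ... < beta_0=1 from Beta(a, 1) quantiles."""

    n_stones: int = 32
    gens_per_stone: int = 5_000
    beta_shape: float = 0.4
    burn_in: float = 0.3
    thin: int = 5

    def powers(self) -> np.ndarray:
        k = np.arange(self.n_stones + 1)
        return (k / self.n_stones) ** (1.0 / self.beta_shape)


@dataclass
class MarginalLikelihood:
    log_value: float
    per_stone: list[dict]
    mc_se: float
    low_ess_stones: list[int] = field(default_factory=list)


def stepping_stone(
    aln: PartitionedAlignment | Alignment,
    model: SubstitutionModel | dict[str, SubstitutionModel],
    constraint: TopologyConstraint | None,
    schedule: SteppingStoneSchedule | None = None,
    seed: int = 0,
    priors: Priors | None = None,
    start_tree: UnrootedTree | None = None,
    **mcmc_kw,
) -> MarginalLikelihood:
    """Stepping-stone estimate of the log marginal likelihood.

    For each adjacent power pair (b_k < b_{k+1}) a chain samples the
    power posterior prior x likelihood^{b_k}; the log ratio contribution
    is log mean L^{b_{k+1}-b_k} over those samples, and the total is the
    sum.  Chains warm-start from the previous (cooler) stone.  The
    Monte-Carlo standard error is the delta-method sum of per-stone
    weight variances; stones whose importance weights collapse
    (effective sample size < 10) are flagged, not silently accepted.
    """
    if isinstance(aln, Alignment):
        aln = single_partition(aln)
    schedule = schedule or SteppingStoneSchedule()
    priors = priors or Priors()
    betas = schedule.powers()
    clauses = constraint.clause_list() if constraint else []
    rng = np.random.default_rng(seed)

    per_stone: list[dict] = []
    log_ml = 0.0
    var_total = 0.0
    low_ess: list[int] = []
    if start_tree is not None and not start_tree.satisfies(clauses):
        start_tree = None
    # run the ladder hot -> cold: the high-power basin is located once
    # (with a doubled first chain) and each cooler stone melts gradually
    stone_order = list(range(len(betas) - 1))[::-1]
    for pos, k in enumerate(stone_order):
        b_lo, b_hi = float(betas[k]), float(betas[k + 1])
        gens = schedule.gens_per_stone * (2 if pos == 0 else 1)
        runs, finals = mcmc_sample(
            aln,
            priors=priors,
            constraints=clauses,
            n_gens=gens,
            n_runs=1,
            thin=schedule.thin,
            seed=int(rng.integers(2**31)),
            models=model,
            burn_in=schedule.burn_in,
            likelihood_power=b_lo,
            start_tree=start_tree,
            return_final_state=True,
            **mcmc_kw,
        )
        samples = runs[0]
        start_tree = finals[0].tree
        lnl = np.array([s.log_likelihood for s in samples])
        d = b_hi - b_lo
        mx = lnl.max()
        w = np.exp(d * (lnl - mx))
        contrib = float(np.log(w.mean()) + d * mx)
        ess = float(w.sum() ** 2 / (w**2).sum())
        # batch means absorb chain autocorrelation into the variance
        n_blocks = min(10, len(w))
        if n_blocks > 1:
            blocks = np.array_split(w, n_blocks)
            bmeans = np.array([b.mean() for b in blocks])
            var_k = float(bmeans.var(ddof=1) / n_blocks / w.mean() ** 2)
        else:
            var_k = 0.0
        log_ml += contrib
        var_total += var_k
        if ess < 10:
            low_ess.append(k)
        per_stone.append(
            {
                "stone": k,
                "beta_lo": b_lo,
                "beta_hi": b_hi,
                "log_ratio": contrib,
                "ess": ess,
                "n": len(w),
            }
        )
    return MarginalLikelihood(
        log_value=float(log_ml),
        per_stone=per_stone,
        mc_se=float(np.sqrt(var_total)),
        low_ess_stones=low_ess,
    )


def _nj_guide_tree(
    aln: PartitionedAlignment, clauses: list[frozenset[str]] | None = None
) -> UnrootedTree | None:
    """Distance-based guide topology used to warm-start the hot chain.

    Chains can fail to locate the high-likelihood basin within
    desk-scale generation counts; seeding the hottest stone with a
    neighbor-joining topology removes that search problem without
    touching the estimator itself.  When monophyly clauses are given,
    within-clause distances are shrunk before joining so the guide lands
    inside the constrained space while preserving the data's grouping;
    a guide that still violates a clause is discarded (the chain then
    starts from a random constraint-satisfying tree).
    """
    try:
        from .ortholog_contour import build_nj_tree, pairwise_distance

        dist = pairwise_distance(aln.alignment)
        # Poisson correction (clipped near saturation) keeps deep
        # distances roughly additive, which matters for the guide
        vals = np.clip(dist.values, 0.0, 0.95)
        corrected = dist.copy()
        corrected.values[:] = -np.log(1.0 - vals)
        np.fill_diagonal(corrected.values, 0.0)

        def finish(matrix):
            tree = build_nj_tree(matrix).tree
            # clamped zero-length branches make poor starting values
            for u, v in tree.edge_list():
                if tree.nbrs[u][v] < 1e-3:
                    tree.set_length(u, v, 1e-3)
            return tree

        plain = finish(corrected)
        if not clauses or plain.satisfies(clauses):
            return plain
        # the data's own NJ tree violates a clause: shrink within-clause
        # distances so the joining respects the constraint
        shrunk = corrected.copy()
        taxa = list(shrunk.index)
        for clause in clauses:
            idx = [i for i, t in enumerate(taxa) if t in clause]
            for a in idx:
                for b in idx:
                    if a != b:
                        shrunk.iat[a, b] *= 0.25
        tree = finish(shrunk)
        if tree.satisfies(clauses):
            return tree
        return None
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Bayes factors


@dataclass
class BayesFactorReport:
    pair: tuple[str, str]
    log_bf: float
    band: str


def _kass_raftery_band(log_bf: float) -> str:
    a = abs(log_bf)
    if a < 1:
        return "weak"
    if a < 3:
        return "positive"
    if a < 5:
        return "strong"
    return "very strong"


def bayes_factor(
    logml_i: float, logml_j: float, pair: tuple[str, str] = ("i", "j")
) -> BayesFactorReport:
    """log BF = log ML_i - log ML_j, with a conventional evidence band."""
    if not (np.isfinite(logml_i) and np.isfinite(logml_j)):
        raise ValueError("marginal likelihoods must be finite")
    log_bf = float(logml_i - logml_j)
    return BayesFactorReport(pair=pair, log_bf=log_bf, band=_kass_raftery_band(log_bf))


@dataclass
class HypothesisReport:
    logml: dict[str, MarginalLikelihood]
    winner: str
    log_bf_vs_alternatives: dict[str, float]

    def log_bf(self, i: str, j: str) -> float:
        return self.logml[i].log_value - self.logml[j].log_value


def hypothesis_suite(
    aln: PartitionedAlignment | Alignment,
    tip_groups: dict[str, set[str]],
    model: SubstitutionModel | dict[str, SubstitutionModel] | None = None,
    schedule: SteppingStoneSchedule | None = None,
    seed: int = 0,
    priors: Priors | None = None,
    hypotheses: tuple[str, ...] = HYPOTHESES,
    **mcmc_kw,
) -> HypothesisReport:
    """Stepping-stone marginal likelihoods for hypotheses A/B/C.

    Data, model, priors and schedule are shared across hypotheses so the
    marginal likelihoods are comparable; only the constraint set varies.
    """
    if isinstance(aln, Alignment):
        aln = single_partition(aln)
    if model is None:
        model = {
            p.name: SubstitutionModel(alphabet=p.alphabet) for p in aln.partitions
        }
    results: dict[str, MarginalLikelihood] = {}
    for hyp in hypotheses:
        constraint = build_hypothesis_constraint(hyp, tip_groups)
        guide = _nj_guide_tree(aln, constraint.clause_list())
        results[hyp] = stepping_stone(
            aln,
            model,
            constraint,
            schedule,
            seed=seed,
            priors=priors,
            start_tree=guide,
            **mcmc_kw,
        )
    winner = max(results, key=lambda h: results[h].log_value)
    bf = {
        h: results[winner].log_value - results[h].log_value
        for h in results
        if h != winner
    }
    return HypothesisReport(logml=results, winner=winner, log_bf_vs_alternatives=bf)


def lgt_pair_test(
    aln: PartitionedAlignment | Alignment,
    donor_clade: set[str],
    recipient_taxon: str,
    relatives: set[str],
    model: SubstitutionModel | dict[str, SubstitutionModel] | None = None,
    schedule: SteppingStoneSchedule | None = None,
    seed: int = 0,
    priors: Priors | None = None,
    **mcmc_kw,
) -> BayesFactorReport:
    """Transfer vs vertical placement for one taxon's gene.

    Compares the constraint "recipient inside the donor clade" against
    "recipient with its species-tree relatives" by stepping-stone log
    Bayes factor (positive favours the transfer placement).
    """
    if isinstance(aln, Alignment):
        aln = single_partition(aln)
    taxa = set(aln.taxa)
    if recipient_taxon in donor_clade:
        raise ValueError("recipient must lie outside the donor clade")
    if len(taxa) < 4:
        raise ValueError(
            "constraints are unsatisfiable/indistinguishable with fewer than 4 taxa"
        )
    for group, name in ((donor_clade, "donor_clade"), (relatives, "relatives")):
        unknown = set(group) - taxa
        if unknown:
            raise ValueError(f"{name} references unknown taxa: {sorted(unknown)}")
    lgt_c = TopologyConstraint(
        {"recipient_with_donor": frozenset(donor_clade) | {recipient_taxon}},
        hypothesis="lgt",
    )
    vert_c = TopologyConstraint(
        {"recipient_with_relatives": frozenset(relatives) | {recipient_taxon}},
        hypothesis="vertical",
    )
    if model is None:
        model = {
            p.name: SubstitutionModel(alphabet=p.alphabet) for p in aln.partitions
        }
    ml_lgt = stepping_stone(
        aln, model, lgt_c, schedule, seed=seed, priors=priors,
        start_tree=_nj_guide_tree(aln, lgt_c.clause_list()), **mcmc_kw,
    )
    ml_vert = stepping_stone(
        aln, model, vert_c, schedule, seed=seed + 1, priors=priors,
        start_tree=_nj_guide_tree(aln, vert_c.clause_list()), **mcmc_kw,
    )
    return bayes_factor(
        ml_lgt.log_value, ml_vert.log_value, pair=("lgt", "vertical")
    )
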