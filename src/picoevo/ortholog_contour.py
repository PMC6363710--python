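"""Contour-based ortholog delimitation.

Candidate homologs recovered by BLAST are scored by the number of
identical residues relative to the query length (identity x alignment
length / query length), placed on a neighbor-joining tree, and grouped
by similarity contours: at each score level, the maximal clades whose
tips all reach that level.  True orthologs form a (mostly) monophyletic
clade around the query with a well-defined contour profile — its
internal scores separated from everything outside by a clear gap; tips
on the boundary of that group are marked uncertain and excluded
downstream, together with their partner subunit from the same genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment
from .treespace import UnrootedTree


@dataclass
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def identical_fraction(hit: BlastHit, query_length: int) -> float:
    """Identical residues as a fraction of query length (uncapped).

    Values above 1 can occur for gapped alignments; capping at 1 is
    applied only when binning scores onto contours.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    return hit.pct_identity / 100.0 * hit.aln_length / query_length


def score_hits(
    hits: list[BlastHit], query_length: int, evalue_max: float = 1e-5
) -> dict[str, float]:
    """Best (highest) identical-fraction score per subject passing e-value."""
    scores: dict[str, float] = {}
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        s = identical_fraction(hit, query_length)
        if s > scores.get(hit.subject_id, -1.0):
            scores[hit.subject_id] = s
    return scores


# ---------------------------------------------------------------------------
# distances and neighbor joining


def pairwise_distance(
    aln: Alignment, correction: str | None = None
) -> pd.DataFrame:
    """p-distance over shared non-gap columns (optionally Poisson-corrected)."""
    taxa = aln.taxa
    enc = aln.encode()
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (enc[i] >= 0) & (enc[j] >= 0)
            if not shared.any():
                raise ValueError(
                    f"no shared ungapped columns for pair ({taxa[i]!r}, {taxa[j]!r})"
                )
            p = float(np.mean(enc[i][shared] != enc[j][shared]))
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated pair; Poisson correction undefined")
                p = -np.log(1.0 - p)
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}")
            D[i, j] = D[j, i] = p
    return pd.DataFrame(D, index=taxa, columns=taxa)


@dataclass
class NJTree:
    tree: UnrootedTree
    scores: dict[str, float] = field(default_factory=dict)


def build_nj_tree(distances: pd.DataFrame) -> NJTree:
    """Standard neighbor joining (Q-criterion agglomeration).

    Recovers additive matrices exactly.  Ties in Q are broken by the
    lexicographically first pair in input order; negative branch-length
    estimates are clamped to zero with the deficit moved to the sibling
    branch.
    """
    labels = list(distances.index)
    D = np.asarray(distances, dtype=float)
    if D.shape[0] != D.shape[1] or list(distances.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if np.any(np.isnan(D)) or np.any(D < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("diagonal must be zero")
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")

    active = list(range(n))  # indices into the growing matrix
    newick: dict[int, str] = {i: labels[i] for i in range(n)}
    Dm = D.copy()

    def dist(i: int, j: int) -> float:
        return Dm[i, j]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(Dm[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * Dm[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * Dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = Dm[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Dm.shape[0]
        row = np.zeros((1, Dm.shape[1]))
        Dm = np.vstack([Dm, row])
        Dm = np.hstack([Dm, np.zeros((Dm.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            Dm[new, k] = Dm[k, new] = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
        newick[new] = f"({newick[i]}:{li:.12g},{newick[j]}:{lj:.12g})"
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    la = 0.5 * (Dm[a, b] + Dm[a, c] - Dm[b, c])
    lb = 0.5 * (Dm[a, b] + Dm[b, c] - Dm[a, c])
    lc = 0.5 * (Dm[a, c] + Dm[b, c] - Dm[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    nwk = f"({newick[a]}:{la:.12g},{newick[b]}:{lb:.12g},{newick[c]}:{lc:.12g});"
    return NJTree(tree=UnrootedTree.from_newick(nwk, labels=sorted(labels)))


# ---------------------------------------------------------------------------
# contours


@dataclass
class ContourSet:
    """Per descending level, maximal clades whose tips all reach the level."""

    levels: list[float]
    groups: dict[float, list[frozenset[str]]]


def default_levels(scores: dict[str, float]) -> list[float]:
    """Deciles of the observed capped scores, descending and de-duplicated."""
    capped = np.minimum(list(scores.values()), 1.0)
    qs = np.quantile(capped, np.linspace(0.1, 0.9, 9))
    levels = sorted({round(float(q), 6) for q in qs if q > 0}, reverse=True)
    return levels or [min(1.0, float(np.max(capped)))]


def _clades(tree: UnrootedTree) -> list[frozenset[str]]:
    out = {frozenset(tree.labels)}
    for u, v in tree.edge_list():
        for side in (tree.side_tips(u, v), tree.side_tips(v, u)):
            out.add(frozenset(tree.labels[i] for i in side))
    return sorted(out, key=lambda s: (len(s), tuple(sorted(s))))


def draw_contours(nj: NJTree, levels: list[float] | None = None) -> ContourSet:
    """Maximal same-similarity tip groups at each score level.

    Scores are capped at 1 for binning.  Groups at a higher level are
    nested inside groups at any lower level (laminar across levels).
    """
    tree = nj.tree
    unscored = [lab for lab in tree.labels if lab not in nj.scores]
    if unscored:
        raise ValueError(f"unscored tips: {unscored}")
    if levels is None:
        levels = default_levels(nj.scores)
    levels = list(levels)
    if any(b >= a for a, b in zip(levels, levels[1:])) or any(
        not 0 < l <= 1 for l in levels
    ):
        raise ValueError("levels must be strictly descending within (0, 1]")
    capped = {lab: min(s, 1.0) for lab, s in nj.scores.items()}
    clades = _clades(tree)
    groups: dict[float, list[frozenset[str]]] = {}
    for level in levels:
        qualifying = [c for c in clades if all(capped[t] >= level for t in c)]
        maximal = [
            c for c in qualifying if not any(c < d for d in qualifying)
        ]
        groups[level] = maximal
    return ContourSet(levels=levels, groups=groups)


# ---------------------------------------------------------------------------
# ortholog calls


@dataclass
class OrthologCall:
    subject_id: str
    verdict: str  # true_ortholog / uncertain / non_ortholog
    evidence: dict = field(default_factory=dict)


def classify_orthologs(
    nj: NJTree,
    contours: ContourSet,
    query_tip: str,
    monophyly_tolerance: float = 0.1,
    gap_min: float = 0.2,
) -> dict[str, OrthologCall]:
    """Call true/uncertain/non-ortholog from the contour profile.

    The candidate clade is the smallest clade containing the query that,
    at some contour level, holds at most ``monophyly_tolerance`` of its
    tips below the level (intruders) and whose internal minimum score
    (over non-intruders) exceeds the maximum score outside by at least
    ``gap_min``.  Intruders and outside tips scoring within ``gap_min``
    of the internal minimum sit on the group boundary and are uncertain.
    """
    tree = nj.tree
    if query_tip not in tree.labels:
        raise ValueError(f"query tip {query_tip!r} not in tree")
    capped = {lab: min(s, 1.0) for lab, s in nj.scores.items()}
    all_tips = set(tree.labels)
    clades = [c for c in _clades(tree) if query_tip in c]

    candidate = None
    cand_level = None
    cand_intruders: set[str] = set()
    cand_inside_min = None
    for level in contours.levels:
        for clade in clades:  # ascending size
            intruders = {t for t in clade if capped[t] < level}
            if len(intruders) / len(clade) > monophyly_tolerance:
                continue
            members = clade - intruders
            if query_tip not in members:
                continue
            inside_min = min(capped[t] for t in members)
            outside = all_tips - clade
            outside_max = max((capped[t] for t in outside), default=0.0)
            if inside_min - outside_max >= gap_min:
                candidate = clade
                cand_level = level
                cand_intruders = intruders
                cand_inside_min = inside_min
                break
        if candidate is not None:
            break

    calls: dict[str, OrthologCall] = {}
    if candidate is None:
        for tip in tree.labels:
            verdict = "true_ortholog" if tip == query_tip else "uncertain"
            calls[tip] = OrthologCall(
                tip, verdict, {"no_well_defined_contour": True, "score": capped[tip]}
            )
        return calls

    boundary_floor = cand_inside_min - gap_min
    for tip in tree.labels:
        ev = {
            "contour_level": cand_level,
            "score": capped[tip],
            "intruder_fraction": len(cand_intruders) / len(candidate),
        }
        if tip == query_tip:
            calls[tip] = OrthologCall(tip, "true_ortholog", ev)
        elif tip in candidate and tip not in cand_intruders:
            calls[tip] = OrthologCall(tip, "true_ortholog", ev)
        elif tip in cand_intruders:
            calls[tip] = OrthologCall(tip, "uncertain", ev | {"boundary": True})
        elif capped[tip] >= boundary_floor:
            calls[tip] = OrthologCall(tip, "uncertain", ev | {"boundary": True})
        else:
            calls[tip] = OrthologCall(tip, "non_ortholog", ev)
    return calls


def apply_pair_exclusion(
    calls_alpha: dict[str, OrthologCall],
    calls_beta: dict[str, OrthologCall],
    genome_map: dict[str, str],
    symmetric: bool = True,
):
    """Exclude the partner subunit of any genome with an uncertain call.

    A genome whose alpha-subunit call is uncertain has its beta-subunit
    sequence excluded from downstream sets; symmetric by default (a
    genome with an uncertain beta also drops its alpha).
    Returns (filtered_alpha, filtered_beta, excluded_genomes).
    """
    missing = (set(calls_alpha) | set(calls_beta)) - set(genome_map)
    if missing:
        raise ValueError(f"genome_map does not cover subjects: {sorted(missing)}")

    def uncertain_genomes(calls):
        return {
            genome_map[s] for s, c in calls.items() if c.verdict == "uncertain"
        }

    excluded = uncertain_genomes(calls_alpha)
    if symmetric:
        excluded |= uncertain_genomes(calls_beta)

    def keep(calls):
        return {
            s: c
            for s, c in calls.items()
            if c.verdict == "true_ortholog" and genome_map[s] not in excluded
        }

    return keep(calls_alpha), keep(calls_beta), excluded
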