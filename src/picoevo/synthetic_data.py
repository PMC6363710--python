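"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the pipeline consumes: birth-death
species trees conditioned on tip count and root age; i.i.d. gamma
branch-rate multipliers (mean 1) for the relaxed clock; gene families
with one duplication, lineage-specific losses and optional lateral
transfers; site-homogeneous sequence evolution with invariant sites and
discrete-gamma rate variation; phycobilisome gene inventories consistent
with pigment Types I/II/IIB/III; and assembly graphs mixing a high-depth
target component with low-depth contaminant components.

All randomness flows from one explicit integer seed through a named
``numpy.random.Generator``; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment
from .chronotree import ChronoTree
from .contig_triage import HIT_COLUMNS, AssemblyGraph
from .models import SubstitutionModel
from .treespace import UnrootedTree

MAX_BD_ATTEMPTS = 10_000


# ---------------------------------------------------------------------------
# species trees


def simulate_species_tree(
    n_taxa: int,
    birth: float,
    death: float,
    root_age: float,
    seed: int,
) -> ChronoTree:
    """Birth-death tree conditioned on tip count and root (MRCA) age.

    Forward simulation from two lineages at ``root_age`` with per-Myr
    rates, accepted when exactly ``n_taxa`` tips survive to the present
    and both root lineages leave descendants (so the root is the MRCA).
    Rejection is bounded at 10,000 attempts.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if root_age <= 0:
        raise ValueError("root age must be positive")
    rng = np.random.default_rng(seed)
    if n_taxa == 2:
        labels = ["t1", "t2"]
        return ChronoTree(labels, [2, 2, -1], [0.0, 0.0, root_age])

    total = birth + death
    p_birth = birth / total

    def lineage(age_start: float) -> dict:
        wait = rng.exponential(1.0 / total)
        age_next = age_start - wait
        if age_next <= 0:
            return {"age": 0.0, "children": None, "extant": True}
        if rng.uniform() < p_birth:
            return {
                "age": age_next,
                "children": [lineage(age_next), lineage(age_next)],
                "extant": False,
            }
        return {"age": age_next, "children": None, "extant": False}

    def prune(node: dict) -> dict | None:
        if node["children"] is None:
            return node if node["extant"] else None
        kids = [prune(c) for c in node["children"]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return {"age": node["age"], "children": kids, "extant": False}

    for _ in range(MAX_BD_ATTEMPTS):
        root = {
            "age": root_age,
            "children": [lineage(root_age), lineage(root_age)],
            "extant": False,
        }
        pruned = prune(root)
        if pruned is None or pruned["age"] != root_age:
            continue

        def count(node):
            if node["children"] is None:
                return 1
            return sum(count(c) for c in node["children"])

        if count(pruned) != n_taxa:
            continue
        return _nodes_to_chronotree(pruned, n_taxa)
    raise RuntimeError(
        f"conditioned birth-death simulation failed after {MAX_BD_ATTEMPTS} attempts"
    )


def _nodes_to_chronotree(root: dict, n_taxa: int) -> ChronoTree:
    labels: list[str] = []
    parent: list[int] = [-1] * (2 * n_taxa - 1)
    ages: list[float] = [0.0] * (2 * n_taxa - 1)
    next_tip = [0]
    next_internal = [n_taxa]

    def assign(node: dict) -> int:
        if node["children"] is None:
            i = next_tip[0]
            next_tip[0] += 1
            labels.append(f"t{i + 1}")
            ages[i] = 0.0
            return i
        i = next_internal[0]
        next_internal[0] += 1
        ages[i] = node["age"]
        for c in node["children"]:
            j = assign(c)
            parent[j] = i
        return i

    root_id = assign(root)
    parent[root_id] = -1
    return ChronoTree(labels, parent, ages)


# ---------------------------------------------------------------------------
# branch rates


@dataclass
class RateAssignment:
    """Per-branch rate multipliers (mean 1) plus a global clock rate."""

    multipliers: dict[int, float]
    global_rate: float = 5e-4  # substitutions/site/Myr

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("rate multipliers must be positive")


def simulate_ugam_rates(
    tree: ChronoTree,
    variance: float,
    seed: int,
    global_rate: float = 5e-4,
) -> RateAssignment:
    """i.i.d. Gamma multipliers with mean 1 and the given variance.

    variance 0 degenerates to a strict clock (every multiplier exactly 1).
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    branches = tree.branches()
    if variance == 0:
        mult = {b: 1.0 for b in branches}
    else:
        shape = 1.0 / variance
        mult = {b: float(rng.gamma(shape, variance)) for b in branches}
    return RateAssignment(multipliers=mult, global_rate=global_rate)


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SimulatedAlignment:
    alignment: Alignment
    site_categories: np.ndarray  # -1 = invariant, else gamma category index
    model: SubstitutionModel
    tree_newick: str


def simulate_sequences(
    tree: UnrootedTree | ChronoTree | str,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    branch_scale=None,
) -> SimulatedAlignment:
    """Evolve sites down a tree with expected-substitution branch lengths.

    Site rates follow the model's +I+Gamma mixture: each site is
    invariant with probability ``p_inv``, otherwise it draws one of the
    discrete-gamma categories uniformly.  Per-site categories are
    recorded for introspection.
    """
    if isinstance(tree, ChronoTree):
        tree = tree.to_unrooted(branch_scale)
    if isinstance(tree, str):
        tree = UnrootedTree.from_newick(tree)
    rng = np.random.default_rng(seed)
    K = model.K
    rates = model.category_rates()
    ncat = len(rates)

    cats = rng.integers(ncat, size=n_sites)
    if model.p_inv > 0:
        inv = rng.uniform(size=n_sites) < model.p_inv
        cats = np.where(inv, -1, cats)
    site_rate = np.where(cats >= 0, rates[np.clip(cats, 0, None)], 0.0)

    order, root = tree.postorder()
    states = {root: rng.choice(K, size=n_sites, p=model.frequencies)}
    for node, parent, length in reversed(order):  # preorder
        if parent == -1:
            continue
        parent_states = states[parent]
        out = parent_states.copy()
        for c in range(ncat):
            mask = cats == c
            if not mask.any():
                continue
            P = model.transition_matrix(length * rates[c])
            cum = P.cumsum(axis=1)
            u = rng.uniform(size=mask.sum())
            rows = cum[parent_states[mask]]
            out[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = out

    seqs = {
        tree.labels[i]: "".join(model.alphabet[s] for s in states[i])
        for i in range(tree.n_tips)
    }
    return SimulatedAlignment(
        alignment=Alignment(seqs, model.alphabet),
        site_categories=cats,
        model=model,
        tree_newick=tree.to_newick(),
    )


# ---------------------------------------------------------------------------
# gene families (duplication / loss / LGT)


@dataclass
class LgtEvent:
    donor_branch: int
    recipient_branch: int
    copy: int
    time: float
    donor_copy: int | None = None  # default: same copy; falls back to copy 1


@dataclass
class GeneFamilyScenario:
    """One duplication plus lineage-specific losses and optional LGTs.

    ``duplication_branch`` is a species-tree branch id (child node id);
    the species root id means a duplication older than the root, giving
    two copies in every taxon.  ``truth_label`` tags the generating
    hypothesis (ancient duplication ``A``, duplication on the focal stem
    ``B``, or transfer ``C``).
    """

    duplication_branch: int | None = None
    duplication_time: float | None = None
    loss_branches: set[tuple[int, int]] = field(default_factory=set)  # (copy, branch)
    lgt_events: list[LgtEvent] = field(default_factory=list)
    truth_label: str = "custom"


@dataclass
class GeneFamily:
    tree: ChronoTree  # tips named taxon__c1 / taxon__c2
    presence: pd.DataFrame  # index taxon, columns copy1/copy2 (bool)
    scenario: GeneFamilyScenario


def simulate_gene_family(
    species: ChronoTree, scenario: GeneFamilyScenario, seed: int = 0
) -> GeneFamily:
    """Embed a duplication/loss/LGT scenario in the species tree.

    The gene tree follows the species tree; a duplication on branch b
    yields two copies in all descendants of b (minus losses); a lateral
    transfer re-attaches the recipient clade's copy inside the donor
    lineage at the event time.
    """
    sp = species
    losses = set(scenario.loss_branches)
    dup = scenario.duplication_branch
    if dup is not None and dup != sp.root:
        if dup not in set(sp.branches()):
            raise ValueError(f"duplication branch {dup} does not exist")
    dup_time = scenario.duplication_time
    if dup is not None and dup_time is None:
        if dup == sp.root:
            dup_time = sp.root_age * 1.25
        else:
            dup_time = 0.5 * (sp.ages[sp.parent[dup]] + sp.ages[dup])

    below_dup = (
        set(range(sp.n_nodes))
        if dup == sp.root
        else (set() if dup is None else {dup} | _descendants(sp, dup))
    )
    for copy, branch in losses:
        if copy not in (1, 2):
            raise ValueError("copies are numbered 1 and 2")
        if copy == 2 and branch not in below_dup:
            raise ValueError(
                f"loss of copy 2 on branch {branch}: copy 2 does not exist there"
            )
        for copy2, other in losses:
            if copy2 == copy and other != branch and _is_ancestor(sp, other, branch):
                raise ValueError(
                    f"copy {copy} already lost above branch {branch}"
                )

    recipients: dict[tuple[int, int], float] = {}
    donor_map: dict[tuple[int, int], list[LgtEvent]] = {}
    for ev in scenario.lgt_events:
        dur_lo, dur_hi = _branch_span(sp, ev.recipient_branch)
        don_lo, don_hi = _branch_span(sp, ev.donor_branch)
        if not (dur_lo <= ev.time <= dur_hi and don_lo <= ev.time <= don_hi):
            raise ValueError(
                f"LGT time {ev.time} outside both branches' durations"
            )
        recipients[(ev.copy, ev.recipient_branch)] = ev.time
        dcopy = ev.donor_copy if ev.donor_copy is not None else ev.copy
        donor_map.setdefault((dcopy, ev.donor_branch), []).append(ev)

    def grow(sp_node: int, copy: int, from_age: float, via_lgt: bool = False):
        if (copy, sp_node) in losses:
            return None
        if not via_lgt and (copy, sp_node) in recipients:
            return None  # vertical lineage replaced by the transfer
        events: list[tuple[float, str, object]] = []
        if copy == 1 and dup is not None and sp_node == dup and dup_time < from_age:
            events.append((dup_time, "dup", None))
        for ev in donor_map.get((copy, sp_node), []):
            if ev.time < from_age:
                events.append((ev.time, "lgt", ev))
        events.sort(key=lambda e: -e[0])
        if events:
            age, kind, payload = events[0]
            donor_map_backup = None
            if kind == "dup":
                left = grow_rest(sp_node, 1, age, events[1:], via_lgt)
                right = grow_rest(sp_node, 2, age, [], via_lgt)
            else:
                ev = payload
                left = grow_rest(sp_node, copy, age, events[1:], via_lgt)
                right = grow(ev.recipient_branch, ev.copy, age, via_lgt=True)
            kids = [k for k in (left, right) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return {"age": age, "children": kids, "label": None}
        return grow_rest(sp_node, copy, from_age, [], via_lgt)

    def grow_rest(sp_node, copy, from_age, remaining, via_lgt):
        if remaining:
            age, kind, payload = remaining[0]
            if kind == "dup":
                left = grow_rest(sp_node, 1, age, remaining[1:], via_lgt)
                right = grow_rest(sp_node, 2, age, [], via_lgt)
            else:
                ev = payload
                left = grow_rest(sp_node, copy, age, remaining[1:], via_lgt)
                right = grow(ev.recipient_branch, ev.copy, age, via_lgt=True)
            kids = [k for k in (left, right) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return {"age": age, "children": kids, "label": None}
        # reach the bottom of this species branch
        if sp_node < sp.n_tips:
            return {
                "age": 0.0,
                "children": None,
                "label": f"{sp.labels[sp_node]}__c{copy}",
            }
        kids = [grow(c, copy, sp.ages[sp_node]) for c in sp.children[sp_node]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return {"age": sp.ages[sp_node], "children": kids, "label": None}

    if dup == sp.root:
        left = grow_rest(sp.root, 1, dup_time, [], False)
        right = grow_rest(sp.root, 2, dup_time, [], False)
        kids = [k for k in (left, right) if k is not None]
        root_node = (
            kids[0]
            if len(kids) == 1
            else {"age": dup_time, "children": kids, "label": None}
        )
    else:
        root_node = grow_rest(sp.root, 1, np.inf, [], False)
    if root_node is None or root_node["children"] is None:
        raise ValueError("scenario leaves fewer than two gene copies")

    labels, parent, ages = [], [], []

    def emit(node) -> int:
        if node["children"] is None:
            labels.append(node["label"])
        my = None
        kids_ids = []
        if node["children"]:
            kids_ids = [emit(c) for c in node["children"]]
        idx = len(parent)
        parent.append(-1)
        ages.append(node["age"])
        for k in kids_ids:
            parent[k] = idx
        return idx

    # two passes: assign tip ids first so tips occupy 0..n-1
    tips: list[dict] = []

    def collect(node):
        if node["children"] is None:
            tips.append(node)
        else:
            for c in node["children"]:
                collect(c)

    collect(root_node)
    tip_ids = {id(t): i for i, t in enumerate(tips)}
    n_tips = len(tips)
    parent_arr = [-1] * (2 * n_tips - 1)
    ages_arr = [0.0] * (2 * n_tips - 1)
    label_arr = [t["label"] for t in tips]
    nxt = [n_tips]

    def build(node) -> int:
        if node["children"] is None:
            i = tip_ids[id(node)]
            ages_arr[i] = node["age"]
            return i
        i = nxt[0]
        nxt[0] += 1
        ages_arr[i] = node["age"]
        for c in node["children"]:
            j = build(c)
            parent_arr[j] = i
        return i

    root_id = build(root_node)
    parent_arr[root_id] = -1
    gene_tree = ChronoTree(label_arr, parent_arr, ages_arr)

    presence = pd.DataFrame(
        False, index=sp.labels, columns=["copy1", "copy2"], dtype=bool
    )
    for lab in label_arr:
        taxon, copy = lab.rsplit("__c", 1)
        presence.loc[taxon, f"copy{copy}"] = True
    return GeneFamily(tree=gene_tree, presence=presence, scenario=scenario)


def _descendants(tree: ChronoTree, node: int) -> set[int]:
    out, stack = set(), list(tree.children[node])
    while stack:
        x = stack.pop()
        out.add(x)
        stack.extend(tree.children[x])
    return out


def _is_ancestor(tree: ChronoTree, anc: int, node: int) -> bool:
    x = tree.parent[node]
    while x >= 0:
        if x == anc:
            return True
        x = tree.parent[x]
    return False


def _branch_span(tree: ChronoTree, branch: int) -> tuple[float, float]:
    if branch == tree.root:
        return tree.root_age, np.inf
    return float(tree.ages[branch]), float(tree.ages[tree.parent[branch]])


# ---------------------------------------------------------------------------
# pigment profiles


PIGMENT_MASTER_ORDER = [
    # stylised single-cluster layout; strands mirror typical arrangements
    ("cpcB", "+"), ("cpcA", "+"), ("cpcG2", "+"), ("cpcE", "+"), ("cpcF", "+"),
    ("cpeB", "+"), ("cpeA", "+"),
    ("cpeC", "+"), ("cpeD", "+"), ("cpeE", "+"),
    ("cpeS", "+"), ("cpeT", "+"), ("cpeR", "+"),
    ("cpeU", "+"), ("cpeY", "+"), ("cpeZ", "+"),
    ("pebB", "+"), ("pebA", "+"),
    ("rpcB", "+"), ("rpcA", "+"),
    ("ferrochelatase", "-"),
    ("aplA", "+"),
    ("mpeB", "+"), ("mpeA", "+"), ("mpeC", "+"), ("mpeU", "+"), ("mpeV", "+"),
]

MPE_GENES = {"mpeA", "mpeB", "mpeC", "mpeU", "mpeV"}
CPE_SR_GENES = {"cpeS", "cpeR", "rpcA", "rpcB"}
PE_GENES = {
    "cpeA", "cpeB", "cpeC", "cpeD", "cpeE", "cpeS", "cpeT", "cpeR",
    "cpeU", "cpeY", "cpeZ", "pebA", "pebB", "rpcA", "rpcB",
} | MPE_GENES

ANCESTRAL_GENES = {g for g, _ in PIGMENT_MASTER_ORDER}

PIGMENT_EVENTS = {
    "lose_mpe": MPE_GENES,  # Type III -> Type II
    "lose_cpeSR": CPE_SR_GENES,  # Type II -> Type IIB
    "lose_PE": PE_GENES,  # any PE type -> Type I
}


def generate_pigment_profiles(
    species: ChronoTree,
    event_map: list[tuple[int, str]],
    seed: int = 0,
):
    """Propagate a Type III ancestral cluster down the tree under losses.

    ``event_map`` lists (branch id, event) with events from
    ``PIGMENT_EVENTS``.  An event whose target genes are already (even
    partially) lost on that lineage is contradictory and rejected.
    Returns (inventories, truth labels) where inventories is a dict
    taxon -> ordered (gene, strand, position) list.
    """
    from .pigment_and_stats import GeneInventory

    events_by_branch: dict[int, list[str]] = {}
    for branch, ev in event_map:
        if ev not in PIGMENT_EVENTS:
            raise ValueError(f"unknown event {ev!r}")
        if branch == species.root or branch not in set(species.branches()):
            raise ValueError(f"event on non-existent branch {branch}")
        events_by_branch.setdefault(branch, []).append(ev)

    present: dict[int, set[str]] = {species.root: set(ANCESTRAL_GENES)}
    for node in reversed(species.postorder()):  # preorder
        if node == species.root:
            continue
        genes = set(present[species.parent[node]])
        for ev in events_by_branch.get(node, []):
            targets = PIGMENT_EVENTS[ev]
            if not targets <= genes:
                raise ValueError(
                    f"event {ev!r} on branch {node}: target genes already lost"
                )
            genes -= targets
        present[node] = genes

    inventories: dict[str, GeneInventory] = {}
    truth: dict[str, str] = {}
    for i, taxon in enumerate(species.labels):
        genes = present[i]
        rows = [
            (g, strand, pos)
            for pos, (g, strand) in enumerate(PIGMENT_MASTER_ORDER)
            if g in genes
        ]
        inventories[taxon] = GeneInventory(taxon=taxon, genes=rows)
        # truth from the event composition on this lineage, independent of
        # the content-rule cascade in pigment_and_stats
        if not genes & PE_GENES:
            truth[taxon] = "I"
        elif genes & MPE_GENES:
            truth[taxon] = "III"
        elif "cpeS" not in genes:
            truth[taxon] = "IIB"
        else:
            truth[taxon] = "II"
    return inventories, truth


def random_pigment_scenario(
    species: ChronoTree, seed: int, n_events: int | None = None
) -> list[tuple[int, str]]:
    """A random, internally consistent loss-event map."""
    rng = np.random.default_rng(seed)
    branches = species.branches()
    if n_events is None:
        n_events = int(rng.integers(0, 4))
    events: list[tuple[int, str]] = []

    def consistent(candidate: list[tuple[int, str]]) -> bool:
        by_branch: dict[int, list[str]] = {}
        for b, ev in candidate:
            by_branch.setdefault(b, []).append(ev)
        genes_at: dict[int, set[str]] = {species.root: set(ANCESTRAL_GENES)}
        for node in reversed(species.postorder()):  # preorder
            if node == species.root:
                continue
            genes = set(genes_at[species.parent[node]])
            for ev in by_branch.get(node, []):
                if not PIGMENT_EVENTS[ev] <= genes:
                    return False
                genes -= PIGMENT_EVENTS[ev]
            genes_at[node] = genes
        return True

    for _ in range(n_events):
        for _attempt in range(50):
            branch = branches[rng.integers(len(branches))]
            ev = list(PIGMENT_EVENTS)[rng.integers(len(PIGMENT_EVENTS))]
            if consistent(events + [(branch, ev)]):
                events.append((branch, ev))
                break
    return events


# ---------------------------------------------------------------------------
# assembly graphs


def generate_contig_graph(
    n_target_nodes: int,
    n_contaminant_components: int,
    target_depth: float,
    contaminant_depth: float,
    hit_fraction: float,
    seed: int,
    nodes_per_contaminant: int = 5,
    depth_cv: float = 0.08,
):
    """Assembly graph: one connected target component plus contaminants.

    Target node depths spread ~Normal around ``target_depth``;
    contaminant components sit at ``contaminant_depth``.  Core-gene hits
    land only on target nodes, on the stated fraction.  Node lengths are
    drawn log-normally to straddle the 200 bp reporting threshold.
    Returns (graph, truth, hits) with truth mapping node -> 'target' or
    'contaminant'.
    """
    if n_target_nodes < 1:
        raise ValueError("need at least one target node")
    if target_depth <= 0 or contaminant_depth <= 0:
        raise ValueError("depths must be positive")
    if not 0 <= hit_fraction <= 1:
        raise ValueError("hit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    lengths: dict[str, int] = {}
    depths: dict[str, float] = {}
    edges: list[tuple[str, str]] = []
    truth: dict[str, str] = {}

    def draw_length() -> int:
        return max(1, int(rng.lognormal(mean=6.3, sigma=1.0)))

    def add_component(prefix: str, n: int, depth: float, kind: str) -> list[str]:
        names = [f"{prefix}{i}" for i in range(n)]
        for name in names:
            lengths[name] = draw_length()
            depths[name] = float(
                max(depth * 0.05, rng.normal(depth, depth_cv * depth))
            )
            truth[name] = kind
        for i in range(1, n):  # random spanning tree keeps it connected
            j = int(rng.integers(i))
            edges.append((names[j], names[i]))
        return names

    target_names = add_component("node_t", n_target_nodes, target_depth, "target")
    for k in range(n_contaminant_components):
        add_component(
            f"node_c{k}_", nodes_per_contaminant, contaminant_depth, "contaminant"
        )

    n_hits = int(round(hit_fraction * len(target_names)))
    hit_nodes = list(rng.choice(target_names, size=n_hits, replace=False))
    hits = pd.DataFrame(
        {
            "query_id": [f"coreCyOG_{i:03d}" for i in range(len(hit_nodes))],
            "node_id": hit_nodes,
            "pct_identity": rng.uniform(70, 100, size=len(hit_nodes)).round(2),
            "aln_length": rng.integers(80, 300, size=len(hit_nodes)),
            "evalue": 10.0 ** rng.uniform(-60, -15, size=len(hit_nodes)),
        },
        columns=HIT_COLUMNS,
    )
    graph = AssemblyGraph(lengths=lengths, depths=depths, edges=edges)
    return graph, truth, hits


# ---------------------------------------------------------------------------
# duplication-vs-LGT study generator (two homologous subunits)


@dataclass
class DuplicationStudy:
    """A synthetic alpha/beta-subunit gene superfamily for hypothesis testing.

    The two subunit halves mirror an ancient subunit duplication (the
    root of the supertree separates all alpha from all beta tips); each
    half carries the focal cpe/mpe scenario.
    """

    alignment: Alignment
    tree: ChronoTree
    tip_groups: dict[str, set[str]]
    species: ChronoTree
    synpro_labels: list[str]
    scenario: GeneFamilyScenario


def _find_clade_of_size(tree: ChronoTree, size: int) -> int | None:
    for node in tree.internal_nodes():
        if node != tree.root and len(tree.tips_below(node)) == size:
            return node
    return None


def simulate_duplication_study(
    scenario_kind: str,
    seed: int,
    n_species: int = 8,
    synpro_size: int = 4,
    root_age: float = 1000.0,
    birth: float = 0.003,
    death: float = 0.0,
    rate: float = 5e-4,
    n_sites: int = 300,
    model: SubstitutionModel | None = None,
) -> DuplicationStudy:
    """Generate the alignment behind the duplication-vs-LGT hypotheses.

    ``scenario_kind``: 'B' plants a cpe->mpe duplication on the stem of
    the picocyanobacteria-analogue clade; 'C' plants a lateral transfer
    of the gene from an outgroup donor lineage onto that stem instead.
    One subunit-level duplication above the root doubles the family into
    alpha and beta halves sharing the same history.
    """
    from .models import jc_like

    if scenario_kind not in ("B", "C"):
        raise ValueError("scenario_kind must be 'B' or 'C'")
    if model is None:
        from .alignment import AA_ALPHABET

        # the real subunits are proteins; 20 states hold deep signal far
        # longer than nucleotides at the same substitution load
        model = jc_like(AA_ALPHABET)
    rng = np.random.default_rng(seed)

    # the planted event must be temporally resolvable: a duplication or
    # transfer squeezed onto a very short stem (or attached right next to
    # the root) leaves no sequence signal for any method to recover
    min_stem = 0.15 * root_age
    min_witness = 0.20 * root_age
    for _attempt in range(500):
        sp = simulate_species_tree(
            n_species, birth, death, root_age, seed=int(rng.integers(2**31))
        )
        synpro_node = _find_clade_of_size(sp, synpro_size)
        if synpro_node is None:
            continue
        stem_lo = float(sp.ages[synpro_node])
        stem_hi = float(sp.ages[sp.parent[synpro_node]])
        if stem_hi - stem_lo < min_stem:
            continue
        if scenario_kind == "B":
            scenario = GeneFamilyScenario(
                duplication_branch=synpro_node, truth_label="B"
            )
            break
        # 'C': need a donor branch outside the clade overlapping the stem in time
        inside = {synpro_node} | _descendants(sp, synpro_node)
        anc = set()
        x = synpro_node
        while sp.parent[x] >= 0:
            x = int(sp.parent[x])
            anc.add(x)
        donors = []
        for b in sp.branches():
            if b in inside or b in anc:
                continue
            lo, hi = _branch_span(sp, b)
            olo, ohi = max(lo, stem_lo), min(hi, stem_hi)
            if ohi <= olo:
                continue
            tau_b = float(olo + 0.1 * (ohi - olo))
            witness = hi - tau_b  # donor-lineage span above the attachment
            if witness < min_witness:
                continue
            depth = 0
            x = b
            while sp.parent[x] >= 0:
                depth += 1
                x = int(sp.parent[x])
            donors.append((depth, b, tau_b))
        if not donors:
            continue
        # prefer deeply nested donors: a transfer from a root-adjacent
        # lineage is nearly indistinguishable from an ancient origin
        max_depth = max(d for d, *_ in donors)
        deep = [d for d in donors if d[0] == max_depth]
        _, b, tau = deep[int(rng.integers(len(deep)))]
        scenario = GeneFamilyScenario(
            duplication_branch=None,
            lgt_events=[
                LgtEvent(
                    donor_branch=b,
                    recipient_branch=synpro_node,
                    copy=2,
                    time=tau,
                    donor_copy=1,
                )
            ],
            truth_label="C",
        )
        break
    else:
        raise RuntimeError("could not draw a species tree fitting the scenario")

    fam = simulate_gene_family(sp, scenario, seed=int(rng.integers(2**31)))
    synpro_labels = sorted(sp.labels[i] for i in sp.tips_below(synpro_node))

    def half_newick(subunit: str) -> str:
        nwk = fam.tree.newick().rstrip(";")
        for taxon in fam.tree.labels:
            sp_name, copy = taxon.rsplit("__c", 1)
            gene = "cpe" if copy == "1" else "mpe"
            nwk = nwk.replace(f"{taxon}:", f"{gene}{subunit}_{sp_name}:")
        return nwk

    stem = fam.tree.root_age
    total_newick = f"({half_newick('A')}:{stem:.10g},{half_newick('B')}:{stem:.10g});"
    total = ChronoTree.from_newick(total_newick)

    sim = simulate_sequences(
        total, model, n_sites, seed=int(rng.integers(2**31)), branch_scale=rate
    )
    groups: dict[str, set[str]] = {
        "cpeA_all": set(),
        "cpeB_all": set(),
        "mpeA": set(),
        "mpeB": set(),
        "cpeA_synpro": set(),
        "cpeB_synpro": set(),
    }
    for tip in total.labels:
        gene_sub, sp_name = tip.split("_", 1)
        gene, sub = gene_sub[:3], gene_sub[3]
        if gene == "cpe":
            groups[f"cpe{sub}_all"].add(tip)
            if sp_name in synpro_labels:
                groups[f"cpe{sub}_synpro"].add(tip)
        else:
            groups[f"mpe{sub}"].add(tip)
    return DuplicationStudy(
        alignment=sim.alignment,
        tree=total,
        tip_groups=groups,
        species=sp,
        synpro_labels=synpro_labels,
        scenario=scenario,
    )
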