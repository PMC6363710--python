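"""Phycobilisome pigment-cluster typing, gene loss/LGT reconstruction,
and comparative genome statistics.

Pigment types are called from gene content of the phycobilisome rod
cluster: Type I has only phycocyanin (cpcBA); Types II, IIB and III all
carry phycoerythrin-I (cpeBA); Type III additionally carries
phycoerythrin-II (mpeBA, with linkers mpeC/mpeU as supporting
evidence); Type II has the full cpeS/cpeT/cpeR lyase set while Type IIB
retains only cpeT (with a cpcBA-aplA arrangement and a ferrochelatase on
the opposite strand as supporting arrangement evidence).

Gene histories are reconstructed under Dollo parsimony (a single gain at
the MRCA of the present taxa, any number of losses below it), and
lateral transfers are flagged where a taxon's gene-tree sister group is
disjoint from its species-tree sister group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chronotree import ChronoTree

PANEL_16 = [
    "aplA", "cpcA", "cpcB", "cpcG2", "cpeA", "cpeB", "cpeC", "cpeS",
    "cpeT", "cpeY", "cpeZ", "mpeA", "mpeB", "mpeV", "pebA", "pebB",
]

RECOGNIZED_GENES = set(PANEL_16) | {
    "cpeD", "cpeE", "cpeR", "cpeU", "mpeC", "mpeU",
    "rpcA", "rpcB", "cpcE", "cpcF", "ferrochelatase",
}


@dataclass
class GeneInventory:
    """Ordered phycobilisome gene list for one taxon."""

    taxon: str
    genes: list[tuple[str, str, int]]  # (symbol, strand, position)

    def __post_init__(self) -> None:
        positions = [p for _, _, p in self.genes]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for _, strand, _ in self.genes:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")

    @property
    def symbols(self) -> set[str]:
        return {g for g, _, _ in self.genes}

    def has(self, *genes: str) -> bool:
        return set(genes) <= self.symbols


@dataclass
class PigmentType:
    label: str  # I / II / IIB / III / none
    matched_rules: list[str] = field(default_factory=list)
    violated_rules: list[str] = field(default_factory=list)
    supporting: list[str] = field(default_factory=list)


def classify_pigment_type(inv: GeneInventory, strict_arrangement: bool = False) -> PigmentType:
    """Rule cascade on gene content, with arrangement as supporting evidence.

    III: cpeBA and mpeBA; II: cpeBA + cpeS/cpeT/cpeR without mpeBA;
    IIB: cpeBA + cpeT without cpeS/cpeR/mpeBA; I: cpcBA without cpeBA.
    """
    if not inv.genes:
        raise ValueError("empty inventory")
    cpeBA = inv.has("cpeA", "cpeB")
    mpeBA = inv.has("mpeA", "mpeB")
    cpcBA = inv.has("cpcA", "cpcB")
    supporting: list[str] = []
    if cpeBA and mpeBA:
        if inv.has("mpeC"):
            supporting.append("mpeC linker present")
        if inv.has("mpeU"):
            supporting.append("mpeU linker present")
        return PigmentType("III", ["cpeBA", "mpeBA"], [], supporting)
    if cpeBA and inv.has("cpeS", "cpeT", "cpeR") and not mpeBA:
        return PigmentType("II", ["cpeBA", "cpeSTR", "no mpeBA"], [])
    if (
        cpeBA
        and inv.has("cpeT")
        and not inv.has("cpeS")
        and not inv.has("cpeR")
        and not mpeBA
    ):
        arrangement_ok = _cpcba_upstream_of_apla(inv)
        ferro = _ferrochelatase_opposite(inv)
        if arrangement_ok:
            supporting.append("cpcBA upstream of aplA")
        if ferro:
            supporting.append("ferrochelatase on opposite strand")
        if strict_arrangement and not arrangement_ok:
            return PigmentType(
                "none", ["cpeBA", "cpeT only"], ["cpcBA-aplA arrangement absent"]
            )
        return PigmentType("IIB", ["cpeBA", "cpeT only", "no mpeBA"], [], supporting)
    if cpcBA and not cpeBA:
        return PigmentType("I", ["cpcBA", "no cpeBA"], [])
    violated = []
    if not cpcBA:
        violated.append("cpcBA absent")
    if cpeBA:
        violated.append("cpeBA present but lyase set matches no type")
    return PigmentType("none", [], violated)


def _cpcba_upstream_of_apla(inv: GeneInventory) -> bool:
    pos = {g: p for g, _, p in inv.genes}
    if not {"cpcA", "cpcB", "aplA"} <= set(pos):
        return False
    return max(pos["cpcA"], pos["cpcB"]) < pos["aplA"]


def _ferrochelatase_opposite(inv: GeneInventory) -> bool:
    strands = {g: s for g, s, _ in inv.genes}
    if "ferrochelatase" not in strands:
        return False
    majority = "+" if sum(1 for _, s, _ in inv.genes if s == "+") >= len(inv.genes) / 2 else "-"
    return strands["ferrochelatase"] != majority


def filter_taxa_by_gene_count(
    inventories: dict[str, GeneInventory],
    gene_panel: list[str] = PANEL_16,
    min_genes: int = 3,
):
    """Exclude taxa holding fewer than ``min_genes`` of the panel."""
    if not gene_panel:
        raise ValueError("empty gene panel")
    panel = set(gene_panel)
    retained, excluded = {}, []
    for taxon, inv in inventories.items():
        count = len(inv.symbols & panel)
        if count < min_genes:
            excluded.append((taxon, count))
        else:
            retained[taxon] = inv
    return retained, excluded


# ---------------------------------------------------------------------------
# Dollo reconstruction


@dataclass
class EventHistory:
    """Single-gain / multiple-loss history for one gene on a species tree."""

    gene: str
    gain_node: int | None
    loss_branches: set[int]
    presence: dict[int, bool]  # ancestral presence per node


def dollo_reconstruct(
    species_tree: ChronoTree, presence: dict[str, bool], gene: str = "gene"
) -> EventHistory:
    """Gain at the MRCA of present tips; minimal losses explaining absences.

    Losses are the stems of the maximal all-absent subtrees below the
    gain node; this is the unique minimum-loss single-gain history.
    """
    missing = set(species_tree.labels) - set(presence)
    if missing:
        raise ValueError(f"presence undefined for tips: {sorted(missing)}")
    present_tips = [t for t in species_tree.labels if presence[t]]
    if not present_tips:
        return EventHistory(gene, None, set(), {n: False for n in range(species_tree.n_nodes)})
    gain = species_tree.mrca(present_tips)

    any_present: dict[int, bool] = {}
    for node in species_tree.postorder():
        if node < species_tree.n_tips:
            any_present[node] = presence[species_tree.labels[node]]
        else:
            any_present[node] = any(any_present[c] for c in species_tree.children[node])

    in_gain = {gain} | _descendant_set(species_tree, gain)
    losses = {
        node
        for node in in_gain
        if not any_present[node]
        and node != gain
        and any_present.get(int(species_tree.parent[node]), False)
        and int(species_tree.parent[node]) in in_gain
    }
    state: dict[int, bool] = {}
    for node in reversed(species_tree.postorder()):  # preorder
        if node not in in_gain:
            state[node] = False
        elif node in losses:
            state[node] = False
        elif node == gain:
            state[node] = True
        else:
            state[node] = state[int(species_tree.parent[node])]
    return EventHistory(gene, gain, losses, state)


def _descendant_set(tree: ChronoTree, node: int) -> set[int]:
    out, stack = set(), list(tree.children[node])
    while stack:
        x = stack.pop()
        out.add(x)
        stack.extend(tree.children[x])
    return out


# ---------------------------------------------------------------------------
# LGT conflict detection


def _sister_set(tree: ChronoTree, taxon: str, universe: set[str]) -> set[str]:
    """Tips of the nearest non-empty sister group of ``taxon`` within
    ``universe`` (walking rootward until one exists)."""
    if taxon not in tree.labels:
        raise ValueError(f"taxon {taxon!r} missing from tree")
    tip = tree.labels.index(taxon)
    node = tip
    seen = {taxon}
    while tree.parent[node] >= 0:
        parent = int(tree.parent[node])
        sibs = set()
        for c in tree.children[parent]:
            if c != node:
                sibs |= {tree.labels[i] for i in tree.tips_below(c)}
        cand = (sibs & universe) - seen
        if cand:
            return cand
        seen |= sibs
        node = parent
    return set()


def detect_lgt_conflict(
    gene_tree: ChronoTree,
    species_tree: ChronoTree,
    focal_taxa: list[str],
) -> dict[str, dict]:
    """Flag taxa whose gene-tree sister group contradicts the species tree.

    A focal taxon is flagged when its gene-tree sister group and its
    species-tree sister group (both restricted to taxa shared by the two
    trees) are disjoint.
    """
    common = set(gene_tree.labels) & set(species_tree.labels)
    flags: dict[str, dict] = {}
    for taxon in focal_taxa:
        if taxon not in gene_tree.labels or taxon not in species_tree.labels:
            raise ValueError(f"focal taxon {taxon!r} missing from a tree")
        gene_sis = _sister_set(gene_tree, taxon, common)
        sp_sis = _sister_set(species_tree, taxon, common)
        conflict = bool(gene_sis) and bool(sp_sis) and not (gene_sis & sp_sis)
        if conflict:
            flags[taxon] = {
                "gene_tree_sister": sorted(gene_sis),
                "species_tree_sister": sorted(sp_sis),
            }
    return flags


# ---------------------------------------------------------------------------
# genome statistics


def gc_content(sequences) -> float:
    """GC fraction over unambiguous A/C/G/T positions only."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous nucleotides in input")
    return gc / (gc + at)


def genome_size(sequences) -> int:
    """Total length in bp, ambiguous positions included."""
    if isinstance(sequences, str):
        sequences = [sequences]
    total = sum(len(s) for s in sequences)
    if total == 0:
        raise ValueError("empty input")
    return total


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction; returns (H, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    h, p = sps.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def genome_stats_table(
    genomes: dict[str, dict[str, str]], clades: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-taxon genome size and GC content (Mbp and fraction)."""
    rows = []
    for taxon, seqs in genomes.items():
        size = genome_size(list(seqs.values()))
        rows.append(
            {
                "taxon": taxon,
                "size_bp": size,
                "size_mbp": size / 1e6,
                "gc": gc_content(list(seqs.values())),
                "clade": (clades or {}).get(taxon, ""),
            }
        )
    return pd.DataFrame(rows)
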