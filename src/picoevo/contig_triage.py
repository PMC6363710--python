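"""Assembly-graph contig triage: separating target cyanobacterial nodes
from contaminant contigs of co-cultured organisms.

Non-axenic cultures yield assemblies mixing the target genome with
commensal biota.  Triage applies four rules in order: (1) flag nodes
carrying hits from core cyanobacterial proteins at a strict e-value
threshold; (2) retain connected components containing flagged nodes,
keeping only nodes of similar read depth (within a fold tolerance of
the component's flagged-node median); (3) remove every node with read
depth below half the mean depth of the provisionally retained set;
(4) drop contigs shorter than 200 bp.

Unconnected nodes whose evidence is mixed (a hit but discordant depth,
or concordant depth but no hit) cannot be resolved without an external
database search; they are labelled ``ambiguous`` and excluded from the
retained set unless ``keep_ambiguous`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_DEPTH_TOLERANCE = 2.0
MIN_CONTIG_LENGTH = 200

HIT_COLUMNS = ["query_id", "node_id", "pct_identity", "aln_length", "evalue"]


@dataclass
class AssemblyGraph:
    """Nodes with length (bp) and mean read depth, plus undirected edges."""

    lengths: dict[str, int]
    depths: dict[str, float]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for n, ln in self.lengths.items():
            if ln < 1:
                raise ValueError(f"node {n!r} has length {ln} < 1 bp")
        for n, d in self.depths.items():
            if d <= 0:
                raise ValueError(f"node {n!r} has non-positive depth {d}")
        if set(self.lengths) != set(self.depths):
            raise ValueError("lengths and depths must cover the same nodes")
        for u, v in self.edges:
            if u not in self.lengths or v not in self.lengths:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")

    @property
    def nodes(self) -> list[str]:
        return list(self.lengths)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class TriageReport:
    labels: dict[str, str]  # retained / removed_depth / removed_length / removed_no_evidence / ambiguous
    retained: set[str]
    mean_retained_depth: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            counts: dict[str, int] = {}
            for lab in self.labels.values():
                counts[lab] = counts.get(lab, 0) + 1
            self.counts = counts

    def to_frame(self, graph: AssemblyGraph) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.labels),
                "label": list(self.labels.values()),
                "depth": [graph.depths[n] for n in self.labels],
                "length": [graph.lengths[n] for n in self.labels],
            }
        )


def flag_core_hits(
    graph: AssemblyGraph, hits: pd.DataFrame, evalue_max: float = DEFAULT_EVALUE_MAX
) -> set[str]:
    """Nodes with at least one core-protein hit at evalue <= threshold."""
    if hits.empty:
        return set()
    unknown = set(hits["node_id"]) - set(graph.lengths)
    if unknown:
        raise ValueError(f"hit table references unknown node(s): {sorted(unknown)}")
    ok = hits[hits["evalue"] <= evalue_max]
    return set(ok["node_id"])


def retain_components(
    graph: AssemblyGraph,
    flagged: set[str],
    depth_tolerance: float = DEFAULT_DEPTH_TOLERANCE,
) -> set[str]:
    """Provisionally retain hit-bearing components at similar read depth.

    A component qualifies iff it holds >=1 flagged node; within it, a node
    is kept when its depth is within ``depth_tolerance``-fold of the median
    depth of the component's flagged nodes.
    """
    if not flagged <= set(graph.lengths):
        raise ValueError("flagged set contains unknown nodes")
    if depth_tolerance < 1.0:
        raise ValueError("depth_tolerance must be >= 1 (fold change)")
    g = graph.to_networkx()
    retained: set[str] = set()
    for comp in nx.connected_components(g):
        comp_flagged = comp & flagged
        if not comp_flagged:
            continue
        med = float(np.median([graph.depths[n] for n in comp_flagged]))
        for n in comp:
            d = graph.depths[n]
            if med / depth_tolerance <= d <= med * depth_tolerance:
                retained.add(n)
    return retained


def depth_filter(
    graph: AssemblyGraph, provisional: set[str], length_weighted: bool = False
) -> set[str]:
    """Drop every graph node below half the provisional-set mean read depth.

    The mean is defined by the provisionally retained (main target) portion
    of the graph; all nodes, including unconnected ones, are assessed
    against it.  Returns the passing nodes (strict less-than removal).
    """
    if not provisional:
        raise ValueError("provisional set is empty; mean depth undefined")
    if length_weighted:
        w = np.array([graph.lengths[n] for n in provisional], dtype=float)
        d = np.array([graph.depths[n] for n in provisional])
        mean = float(np.average(d, weights=w))
    else:
        mean = float(np.mean([graph.depths[n] for n in provisional]))
    return {n for n in graph.nodes if not graph.depths[n] < 0.5 * mean}


def length_filter(graph: AssemblyGraph, nodes: set[str]) -> set[str]:
    """Drop contigs shorter than 200 bp (strict less-than)."""
    return {n for n in nodes if graph.lengths[n] >= MIN_CONTIG_LENGTH}


def triage(
    graph: AssemblyGraph,
    hits: pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    depth_tolerance: float = DEFAULT_DEPTH_TOLERANCE,
    length_weighted_mean: bool = False,
    keep_ambiguous: bool = False,
) -> TriageReport:
    """Apply flag -> retain -> depth -> length, labelling every node."""
    flagged = flag_core_hits(graph, hits, evalue_max)
    provisional = retain_components(graph, flagged, depth_tolerance)
    g = graph.to_networkx()
    degree = dict(g.degree())
    # the "main portion" whose mean depth anchors the filter is connected;
    # unconnected nodes are screened separately against that mean
    main = {n for n in provisional if degree.get(n, 0) > 0}

    labels: dict[str, str] = {}
    if main:
        depth_pass = depth_filter(graph, main, length_weighted_mean)
    else:
        depth_pass = set()
    after_depth = main & depth_pass
    unconnected_ok = {
        n
        for n in graph.nodes
        if degree.get(n, 0) == 0 and n in flagged and n in depth_pass
    }
    after_length = length_filter(graph, after_depth | unconnected_ok)
    in_flagged_component: set[str] = set()
    for comp in nx.connected_components(g):
        if comp & flagged and len(comp) > 1:
            in_flagged_component |= comp

    for n in graph.nodes:
        if n in after_length:
            labels[n] = "retained"
        elif n in after_depth or n in unconnected_ok:
            labels[n] = "removed_length"
        elif n in main:
            labels[n] = "removed_depth"
        elif degree.get(n, 0) == 0 and (n in flagged) != (n in depth_pass):
            # one line of evidence only: these belong in a manual screen
            # against an external database, not in the automated call
            labels[n] = "ambiguous"
        elif n in in_flagged_component:
            labels[n] = "removed_depth"  # excluded by the similar-depth rule
        else:
            labels[n] = "removed_no_evidence"

    retained = {n for n, lab in labels.items() if lab == "retained"}
    if keep_ambiguous:
        ambiguous = {
            n
            for n, lab in labels.items()
            if lab == "ambiguous" and graph.lengths[n] >= MIN_CONTIG_LENGTH
        }
        retained |= ambiguous
    mean_ret = (
        float(np.mean([graph.depths[n] for n in retained])) if retained else float("nan")
    )
    return TriageReport(labels=labels, retained=retained, mean_retained_depth=mean_ret)


# ---------------------------------------------------------------------------
# GFA / BLAST-TSV plumbing


def read_gfa(path) -> AssemblyGraph:
    """GFA v1 subset: S lines with LN:i: and DP:f: tags, L lines for edges."""
    lengths: dict[str, int] = {}
    depths: dict[str, float] = {}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                name, seq = fields[1], fields[2]
                ln = len(seq) if seq != "*" else None
                dp = None
                for tag in fields[3:]:
                    if tag.startswith("LN:i:"):
                        ln = int(tag[5:])
                    elif tag.startswith("DP:f:"):
                        dp = float(tag[5:])
                if ln is None or dp is None:
                    raise ValueError(f"S-line for {name!r} lacks LN/DP tags")
                lengths[name] = ln
                depths[name] = dp
            elif fields[0] == "L":
                edges.append((fields[1], fields[3]))
    return AssemblyGraph(lengths=lengths, depths=depths, edges=edges)


def write_gfa(graph: AssemblyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for n in graph.nodes:
            fh.write(f"S\t{n}\t*\tLN:i:{graph.lengths[n]}\tDP:f:{graph.depths[n]:.4f}\n")
        for u, v in graph.edges:
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\n")


def read_hits_tsv(path) -> pd.DataFrame:
    """BLAST outfmt-6-style TSV: query, subject(node), identity, length, evalue.

    A header line (as written by the simulators) is detected and skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = pd.read_csv(path, sep="\t", header=0)
        df.columns = list(df.columns)
        return df[HIT_COLUMNS] if set(HIT_COLUMNS) <= set(df.columns) else df
    if df.shape[1] == 5:
        df.columns = HIT_COLUMNS
    elif df.shape[1] >= 12:  # full outfmt 6: qseqid sseqid pident length ... evalue bitscore
        df = df.iloc[:, [0, 1, 2, 3, 10]]
        df.columns = HIT_COLUMNS
    else:
        raise ValueError("unrecognised hit table layout")
    return df
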