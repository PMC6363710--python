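"""Aligned character matrices and partition bookkeeping.

An :class:`Alignment` is an ordered mapping taxon -> residue string over a
declared alphabet; characters outside the alphabet (gaps ``-``, ``?``,
ambiguity codes) are treated as missing data by the likelihood machinery.
A :class:`PartitionedAlignment` adds disjoint, covering column ranges with
one substitution-model binding and one rate multiplier per partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
BINARY_ALPHABET = "01"


@dataclass
class Alignment:
    """Equal-length aligned sequences over one alphabet."""

    sequences: dict[str, str]
    alphabet: str = NT_ALPHABET

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_sites(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    def encode(self, taxa_order: Sequence[str] | None = None) -> np.ndarray:
        """Integer-encode: state index, or -1 for missing/gap characters."""
        order = list(taxa_order) if taxa_order is not None else self.taxa
        lookup = {c: i for i, c in enumerate(self.alphabet)}
        lookup.update({c.lower(): i for i, c in enumerate(self.alphabet)})
        out = np.full((len(order), self.n_sites), -1, dtype=np.int64)
        for row, taxon in enumerate(order):
            seq = self.sequences[taxon]
            for col, ch in enumerate(seq):
                out[row, col] = lookup.get(ch, -1)
        return out

    def subset_columns(self, start: int, stop: int) -> "Alignment":
        return Alignment(
            {t: s[start:stop] for t, s in self.sequences.items()}, self.alphabet
        )


@dataclass
class Partition:
    name: str
    start: int
    stop: int  # half-open
    alphabet: str = NT_ALPHABET


@dataclass
class PartitionedAlignment:
    """Alignment plus disjoint covering partitions and per-partition rate multipliers."""

    alignment: Alignment
    partitions: list[Partition]
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted((p.start, p.stop) for p in self.partitions)
        pos = 0
        empty_ok = self.alignment.n_sites == 0
        for start, stop in spans:
            if start != pos or (stop <= start and not empty_ok):
                raise ValueError("partitions must be disjoint and covering")
            pos = stop
        if pos != self.alignment.n_sites:
            raise ValueError(
                f"partitions cover {pos} of {self.alignment.n_sites} columns"
            )
        if not self.rate_multipliers:
            self.rate_multipliers = {p.name: 1.0 for p in self.partitions}
        mults = np.array([self.rate_multipliers[p.name] for p in self.partitions])
        if np.any(mults <= 0):
            raise ValueError("rate multipliers must be positive")

    @property
    def taxa(self) -> list[str]:
        return self.alignment.taxa

    def partition_alignment(self, name: str) -> Alignment:
        part = next(p for p in self.partitions if p.name == name)
        sub = self.alignment.subset_columns(part.start, part.stop)
        sub.alphabet = part.alphabet
        return sub


def single_partition(aln: Alignment, name: str = "all") -> PartitionedAlignment:
    return PartitionedAlignment(
        aln, [Partition(name, 0, aln.n_sites, aln.alphabet)]
    )


def concatenate(named: Mapping[str, Alignment]) -> PartitionedAlignment:
    """Concatenate per-gene alignments into one partitioned matrix.

    Taxa are united across inputs; a taxon absent from a gene is padded
    with gaps over that gene's columns.  A taxon occurring twice within
    one input with conflicting sequences is rejected upstream (dict keys
    are unique here, so the conflict surfaces when callers merge rows).
    """
    if not named:
        raise ValueError("no alignments to concatenate")
    all_taxa: list[str] = []
    for aln in named.values():
        for t in aln.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    parts: list[Partition] = []
    merged: dict[str, list[str]] = {t: [] for t in all_taxa}
    pos = 0
    for name, aln in named.items():
        n = aln.n_sites
        parts.append(Partition(name, pos, pos + n, aln.alphabet))
        for t in all_taxa:
            merged[t].append(aln.sequences.get(t, "-" * n))
        pos += n
    seqs = {t: "".join(chunks) for t, chunks in merged.items()}
    return PartitionedAlignment(Alignment(seqs, named[next(iter(named))].alphabet), parts)


def read_fasta(path) -> Alignment:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return Alignment(seqs)


def write_fasta(aln: Alignment | Mapping[str, str], path) -> None:
    seqs = aln.sequences if isinstance(aln, Alignment) else aln
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def compress_patterns(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (patterns[n_taxa, n_pat], weights)."""
    cols, counts = np.unique(encoded.T, axis=0, return_counts=True)
    return cols.T.copy(), counts.astype(float)
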