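"""CDS ingestion, filtering, codon counting and synonymous-codon runs.

The observables of all three inference methods come from here: per-family
codon counts over the whole corpus, per-gene ordered runs of synonymous
codons (consecutive occurrences of one amino acid, regardless of how far
apart they sit in the gene), and the matrix of consecutive synonymous codon
pairs.  Runs never cross gene boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .code_tables import (
    AminoAcidFamily,
    GeneticCode,
    RNA_BASES,
    normalize_rna,
)


@dataclass(frozen=True)
class FilterPolicy:
    """Sequence-quality filters applied before any counting.

    Genes shorter than ``min_length_aa`` amino acids (terminal stop
    excluded), with internal stops, ambiguous nucleotides, or a length not
    divisible by three (the observable proxy for programmed frameshifts in
    plain FASTA) are discarded.  ``min_instances_for_pairs`` governs which
    genes contribute synonymous runs for a given amino acid.
    """

    min_length_aa: int = 50
    reject_internal_stops: bool = True
    reject_ambiguous: bool = True
    reject_non_triplet: bool = True
    min_instances_for_pairs: int = 3

    def __post_init__(self) -> None:
        if self.min_length_aa < 0 or self.min_instances_for_pairs < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class Gene:
    """A retained coding sequence as a tuple of RNA codons (stop stripped)."""

    id: str
    codons: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class RejectionReport:
    """Per-record filter outcome; reason counts partition the input."""

    retained: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {"retained": self.retained}
        for _, reason in self.rejections:
            out[reason] = out.get(reason, 0) + 1
        return out

    @property
    def total(self) -> int:
        return self.retained + len(self.rejections)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("record\treason\n")
            for rec_id, reason in self.rejections:
                handle.write(f"{rec_id}\t{reason}\n")


def _classify(seq: str, code: GeneticCode, policy: FilterPolicy) -> tuple[str | None, tuple[str, ...]]:
    """Return (rejection reason or None, codons) for one normalized sequence."""
    if policy.reject_non_triplet and len(seq) % 3 != 0:
        return "non_triplet", ()
    if len(seq) % 3 != 0:
        seq = seq[: len(seq) - len(seq) % 3]
    if policy.reject_ambiguous and (set(seq) - RNA_BASES):
        return "ambiguous", ()
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]  # terminal stop is stripped, not counted
    if policy.reject_internal_stops and any(c in code.stop_codons for c in codons):
        return "internal_stop", ()
    if len(codons) < policy.min_length_aa:
        return "short", ()
    return None, codons


def load_cds(
    source: str | Path | Iterable[SeqRecord],
    code: GeneticCode,
    policy: FilterPolicy | None = None,
) -> tuple[list[Gene], RejectionReport]:
    """Read CDS FASTA (path or SeqRecords), filter, and codonize.

    Input may be DNA or RNA, any case; sequences are normalized to
    uppercase RNA.  Each record is either retained as a :class:`Gene` or
    rejected with a reason code (``non_triplet``, ``ambiguous``,
    ``internal_stop``, ``short``).
    """
    if policy is None:
        policy = FilterPolicy()
    if isinstance(source, (str, Path)):
        records: Iterable[SeqRecord] = SeqIO.parse(str(source), "fasta")
    else:
        records = source
    genes: list[Gene] = []
    report = RejectionReport()
    for rec in records:
        seq = normalize_rna(str(rec.seq))
        reason, codons = _classify(seq, code, policy)
        if reason is None:
            genes.append(Gene(rec.id, codons))
            report.retained += 1
        else:
            report.rejections.append((rec.id, reason))
    return genes, report


@dataclass(frozen=True)
class CodonCounts:
    """Corpus-wide codon tally, queryable per amino-acid family."""

    counts: Mapping[str, int]

    def count(self, codon: str) -> int:
        return int(self.counts.get(codon, 0))

    def family_counts(self, family: AminoAcidFamily) -> dict[str, int]:
        return {c: self.count(c) for c in family.codons}

    def vector(self, family: AminoAcidFamily) -> np.ndarray:
        return np.array([self.count(c) for c in family.codons], dtype=float)

    def total(self, family: AminoAcidFamily) -> int:
        return sum(self.count(c) for c in family.codons)

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "CodonCounts":
        return cls(dict(counts))


def count_codons(genes: Sequence[Gene], code: GeneticCode) -> CodonCounts:
    """Exact codon tally over retained genes (sense codons only)."""
    counts: dict[str, int] = {}
    sense = code.codon_to_aa
    for gene in genes:
        for c in gene.codons:
            if c in sense:
                counts[c] = counts.get(c, 0) + 1
    return CodonCounts(counts)


def write_codon_counts(counts: CodonCounts, code: GeneticCode, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("family\tcodon\tcount\n")
        for codon in sorted(counts.counts):
            aa = code.codon_to_aa.get(codon, "*")
            handle.write(f"{aa}\t{codon}\t{counts.counts[codon]}\n")


@dataclass(frozen=True)
class SynonymousRuns:
    """Per-gene ordered synonymous-codon sequences for one family.

    Each run lists the family's codons in 5'->3' gene order, regardless of
    the spacing between occurrences.  Only genes with at least
    ``min_instances_for_pairs`` occurrences contribute.
    """

    family: AminoAcidFamily
    runs: tuple[tuple[str, tuple[str, ...]], ...]  # (gene_id, codons)

    def __post_init__(self) -> None:
        members = set(self.family.codons)
        for _, run in self.runs:
            if not set(run) <= members:
                raise ValueError("run contains codons outside the family")

    @property
    def sequences(self) -> tuple[tuple[str, ...], ...]:
        return tuple(run for _, run in self.runs)

    def __len__(self) -> int:
        return len(self.runs)


def build_runs(
    genes: Sequence[Gene],
    family: AminoAcidFamily,
    policy: FilterPolicy | None = None,
) -> SynonymousRuns:
    if policy is None:
        policy = FilterPolicy()
    members = set(family.codons)
    runs = []
    for gene in genes:
        run = tuple(c for c in gene.codons if c in members)
        if len(run) >= policy.min_instances_for_pairs:
            runs.append((gene.id, run))
    return SynonymousRuns(family, tuple(runs))


@dataclass(frozen=True)
class PairCountMatrix:
    """Counts of consecutive synonymous codon pairs within runs.

    ``X[i, j]`` counts occurrences of codon i immediately followed (at the
    next instance of the amino acid in the same gene) by codon j, summed
    over all qualifying genes.
    """

    family: AminoAcidFamily
    X: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        k = len(self.family.codons)
        if self.X.shape != (k, k):
            raise ValueError("pair matrix shape must match the family")
        if (self.X < 0).any():
            raise ValueError("pair counts must be non-negative")


def count_pairs(runs: SynonymousRuns) -> PairCountMatrix:
    family = runs.family
    k = len(family.codons)
    index = {c: i for i, c in enumerate(family.codons)}
    X = np.zeros((k, k), dtype=float)
    n_pairs = 0
    for _, run in runs.runs:
        idx = [index[c] for c in run]
        for a, b in zip(idx, idx[1:]):
            X[a, b] += 1
        n_pairs += max(0, len(idx) - 1)
    return PairCountMatrix(family, X, n_pairs)
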