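"""Genetic-code and nucleotide bookkeeping.

Everything downstream works in RNA space (``U`` not ``T``); DNA input is
transliterated on ingestion.  Codons within an amino-acid family are kept in
a fixed canonical order (``U < C < A < G`` at every position) so that all
matrix representations -- reading matrices, emission matrices, pair-count
matrices -- are reproducible and printable in the conventional genetic-code
layout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio.Data import CodonTable
from Bio.Data.IUPACData import protein_letters_3to1

RNA_BASES = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: Canonical base order used for all matrix indexing.
BASE_ORDER = {"U": 0, "C": 1, "A": 2, "G": 3}


class AlphabetError(ValueError):
    """A sequence contains characters outside the RNA alphabet {A,C,G,U}."""


class TrnaTableError(ValueError):
    """A tRNA isoacceptor table could not be parsed or validated."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and transliterate DNA ``T`` to RNA ``U``.

    No alphabet validation is performed here; use :func:`validate_rna` where
    strictness is required (ambiguity codes must survive normalization so the
    corpus filter can reject them with the right reason).
    """
    return seq.upper().replace("T", "U")


def validate_rna(seq: str) -> str:
    seq = normalize_rna(seq)
    bad = set(seq) - RNA_BASES
    if bad:
        raise AlphabetError(f"non-RNA characters {sorted(bad)} in {seq!r}")
    return seq


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"cannot complement {base!r}") from None


def reverse_complement(seq: str) -> str:
    seq = validate_rna(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def cognate_codon(anticodon: str) -> str:
    """Watson-Crick cognate codon of a 5'->3' anticodon.

    Pairing is antiparallel: codon position 3 pairs anticodon position 1
    (the wobble position), so the cognate codon is simply the reverse
    complement, e.g. anticodon ``AGC`` -> codon ``GCU``.
    """
    anticodon = validate_rna(anticodon)
    if len(anticodon) != 3:
        raise AlphabetError(f"anticodon must have length 3, got {anticodon!r}")
    return reverse_complement(anticodon)


def codon_sort_key(codon: str) -> tuple[int, int, int]:
    return tuple(BASE_ORDER[b] for b in codon)  # type: ignore[return-value]


@dataclass(frozen=True)
class GeneticCode:
    """A translation table over the 64 RNA codons.

    ``codon_to_aa`` maps every sense codon to a one-letter amino acid;
    together with ``stop_codons`` it partitions the 64 codons.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        sense = set(self.codon_to_aa)
        if sense & self.stop_codons:
            raise ValueError("sense and stop codons overlap")
        if len(sense) + len(self.stop_codons) != 64:
            raise ValueError("sense + stop codons must partition the 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        """Load an NCBI translation table (default: the standard code)."""
        table = CodonTable.unambiguous_rna_by_id[table_id]
        return cls(
            table_id=table_id,
            codon_to_aa=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
        )

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.codon_to_aa.values())))

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        codons = [c for c, aa in self.codon_to_aa.items() if aa == amino_acid]
        if not codons:
            raise KeyError(f"amino acid {amino_acid!r} not in table {self.table_id}")
        return tuple(sorted(codons, key=codon_sort_key))


@dataclass(frozen=True)
class AminoAcidFamily:
    """The synonymous codons of one amino acid, in canonical order.

    ``box`` is set when the family is one codon box (shared first two codon
    positions); six-codon amino acids (Leu/Ser/Arg in the standard code)
    split into a four-box and a two-box which are analyzed independently.
    """

    amino_acid: str
    codons: tuple[str, ...]
    box: str | None = None

    def __post_init__(self) -> None:
        for c in self.codons:
            validate_rna(c)
            if len(c) != 3:
                raise ValueError(f"bad codon {c!r}")
        if list(self.codons) != sorted(self.codons, key=codon_sort_key):
            raise ValueError("family codons must be in canonical order")
        if self.box is not None and any(not c.startswith(self.box) for c in self.codons):
            raise ValueError(f"codons {self.codons} do not all lie in box {self.box}")

    @property
    def key(self) -> str:
        return f"{self.amino_acid}:{self.box or '*'}"

    def index_of(self, codon: str) -> int:
        return self.codons.index(codon)

    def __len__(self) -> int:
        return len(self.codons)


def family_of(code: GeneticCode, amino_acid: str) -> AminoAcidFamily:
    """All synonymous codons of ``amino_acid``, across boxes."""
    return AminoAcidFamily(amino_acid, code.codons_for(amino_acid))


def family_boxes(code: GeneticCode, amino_acid: str) -> tuple[AminoAcidFamily, ...]:
    """Split an amino acid's codons into codon boxes (shared first two bases)."""
    boxes: dict[str, list[str]] = {}
    for c in code.codons_for(amino_acid):
        boxes.setdefault(c[:2], []).append(c)
    return tuple(
        AminoAcidFamily(amino_acid, tuple(cs), box=prefix)
        for prefix, cs in sorted(boxes.items(), key=lambda kv: codon_sort_key(kv[0] + "U"))
    )


@dataclass(frozen=True)
class TrnaIsoacceptor:
    """One tRNA species: amino acid, anticodon (5'->3'), gene copy number.

    Gene copy number serves as the abundance proxy throughout.  The wobble
    base is the first (5') base of the anticodon; chemically modified wobble
    bases are represented by their unmodified parent.
    """

    amino_acid: str
    anticodon: str
    gene_copy_number: int

    def __post_init__(self) -> None:
        validate_rna(self.anticodon)
        if len(self.anticodon) != 3:
            raise TrnaTableError(f"anticodon must have length 3: {self.anticodon!r}")
        if self.gene_copy_number < 0:
            raise TrnaTableError(
                f"gene copy number must be >= 0, got {self.gene_copy_number}"
            )

    @property
    def wobble_base(self) -> str:
        return self.anticodon[0]

    @property
    def cognate(self) -> str:
        return cognate_codon(self.anticodon)

    @property
    def box_prefix(self) -> str:
        """First two codon positions this tRNA pairs with (Watson-Crick)."""
        return self.cognate[:2]


@dataclass(frozen=True)
class TrnaSet:
    """tRNA isoacceptors of a genome, grouped by amino acid on demand."""

    isoacceptors: tuple[TrnaIsoacceptor, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for t in self.isoacceptors:
            key = (t.amino_acid, t.anticodon)
            if key in seen:
                raise TrnaTableError(f"duplicate isoacceptor {key}")
            seen.add(key)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({t.amino_acid for t in self.isoacceptors}))

    def for_amino_acid(self, amino_acid: str) -> tuple[TrnaIsoacceptor, ...]:
        return tuple(
            sorted(
                (t for t in self.isoacceptors if t.amino_acid == amino_acid),
                key=lambda t: codon_sort_key(t.anticodon),
            )
        )

    def for_family(self, family: AminoAcidFamily) -> tuple[TrnaIsoacceptor, ...]:
        """Isoacceptors whose anticodon positions 2-3 pair with the family's box."""
        prefixes = {c[:2] for c in family.codons}
        return tuple(
            t for t in self.for_amino_acid(family.amino_acid) if t.box_prefix in prefixes
        )

    def __len__(self) -> int:
        return len(self.isoacceptors)


_AA3_TO_1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


def _parse_amino_acid(token: str) -> str:
    token = token.strip()
    if len(token) == 1:
        return token.upper()
    aa = _AA3_TO_1.get(token.upper())
    if aa is None:
        raise TrnaTableError(f"unknown amino acid {token!r}")
    return aa


def parse_trna_table(path: str | Path) -> TrnaSet:
    """Parse a delimited tRNA table: columns amino_acid, anticodon, copies.

    The format emulates Genomic tRNA Database exports: tab- (or whitespace-)
    delimited, optional header line, three-letter or one-letter amino-acid
    names, DNA or RNA anticodons.  Duplicate (amino acid, anticodon) rows
    have their copy numbers summed.
    """
    merged: dict[tuple[str, str], int] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if len(row) == 1:  # fall back to whitespace splitting
                row = row[0].split()
            fields = [f.strip() for f in row if f.strip()]
            if not fields or fields[0].startswith("#"):
                continue
            if lineno == 1 and fields[0].lower() in {"amino_acid", "aa", "amino"}:
                continue
            if len(fields) != 3:
                raise TrnaTableError(f"line {lineno}: expected 3 columns, got {fields}")
            aa = _parse_amino_acid(fields[0])
            try:
                anticodon = validate_rna(fields[1])
            except AlphabetError as exc:
                raise TrnaTableError(f"line {lineno}: {exc}") from None
            try:
                copies = int(fields[2])
            except ValueError:
                raise TrnaTableError(
                    f"line {lineno}: copy number {fields[2]!r} is not an integer"
                ) from None
            if copies < 0:
                raise TrnaTableError(f"line {lineno}: negative copy number {copies}")
            merged[(aa, anticodon)] = merged.get((aa, anticodon), 0) + copies
    return TrnaSet(
        tuple(
            TrnaIsoacceptor(aa, anticodon, copies)
            for (aa, anticodon), copies in sorted(merged.items())
        )
    )


def write_trna_table(trna_set: TrnaSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("amino_acid\tanticodon\tcopies\n")
        for t in trna_set.isoacceptors:
            handle.write(f"{t.amino_acid}\t{t.anticodon}\t{t.gene_copy_number}\n")
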