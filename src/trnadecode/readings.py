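"""Binary anticodon-codon reading hypotheses.

A *reading matrix* is the binary relation between the tRNA isoacceptors of
one amino-acid family and the family's codons: entry (i, j) is 1 iff tRNA i
can decode codon j.  This module represents these hypotheses, enumerates the
full solution space of valid binary matrices, restricts it to the plausible
subset built from experimentally observed wobble behaviour, and provides the
two rule-based baselines (Crick's wobble rules and wobble parsimony).

Cross-box reading is excluded throughout: a tRNA only ever reads codons
whose first two positions are the Watson-Crick partners of its anticodon
positions 2-3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .code_tables import (
    AminoAcidFamily,
    TrnaIsoacceptor,
    complement,
    validate_rna,
)


class InvalidReadingError(ValueError):
    """A reading matrix violates coverage or shape constraints."""


class InfeasibleReadingError(ValueError):
    """No combination of wobble options covers every codon of the family."""

    def __init__(self, family: AminoAcidFamily, uncovered: Sequence[str]):
        self.family = family
        self.uncovered = tuple(uncovered)
        super().__init__(
            f"no plausible reading covers codons {list(uncovered)} of "
            f"family {family.key}"
        )


class SolutionSpaceTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class ReadingMatrix:
    """One binary decoding hypothesis for an amino-acid family.

    Rows are tRNAs (in the given order), columns the family's codons in
    canonical order.  Valid matrices have no all-zero row (every tRNA reads
    something) and no all-zero column (every codon is decodable); rule-based
    baselines may return matrices violating coverage, in which case the
    violations are listed in ``coverage_warnings``.
    """

    family: AminoAcidFamily
    trnas: tuple[TrnaIsoacceptor, ...]
    reads: tuple[tuple[int, ...], ...]
    coverage_warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.trnas):
            raise InvalidReadingError("one row per tRNA required")
        k = len(self.family.codons)
        for row in self.reads:
            if len(row) != k:
                raise InvalidReadingError("one column per codon required")
            if any(v not in (0, 1) for v in row):
                raise InvalidReadingError("entries must be 0 or 1")
        m = self.matrix
        if not self.coverage_warnings:
            if m.shape[0] and (m.sum(axis=1) == 0).any():
                raise InvalidReadingError("every tRNA must read at least one codon")
            if m.shape[0] and (m.sum(axis=0) == 0).any():
                raise InvalidReadingError("every codon must be read by at least one tRNA")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.reads, dtype=int).reshape(len(self.trnas), len(self.family))

    @property
    def bits(self) -> str:
        """Compact row-wise identifier, e.g. ``1100-0011``."""
        return "-".join("".join(str(v) for v in row) for row in self.reads)

    def codons_read_by(self, trna_index: int) -> tuple[str, ...]:
        return tuple(
            c for c, v in zip(self.family.codons, self.reads[trna_index]) if v
        )

    @property
    def assignment(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        """Row-order-independent identity: (anticodon, codons read) pairs."""
        return tuple(
            sorted(
                (t.anticodon, self.codons_read_by(i))
                for i, t in enumerate(self.trnas)
            )
        )

    @classmethod
    def from_codon_sets(
        cls,
        family: AminoAcidFamily,
        trnas: Sequence[TrnaIsoacceptor],
        codon_sets: Sequence[Iterable[str]],
        allow_uncovered: bool = False,
    ) -> "ReadingMatrix":
        rows = []
        for cs in codon_sets:
            cs = set(cs)
            rows.append(tuple(1 if c in cs else 0 for c in family.codons))
        reads = tuple(rows)
        warnings: tuple[str, ...] = ()
        if allow_uncovered:
            warnings = _coverage_warnings(family, trnas, reads)
        return cls(family, tuple(trnas), reads, coverage_warnings=warnings)


def _coverage_warnings(
    family: AminoAcidFamily,
    trnas: Sequence[TrnaIsoacceptor],
    reads: tuple[tuple[int, ...], ...],
) -> tuple[str, ...]:
    m = np.asarray(reads, dtype=int).reshape(len(trnas), len(family))
    warnings = []
    for j, codon in enumerate(family.codons):
        if m.shape[0] == 0 or m[:, j].sum() == 0:
            warnings.append(f"codon {codon} is not read by any tRNA")
    for i, t in enumerate(trnas):
        if m.shape[1] == 0 or m[i, :].sum() == 0:
            warnings.append(f"tRNA {t.anticodon} reads no codon")
    return tuple(warnings)


@dataclass(frozen=True)
class WobbleOptionSet:
    """Allowed codon-third-base sets per anticodon wobble base.

    Encodes which decodings have been observed experimentally: C pairs only
    with G, G constitutively reads the pyrimidines {C, U}, while A and U
    (through their wobble-position modifications) each admit several
    alternative sets.  Every option must contain the Watson-Crick partner of
    the wobble base.
    """

    options: dict[str, tuple[frozenset[str], ...]]

    def __post_init__(self) -> None:
        for base, opts in self.options.items():
            validate_rna(base)
            if not opts:
                raise ValueError(f"empty option list for wobble base {base}")
            partner = complement(base)
            for opt in opts:
                if not opt:
                    raise ValueError(f"empty option set for wobble base {base}")
                if partner not in opt:
                    raise ValueError(
                        f"option {sorted(opt)} for wobble base {base} lacks the "
                        f"Watson-Crick partner {partner}"
                    )
        if self.options.get("C", ()) not in ((frozenset("G"),), ()):
            raise ValueError("C must map only to {G}")
        if self.options.get("G", ()) not in ((frozenset("CU"),), ()):
            raise ValueError("G must map only to {C, U}")

    def for_base(self, base: str) -> tuple[frozenset[str], ...]:
        try:
            return self.options[base]
        except KeyError:
            raise KeyError(f"no wobble options configured for base {base!r}") from None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "WobbleOptionSet":
        return cls(
            {
                base: tuple(frozenset(validate_rna("".join(opt))) for opt in opts)
                for base, opts in mapping.items()
            }
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WobbleOptionSet":
        with open(path) as handle:
            return cls.from_mapping(yaml.safe_load(handle))

    @classmethod
    def default(cls) -> "WobbleOptionSet":
        text = resources.files("trnadecode.data").joinpath("wobble_options.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class SolutionSpace:
    """All valid binary readings of one family, with plausibility flags."""

    family: AminoAcidFamily
    trnas: tuple[TrnaIsoacceptor, ...]
    readings: tuple[ReadingMatrix, ...]
    plausible_flags: tuple[bool, ...]
    trivial: bool = False

    def __post_init__(self) -> None:
        if len(self.readings) != len(self.plausible_flags):
            raise ValueError("one flag per reading required")

    @property
    def plausible(self) -> tuple[ReadingMatrix, ...]:
        return tuple(
            r for r, f in zip(self.readings, self.plausible_flags) if f
        )

    def __len__(self) -> int:
        return len(self.readings)


_MAX_ENUMERATION = 5_000_000


def enumerate_all_readings(
    family: AminoAcidFamily,
    trnas: Sequence[TrnaIsoacceptor],
    options: WobbleOptionSet | None = None,
    require_cognate: bool = False,
) -> SolutionSpace:
    """Enumerate every valid binary reading matrix of a family.

    Valid means: each tRNA reads at least one codon, each codon is read by
    at least one tRNA.  With ``require_cognate=True`` each tRNA whose
    Watson-Crick cognate codon lies in the family must additionally read
    it (a stricter notion of validity; off by default).  Readings that
    additionally arise from a combination of observed wobble options (see
    :func:`plausible_readings`) are flagged plausible.  A single-codon
    family has exactly one reading and is returned with ``trivial=True``.
    """
    if not trnas:
        raise InvalidReadingError("at least one tRNA required")
    trnas = tuple(trnas)
    k = len(family.codons)
    if k == 1:
        reading = ReadingMatrix(family, trnas, tuple((1,) for _ in trnas))
        return SolutionSpace(family, trnas, (reading,), (True,), trivial=True)

    n_rows = (1 << k) - 1
    if n_rows ** len(trnas) > _MAX_ENUMERATION:
        raise SolutionSpaceTooLargeError(
            f"{n_rows ** len(trnas)} candidate matrices for family {family.key}"
        )
    full_mask = (1 << k) - 1
    row_masks = range(1, 1 << k)  # non-empty rows only
    cognate_masks = [0] * len(trnas)
    if require_cognate:
        for i, t in enumerate(trnas):
            if t.cognate in family.codons:
                cognate_masks[i] = 1 << (k - 1 - family.codons.index(t.cognate))
    readings: list[ReadingMatrix] = []
    for combo in itertools.product(row_masks, repeat=len(trnas)):
        if require_cognate and any(
            (m & cm) != cm for m, cm in zip(combo, cognate_masks)
        ):
            continue
        cover = 0
        for m in combo:
            cover |= m
        if cover != full_mask:
            continue
        reads = tuple(
            tuple((m >> (k - 1 - j)) & 1 for j in range(k)) for m in combo
        )
        readings.append(ReadingMatrix(family, trnas, reads))

    try:
        plaus = plausible_readings(family, trnas, options)
        plaus_bits = {r.bits for r in plaus}
    except InfeasibleReadingError:
        plaus_bits = set()
    flags = tuple(r.bits in plaus_bits for r in readings)
    return SolutionSpace(family, trnas, tuple(readings), flags,
                         trivial=len(readings) == 1)


def plausible_readings(
    family: AminoAcidFamily,
    trnas: Sequence[TrnaIsoacceptor],
    options: WobbleOptionSet | None = None,
) -> tuple[ReadingMatrix, ...]:
    """Cross-product of per-tRNA wobble options, restricted to full coverage.

    For each tRNA, every configured option of its wobble base defines the
    set of codons it reads (codons with cognate positions 1-2 and third base
    in the option).  One reading per combination of options; combinations
    leaving a codon unread or a tRNA reading nothing are dropped, and
    duplicate matrices (options indistinguishable within this family) are
    merged.
    """
    if options is None:
        options = WobbleOptionSet.default()
    trnas = tuple(trnas)
    per_trna_rows: list[list[tuple[int, ...]]] = []
    for t in trnas:
        rows = []
        for opt in options.for_base(t.wobble_base):
            row = tuple(
                1 if c[:2] == t.box_prefix and c[2] in opt else 0
                for c in family.codons
            )
            if sum(row) and row not in rows:
                rows.append(row)
        if not rows:
            raise InfeasibleReadingError(family, family.codons)
        per_trna_rows.append(rows)

    k = len(family.codons)
    seen: set[tuple[tuple[int, ...], ...]] = set()
    result: list[ReadingMatrix] = []
    for combo in itertools.product(*per_trna_rows):
        if combo in seen:
            continue
        seen.add(combo)
        if any(sum(combo[i][j] for i in range(len(trnas))) == 0 for j in range(k)):
            continue
        result.append(ReadingMatrix(family, trnas, combo))
    if not result:
        covered = set()
        for rows in per_trna_rows:
            for row in rows:
                covered |= {c for c, v in zip(family.codons, row) if v}
        raise InfeasibleReadingError(
            family, [c for c in family.codons if c not in covered]
        )
    return tuple(result)


#: Crick's wobble rules, with adenine treated as its inosine derivative.
WOBBLE_RULES_ORIGINAL = {
    "A": frozenset("UCA"),  # I:{A,C,U}
    "U": frozenset("AG"),
    "C": frozenset("G"),
    "G": frozenset("CU"),
}
#: Restricted eukaryotic variant: the I:A wobble is disallowed.
WOBBLE_RULES_RESTRICTED = {**WOBBLE_RULES_ORIGINAL, "A": frozenset("UC")}


def wobble_rules_reading(
    family: AminoAcidFamily,
    trnas: Sequence[TrnaIsoacceptor],
    variant: str = "restricted",
) -> ReadingMatrix:
    """Deterministic assignment by Crick's wobble rules.

    ``variant='original'`` applies A:U/C:G/G:{C,U}/U:{A,G} with wobble-A
    treated as inosine (I:{A,C,U}); ``'restricted'`` removes the I:A
    pairing.  Codons left unreadable are reported via
    ``coverage_warnings`` rather than raising.
    """
    if variant == "original":
        rules = WOBBLE_RULES_ORIGINAL
    elif variant == "restricted":
        rules = WOBBLE_RULES_RESTRICTED
    else:
        raise ValueError(f"unknown wobble-rules variant {variant!r}")
    codon_sets = []
    for t in trnas:
        allowed = rules[t.wobble_base]
        codon_sets.append(
            {c for c in family.codons if c[:2] == t.box_prefix and c[2] in allowed}
        )
    return ReadingMatrix.from_codon_sets(family, trnas, codon_sets, allow_uncovered=True)


def wobble_parsimony_reading(
    family: AminoAcidFamily,
    trnas: Sequence[TrnaIsoacceptor],
    eukaryote: bool = True,
) -> ReadingMatrix:
    """Wobble-parsimony assignment (eukaryotes only).

    Three passes: (i) codons with a cognate tRNA get canonical decoding
    only; (ii) codons without a cognate tRNA are assigned by restricted
    wobbling (G:U, A:C, the latter via inosine); (iii) codons still
    unassigned get the extended pairings (A:A, U:G).
    """
    if not eukaryote:
        raise ValueError("Wobble parsimony is only applicable for eukaryotes")
    trnas = tuple(trnas)
    codon_sets: list[set[str]] = [set() for _ in trnas]
    cognates = {t.cognate for t in trnas}

    # pass (i): canonical decoding
    for i, t in enumerate(trnas):
        if t.cognate in family.codons:
            codon_sets[i].add(t.cognate)

    def assign(codon: str, wobble_base: str) -> bool:
        hit = False
        for i, t in enumerate(trnas):
            if t.wobble_base == wobble_base and t.box_prefix == codon[:2]:
                codon_sets[i].add(codon)
                hit = True
        return hit

    # pass (ii): restricted wobbling G:U and A(I):C for cognate-less codons
    orphans = [c for c in family.codons if c not in cognates]
    assigned: set[str] = set()
    for c in orphans:
        if c[2] == "U" and assign(c, "G"):
            assigned.add(c)
        elif c[2] == "C" and assign(c, "A"):
            assigned.add(c)

    # pass (iii): extended pairings A:A and U:G for the remainder
    for c in orphans:
        if c in assigned:
            continue
        if c[2] == "A":
            assign(c, "A")
        elif c[2] == "G":
            assign(c, "U")

    return ReadingMatrix.from_codon_sets(family, trnas, codon_sets, allow_uncovered=True)
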