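"""Block structure in consecutive synonymous codon pairs (the CC method).

Codons decoded by the same tRNA are used in a correlated way at successive
instances of an amino acid, which shows up as blocks of positive z-scores
in the matrix of consecutive-pair counts.  A candidate reading is scored by
summing observed pair counts with sign +1 for codon pairs sharing a tRNA
and -1 otherwise (the diagonal -- plain codon-repetition bias -- is
ignored), subtracting the same sum over expected counts, and standardizing.
The reading with the highest total z-score wins.

Expectations assume independent pair members: with within-family codon
frequencies p_i estimated corpus-wide, E[i,j] = N * p_i * p_j and each cell
is treated as binomial(N, p_i * p_j).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import CodonCounts, PairCountMatrix
from .readings import ReadingMatrix


class DegenerateFamilyError(ValueError):
    """The CC score carries no information (e.g. a single shared block)."""


def expected_pairs(
    counts: CodonCounts, pairs: PairCountMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial expectation and variance for every pair cell.

    Returns (E, V) with ``E = N p_i p_j`` and ``V = N p_i p_j (1 - p_i p_j)``
    where p is the corpus-wide within-family codon frequency and N the
    total pair count.  Zero matrices signal an empty corpus (N = 0).
    """
    k = len(pairs.family.codons)
    total = counts.total(pairs.family)
    N = pairs.n_pairs
    if N == 0 or total == 0:
        return np.zeros((k, k)), np.zeros((k, k))
    p = counts.vector(pairs.family) / total
    pp = np.outer(p, p)
    return N * pp, N * pp * (1.0 - pp)


@dataclass(frozen=True)
class ZMatrix:
    """Standardized deviations of pair counts from independence."""

    family_key: str
    Z: np.ndarray
    E: np.ndarray
    V: np.ndarray
    mask: np.ndarray  # True where V > 0 (Z defined)


def z_matrix(pairs: PairCountMatrix, E: np.ndarray, V: np.ndarray) -> ZMatrix:
    if E.shape != pairs.X.shape or V.shape != pairs.X.shape:
        raise ValueError("shape mismatch")
    mask = V > 0
    Z = np.zeros_like(E)
    Z[mask] = (pairs.X[mask] - E[mask]) / np.sqrt(V[mask])
    return ZMatrix(pairs.family.key, Z, E, V, mask)


def write_z_matrix(z: ZMatrix, codons: Sequence[str], path) -> None:
    with open(path, "w") as handle:
        handle.write("codon\t" + "\t".join(codons) + "\n")
        for codon, row in zip(codons, z.Z):
            handle.write(codon + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")


def block_coefficients(reading: ReadingMatrix) -> np.ndarray:
    """+1 where two codons share at least one decoding tRNA, else -1."""
    m = reading.matrix
    shared = (m.T @ m) > 0
    return np.where(shared, 1.0, -1.0)


@dataclass(frozen=True)
class BlockScore:
    reading: ReadingMatrix
    C: np.ndarray
    s_obs: float
    s_exp: float
    z_total: float
    degenerate: bool = False


def score_reading_cc(
    reading: ReadingMatrix,
    pairs: PairCountMatrix,
    counts: CodonCounts,
) -> BlockScore:
    """Signed off-diagonal pair sum, standardized against independence.

    ``z_total = (s_obs - s_exp) / sqrt(sum_offdiag V)``; the cell variances
    are summed under an independence approximation.  Degenerate cases
    (every codon pair in one block, or no pairs observed) are flagged with
    a zero score rather than scored.
    """
    C = block_coefficients(reading)
    E, V = expected_pairs(counts, pairs)
    off = ~np.eye(len(reading.family.codons), dtype=bool)
    s_obs = float((C * pairs.X)[off].sum())
    s_exp = float((C * E)[off].sum())
    var = float(V[off].sum())
    degenerate = var == 0 or bool((C[off] == 1).all())
    z = 0.0 if var == 0 else (s_obs - s_exp) / np.sqrt(var)
    return BlockScore(reading, C, s_obs, s_exp, z, degenerate=degenerate)


def score_readings_cc(
    readings: Sequence[ReadingMatrix],
    pairs: PairCountMatrix,
    counts: CodonCounts,
) -> np.ndarray:
    return np.array([score_reading_cc(r, pairs, counts).z_total for r in readings])
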