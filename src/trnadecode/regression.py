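"""Quadratic regression of tRNA abundance on summed codon usage.

Abundant tRNAs decode frequent codons; empirically the gene copy number
scales with the *square* of the summed frequency of the codons the tRNA
reads.  For a candidate reading matrix, each tRNA is allocated a share of
every codon it reads (inverse-breadth normalization n_c, so shares over a
codon always sum to one), the shares are summed into x_i, and the
one-parameter model ``copies_i = gamma * x_i**2 + eps_i`` is fit through
the origin.  The reading with the best coefficient of determination wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import CodonCounts
from .readings import ReadingMatrix


class DegenerateFitError(ValueError):
    """The regression is undefined (all-zero usage or a single usable tRNA)."""


def sharing_weights(reading: ReadingMatrix) -> np.ndarray:
    """Per-(tRNA, codon) allocation factors n_c.

    A tRNA reading k_i codons claims weight 1/k_i on each; the claims on a
    codon are renormalized to sum to one:
    ``n[i, c] = (1/k_i) / sum_{j reads c} (1/k_j)``.  A codon read by a
    four-codon tRNA and a three-codon tRNA therefore splits 3/7 : 4/7.
    """
    m = reading.matrix.astype(float)
    k = m.sum(axis=1, keepdims=True)  # codons read per tRNA
    claims = m / k
    col_tot = claims.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(m > 0, claims / col_tot, 0.0)
    return n


def summed_counts(reading: ReadingMatrix, counts: CodonCounts) -> np.ndarray:
    """Sharing-normalized codon-count totals x_i per tRNA.

    Conserves mass: the x_i always sum to the family's total codon count.
    """
    y = counts.vector(reading.family)
    return sharing_weights(reading) @ y


@dataclass(frozen=True)
class RegressionFit:
    reading: ReadingMatrix
    x: np.ndarray
    copies: np.ndarray
    gamma: float
    r_squared: float
    residuals: np.ndarray


def fit_quadratic_origin(
    x: np.ndarray, copies: np.ndarray, centered: bool = False
) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of ``y = gamma * x**2`` through the origin.

    Closed form: ``gamma = sum(x^2 y) / sum(x^4)``.  The default R^2 is the
    uncentered one (1 - SS_res / sum(y^2)), which stays in [0, 1] for a
    no-intercept model; ``centered=True`` uses the conventional total sum
    of squares about the mean instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(copies, dtype=float)
    sx4 = float((x**4).sum())
    if sx4 == 0:
        raise DegenerateFitError("all summed codon counts are zero")
    gamma = float((x**2 * y).sum() / sx4)
    resid = y - gamma * x**2
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum()) if centered else float((y**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return gamma, r2, resid


def score_reading_reg(
    reading: ReadingMatrix,
    counts: CodonCounts,
    centered: bool = False,
) -> RegressionFit:
    """Fit quality of one reading: compose sharing, summing and the fit.

    tRNAs annotated with zero gene copies are excluded from the fit (their
    abundance proxy is undefined); at least two tRNAs with copies are
    required.
    """
    copies = np.array([t.gene_copy_number for t in reading.trnas], dtype=float)
    x = summed_counts(reading, counts)
    mask = copies > 0
    if mask.sum() < 2:
        raise DegenerateFitError(
            "regression needs at least two tRNAs with positive copy number"
        )
    gamma, r2, resid = fit_quadratic_origin(x[mask], copies[mask], centered=centered)
    residuals = np.full(len(copies), np.nan)
    residuals[mask] = resid
    return RegressionFit(reading, x, copies, gamma, r2, residuals)


def score_readings_reg(
    readings: Sequence[ReadingMatrix], counts: CodonCounts, centered: bool = False
) -> np.ndarray:
    return np.array(
        [score_reading_reg(r, counts, centered=centered).r_squared for r in readings]
    )
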