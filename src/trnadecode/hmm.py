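"""Hidden-Markov scoring of reading hypotheses.

The hidden states are the tRNA isoacceptors of one amino-acid family; the
observables are the runs of synonymous codons.  A candidate reading matrix
fixes the emission matrix E (uniform over the codons each tRNA reads); the
transition matrix T is shared by all candidates and derives from relative
tRNA abundance plus a linear *reuse* boost on the diagonal (consecutive
synonymous codons tend to be decoded by the same tRNA, more so for rare
tRNAs); the start vector is the stationary distribution of T.  No
parameters are optimized while scoring -- the candidate with the highest
total forward likelihood over all runs is the inferred reading.

The reuse parameters (alpha, beta) are pre-estimated once from data by
iterating Viterbi decoding against a fixed reference reading and refitting
the diagonal excess against relative abundance until convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .code_tables import TrnaIsoacceptor
from .corpus import SynonymousRuns
from .readings import ReadingMatrix


class DegenerateAbundanceError(ValueError):
    """All gene copy numbers are zero; abundance weights are undefined."""


@dataclass(frozen=True)
class ReuseParams:
    """Linear tRNA-reuse term added to the transition diagonal.

    The pre-renormalization boost for state i is ``max(0, alpha + beta *
    w_i)`` with ``w_i`` the relative gene-copy frequency; a negative
    gradient therefore boosts the reuse of rare tRNAs most.  Defaults are
    the values pre-estimated from the yeast corpus.
    """

    alpha: float = 0.065
    beta: float = -0.087

    def boost(self, w: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.alpha + self.beta * np.asarray(w, dtype=float))


def abundance_weights(trnas: Sequence[TrnaIsoacceptor]) -> np.ndarray:
    copies = np.array([t.gene_copy_number for t in trnas], dtype=float)
    total = copies.sum()
    if total <= 0:
        raise DegenerateAbundanceError("all gene copy numbers are zero")
    return copies / total


def build_emissions(reading: ReadingMatrix) -> np.ndarray:
    """Row-stochastic emission matrix: uniform over the codons each tRNA reads."""
    m = reading.matrix.astype(float)
    row_sums = m.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("reading has a tRNA that reads no codon")
    return m / row_sums


def build_transitions(
    trnas: Sequence[TrnaIsoacceptor], reuse: ReuseParams | None = None
) -> np.ndarray:
    """Transition matrix from relative abundance with the diagonal reuse boost.

    Row i is the abundance vector w with ``max(0, alpha + beta*w_i)`` added
    at position i, renormalized to sum to one.  T is identical for every
    reading hypothesis of the family.
    """
    if reuse is None:
        reuse = ReuseParams()
    w = abundance_weights(trnas)
    n = len(w)
    T = np.tile(w, (n, 1))
    T[np.diag_indices(n)] += reuse.boost(w)
    return T / T.sum(axis=1, keepdims=True)


def stationary_start(T: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    """Stationary distribution of T via eigendecomposition (limiting tRNA usage).

    Falls back to ``fallback`` (e.g. the abundance vector) with a warning
    when no valid non-negative unit eigenvector exists (reducible chains).
    """
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    if abs(np.imag(vals[idx])) > 1e-9 or abs(np.real(vals[idx]) - 1.0) > 1e-6:
        pi = None  # type: ignore[assignment]
    else:
        pi = pi / pi.sum()
        if (pi < -1e-9).any():
            pi = None  # type: ignore[assignment]
    if pi is None:
        if fallback is None:
            raise np.linalg.LinAlgError("no valid stationary distribution")
        warnings.warn("transition matrix is reducible; using abundance fallback")
        pi = np.asarray(fallback, dtype=float)
        pi = pi / pi.sum()
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass(frozen=True)
class HmmModel:
    """One scoring model: emission E, transition T and start vector pi."""

    reading: ReadingMatrix
    E: np.ndarray
    T: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        n, k = self.E.shape
        if self.T.shape != (n, n) or self.pi.shape != (n,):
            raise ValueError("inconsistent model dimensions")
        for name, m in (("E", self.E), ("T", self.T)):
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to one")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to one")
        if not np.allclose(self.pi @ self.T, self.pi, atol=1e-8):
            raise ValueError("pi must be stationary for T")

    @property
    def n_states(self) -> int:
        return self.E.shape[0]


def build_model(reading: ReadingMatrix, reuse: ReuseParams | None = None) -> HmmModel:
    E = build_emissions(reading)
    T = build_transitions(reading.trnas, reuse)
    try:
        w = abundance_weights(reading.trnas)
    except DegenerateAbundanceError:
        w = None
    pi = stationary_start(T, fallback=w)
    return HmmModel(reading, E, T, pi)


def _runs_to_indices(reading: ReadingMatrix, runs: Sequence[Sequence[str]]) -> list[np.ndarray]:
    index = {c: i for i, c in enumerate(reading.family.codons)}
    out = []
    for run in runs:
        try:
            out.append(np.array([index[c] for c in run], dtype=int))
        except KeyError as exc:
            raise ValueError(
                f"codon {exc.args[0]!r} does not belong to family {reading.family.key}"
            ) from None
    return out


def _batch_forward(
    E: np.ndarray, T: np.ndarray, pi: np.ndarray, runs_idx: Sequence[np.ndarray]
) -> np.ndarray:
    """Scaled forward log-likelihood of many runs at once.

    Runs are padded to the longest length and frozen (via a mask) once they
    end; scaling at every step keeps the recursion stable for arbitrarily
    long runs.  Runs containing a codon with zero probability under every
    state yield -inf.
    """
    n_runs = len(runs_idx)
    if n_runs == 0:
        return np.zeros(0)
    lengths = np.array([len(r) for r in runs_idx], dtype=int)
    if (lengths == 0).any():
        raise ValueError("empty run")
    L = int(lengths.max())
    obs = np.zeros((n_runs, L), dtype=int)
    for i, r in enumerate(runs_idx):
        obs[i, : len(r)] = r
    k = E.shape[0]

    alpha = pi[None, :] * E[:, obs[:, 0]].T  # (n_runs, k)
    c = alpha.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_lik = np.log(c)
    dead = c == 0
    alpha[dead] = 1.0 / k
    alpha[~dead] /= c[~dead, None]

    for t in range(1, L):
        active = lengths > t
        if not active.any():
            break
        a2 = (alpha @ T) * E[:, obs[:, t]].T
        c = a2.sum(axis=1)
        with np.errstate(divide="ignore"):
            step = np.log(c)
        log_lik[active] += step[active]
        dead = c == 0
        a2[dead] = 1.0 / k
        a2[~dead] /= c[~dead, None]
        alpha[active] = a2[active]
    return log_lik


def forward_log_prob(model: HmmModel, run: Sequence[str]) -> float:
    """log P(run | model) by the scaled forward recursion."""
    idx = _runs_to_indices(model.reading, [run])
    return float(_batch_forward(model.E, model.T, model.pi, idx)[0])


@dataclass(frozen=True)
class HmmScore:
    """Total log-likelihood of all runs under one reading hypothesis."""

    reading: ReadingMatrix
    total_log_prob: float
    n_runs: int


def score_reading_hmm(
    reading: ReadingMatrix,
    runs: SynonymousRuns | Sequence[Sequence[str]],
    reuse: ReuseParams | None = None,
    model: HmmModel | None = None,
) -> HmmScore:
    """Sum of forward log-likelihoods over all runs; no parameter fitting."""
    sequences = runs.sequences if isinstance(runs, SynonymousRuns) else tuple(runs)
    if model is None:
        model = build_model(reading, reuse)
    if not sequences:
        return HmmScore(reading, 0.0, 0)
    idx = _runs_to_indices(reading, sequences)
    lls = _batch_forward(model.E, model.T, model.pi, idx)
    return HmmScore(reading, float(lls.sum()), len(sequences))


def score_readings_hmm(
    readings: Sequence[ReadingMatrix],
    runs: SynonymousRuns | Sequence[Sequence[str]],
    reuse: ReuseParams | None = None,
) -> np.ndarray:
    """Total log-likelihood for many readings of the same family.

    T and pi are shared across readings (only E differs), so the batch
    forward recursion is vectorized over readings as well as runs.
    """
    sequences = runs.sequences if isinstance(runs, SynonymousRuns) else tuple(runs)
    if not readings:
        return np.zeros(0)
    first = readings[0]
    T = build_transitions(first.trnas, reuse)
    pi = stationary_start(T, fallback=abundance_weights(first.trnas))
    if not sequences:
        return np.zeros(len(readings))
    runs_idx = _runs_to_indices(first, sequences)

    lengths = np.array([len(r) for r in runs_idx], dtype=int)
    L = int(lengths.max())
    n_runs = len(runs_idx)
    obs = np.zeros((n_runs, L), dtype=int)
    for i, r in enumerate(runs_idx):
        obs[i, : len(r)] = r

    totals = np.zeros(len(readings))
    chunk = max(1, int(2e7 // max(1, n_runs * T.shape[0])))
    for start in range(0, len(readings), chunk):
        block = readings[start : start + chunk]
        Es = np.stack([build_emissions(r) for r in block])  # (R, k, m)
        R, k, _ = Es.shape
        emis0 = Es[:, :, obs[:, 0]].transpose(0, 2, 1)  # (R, n_runs, k)
        alpha = pi[None, None, :] * emis0
        c = alpha.sum(axis=2)
        with np.errstate(divide="ignore"):
            log_lik = np.log(c)
        dead = c == 0
        alpha = np.where(dead[:, :, None], 1.0 / k, alpha / np.where(dead, 1.0, c)[:, :, None])
        for t in range(1, L):
            active = lengths > t
            if not active.any():
                break
            a2 = (alpha @ T) * Es[:, :, obs[:, t]].transpose(0, 2, 1)
            c = a2.sum(axis=2)
            with np.errstate(divide="ignore"):
                step = np.log(c)
            log_lik[:, active] += step[:, active]
            dead = c == 0
            a2 = np.where(dead[:, :, None], 1.0 / k, a2 / np.where(dead, 1.0, c)[:, :, None])
            alpha[:, active] = a2[:, active]
        totals[start : start + chunk] = log_lik.sum(axis=1)
    return totals


def viterbi_path(model: HmmModel, run: Sequence[str] | np.ndarray) -> np.ndarray:
    """Most likely state path; ties break toward the lower state index."""
    if isinstance(run, np.ndarray) and run.dtype.kind in "iu":
        idx = run
    else:
        idx = _runs_to_indices(model.reading, [run])[0]
    with np.errstate(divide="ignore"):
        logE = np.log(model.E)
        logT = np.log(model.T)
        logpi = np.log(model.pi)
    n = len(idx)
    k = model.n_states
    delta = logpi + logE[:, idx[0]]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logT  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max = lower index
        delta = cand[back[t], np.arange(k)] + logE[:, idx[t]]
    states = np.zeros(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


@dataclass(frozen=True)
class ReuseEstimate:
    params: ReuseParams
    converged: bool
    n_iter: int
    trace: tuple[tuple[float, float], ...] = field(default=(), compare=False)


def estimate_reuse(
    runs: SynonymousRuns | Sequence[Sequence[str]],
    reference_reading: ReadingMatrix,
    init: ReuseParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 25,
) -> ReuseEstimate:
    """Iterative Viterbi estimation of the reuse parameters (alpha, beta).

    With emissions fixed by a reference reading, each iteration (1) builds T
    from the current parameters, (2) Viterbi-decodes every run, (3) tallies
    the per-state self-transition frequency f_i, converts it to the implied
    diagonal excess r_i = (f_i - w_i) / (1 - f_i), and (4) refits
    r ~ alpha + beta * w by least squares weighted by the transition counts.
    Stops when both parameter changes fall below ``tol`` (returning the
    pre-update iterate, so an infinite tolerance returns the initial guess
    after one pass) or after ``max_iter`` iterations (flagged unconverged).
    """
    sequences = runs.sequences if isinstance(runs, SynonymousRuns) else tuple(runs)
    if not sequences:
        raise ValueError("reuse estimation requires at least one run")
    params = init if init is not None else ReuseParams()
    trnas = reference_reading.trnas
    w = abundance_weights(trnas)
    E = build_emissions(reference_reading)
    runs_idx = _runs_to_indices(reference_reading, sequences)
    trace: list[tuple[float, float]] = [(params.alpha, params.beta)]

    for iteration in range(1, max_iter + 1):
        T = build_transitions(trnas, params)
        pi = stationary_start(T, fallback=w)
        model = HmmModel(reference_reading, E, T, pi)
        n_states = len(trnas)
        self_counts = np.zeros(n_states)
        out_counts = np.zeros(n_states)
        for idx in runs_idx:
            if len(idx) < 2:
                continue
            states = viterbi_path(model, idx)
            for a, b in zip(states, states[1:]):
                out_counts[a] += 1
                if a == b:
                    self_counts[a] += 1
        visited = out_counts > 0
        if visited.sum() < 2:
            return ReuseEstimate(params, False, iteration, tuple(trace))
        f = np.clip(self_counts[visited] / out_counts[visited], 0.0, 1.0 - 1e-9)
        wv = w[visited]
        r = (f - wv) / (1.0 - f)
        weights = out_counts[visited]
        if np.unique(wv).size < 2:
            beta_new = params.beta
            alpha_new = float(np.average(r - beta_new * wv, weights=weights))
        else:
            beta_new, alpha_new = np.polyfit(wv, r, deg=1, w=np.sqrt(weights))
        delta = max(abs(alpha_new - params.alpha), abs(beta_new - params.beta))
        if delta < tol:
            return ReuseEstimate(params, True, iteration, tuple(trace))
        params = ReuseParams(float(alpha_new), float(beta_new))
        trace.append((params.alpha, params.beta))
    return ReuseEstimate(params, False, max_iter, tuple(trace))
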