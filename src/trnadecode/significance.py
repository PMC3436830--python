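"""Score normalization, randomized nulls, empirical p-values, consensus.

Raw method scores live on incomparable scales, so each family's solution
space is min-max normalized to [0, 1].  Significance is assessed by a
Monte-Carlo procedure: the best plausible score on the real corpus is
ranked against the best plausible scores on randomized corpora (synonymous
codons redrawn i.i.d. from the global frequencies for the run-based
methods; codon counts redrawn from a moment-matched skew normal for the
regression method), giving the distribution-free empirical p-value
``(r + 1) / (n + 1)``.  Cross-method agreement is tallied as a Venn
partition with randomization-based expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import CodonCounts, SynonymousRuns
from .readings import ReadingMatrix


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def normalize_scores(scores: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Affine map of scores to [0, 1]: ``s_n = (s - min s) / (max s - min s)``.

    Returns ``(s_n, degenerate)``; when all scores are equal the map is
    undefined and every score becomes 0.5 with the degenerate flag set.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 1:
        raise ValueError("no scores to normalize")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        return np.full(s.shape, 0.5), True
    return (s - lo) / (hi - lo), False


@dataclass(frozen=True)
class ScoredSolutionSpace:
    """All readings of one family scored by one method."""

    family_key: str
    method: str
    readings: tuple[ReadingMatrix, ...]
    plausible_flags: tuple[bool, ...]
    scores: np.ndarray
    s_n: np.ndarray = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        if not any(self.plausible_flags):
            raise ValueError("at least one plausible reading required")
        s_n, degenerate = normalize_scores(self.scores)
        object.__setattr__(self, "s_n", s_n)
        object.__setattr__(self, "degenerate", degenerate)

    @property
    def best_plausible_index(self) -> int:
        flags = np.asarray(self.plausible_flags)
        idx = np.flatnonzero(flags)
        return int(idx[np.argmax(self.scores[idx])])

    @property
    def best_plausible(self) -> ReadingMatrix:
        return self.readings[self.best_plausible_index]

    @property
    def best_plausible_score(self) -> float:
        return float(self.scores[self.best_plausible_index])

    @property
    def rank_of_best_plausible(self) -> int:
        """1-based rank of the best plausible score among all readings."""
        return 1 + int((self.scores > self.best_plausible_score).sum())


def randomize_runs(
    runs: SynonymousRuns,
    counts: CodonCounts,
    seed: int | np.random.Generator | None = None,
) -> SynonymousRuns:
    """Null corpus for the run-based methods.

    Keeps the gene structure and every run length, but redraws each codon
    i.i.d. from the corpus-wide within-family codon frequencies, erasing
    any decoding signal while preserving composition.
    """
    rng = _as_rng(seed)
    family = runs.family
    total = counts.total(family)
    if total <= 0:
        raise ValueError("cannot randomize with all-zero codon counts")
    p = counts.vector(family) / total
    codons = np.array(family.codons)
    new_runs = []
    for gene_id, run in runs.runs:
        draw = rng.choice(len(codons), size=len(run), p=p)
        new_runs.append((gene_id, tuple(codons[draw])))
    return SynonymousRuns(family, tuple(new_runs))


def _skewnorm_params(values: np.ndarray) -> tuple[float, float, float]:
    """Moment-matched skew-normal (shape a, loc, scale) for a sample."""
    m = float(values.mean())
    s = float(values.std())
    if s == 0:
        return 0.0, m, 0.0
    g1 = float(stats.skew(values))
    g1 = float(np.clip(g1, -0.995, 0.995))
    # invert the skewness formula for delta = a / sqrt(1 + a^2)
    num = np.pi / 2 * abs(g1) ** (2 / 3)
    den = abs(g1) ** (2 / 3) + ((4 - np.pi) / 2) ** (2 / 3)
    delta = np.sign(g1) * np.sqrt(num / den) if g1 != 0 else 0.0
    a = delta / np.sqrt(1 - delta**2) if abs(delta) < 1 else np.sign(delta) * 1e6
    scale = s / np.sqrt(1 - 2 * delta**2 / np.pi)
    loc = m - scale * delta * np.sqrt(2 / np.pi)
    return float(a), float(loc), float(scale)


def randomize_counts_skewnormal(
    counts: CodonCounts,
    family,
    seed: int | np.random.Generator | None = None,
) -> CodonCounts:
    """Null codon counts for the regression method.

    Each family codon count is redrawn from a skew-normal distribution
    whose location, scale and shape are moment-matched (mean, variance,
    skewness; skewness clamped to the admissible range) to the family's
    observed codon-count distribution.  With fewer than three codons the
    shape degenerates to a normal.  Negative draws are clamped to zero.
    """
    rng = _as_rng(seed)
    values = counts.vector(family)
    a, loc, scale = _skewnorm_params(values)
    if len(values) < 3:
        a = 0.0
    if scale == 0:
        draws = np.full(len(values), loc)
    else:
        draws = stats.skewnorm.rvs(a, loc=loc, scale=scale, size=len(values), random_state=rng)
    draws = np.clip(draws, 0.0, None)
    return CodonCounts({c: float(v) for c, v in zip(family.codons, draws)})


@dataclass(frozen=True)
class EmpiricalP:
    """Monte-Carlo rank p-value: p = (r + 1) / (n + 1), ties counted in r."""

    n: int
    r: int
    p: float


def empirical_p(real_score: float, null_scores: Sequence[float]) -> EmpiricalP:
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.size == 0:
        raise ValueError("empirical p-value needs at least one null score")
    r = int((nulls >= real_score).sum())
    n = int(nulls.size)
    return EmpiricalP(n=n, r=r, p=(r + 1) / (n + 1))


VENN_REGIONS = ("all_three", "hmm_reg", "hmm_cc", "reg_cc", "none")


def _classify_family(preds: Mapping[str, str]) -> str:
    h, r, c = preds["hmm"], preds["reg"], preds["cc"]
    if h == r == c:
        return "all_three"
    if h == r:
        return "hmm_reg"
    if h == c:
        return "hmm_cc"
    if r == c:
        return "reg_cc"
    return "none"


def venn_counts(predictions: Mapping[str, Mapping[str, str]]) -> dict[str, int]:
    """Partition families by which methods agree on the predicted reading.

    ``predictions`` maps method ('hmm'|'reg'|'cc') to {family_key:
    reading bits}.  Families missing any method are excluded.  Agreement
    means exact reading-matrix identity.
    """
    methods = ("hmm", "reg", "cc")
    for m in methods:
        if m not in predictions:
            raise ValueError(f"missing predictions for method {m!r}")
    keys = set.intersection(*(set(predictions[m]) for m in methods))
    out = {region: 0 for region in VENN_REGIONS}
    for key in keys:
        region = _classify_family({m: predictions[m][key] for m in methods})
        out[region] += 1
    return out


@dataclass(frozen=True)
class ConsensusTally:
    observed: dict[str, int]
    expected: dict[str, float]
    p_ge: dict[str, EmpiricalP]
    p_le: dict[str, EmpiricalP]
    n_families: int


def consensus_tally(
    predictions: Mapping[str, Mapping[str, str]],
    null_replicates: Sequence[Mapping[str, Mapping[str, str]]],
) -> ConsensusTally:
    """Observed vs. randomized Venn counts with per-region empirical p-values.

    ``null_replicates`` are prediction sets of the same shape obtained on
    randomized data; expectations are their region-count means, and each
    region gets two one-sided Monte-Carlo p-values (count at least / at
    most as extreme as observed).
    """
    observed = venn_counts(predictions)
    if not null_replicates:
        raise ValueError("at least one null replicate required")
    null_counts = {region: [] for region in VENN_REGIONS}
    for rep in null_replicates:
        rep_counts = venn_counts(rep)
        for region in VENN_REGIONS:
            null_counts[region].append(rep_counts[region])
    expected = {region: float(np.mean(null_counts[region])) for region in VENN_REGIONS}
    p_ge = {
        region: empirical_p(observed[region], null_counts[region])
        for region in VENN_REGIONS
    }
    p_le = {
        region: empirical_p(-observed[region], [-v for v in null_counts[region]])
        for region in VENN_REGIONS
    }
    return ConsensusTally(observed, expected, p_ge, p_le, sum(observed.values()))


def write_consensus_tsv(tally: ConsensusTally, path) -> None:
    with open(path, "w") as handle:
        handle.write("region\tobserved\texpected\tp_ge\tp_le\n")
        for region in VENN_REGIONS:
            handle.write(
                f"{region}\t{tally.observed[region]}\t{tally.expected[region]:.3f}"
                f"\t{tally.p_ge[region].p:.4f}\t{tally.p_le[region].p:.4f}\n"
            )
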