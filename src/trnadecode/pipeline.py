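"""End-to-end prediction: corpus -> solution spaces -> scores -> p-values.

This is the library layer behind the command-line interface: it walks the
amino-acid families (per codon box) present in a tRNA set, enumerates and
scores reading hypotheses with the requested methods, normalizes scores
over each solution space, and attaches Monte-Carlo empirical p-values from
randomized corpora.  Trivial families (a single tRNA covering the box, a
single-codon box, or a single plausible reading) are reported as such and
not scored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .code_tables import GeneticCode, TrnaSet, family_boxes
from .codon_correlation import score_readings_cc
from .corpus import (
    FilterPolicy,
    Gene,
    RejectionReport,
    build_runs,
    count_codons,
    count_pairs,
    load_cds,
)
from .hmm import ReuseParams, score_readings_hmm
from .readings import (
    InfeasibleReadingError,
    SolutionSpaceTooLargeError,
    WobbleOptionSet,
    enumerate_all_readings,
)
from .regression import DegenerateFitError, score_readings_reg
from .significance import (
    ScoredSolutionSpace,
    empirical_p,
    randomize_counts_skewnormal,
    randomize_runs,
)

METHODS = ("hmm", "reg", "cc")


@dataclass(frozen=True)
class RunConfig:
    """Everything a prediction run depends on; hashed into every output."""

    cds_path: str
    trna_path: str
    code_id: int = 1
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    wobble_options_path: str | None = None
    methods: tuple[str, ...] = METHODS
    n_randomizations: int = 99
    seed: int = 0
    reuse: ReuseParams = field(default_factory=ReuseParams)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cds": str(self.cds_path),
                "trna": str(self.trna_path),
                "code_id": self.code_id,
                "policy": vars(self.policy) | {},
                "wobble": self.wobble_options_path,
                "methods": list(self.methods),
                "n_rand": self.n_randomizations,
                "seed": self.seed,
                "reuse": [self.reuse.alpha, self.reuse.beta],
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PredictReport:
    table: pd.DataFrame
    warnings: list[str]
    rejection_report: RejectionReport | None = None

    def write(self, out_dir: str | Path, config: RunConfig | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
        with open(out_dir / "warnings.tsv", "w") as handle:
            handle.write("warning\n")
            for w in self.warnings:
                handle.write(w.replace("\t", " ") + "\n")
        if self.rejection_report is not None:
            self.rejection_report.write_tsv(out_dir / "rejections.tsv")
        if config is not None:
            with open(out_dir / "config.json", "w") as handle:
                json.dump(
                    {
                        "config_hash": config.config_hash,
                        "seed": config.seed,
                        "methods": list(config.methods),
                        "n_randomizations": config.n_randomizations,
                        "code_id": config.code_id,
                    },
                    handle,
                    indent=2,
                )
                handle.write("\n")


def _score_methods(
    methods: Sequence[str],
    readings,
    runs,
    pairs,
    counts,
    reuse,
) -> dict[str, np.ndarray]:
    out = {}
    for method in methods:
        if method == "hmm":
            out[method] = score_readings_hmm(readings, runs, reuse)
        elif method == "reg":
            out[method] = score_readings_reg(readings, counts)
        elif method == "cc":
            out[method] = score_readings_cc(readings, pairs, counts)
    return out


def predict_genes(
    genes: Sequence[Gene],
    trna_set: TrnaSet,
    code: GeneticCode,
    options: WobbleOptionSet | None = None,
    methods: Sequence[str] = METHODS,
    policy: FilterPolicy | None = None,
    n_randomizations: int = 99,
    seed: int = 0,
    reuse: ReuseParams | None = None,
) -> PredictReport:
    """Predict the codon reading of every non-trivial family in the corpus."""
    if options is None:
        options = WobbleOptionSet.default()
    if policy is None:
        policy = FilterPolicy()
    if reuse is None:
        reuse = ReuseParams()
    rng = np.random.default_rng(seed)
    counts = count_codons(genes, code)
    rows: list[dict] = []
    warnings: list[str] = []

    for amino_acid in trna_set.amino_acids:
        if amino_acid not in code.amino_acids:
            warnings.append(f"{amino_acid}: not in genetic code {code.table_id}; skipped")
            continue
        for family in family_boxes(code, amino_acid):
            trnas = trna_set.for_family(family)
            base_row = {
                "family": amino_acid,
                "box": family.box,
                "codons": ",".join(family.codons),
                "anticodons": ",".join(t.anticodon for t in trnas),
                "seed": seed,
            }
            if not trnas:
                warnings.append(f"{family.key}: no tRNA in table; skipped")
                continue
            try:
                space = enumerate_all_readings(family, trnas, options)
            except (InfeasibleReadingError, SolutionSpaceTooLargeError) as exc:
                warnings.append(f"{family.key}: {exc}")
                continue
            plausible = space.plausible
            if space.trivial or len(trnas) == 1 or len(plausible) <= 1:
                reading = plausible[0] if plausible else space.readings[0]
                rows.append(
                    base_row
                    | {
                        "method": "trivial",
                        "best_reading": reading.bits,
                        "score": np.nan,
                        "s_n": np.nan,
                        "rank": 1,
                        "n_solutions": len(space),
                        "n_plausible": len(plausible),
                        "p_value": np.nan,
                        "n_rand": 0,
                    }
                )
                continue

            runs = build_runs(genes, family, policy)
            pairs = count_pairs(runs)
            try:
                scores = _score_methods(methods, space.readings, runs, pairs, counts, reuse)
            except DegenerateFitError as exc:
                warnings.append(f"{family.key}: {exc}")
                continue

            plaus_idx = [i for i, f in enumerate(space.plausible_flags) if f]
            for method in methods:
                scored = ScoredSolutionSpace(
                    family.key, method, space.readings, space.plausible_flags, scores[method]
                )
                # Monte-Carlo null: best plausible score on randomized data
                null_scores = []
                for _ in range(n_randomizations):
                    if method == "reg":
                        null_counts = randomize_counts_skewnormal(counts, family, rng)
                        null = score_readings_reg(plausible, null_counts)
                    else:
                        null_runs = randomize_runs(runs, counts, rng)
                        null_pairs = count_pairs(null_runs) if method == "cc" else pairs
                        null = _score_methods(
                            [method], plausible, null_runs, null_pairs, counts, reuse
                        )[method]
                    null_scores.append(float(np.max(null)))
                pval = (
                    empirical_p(scored.best_plausible_score, null_scores).p
                    if null_scores
                    else np.nan
                )
                rows.append(
                    base_row
                    | {
                        "method": method,
                        "best_reading": scored.best_plausible.bits,
                        "score": scored.best_plausible_score,
                        "s_n": float(scored.s_n[scored.best_plausible_index]),
                        "rank": scored.rank_of_best_plausible,
                        "n_solutions": len(space),
                        "n_plausible": len(plausible),
                        "p_value": pval,
                        "n_rand": n_randomizations,
                    }
                )
    table = pd.DataFrame(rows)
    return PredictReport(table, warnings)


def predict(config: RunConfig) -> PredictReport:
    """File-level entry point: load, filter, predict."""
    code = GeneticCode.from_ncbi_id(config.code_id)
    genes, report = load_cds(config.cds_path, code, config.policy)
    from .code_tables import parse_trna_table

    trna_set = parse_trna_table(config.trna_path)
    options = (
        WobbleOptionSet.from_yaml(config.wobble_options_path)
        if config.wobble_options_path
        else WobbleOptionSet.default()
    )
    result = predict_genes(
        genes,
        trna_set,
        code,
        options=options,
        methods=config.methods,
        policy=config.policy,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
        reuse=config.reuse,
    )
    result.rejection_report = report
    return result


def baselines(
    trna_set: TrnaSet,
    code: GeneticCode,
    eukaryote: bool = True,
    variant: str = "restricted",
) -> pd.DataFrame:
    """Wobble-rules and wobble-parsimony assignments for every family box."""
    from .readings import wobble_parsimony_reading, wobble_rules_reading

    rows = []
    for amino_acid in trna_set.amino_acids:
        if amino_acid not in code.amino_acids:
            continue
        for family in family_boxes(code, amino_acid):
            trnas = trna_set.for_family(family)
            if not trnas:
                continue
            rules = wobble_rules_reading(family, trnas, variant=variant)
            row = {
                "family": amino_acid,
                "box": family.box,
                "anticodons": ",".join(t.anticodon for t in trnas),
                "wobble_rules": rules.bits,
                "wobble_rules_warnings": ";".join(rules.coverage_warnings),
            }
            if eukaryote:
                pars = wobble_parsimony_reading(family, trnas)
                row["wobble_parsimony"] = pars.bits
                row["wobble_parsimony_warnings"] = ";".join(pars.coverage_warnings)
            rows.append(row)
    return pd.DataFrame(rows)
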