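"""Generative mirror of the decoding model: synthetic CDS with known truth.

Each gene is an i.i.d. amino-acid string; within a gene, the synonymous
codons of each family are emitted by running the family's tRNA Markov
chain forward (transitions from relative abundance plus the diagonal reuse
boost, start from the stationary distribution) and drawing codons
uniformly over each hidden tRNA's reading set -- exactly the process the
HMM scoring assumes.  The null variant drops the hidden-state memory and
draws codons i.i.d. from the chain's implied marginal, preserving codon
composition but erasing the reuse signal.

Corpora are written as DNA FASTA (with a terminal stop codon) so the
ingestion path, including transliteration and filtering, is exercised
end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code_tables import TrnaIsoacceptor, TrnaSet
from .hmm import ReuseParams, build_emissions, build_transitions, stationary_start, abundance_weights
from .readings import ReadingMatrix


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Ground truth and corpus shape for one simulation.

    ``true_readings`` holds one reading matrix per simulated family (each
    embeds its family and tRNAs); ``composition`` gives the probability of
    each family key in the amino-acid sequence (uniform by default).  Gene
    lengths are Poisson around ``mean_length_aa`` with a floor at
    ``min_length_aa`` so every gene clears the default corpus filters.
    """

    true_readings: tuple[ReadingMatrix, ...]
    reuse: ReuseParams = field(default_factory=ReuseParams)
    n_genes: int = 1000
    mean_length_aa: float = 150.0
    min_length_aa: int = 50
    composition: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.true_readings:
            raise SimConfigError("at least one family with a true reading required")
        if self.min_length_aa < 50:
            raise SimConfigError("minimum gene length must clear the 50-aa filter")
        for reading in self.true_readings:
            if not reading.trnas:
                raise SimConfigError(f"family {reading.family.key} has no tRNA")
            if sum(t.gene_copy_number for t in reading.trnas) <= 0:
                raise SimConfigError(
                    f"family {reading.family.key} has all-zero copy numbers"
                )
        comp = self.resolved_composition
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise SimConfigError("composition must sum to 1")
        keys = {r.family.key for r in self.true_readings}
        if set(comp) - keys:
            raise SimConfigError("composition names a family without a true reading")

    @property
    def resolved_composition(self) -> dict[str, float]:
        if self.composition is not None:
            return dict(self.composition)
        keys = [r.family.key for r in self.true_readings]
        return {k: 1.0 / len(keys) for k in keys}

    @property
    def trna_set(self) -> TrnaSet:
        isoacceptors = []
        for reading in self.true_readings:
            isoacceptors.extend(reading.trnas)
        return TrnaSet(tuple(isoacceptors))


@dataclass(frozen=True)
class SimulatedCorpus:
    records: tuple[SeqRecord, ...]
    truth: dict

    def write(self, fasta_path: str | Path, truth_path: str | Path | None = None) -> None:
        with open(fasta_path, "w") as handle:
            for rec in self.records:
                handle.write(f">{rec.id}\n{rec.seq}\n")
        if truth_path is not None:
            with open(truth_path, "w") as handle:
                json.dump(self.truth, handle, indent=2)
                handle.write("\n")


def _family_machinery(config: SimConfig):
    out = {}
    for reading in config.true_readings:
        E = build_emissions(reading)
        T = build_transitions(reading.trnas, config.reuse)
        pi = stationary_start(T, fallback=abundance_weights(reading.trnas))
        out[reading.family.key] = (reading, E, np.cumsum(T, axis=1), np.cumsum(pi), E, pi)
    return out


def _truth_record(config: SimConfig, seed, null: bool) -> dict:
    return {
        "seed": seed,
        "null": null,
        "n_genes": config.n_genes,
        "mean_length_aa": config.mean_length_aa,
        "reuse": {"alpha": config.reuse.alpha, "beta": config.reuse.beta},
        "composition": config.resolved_composition,
        "families": [
            {
                "amino_acid": r.family.amino_acid,
                "box": r.family.box,
                "codons": list(r.family.codons),
                "anticodons": [t.anticodon for t in r.trnas],
                "copies": [t.gene_copy_number for t in r.trnas],
                "bits": r.bits,
            }
            for r in config.true_readings
        ],
    }


def simulate_corpus(config: SimConfig, seed: int | None = None) -> SimulatedCorpus:
    """Forward-simulate a CDS corpus under the hidden-tRNA model."""
    return _simulate(config, seed, null=False)


def simulate_null_corpus(config: SimConfig, seed: int | None = None) -> SimulatedCorpus:
    """Same corpus shape, but codons i.i.d. (no hidden-state memory)."""
    return _simulate(config, seed, null=True)


def _simulate(config: SimConfig, seed: int | None, null: bool) -> SimulatedCorpus:
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    machinery = _family_machinery(config)
    comp = config.resolved_composition
    keys = sorted(comp)
    probs = np.array([comp[k] for k in keys])
    records = []
    for g in range(config.n_genes):
        length = max(config.min_length_aa, int(rng.poisson(config.mean_length_aa)))
        fam_seq = rng.choice(len(keys), size=length, p=probs)
        codons: list[str] = [""] * length
        for fi, key in enumerate(keys):
            positions = np.flatnonzero(fam_seq == fi)
            if positions.size == 0:
                continue
            reading, E, T_cum, pi_cum, _, pi = machinery[key]
            fam_codons = reading.family.codons
            if null:
                marginal = pi @ E
                draws = rng.choice(len(fam_codons), size=positions.size, p=marginal)
                for pos, ci in zip(positions, draws):
                    codons[pos] = fam_codons[ci]
            else:
                u = rng.random(positions.size)
                e_u = rng.random(positions.size)
                state = int(np.searchsorted(pi_cum, u[0]))
                E_cum = np.cumsum(E, axis=1)
                for j, pos in enumerate(positions):
                    if j > 0:
                        state = int(np.searchsorted(T_cum[state], u[j]))
                    ci = int(np.searchsorted(E_cum[state], e_u[j]))
                    codons[pos] = fam_codons[ci]
        rna = "".join(codons) + "UAA"
        dna = rna.replace("U", "T")
        records.append(SeqRecord(Seq(dna), id=f"gene{g:05d}", description=""))
    return SimulatedCorpus(tuple(records), _truth_record(config, seed, null))


def alanine_example(
    n_genes: int = 1000,
    seed: int | None = None,
    copies: tuple[int, int] = (11, 5),
    mean_length_aa: float = 60.0,
    reuse: ReuseParams | None = None,
) -> SimConfig:
    """Two-tRNA alanine family with the yeast-like exclusive reading.

    tRNA(AGC) (11 gene copies) reads {GCU, GCC} and tRNA(UGC) (5 copies)
    reads {GCA, GCG}; genes are pure-alanine runs, which is all the
    within-family methods ever observe.
    """
    from .code_tables import AminoAcidFamily

    family = AminoAcidFamily("A", ("GCU", "GCC", "GCA", "GCG"), box="GC")
    trnas = (
        TrnaIsoacceptor("A", "AGC", copies[0]),
        TrnaIsoacceptor("A", "UGC", copies[1]),
    )
    reading = ReadingMatrix.from_codon_sets(
        family, trnas, [{"GCU", "GCC"}, {"GCA", "GCG"}]
    )
    return SimConfig(
        true_readings=(reading,),
        reuse=reuse if reuse is not None else ReuseParams(),
        n_genes=n_genes,
        mean_length_aa=mean_length_aa,
        seed=seed,
    )


def yeast_like_example(
    n_genes: int = 500,
    seed: int | None = None,
    mean_length_aa: float = 150.0,
    reuse: ReuseParams | None = None,
) -> SimConfig:
    """A small multi-family corpus with yeast-like isoacceptor structure.

    Three families -- a four-box with two tRNAs (Ala), a four-box with
    three tRNAs (Gly) and a purine two-box (Gln) -- with gene copy numbers
    in the range observed in the yeast genome.
    """
    from .code_tables import AminoAcidFamily

    ala_family = AminoAcidFamily("A", ("GCU", "GCC", "GCA", "GCG"), box="GC")
    ala_trnas = (TrnaIsoacceptor("A", "AGC", 11), TrnaIsoacceptor("A", "UGC", 5))
    ala = ReadingMatrix.from_codon_sets(
        ala_family, ala_trnas, [{"GCU", "GCC"}, {"GCA", "GCG"}]
    )

    gly_family = AminoAcidFamily("G", ("GGU", "GGC", "GGA", "GGG"), box="GG")
    gly_trnas = (
        TrnaIsoacceptor("G", "GCC", 16),
        TrnaIsoacceptor("G", "UCC", 3),
        TrnaIsoacceptor("G", "CCC", 2),
    )
    gly = ReadingMatrix.from_codon_sets(
        gly_family, gly_trnas, [{"GGU", "GGC"}, {"GGA", "GGG"}, {"GGG"}]
    )

    gln_family = AminoAcidFamily("Q", ("CAA", "CAG"), box="CA")
    gln_trnas = (TrnaIsoacceptor("Q", "UUG", 9), TrnaIsoacceptor("Q", "CUG", 1))
    gln = ReadingMatrix.from_codon_sets(gln_family, gln_trnas, [{"CAA"}, {"CAG"}])

    return SimConfig(
        true_readings=(ala, gly, gln),
        reuse=reuse if reuse is not None else ReuseParams(),
        n_genes=n_genes,
        mean_length_aa=mean_length_aa,
        seed=seed,
    )
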