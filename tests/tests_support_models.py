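"""Shared helpers for building random HMM scoring models in tests."""

import numpy as np

from trnadecode.code_tables import AminoAcidFamily, TrnaIsoacceptor
from trnadecode.hmm import ReuseParams, build_model
from trnadecode.readings import ReadingMatrix


def random_family_model(rng: np.random.Generator, n_states: int, n_codons: int = 4):
    """A valid reading over an alanine-like family with random structure."""
    family = AminoAcidFamily("A", ("GCU", "GCC", "GCA", "GCG")[:n_codons], box="GC")
    anticodons = ("AGC", "UGC", "CGC")[:n_states]
    trnas = tuple(
        TrnaIsoacceptor("A", a, int(rng.integers(1, 20))) for a in anticodons
    )
    while True:
        reads = rng.integers(0, 2, size=(n_states, n_codons))
        if (reads.sum(axis=1) > 0).all() and (reads.sum(axis=0) > 0).all():
            break
    reading = ReadingMatrix(family, trnas, tuple(map(tuple, reads.tolist())))
    reuse = ReuseParams(float(rng.uniform(0, 0.2)), float(rng.uniform(-0.2, 0)))
    return build_model(reading, reuse)
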