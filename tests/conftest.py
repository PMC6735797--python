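"""Shared fixtures: one small synthetic dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from lncproteo.simulate import (
    PeptideNoise,
    SimulationParams,
    simulate_expression,
    simulate_peptides,
    simulate_transcriptome,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def small_sim():
    """Noise-free benchmark: 200 coding genes, 50 lncRNAs, 20 planted ORFs."""
    params = SimulationParams(seed=7)
    return simulate_transcriptome(params)


@pytest.fixture(scope="session")
def small_sim_counts(small_sim):
    records, tr_truth = simulate_expression(small_sim)
    return records, tr_truth


@pytest.fixture(scope="session")
def small_sim_peptides(small_sim):
    return simulate_peptides(small_sim)


@pytest.fixture(scope="session")
def noisy_sim():
    """Benchmark with shared peptides and distance-0/1 contaminants."""
    params = SimulationParams(
        seed=11,
        peptide_noise=PeptideNoise(n_shared=5, n_contaminant_d0=10, n_contaminant_d1=8),
    )
    return simulate_transcriptome(params)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
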