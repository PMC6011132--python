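"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import pytest

from ssrkit.synthetic_data import (
    GenotypeSimSpec, ImplantSpec, simulate_genotypes,
    simulate_transcripts_with_ssrs,
)


@pytest.fixture(scope="session")
def implanted_transcripts():
    """Small transcript set with known SSR implants and its truth table."""
    records, truth = simulate_transcripts_with_ssrs(
        n_seqs=12,
        length_bounds=(250, 400),
        implants=[
            ImplantSpec(motif="AT", repeats=6, count=4),
            ImplantSpec(motif="AAG", repeats=5, count=3),
            ImplantSpec(motif="A", repeats=13, count=2),
        ],
        seed=42,
    )
    return records, truth


@pytest.fixture(scope="session")
def two_population_matrices():
    """Two 12-individual populations typed at the same 5 loci."""
    freqs = {
        "L1": [0.6, 0.4],
        "L2": [0.5, 0.3, 0.2],
        "L3": [0.7, 0.2, 0.1],
        "L4": [0.9, 0.1],
        "L5": [0.4, 0.35, 0.25],
    }
    pop1 = simulate_genotypes(
        GenotypeSimSpec(allele_freqs=freqs, n_individuals=12, seed=11)
    )
    pop2 = simulate_genotypes(
        GenotypeSimSpec(
            allele_freqs=freqs, n_individuals=12, inbreeding_f=0.4, seed=12
        )
    )
    return [pop1, pop2]
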