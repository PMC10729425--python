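"""Shared fixtures: a small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from thstools.atac_qc import make_insertion_track
from thstools.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_fragments,
    simulate_genome_and_genes,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced study: 300 kb, 24 genes, 4 conditions x 3 replicates."""
    return SimulationConfig(
        seed=42,
        chrom_len=300_000,
        n_genes=24,
        n_accessible_genes=16,
        n_decoy_regions=4,
        fragments_per_sample=8_000,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    genome, genes, truth = simulate_genome_and_genes(small_cfg)
    frag_sets = simulate_fragments(small_cfg, truth, genome)
    expr = simulate_expression(small_cfg, truth, genes)
    return {
        "cfg": small_cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "frag_sets": frag_sets,
        "expr": expr,
    }


@pytest.fixture(scope="session")
def small_tracks(small_study):
    return [
        make_insertion_track(f, small_study["genome"])
        for f in small_study["frag_sets"]
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
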