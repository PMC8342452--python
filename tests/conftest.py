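"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from allelekit.simulate import (
    SimulationConfig,
    generate_diploid_annotation,
    plant_regulatory_context,
    simulate_cds_pairs,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_chromosome_pairs=2, genes_per_chromosome=30)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Annotation + counts + CDS + regulatory context for 2 chromosome
    pairs of 30 genes (10% unpaired)."""
    genes, genome, truth = generate_diploid_annotation(small_config)
    counts, sample_tissue = simulate_counts(truth, small_config)
    cds = simulate_cds_pairs(truth, small_config)
    promoters, tes, motifs = plant_regulatory_context(truth, small_config, genes)
    return dict(
        config=small_config,
        genes=genes,
        genome=genome,
        truth=truth,
        counts=counts,
        sample_tissue=sample_tissue,
        cds=cds,
        promoters=promoters,
        tes=tes,
        motifs=motifs,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
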