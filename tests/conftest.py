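"""Shared fixtures: seeded random sequences and simulated libraries.

The expensive simulated libraries are session-scoped so digestion,
demultiplexing, tag counting, saturation and QC tests all reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddgbs import SimConfig, demultiplex, simulate_genome, simulate_reads
from ddgbs.simulate import tag_table_from_demux


def random_dna(length: int, seed: int, gc: float = 0.42) -> str:
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture(scope="session")
def sim_library():
    """A 3-plex EcoRI-MseI library: genome, reads, truth, demux, tag table."""
    cfg = SimConfig(
        seed=7,
        genome_length=3_000_000,
        n_samples=3,
        abundance_sigma=0.8,
        mean_depth=30.0,
        n_snps=500,
    )
    genome = simulate_genome(cfg)
    reads, truth = simulate_reads(genome, cfg)
    demux = demultiplex(reads, truth.barcodes)
    tag_table = tag_table_from_demux(demux, truth)
    return {
        "cfg": cfg,
        "genome": genome,
        "reads": reads,
        "truth": truth,
        "demux": demux,
        "tags": tag_table,
    }


@pytest.fixture(scope="session")
def sim_multiplex():
    """A 48-plex library for depth-CV dispersion recovery (heavier tail
    statistics need many samples per fragment)."""
    cfg = SimConfig(
        seed=3,
        genome_length=2_000_000,
        n_samples=48,
        abundance_sigma=0.8,
        mean_depth=30.0,
        n_snps=300,
    )
    genome = simulate_genome(cfg)
    reads, truth = simulate_reads(genome, cfg)
    demux = demultiplex(reads, truth.barcodes)
    tag_table = tag_table_from_demux(demux, truth)
    return {"cfg": cfg, "truth": truth, "demux": demux, "tags": tag_table}
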