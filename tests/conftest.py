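"""Shared fixtures: synthetic datasets at the scales the checks need.

Heavy genome-scale fixtures are session-scoped so the simulation and
exact matching run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import syngraft as sg


@pytest.fixture(scope="session")
def tiny_dataset() -> sg.SimulatedDataset:
    """Small collinear genome: 3 chromosomes, fast enough for unit tests."""
    cfg = sg.SimulationConfig(seed=7, n_chromosomes=3, chrom_length_bp=300_000,
                              n_genes_per_chrom=60, n_scaffolds_per_chrom=6,
                              small_scaffold_fraction=0.3)
    return sg.simulate(cfg)


@pytest.fixture(scope="session")
def tiny_anchors(tiny_dataset):
    hits = sg.match_cds_builtin(tiny_dataset.cds_sequences,
                                tiny_dataset.scaffolds,
                                gene_table=tiny_dataset.reference_genes)
    best = sg.best_hit_per_cds(hits)
    return sg.anchor_all(best), best


@pytest.fixture(scope="session")
def collinear_genome() -> sg.SimulatedDataset:
    """11 chromosomes x ~1 Mb, 100 genes and 20 scaffolds per chromosome,
    no rearrangement: the truth-recovery reference condition."""
    cfg = sg.SimulationConfig(seed=11, n_chromosomes=11,
                              chrom_length_bp=1_000_000,
                              n_genes_per_chrom=100,
                              n_scaffolds_per_chrom=20,
                              small_scaffold_fraction=0.3)
    return sg.simulate(cfg)


@pytest.fixture(scope="session")
def collinear_anchors(collinear_genome):
    ds = collinear_genome
    hits = sg.match_cds_builtin(ds.cds_sequences, ds.scaffolds,
                                gene_table=ds.reference_genes)
    return sg.anchor_all(sg.best_hit_per_cds(hits))


@pytest.fixture(scope="session")
def translocated_genome() -> sg.SimulatedDataset:
    """Same conditions with 12% of genes translocated between chromosomes."""
    cfg = sg.SimulationConfig(seed=11, n_chromosomes=11,
                              chrom_length_bp=1_000_000,
                              n_genes_per_chrom=100,
                              n_scaffolds_per_chrom=20,
                              small_scaffold_fraction=0.3,
                              translocation_fraction=0.12)
    return sg.simulate(cfg)


@pytest.fixture(scope="session")
def tir_genome():
    """5-Mb uniform background with planted TIR families + one single-copy
    candidate that must be rejected."""
    from syngraft.simulate import TeSeedSpec, plant_te_copies, random_genome
    g = sg.random_genome({"chr01": 3_000_000, "chr02": 2_000_000}, seed=13)
    fams = [
        TeSeedSpec("tirA", "TIR", 1500, tir_length_bp=15, tsd_length_bp=9,
                   copy_number=5),
        TeSeedSpec("tirB", "TIR", 900, tir_length_bp=15, tsd_length_bp=9,
                   copy_number=4),
        TeSeedSpec("tirC", "TIR", 600, tir_length_bp=15, tsd_length_bp=9,
                   copy_number=3),
        TeSeedSpec("lonely", "TIR", 1200, tir_length_bp=15, tsd_length_bp=9,
                   copy_number=1),
    ]
    genome = plant_te_copies(g, fams, seed=13)
    return genome, genome.te_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_19)
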