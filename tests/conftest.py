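"""Shared fixtures: one default synthetic dataset reused across the suite."""

import numpy as np
import pytest

import homeophase as hp


@pytest.fixture(scope="session")
def default_params() -> hp.SimulationParams:
    return hp.SimulationParams()


@pytest.fixture(scope="session")
def default_genome(default_params) -> hp.SyntheticGenome:
    return hp.simulate_genome(default_params, seed=1)


@pytest.fixture(scope="session")
def default_profiles(default_genome):
    return hp.compute_dgc_profiles(
        default_genome.genes, default_genome.pairs, default_genome.pairings, window=11
    )


@pytest.fixture(scope="session")
def default_assignment(default_genome, default_profiles) -> hp.SubgenomeAssignment:
    return hp.assign_subgenomes(default_genome.pairings, default_profiles)


@pytest.fixture(scope="session")
def default_expression(default_params, default_genome):
    return hp.simulate_expression(default_params, default_genome, seed=2)


@pytest.fixture(scope="session")
def noiseless_expression(default_params, default_genome):
    return hp.simulate_expression(default_params, default_genome, seed=2, noise_sd=0.0)


@pytest.fixture(scope="session")
def fsolaris_table():
    return hp.load_fsolaris_chromosome_counts()


@pytest.fixture(scope="session")
def small_genome():
    """A small genome for cheap structural tests (no crossovers)."""
    params = hp.SimulationParams(
        n_chrom_pairs=3, genes_per_chrom=80, codons_per_gene=120,
        n_crossovers=0, crossover_min_offset=10,
    )
    return hp.simulate_genome(params, seed=7)


def per_gene_accuracy(genome: hp.SyntheticGenome, assignment: hp.SubgenomeAssignment) -> float:
    truth = genome.truth.gene_subgenome
    labelled = [g for g in truth if g in assignment.labels]
    return float(np.mean([assignment.labels[g] == truth[g] for g in labelled]))


def truth_majority_x_is_h(genome: hp.SyntheticGenome, pair_name: str) -> bool:
    """Majority true subgenome of the X-copy genes of one chromosome pairing."""
    truth = genome.truth.gene_subgenome
    votes = [
        truth[p.gene_x] == hp.SUBGENOME_H
        for p in genome.pairs
        if p.chrom_pair == pair_name
    ]
    return sum(votes) * 2 >= len(votes)


def chromosome_level_accuracy(
    genome: hp.SyntheticGenome, assignment: hp.SubgenomeAssignment
) -> float:
    """Fraction of pairings whose majority polarity matches the truth majority."""
    hits = [
        assignment.pairings[p.pair_name].x_is_h == truth_majority_x_is_h(genome, p.pair_name)
        for p in genome.pairings
    ]
    return float(np.mean(hits))
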