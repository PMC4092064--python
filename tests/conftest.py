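"""Shared fixtures.

The heavy fixtures build one desk-scale scenario (500 kb genome, 25 genes)
per session and push it through the whole pipeline; the acceptance tests and
several module tests share it to stay inside the runtime budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from rrbskit import (
    GenomeSpec,
    LibraryParams,
    align_library,
    build_index,
    extract_calls,
    generate_expression,
    generate_genome,
    generate_truth_methylome,
    simulate_library,
)

#: island wider than the hypomethylated zone so the TSS dip has shoulders;
#: the hypomethylated zone is asymmetric (500 bp upstream, 1 kb downstream)
ACC_SPEC = GenomeSpec(
    n_contigs=5,
    contig_length=100_000,
    n_genes=25,
    island_half_width=1_000,
    seed=101,
)


@pytest.fixture(scope="session")
def acc_scenario():
    genome, genes = generate_genome(ACC_SPEC)
    truth = generate_truth_methylome(
        genome, genes, active_fraction=0.5,
        promoter_upstream=500, promoter_downstream=1_000, seed=102,
    )
    index = build_index(genome)
    lengths = {c: len(s) for c, s in genome.items()}
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "index": index,
        "lengths": lengths,
    }


@pytest.fixture(scope="session")
def acc_library(acc_scenario):
    params = LibraryParams(mean_depth=150.0, seed=103)
    pairs = simulate_library(
        acc_scenario["genome"], acc_scenario["truth"], params)
    return pairs


@pytest.fixture(scope="session")
def acc_alignments(acc_scenario, acc_library):
    accepted, rejected = align_library(acc_scenario["index"], acc_library)
    return accepted, rejected


@pytest.fixture(scope="session")
def acc_calls(acc_scenario, acc_alignments):
    accepted, _ = acc_alignments
    table, qc = extract_calls(accepted, acc_scenario["genome"])
    return table, qc


@pytest.fixture(scope="session")
def strat_scenario(acc_scenario):
    """Three simulated animals with expression coupled to promoter state.

    active_fraction matches the size of the high-expression class and
    coupling is 1, so the active genes are exactly the high class.
    """
    from rrbskit import filter_by_coverage

    genome = acc_scenario["genome"]
    genes = acc_scenario["genes"]
    truth = generate_truth_methylome(
        genome, genes, active_fraction=0.2,
        promoter_upstream=500, promoter_downstream=1_000, seed=202,
    )
    expr = generate_expression(genes, truth.active_genes, coupling=1.0,
                               seed=203)
    calls_by_animal = {}
    for i, seed in enumerate((211, 212, 213)):
        pairs = simulate_library(
            genome, truth, LibraryParams(mean_depth=100.0, seed=seed))
        accepted, _ = align_library(acc_scenario["index"], pairs)
        table, _ = extract_calls(accepted, genome)
        calls_by_animal[f"animal{i + 1}"] = filter_by_coverage(table, 10)
    return {"truth": truth, "expression": expr,
            "calls_by_animal": calls_by_animal}


@pytest.fixture(scope="session")
def replicate_tables(acc_scenario):
    """Two technical replicates of the same truth with dispersed depth."""
    genome = acc_scenario["genome"]
    out = []
    for seed in (301, 302):
        pairs = simulate_library(
            genome, acc_scenario["truth"],
            LibraryParams(mean_depth=250.0, depth_dispersion=1.5, seed=seed))
        accepted, _ = align_library(acc_scenario["index"], pairs)
        table, _ = extract_calls(accepted, genome)
        out.append(table)
    return tuple(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
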