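"""Shared fixtures: handcrafted toy inputs and seeded simulated datasets.

The simulated fixtures are session-scoped because they drive several test
modules; every generator call is fully determined by its seed.
"""

from __future__ import annotations

import pytest

from uarna import DictGenome, SimConfig, run_analysis, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """120-gene, 30k reads/library dataset with 12 UP and 2 DN planted genes."""
    cfg = SimConfig(
        seed=7, n_chroms=1, chrom_len=1_600_000, n_genes=120,
        reads_per_library=30_000, n_up=12, n_dn=2,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return run_analysis(
        small_sim.genome, small_sim.genes, small_sim.libraries, "mut", "ctrl"
    )


@pytest.fixture(scope="session")
def allup_sim():
    """Every detectable-uaRNA gene planted UP: strong antisense excess."""
    cfg = SimConfig(
        seed=19, n_chroms=1, chrom_len=1_600_000, n_genes=120,
        reads_per_library=15_000, n_up=36, n_dn=0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def allup_result(allup_sim):
    return run_analysis(
        allup_sim.genome, allup_sim.genes, allup_sim.libraries, "mut", "ctrl"
    )


@pytest.fixture()
def flat_genome():
    """200 bp of G on one chromosome: any A tail is trivially non-genomic."""
    return DictGenome({"chr1": "G" * 200})
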