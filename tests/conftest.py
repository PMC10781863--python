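import numpy as np
import pytest

from ddradmap.pipeline import RunConfig, run_all
from ddradmap.simdata import (
    SimConfig,
    build_parent_genomes,
    simulate_f2_population,
)

# study-scale conditions: 3 chromosomes x 1 Mbp, 96 F2 individuals
E2E_SEED = 42


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_chromosomes=3, chromosome_length=300_000, n_f2=48)


@pytest.fixture(scope="session")
def small_parents(small_cfg):
    return build_parent_genomes(small_cfg)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full seeded pipeline run at study scale, shared across tests.

    Returns (run directory, RunConfig, reference, haplotypes, causal spec,
    F2 population) — the simulation objects are regenerated from the same
    seed, which reproduces the run's truth exactly.
    """
    out = tmp_path_factory.mktemp("e2e")
    rc = RunConfig(sim=SimConfig(seed=E2E_SEED))
    run_all(rc, out)
    ref, hap_a, hap_b, causal = build_parent_genomes(rc.sim)
    pop = simulate_f2_population(ref, causal, rc.sim)
    return out, rc, ref, hap_a, hap_b, causal, pop


def truth_discordant_count(pop, causal, chrom: str, pos: int) -> int:
    """Independent truth bookkeeping: individuals whose true genotype at
    (chrom, pos) disagrees with their phenotype under the recessive model."""
    n = 0
    for ind in pop:
        geno = str(ind.genotype_at(chrom, pos))
        white = ind.phenotype == causal.recessive_phenotype
        if white != (geno == "AA"):
            n += 1
    return n
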