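import numpy as np
import pandas as pd
import pytest

from temporalpopgen.core import GenotypeMatrix, make_sites
from temporalpopgen.simkit import (InversionSpec, SamplingEvent, SimConfig,
                                   simulate_cohorts)


def build_gm(dosage, chrom="LG01", pos=None, samples=None, ref=None, alt=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1)
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosage, make_sites(chrom, pos, ref, alt), samples)


@pytest.fixture(scope="session")
def drift_config():
    """Pure-drift two-sample design used by the Fs' calibration."""
    def factory(seed, t=10, n=50, ne=500, loci=2000):
        if t > 0:
            schedule = [SamplingEvent(2000, "migratory", n),
                        SamplingEvent(2000 + t, "migratory", n)]
        else:
            schedule = [SamplingEvent(2000, "migratory", 2 * n)]
        return SimConfig(
            n_migratory=ne, n_coastal=50, n_generations=max(t, 1),
            generation_time_years=1.0, start_year=2000,
            n_neutral_snps=loci, n_chromosomes=4,
            chromosome_length_bp=1_000_000, burn_in_generations=0,
            sampling_schedule=schedule, seed=seed)
    return factory


@pytest.fixture(scope="session")
def inversion_cohort():
    """One simulated inversion with a mixed karyotype pool of 100 fish,
    200 block SNPs at tag fidelity 0.98, plus its ground truth."""
    inv = InversionSpec("INV01", "LG01", 400_001, 1_000_000,
                        n_block_snps=200, tag_fidelity=0.98,
                        init_freq_migratory=0.5, init_freq_coastal=0.5)
    cfg = SimConfig(
        n_migratory=300, n_coastal=50, n_generations=2,
        generation_time_years=1.0, start_year=2000,
        n_neutral_snps=300, n_chromosomes=2, chromosome_length_bp=2_000_000,
        burn_in_generations=5, inversions=[inv],
        sampling_schedule=[SamplingEvent(2002, "migratory", 100)], seed=11)
    gm, samples, truth = simulate_cohorts(cfg)
    return cfg, gm, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
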