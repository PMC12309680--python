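import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temporalpopgen.core import MISSING
from temporalpopgen.simkit import (InversionSpec, MigrationEpoch,
                                   MissingnessEra, SamplingEvent,
                                   SelectionEpoch, SimConfig,
                                   inject_missingness, simulate_cohorts,
                                   write_outputs)
from temporalpopgen.geno_io import read_vcf


def tiny_config(seed=0, **kw):
    base = dict(
        n_migratory=200, n_coastal=200, n_generations=5,
        generation_time_years=1.0, start_year=2000,
        n_neutral_snps=200, n_chromosomes=2, chromosome_length_bp=1_000_000,
        burn_in_generations=0,
        sampling_schedule=[SamplingEvent(2005, "migratory", 20)], seed=seed)
    base.update(kw)
    return SimConfig(**base)


class TestNeutralDrift:
    def test_martingale_mean_frequency(self):
        """With no migration/selection the across-replicate mean terminal
        frequency equals the initial frequency within Monte-Carlo error."""
        diffs = []
        for seed in range(200):
            cfg = tiny_config(seed=seed, n_neutral_snps=50, n_generations=10)
            _, _, truth = simulate_cohorts(cfg)
            traj = truth.neutral_freq["migratory"]
            diffs.append(traj[-1] - traj[0])
        mean_shift = np.mean(diffs)
        assert abs(mean_shift) < 0.005

    def test_drift_variance(self):
        """Var(p_t - p_0) matches p0(1-p0)(1-(1-1/2N)^t) within 15% at
        N=200, t=20."""
        num, den = [], []
        for seed in range(300):
            cfg = tiny_config(seed=seed + 500, n_neutral_snps=40,
                              n_generations=20)
            _, _, truth = simulate_cohorts(cfg)
            traj = truth.neutral_freq["migratory"]
            num.append(traj[-1] - traj[0])
            den.append(traj[0])
        num = np.concatenate(num)
        p0 = np.concatenate(den)
        expected = p0 * (1 - p0) * (1 - (1 - 1 / 400) ** 20)
        keep = expected > 1e-4
        ratio = (num[keep] ** 2).mean() / expected[keep].mean()
        assert 0.85 < ratio < 1.15

    def test_determinism(self):
        a = simulate_cohorts(tiny_config(seed=42))
        b = simulate_cohorts(tiny_config(seed=42))
        np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
        pd.testing.assert_frame_equal(a[1], b[1])


class TestInversions:
    def test_perfect_tag_makes_fixed_blocks(self):
        inv = InversionSpec("I", "LG01", 1000, 200_000, n_block_snps=20,
                            tag_fidelity=1.0, init_freq_migratory=1.0,
                            init_freq_coastal=0.0)
        cfg = tiny_config(inversions=[inv])
        gm, samples, truth = simulate_cohorts(cfg)
        block = gm.take_sites(((gm.sites["pos"] >= 1000)
                               & (gm.sites["pos"] <= 200_000)
                               & (gm.sites["chrom"] == "LG01")).to_numpy())
        assert block.n_sites == 20
        assert (block.dosage == 2).all()
        assert (truth.karyotypes["I"] == 2).all()

    def test_random_mating_hwe(self):
        """Neutral replicates: karyotype counts consistent with HWE in
        >= 90% of replicates (chi-square at alpha 0.05)."""
        ok = 0
        reps = 40
        for seed in range(reps):
            inv = InversionSpec("I", "LG01", 1000, 200_000, n_block_snps=10,
                                init_freq_migratory=0.5, init_freq_coastal=0.5)
            cfg = tiny_config(seed=seed, inversions=[inv], n_generations=3,
                              sampling_schedule=[SamplingEvent(2003, "migratory", 100)])
            _, _, truth = simulate_cohorts(cfg)
            k = truth.karyotypes["I"]
            n = np.array([(k == 0).sum(), (k == 1).sum(), (k == 2).sum()])
            p = (2 * n[2] + n[1]) / (2 * n.sum())
            exp = n.sum() * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            chi2 = ((n - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            if stats.chi2.sf(chi2, 1) > 0.05:
                ok += 1
        assert ok >= 0.9 * reps - 2  # binomial slack on 40 replicates

    def test_het_advantage_rises_toward_equilibrium(self):
        """Overdominance drives expected HET frequency (2p(1-p)) up
        monotonically toward the polymorphic equilibrium."""
        het_traj = []
        for seed in range(30):
            inv = InversionSpec("I", "LG01", 1000, 200_000, n_block_snps=10,
                                init_freq_migratory=0.9, init_freq_coastal=0.9)
            cfg = tiny_config(
                seed=seed + 77, inversions=[inv], n_generations=10,
                selection_schedule=[SelectionEpoch(0, 10, "I", 0.5, 1.0, 0.5)],
                sampling_schedule=[SamplingEvent(2010, "migratory", 10)])
            _, _, truth = simulate_cohorts(cfg)
            f = truth.inversion_freq.query("population == 'migratory'") \
                .sort_values("generation")["freq"].to_numpy()
            het_traj.append(2 * f * (1 - f))
        mean_het = np.mean(het_traj, axis=0)
        assert np.all(np.diff(mean_het) > -0.01)  # monotone in expectation
        assert mean_het[-1] > mean_het[0] + 0.15


class TestMigration:
    def test_one_generation_pulse_mixing_identity(self):
        """A single 0.15 coastal->migratory pulse gives newborn migratory
        mean coastal ancestry 0.15 within binomial error."""
        fracs = []
        for seed in range(30):
            cfg = tiny_config(
                seed=seed, n_generations=3,
                migration_schedule=[MigrationEpoch(2, 3, 0.15, 0.0)],
                sampling_schedule=[SamplingEvent(2003, "migratory", 50)])
            _, _, truth = simulate_cohorts(cfg)
            fracs.append(truth.ancestry.mean())
        se = np.sqrt(0.15 * 0.85 / (2 * 200)) / np.sqrt(30)
        assert abs(np.mean(fracs) - 0.15) < 5 * se + 0.005


class TestMissingness:
    def test_rate_zero_identity(self, inversion_cohort):
        _, gm, samples, _ = inversion_cohort
        out = inject_missingness(gm, [MissingnessEra(1900, 2100, 0.0, 0.0)],
                                 seed=1, metadata=samples)
        np.testing.assert_array_equal(out.dosage, gm.dosage)

    def test_rate_one_all_missing(self, inversion_cohort):
        _, gm, samples, _ = inversion_cohort
        out = inject_missingness(gm, [MissingnessEra(1900, 2100, 1.0, 0.0)],
                                 seed=1, metadata=samples)
        assert (out.dosage == MISSING).all()

    def test_binomial_band(self):
        cfg = tiny_config(n_neutral_snps=500,
                          sampling_schedule=[SamplingEvent(2005, "migratory", 20)])
        gm, samples, _ = simulate_cohorts(cfg)
        out = inject_missingness(gm, [MissingnessEra(1900, 2100, 0.2, 0.0)],
                                 seed=3, metadata=samples)
        n = gm.dosage.size  # 10,000 genotypes
        missing = int((out.dosage == MISSING).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.2)
        assert lo <= missing <= hi

    def test_error_rate_changes_dosage(self):
        cfg = tiny_config()
        gm, samples, _ = simulate_cohorts(cfg)
        out = inject_missingness(gm, [MissingnessEra(1900, 2100, 0.0, 0.5)],
                                 seed=3, metadata=samples)
        changed = (out.dosage != gm.dosage).mean()
        assert 0.4 < changed < 0.6
        assert set(np.unique(out.dosage)) <= {0, 1, 2}


class TestOutputsAndValidation:
    def test_write_outputs_round_trip(self, tmp_path, inversion_cohort):
        cfg, gm, samples, truth = inversion_cohort
        paths = write_outputs(gm, samples, truth, tmp_path, config=cfg)
        back = read_vcf(paths["vcf"])
        np.testing.assert_array_equal(back.dosage, gm.dosage)
        assert back.samples == list(samples["sample_id"])
        bed = pd.read_csv(paths["inversions_bed"], sep="\t", header=None)
        assert bed.iloc[0, 1] == 400_000  # 0-based start

    def test_sample_exceeds_census_rejected(self):
        with pytest.raises(ValueError, match="exceeds census"):
            tiny_config(sampling_schedule=[
                SamplingEvent(2005, "migratory", 500)]).validate()

    def test_sampling_year_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tiny_config(sampling_schedule=[
                SamplingEvent(2050, "migratory", 5)]).validate()

    def test_birth_year_equals_catch_minus_age(self):
        from temporalpopgen.simkit import AgeDistribution
        cfg = tiny_config(age_distribution=AgeDistribution(1, 3, 0.5),
                          n_generations=6,
                          sampling_schedule=[SamplingEvent(2006, "migratory", 30)])
        _, samples, _ = simulate_cohorts(cfg)
        assert (samples["birth_year"] == samples["catch_year"] - samples["age"]).all()
        assert samples["age"].between(1, 3).all()
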