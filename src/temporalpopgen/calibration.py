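"""Calibration experiments: simulate known truth, run the estimators,
measure recovery.

Each function wires the simulator to one analysis stage under conditions
where the expected answer is known analytically (drift expectation
E[Fs'] ~ t/(2Ne), exchangeable permutation nulls, constructed crosses) or
recorded as simulation truth (karyotypes, ancestry pulses, selection
trajectories), and returns summary numbers. The test suite asserts on
them; the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import cohort_summary, fit_q, fit_q_all, panel_freqs
from .core import GenotypeMatrix, make_sites
from .diff_scan import permutation_q, site_fst, window_fst
from .genotype_tests import fisher_years
from .pca_karyotype import call_karyotypes
from .simkit import (InversionSpec, MigrationEpoch, SamplingEvent,
                     SelectionEpoch, SimConfig, inversion_bed,
                     simulate_cohorts)


def _drift_pair(seed, ne=500, t=10, n=50, loci=2000):
    """One plan-II drift replicate: two temporal samples of the same
    population (or one split sample when t = 0)."""
    from .temporal_f import fs_prime
    if t > 0:
        schedule = [SamplingEvent(2000, "migratory", n),
                    SamplingEvent(2000 + t, "migratory", n)]
    else:
        schedule = [SamplingEvent(2000, "migratory", 2 * n)]
    cfg = SimConfig(
        n_migratory=ne, n_coastal=50, n_generations=max(t, 1),
        generation_time_years=1.0, start_year=2000, n_neutral_snps=loci,
        n_chromosomes=4, chromosome_length_bp=1_000_000,
        burn_in_generations=0, sampling_schedule=schedule, seed=seed)
    gm, samples, _ = simulate_cohorts(cfg)
    if t > 0:
        s0 = samples[samples.catch_year == 2000]["sample_id"].tolist()
        s1 = samples[samples.catch_year == 2000 + t]["sample_id"].tolist()
        return fs_prime(gm, s0, s1, t)
    ids = samples["sample_id"].tolist()
    return fs_prime(gm, ids[:n], ids[n:], 1)


def drift_calibration(n_reps=200, seed=0, ne=500, t=10, n=50, loci=2000):
    """Wright-Fisher plan-II calibration of Fs'.

    Returns mean Fs' across replicates, the fraction of 95% jackknife CIs
    covering the drift truth t/(2Ne), and the per-replicate estimates.
    """
    truth = t / (2.0 * ne)
    res = [_drift_pair(seed + i, ne, t, n, loci) for i in range(n_reps)]
    vals = np.array([r.fs_prime for r in res])
    cover = float(np.mean([r.ci_low <= truth <= r.ci_high for r in res]))
    return {"mean_fs_prime": float(vals.mean()), "truth": truth,
            "ci_coverage": cover, "values": vals}


def null_resampling_coverage(n_reps=200, seed=0, ne=500, n=50, loci=2000):
    """Two same-generation samples (no drift): fraction of CIs covering 0."""
    res = [_drift_pair(seed + i, ne, t=0, n=n, loci=loci)
           for i in range(n_reps)]
    cover = float(np.mean([r.ci_low <= 0.0 <= r.ci_high for r in res]))
    vals = np.array([r.fs_prime for r in res])
    return {"ci_covers_zero": cover, "mean_fs_prime": float(vals.mean())}


def karyotype_recovery(seed=11, n_block_snps=200, tag_fidelity=0.98,
                       n_samples=100):
    """Simulated inversion with a mixed karyotype pool; concordance of the
    PCA/cluster calls with the simulator truth, and per-class mean
    heterozygous-site fractions."""
    inv = InversionSpec("INV01", "LG01", 400_001, 1_000_000,
                        n_block_snps=n_block_snps, tag_fidelity=tag_fidelity,
                        init_freq_migratory=0.5, init_freq_coastal=0.5)
    cfg = SimConfig(
        n_migratory=300, n_coastal=50, n_generations=2,
        generation_time_years=1.0, start_year=2000, n_neutral_snps=300,
        n_chromosomes=2, chromosome_length_bp=2_000_000,
        burn_in_generations=5, inversions=[inv],
        sampling_schedule=[SamplingEvent(2002, "migratory", n_samples)],
        seed=seed)
    gm, _, truth = simulate_cohorts(cfg)
    calls = call_karyotypes(gm, inversion_bed(cfg))
    merged = calls.merge(truth.karyotypes.reset_index(), on="sample_id")
    concordance = float((merged["call_code"] == merged["INV01"]).mean())
    het_means = merged.groupby("call")["het_fraction"].mean().to_dict()
    return {"concordance": concordance, "het_means": het_means}


def permutation_null_uniformity(seed=1, n_windows=500, n_perm=500,
                                n_samples=40):
    """Exchangeable-groups FST scan: KS test of the permutation p-values
    against Uniform(0,1)."""
    rng = np.random.default_rng(seed)
    loci = 2 * n_windows
    pos = np.arange(1, n_windows * 1000 + 1, 500)[:loci]
    p = rng.uniform(0.1, 0.9, loci)
    d = rng.binomial(2, p, size=(n_samples, loci)).astype(np.int8)
    gm = GenotypeMatrix(d, make_sites("LG01", pos),
                        [f"s{i}" for i in range(n_samples)])
    half = n_samples // 2
    ga, gb = gm.samples[:half], gm.samples[half:]
    comps = site_fst(gm, ga, gb)
    win = window_fst(comps, 1000, 1000)
    out = permutation_q(win, gm, ga, gb, n_perm=n_perm, seed=seed + 1,
                        window_bp=1000, step_bp=1000)
    pvals = out["p"].dropna().to_numpy()
    ks = stats.kstest(pvals, "uniform")
    return {"n_windows": int(len(pvals)), "ks_p": float(ks.pvalue),
            "frac_below_05": float((pvals < 0.05).mean())}


def hwe_rejection_rate(n_reps=400, seed=0, n=100, alpha=0.05):
    """HWE chi-square rejection rate on multinomial draws from exact HWE."""
    from .genotype_tests import hwe_chisq
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        counts = rng.multinomial(n, [0.25, 0.5, 0.25])
        if hwe_chisq(*counts).p < alpha:
            rej += 1
    return {"rejection_rate": rej / n_reps}


def kruskal_rejection_rate(n_reps=300, seed=0, alpha=0.05):
    """Kruskal-Wallis rejection rate with three exchangeable groups."""
    from .genotype_tests import kruskal_dunn
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        vals = rng.normal(size=30)
        res = kruskal_dunn({"a": vals[:10], "b": vals[10:20], "c": vals[20:]})
        if res.p < alpha:
            rej += 1
    return {"rejection_rate": rej / n_reps}


def _fixed_difference_panels(L=2000, n_panel=10):
    panelA = np.zeros((n_panel, L), dtype=np.int8)
    panelB = np.full((n_panel, L), 2, dtype=np.int8)
    samples = ([f"A{i}" for i in range(n_panel)]
               + [f"B{i}" for i in range(n_panel)])
    gm = GenotypeMatrix(np.vstack([panelA, panelB]),
                        make_sites("LG01", np.arange(1, L + 1)), samples)
    return panel_freqs(gm, {"A": samples[:n_panel], "B": samples[n_panel:]})


def ancestry_f1_recovery(L=2000):
    """All-heterozygous F1 between fixed-difference panels: estimated q."""
    names, freqs = _fixed_difference_panels(L)
    est = fit_q(np.ones(L, dtype=np.int8), freqs, panels=names)
    return {"q": est.q, "max_abs_err": float(np.abs(est.q - 0.5).max())}


def ancestry_backcross_recovery(n_reps=50, seed=0, true_q=0.25, L=2000):
    """Backcross genomes drawn at mixture q: mean absolute error of q-hat."""
    rng = np.random.default_rng(seed)
    names, freqs = _fixed_difference_panels(L)
    mix = true_q * freqs[0] + (1 - true_q) * freqs[1]
    errs = []
    for _ in range(n_reps):
        g = rng.binomial(2, mix).astype(np.int8)
        est = fit_q(g, freqs, panels=names)
        errs.append(abs(est.q[0] - true_q))
    return {"mae": float(np.mean(errs)), "true_q": true_q}


def ancestry_pulse_detection(n_reps=20, seed=0, pulse=0.15, n_per_cohort=20,
                             alpha=0.05):
    """A one-generation coastal->migratory pulse; per replicate the
    supervised q estimates are aggregated by birth cohort and tested with
    Kruskal-Wallis. Returns the detection rate and whether the post-pulse
    cohort had the top mean in each replicate."""
    detected = 0
    top_is_post_pulse = 0
    for r in range(n_reps):
        cfg = SimConfig(
            n_migratory=200, n_coastal=200, n_generations=6,
            generation_time_years=1.0, start_year=2000,
            n_neutral_snps=1200, n_chromosomes=3,
            chromosome_length_bp=1_000_000, burn_in_generations=40,
            migration_schedule=[MigrationEpoch(3, 4, pulse, 0.0)],
            sampling_schedule=(
                [SamplingEvent(2000, "migratory", n_per_cohort),
                 SamplingEvent(2000, "coastal", n_per_cohort)]
                + [SamplingEvent(2000 + g, "migratory", n_per_cohort)
                   for g in range(2, 7)]),
            seed=seed + r)
        gm, samples, _ = simulate_cohorts(cfg)
        panels = {
            "migratory": samples[(samples.catch_year == 2000)
                                 & (samples.population == "migratory")]
            ["sample_id"].tolist(),
            "coastal": samples[samples.population == "coastal"]
            ["sample_id"].tolist()}
        targets = samples[(samples.population == "migratory")
                          & (samples.catch_year > 2000)]
        est = fit_q_all(gm, panels, targets["sample_id"].tolist())
        summary, test = cohort_summary(est, samples, "q_coastal",
                                       class_width_years=1)
        if test is not None and test.p < alpha:
            detected += 1
        top = summary.loc[summary["mean"].idxmax(), "cohort"]
        if int(top.split("-")[0]) >= 2004:  # born at/after the pulse
            top_is_post_pulse += 1
    return {"detection_rate": detected / n_reps,
            "top_cohort_post_pulse_rate": top_is_post_pulse / n_reps}


def het_advantage_separation(n_reps=20, seed=0, w_hom=0.5, alpha=0.05):
    """Overdominant selection epoch: per replicate, did the true HET
    karyotype frequency rise between the early and late samples, and did
    the early/late genotype tables separate in the exact test?"""
    both = 0
    for r in range(n_reps):
        inv = InversionSpec("I", "LG01", 1000, 300_000, n_block_snps=20,
                            init_freq_migratory=0.9, init_freq_coastal=0.9)
        cfg = SimConfig(
            n_migratory=200, n_coastal=50, n_generations=10,
            generation_time_years=1.0, start_year=2000, n_neutral_snps=100,
            n_chromosomes=1, chromosome_length_bp=1_000_000,
            burn_in_generations=0, inversions=[inv],
            selection_schedule=[SelectionEpoch(0, 10, "I", w_hom, 1.0, w_hom)],
            sampling_schedule=[SamplingEvent(2000, "migratory", 50),
                               SamplingEvent(2010, "migratory", 50)],
            seed=seed + r)
        _, samples, truth = simulate_cohorts(cfg)
        k = truth.karyotypes.join(samples.set_index("sample_id")["catch_year"])
        counts = (k.groupby("catch_year")["I"].value_counts()
                  .unstack(fill_value=0).reindex(columns=[0, 1, 2],
                                                 fill_value=0))
        counts.columns = ["n_ANCESTRAL", "n_HET", "n_DERIVED"]
        het = counts["n_HET"] / counts.sum(axis=1)
        res = fisher_years(counts, alpha=alpha)
        if het[2010] > het[2000] and res.letters[2000] != res.letters[2010]:
            both += 1
    return {"success_rate": both / n_reps}
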