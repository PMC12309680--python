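"""End-to-end orchestration: simulate -> filter/prune -> PCA -> karyotype
-> Fs' -> FST scan -> diversity -> genotype tests -> ancestry.

Every stage reads its inputs from, and writes TSV/VCF outputs to, a run
directory; a stage is skipped when all of its outputs already exist, so
deleting an intermediate reruns only that stage and everything downstream.
All randomness flows from the manifest's per-stage seed registry, derived
deterministically from one master seed; rerunning with the same seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc_mod
from . import diff_scan, diversity, geno_io, genotype_tests, pca_karyotype, simkit
from . import temporal_f
from .core import read_bed, read_metadata

STAGES = ["simulate", "filter", "pca", "karyotype", "fsprime",
          "fst_scan", "diversity", "genotest", "ancestry"]


def default_config(seed: int = 0) -> dict:
    """Demonstration configuration mirroring the study design: two
    ecotypes, 5,000 genome-wide SNPs, four inversion supergenes, seven
    sampling years across a century, recent coastal-into-migratory gene
    flow, a late heterozygote-advantage epoch on the LG01 inversion, and
    heavier missingness for historical eras."""
    inversions = [
        dict(inversion_id="INV01", chromosome="LG01", start=400_001, end=1_000_000),
        dict(inversion_id="INV02", chromosome="LG02", start=200_001, end=700_000),
        dict(inversion_id="INV07", chromosome="LG07", start=600_001, end=1_100_000),
        dict(inversion_id="INV12", chromosome="LG12", start=100_001, end=500_000),
    ]
    for inv in inversions:
        inv.update(n_block_snps=120, tag_fidelity=0.98,
                   init_freq_migratory=0.92, init_freq_coastal=0.08)
    sim = dict(
        n_migratory=400, n_coastal=400,
        n_generations=14, generation_time_years=8.0, start_year=1900,
        n_neutral_snps=5000, n_chromosomes=12, chromosome_length_bp=2_000_000,
        beta_shape=[0.8, 0.8], burn_in_generations=20,
        inversions=inversions,
        migration_schedule=[
            dict(gen_start=0, gen_end=9, m_coastal_to_migratory=0.005,
                 m_migratory_to_coastal=0.002),
            dict(gen_start=9, gen_end=14, m_coastal_to_migratory=0.04,
                 m_migratory_to_coastal=0.002),
        ],
        selection_schedule=[
            dict(gen_start=9, gen_end=14, inversion_id="INV01",
                 w_ancestral=0.75, w_het=1.0, w_derived=0.85,
                 population="migratory"),
        ],
        sampling_schedule=(
            [dict(year=y, population="migratory", n=40)
             for y in (1908, 1932, 1956, 1972, 1988, 2004, 2012)]
            + [dict(year=y, population="coastal", n=40) for y in (1988, 2012)]
        ),
        missingness_schedule=[
            dict(year_min=1900, year_max=1960, missing_rate=0.08, error_rate=0.01),
            dict(year_min=1961, year_max=2100, missing_rate=0.01, error_rate=0.001),
        ],
        age_distribution=dict(age_min=3, age_max=15, p=0.35),
        seed=seed,
    )
    return {
        "simulate": sim,
        "filter": dict(max_site_missing=0.3, max_sample_missing=0.5,
                       maf_min=0.01, drop_ct_ga=False,
                       prune_window=50, prune_step=5, prune_r2=0.5),
        "pca": dict(k=5),
        "karyotype": dict(min_sites=10),
        "fsprime": dict(pairs=[[1908, 2012], [1908, 1972], [1972, 2012]]),
        "fst_scan": dict(year_a=1908, year_b=2012, window_bp=30_000,
                         step_bp=15_000, n_perm=200, afd_quantile=0.999),
        "diversity": dict(group_year=2012, tajima_window=30_000, pi_window=50_000),
        "genotest": dict(alpha=0.05, fisher_draws=20_000),
        "ancestry": dict(class_width_years=3, min_sites=100,
                         panel_year=2012),
        "seed": seed,
    }


def _seed_registry(master: int) -> dict:
    return {name: (master * 1000 + i * 101) % (2 ** 31 - 1)
            for i, name in enumerate(STAGES)}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Pipeline:
    """Cached, seeded execution of the full workflow in `out_dir`."""

    def __init__(self, config: dict, out_dir: str, log=print):
        self.config = config
        self.out_dir = out_dir
        self.seed = int(config.get("seed", 0))
        self.seeds = _seed_registry(self.seed)
        self.log = log or (lambda *a: None)
        os.makedirs(out_dir, exist_ok=True)

    # -- helpers ----------------------------------------------------------
    def path(self, *parts) -> str:
        p = os.path.join(self.out_dir, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def _cached(self, stage, outputs):
        if all(os.path.exists(p) for p in outputs.values()):
            self.log(f"[{stage}] cached ({len(outputs)} outputs present)")
            return True
        return False

    def _load_neutral(self):
        gm = geno_io.read_vcf(self.path("filter", "neutral.vcf"))
        meta = read_metadata(self.path("simulate", "metadata.tsv"))
        meta = meta[meta["sample_id"].isin(gm.samples)]
        return gm, meta

    def _load_filtered(self):
        gm = geno_io.read_vcf(self.path("filter", "filtered.vcf"))
        meta = read_metadata(self.path("simulate", "metadata.tsv"))
        meta = meta[meta["sample_id"].isin(gm.samples)]
        return gm, meta

    def _year_samples(self, meta, year, population="migratory"):
        m = meta[(meta["catch_year"] == year) & (meta["population"] == population)]
        return m["sample_id"].tolist()

    # -- stages -----------------------------------------------------------
    def simulate(self):
        out = {k: self.path("simulate", v) for k, v in [
            ("vcf", "cohorts.vcf"), ("meta", "metadata.tsv"),
            ("truth", "truth_samples.tsv"), ("bed", "inversions.bed")]}
        if self._cached("simulate", out):
            return out
        scfg = dict(self.config["simulate"])
        scfg["seed"] = self.seeds["simulate"]
        cfg = simkit.SimConfig.from_dict(scfg)
        gm, samples, truth = simkit.simulate_cohorts(cfg)
        gm = simkit.inject_missingness(gm, cfg.missingness_schedule,
                                       self.seeds["simulate"] + 1, samples)
        simkit.write_outputs(gm, samples, truth, os.path.dirname(out["vcf"]),
                             config=cfg)
        self.log(f"[simulate] {gm.n_samples} samples x {gm.n_sites} sites")
        return out

    def filter(self):
        out = {"filtered": self.path("filter", "filtered.vcf"),
               "neutral": self.path("filter", "neutral.vcf"),
               "report": self.path("filter", "filter_report.tsv")}
        if self._cached("filter", out):
            return out
        fc = self.config["filter"]
        gm = geno_io.read_vcf(self.path("simulate", "cohorts.vcf"))
        rules = geno_io.FilterRules(
            biallelic_only=True,
            max_site_missing=fc["max_site_missing"],
            max_sample_missing=fc["max_sample_missing"],
            maf_min=fc["maf_min"], drop_ct_ga=fc.get("drop_ct_ga", False))
        filt, report = geno_io.apply_site_filters(gm, rules)
        geno_io.write_vcf(filt, out["filtered"])
        bed = read_bed(self.path("simulate", "inversions.bed"))
        neutral = geno_io.exclude_regions(filt, bed)
        neutral = geno_io.ld_prune(neutral, fc["prune_window"],
                                   fc["prune_step"], fc["prune_r2"])
        geno_io.write_vcf(neutral, out["neutral"])
        report.to_frame().to_csv(out["report"], sep="\t", index=False)
        self.log(f"[filter] {gm.n_sites} -> {filt.n_sites} sites "
                 f"(neutral set: {neutral.n_sites})")
        return out

    def pca(self):
        out = {"coords": self.path("pca", "coords.tsv"),
               "evals": self.path("pca", "explained_variance.tsv")}
        if self._cached("pca", out):
            return out
        gm, meta = self._load_neutral()
        res = pca_karyotype.run_pca(gm, k=self.config["pca"]["k"])
        coords = pd.DataFrame(res.coords, index=res.samples,
                              columns=[f"PC{i + 1}" for i in range(res.coords.shape[1])])
        coords.index.name = "sample_id"
        coords.to_csv(out["coords"], sep="\t")
        pd.DataFrame({"axis": np.arange(1, len(res.explained_var) + 1),
                      "explained_var": res.explained_var}) \
            .to_csv(out["evals"], sep="\t", index=False)
        self.log(f"[pca] PC1 explains {res.explained_var[0]:.3f}")
        return out

    def karyotype(self):
        out = {"calls": self.path("karyotype", "calls.tsv")}
        if self._cached("karyotype", out):
            return out
        gm, meta = self._load_filtered()
        bed = pd.read_csv(self.path("simulate", "inversions.bed"), sep="\t",
                          header=None, names=["chrom", "start", "end", "name"])
        anchors = self._year_samples(
            meta, int(meta[meta["population"] == "migratory"]["catch_year"].min()))
        calls = pca_karyotype.call_karyotypes(
            gm, bed, anchor_samples=anchors,
            min_sites=self.config["karyotype"]["min_sites"])
        calls.to_csv(out["calls"], sep="\t", index=False)
        self.log(f"[karyotype] {len(calls)} calls over "
                 f"{calls['inversion'].nunique()} inversions")
        return out

    def fsprime(self):
        out = {"table": self.path("fsprime", "fs_prime.tsv")}
        if self._cached("fsprime", out):
            return out
        gm, meta = self._load_neutral()
        gen_time = self.config["simulate"]["generation_time_years"]
        rows = []
        for ya, yb in self.config["fsprime"]["pairs"]:
            sa = self._year_samples(meta, ya)
            sb = self._year_samples(meta, yb)
            t = abs(yb - ya) / gen_time
            res = temporal_f.fs_prime(gm, sa, sb, t, pair=(ya, yb))
            rows.append({"year_a": ya, "year_b": yb, "fs_raw": res.fs_raw,
                         "fs_prime": res.fs_prime, "se": res.se,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "n_harmonic": res.n_harmonic, "n_loci": res.n_loci,
                         "t_generations": res.t_generations,
                         "ne": res.ne_estimate})
            self.log(f"[fsprime] {res.summary()}")
        pd.DataFrame(rows).to_csv(out["table"], sep="\t", index=False)
        return out

    def fst_scan(self):
        out = {"windows": self.path("fst_scan", "windows.tsv"),
               "afd": self.path("fst_scan", "afd.tsv")}
        if self._cached("fst_scan", out):
            return out
        fc = self.config["fst_scan"]
        gm, meta = self._load_filtered()
        ga = self._year_samples(meta, fc["year_a"])
        gb = self._year_samples(meta, fc["year_b"])
        comps = diff_scan.site_fst(gm, ga, gb)
        win = diff_scan.window_fst(comps, fc["window_bp"], fc["step_bp"])
        win = diff_scan.permutation_q(win, gm, ga, gb, n_perm=fc["n_perm"],
                                      seed=self.seeds["fst_scan"],
                                      window_bp=fc["window_bp"],
                                      step_bp=fc["step_bp"])
        win.to_csv(out["windows"], sep="\t", index=False)
        adf = diff_scan.afd(gm, ga, gb, fc["afd_quantile"])
        adf.to_csv(out["afd"], sep="\t", index=False)
        self.log(f"[fst_scan] {len(win)} windows, "
                 f"{int((win['q'] < 0.05).sum())} with q<0.05")
        return out

    def diversity(self):
        out = {"tajima": self.path("diversity", "tajima_windows.tsv"),
               "pi": self.path("diversity", "pi_windows.tsv"),
               "contrast": self.path("diversity", "region_contrast.tsv")}
        if self._cached("diversity", out):
            return out
        dc = self.config["diversity"]
        gm, meta = self._load_filtered()
        ids = self._year_samples(meta, dc["group_year"])
        taj = diversity.tajimas_d_windows(gm, ids, dc["tajima_window"])
        pi = diversity.pi_windows(gm, ids, dc["pi_window"])
        taj.to_csv(out["tajima"], sep="\t", index=False)
        pi.to_csv(out["pi"], sep="\t", index=False)
        bed = pd.read_csv(self.path("simulate", "inversions.bed"), sep="\t",
                          header=None, names=["chrom", "start", "end", "name"])
        contrast = diversity.region_contrast(taj, bed, stat="tajima_d")
        contrast.to_csv(out["contrast"], sep="\t", index=False)
        self.log(f"[diversity] {len(taj)} D windows, {len(pi)} pi windows")
        return out

    def genotest(self):
        out = {"freqs": self.path("genotest", "genotype_freqs.tsv"),
               "tests": self.path("genotest", "tests.tsv")}
        if self._cached("genotest", out):
            return out
        gc = self.config["genotest"]
        calls = pd.read_csv(self.path("karyotype", "calls.tsv"), sep="\t")
        meta = read_metadata(self.path("simulate", "metadata.tsv"))
        calls = calls.merge(meta[["sample_id", "population", "catch_year"]],
                            on="sample_id")
        calls = calls[calls["population"] == "migratory"]
        freq_rows, test_rows = [], []
        for inv, sub in calls.groupby("inversion"):
            table = genotype_tests.genotype_freq_table(sub, by="catch_year")
            table.insert(0, "inversion", inv)
            freq_rows.append(table.reset_index())
            fisher = genotype_tests.fisher_years(
                table, alpha=gc["alpha"], n_draws=gc["fisher_draws"],
                seed=self.seeds["genotest"])
            for year, g in sub.groupby("catch_year"):
                n = g["call"].value_counts()
                hwe = genotype_tests.hwe_chisq(
                    int(n.get("ANCESTRAL", 0)), int(n.get("HET", 0)),
                    int(n.get("DERIVED", 0)))
                test_rows.append({
                    "inversion": inv, "catch_year": year,
                    "hwe_chi2": hwe.statistic, "hwe_p": hwe.p,
                    "fisher_overall_p": fisher.p,
                    "letter": fisher.letters.get(year, "")})
        pd.concat(freq_rows).to_csv(out["freqs"], sep="\t", index=False)
        pd.DataFrame(test_rows).to_csv(out["tests"], sep="\t", index=False)
        self.log(f"[genotest] {len(test_rows)} group tests")
        return out

    def ancestry(self):
        out = {"q": self.path("ancestry", "ancestry_q.tsv"),
               "cohorts": self.path("ancestry", "cohort_summary.tsv")}
        if self._cached("ancestry", out):
            return out
        ac = self.config["ancestry"]
        gm, meta = self._load_neutral()
        panels = {
            "coastal": self._year_samples(meta, ac["panel_year"], "coastal"),
            "migratory": self._year_samples(
                meta, int(meta[meta["population"] == "migratory"]["catch_year"].min())),
        }
        targets = meta[(meta["population"] == "migratory")
                       & ~meta["sample_id"].isin(panels["migratory"])]
        est = anc_mod.fit_q_all(gm, panels, targets["sample_id"].tolist(),
                                min_sites=ac["min_sites"])
        est.to_csv(out["q"], sep="\t")
        summary, test = anc_mod.cohort_summary(
            est, meta, "q_coastal", ac["class_width_years"])
        if test is not None:
            summary["kw_p"] = test.p
        summary.to_csv(out["cohorts"], sep="\t", index=False)
        self.log(f"[ancestry] mean coastal q = {est['q_coastal'].mean():.3f}"
                 + (f", KW p = {test.p:.3g}" if test is not None else ""))
        return out

    # -- driver -----------------------------------------------------------
    def run_all(self) -> dict:
        manifest = {"config_hash": _config_hash(self.config),
                    "seed": self.seed, "seeds": self.seeds, "stages": {}}
        for stage in STAGES:
            try:
                outputs = getattr(self, stage)()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            manifest["stages"][stage] = {
                k: os.path.relpath(v, self.out_dir) for k, v in outputs.items()}
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def load_config(path=None, seed: int = 0) -> dict:
    """Load a YAML run configuration; with no path, the built-in demo
    configuration is used. A top-level `seed` in the file is overridden by
    the `seed` argument only when the file does not set one."""
    if path is None:
        return default_config(seed)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("seed", seed)
    base = default_config(int(cfg["seed"]))
    for key, val in cfg.items():
        if isinstance(val, dict) and key in base:
            base[key].update(val)
        else:
            base[key] = val
    return base
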