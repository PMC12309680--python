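"""Forward Wright-Fisher simulator of two interbreeding ecotypes.

Emulates a century-scale temporal sampling design on a migratory and a
coastal population: genome-wide weakly differentiated neutral SNPs, a set
of inversion supergenes in strong internal LD that discriminate the
ecotypes, time-varying directional gene flow, optional karyotype-dependent
viability selection, and era-specific missingness/genotyping error for
historical samples.

Model
-----
* Neutral loci evolve per population as allele COUNTS out of 2N: binomial
  resampling each generation, with migration applied as deterministic
  frequency mixing before reproduction. Individuals are instantiated only
  when sampled, by drawing alleles without replacement (hypergeometric)
  from their birth generation's allele pool and pairing them at random
  (Hardy-Weinberg within cohort).
* Each inversion is a single Mendelian biallelic locus (arrangement
  alleles ANCESTRAL/DERIVED) transmitted without recombination, tracked
  through an explicit individual layer that also carries each fish's
  coastal-ancestry fraction (the recursive average of its parents').
* Sampling follows plan II: sampled individuals are removed from the
  breeding pool of their generation and do not reproduce.
* Block SNPs inside an inversion copy the arrangement allele of each
  haplotype with probability ``tag_fidelity`` (gene flux / genotyping
  error makes a tag imperfect).
* Calendar: generation g corresponds to year ``start_year + round(g * T)``
  with T the generation time in years; age at catch is drawn from a
  truncated geometric distribution and birth year = catch year - age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, META_COLUMNS, make_sites, write_bed, write_metadata
from .geno_io import write_vcf

MIGRATORY = "migratory"
COASTAL = "coastal"

KARYOTYPE_NAMES = {0: "ANCESTRAL", 1: "HET", 2: "DERIVED"}


@dataclass
class InversionSpec:
    """One inversion supergene: interval, tag-SNP block and initial
    arrangement frequencies (DERIVED allele) per population."""

    inversion_id: str
    chromosome: str
    start: int               # 1-based inclusive, bp
    end: int                 # 1-based inclusive, bp
    n_block_snps: int = 100
    tag_fidelity: float = 0.98
    init_freq_migratory: float = 0.95
    init_freq_coastal: float = 0.05

    def validate(self):
        if not (0.5 < self.tag_fidelity <= 1.0):
            raise ValueError("tag_fidelity must be in (0.5, 1]")
        for f in (self.init_freq_migratory, self.init_freq_coastal):
            if not 0.0 <= f <= 1.0:
                raise ValueError("initial arrangement frequencies must be in [0,1]")
        if self.end <= self.start:
            raise ValueError("inversion end must exceed start")


@dataclass
class MigrationEpoch:
    """Per-generation gene-flow proportions active while producing
    generations gen_start+1 .. gen_end (i.e. for parents in
    [gen_start, gen_end))."""

    gen_start: int
    gen_end: int
    m_coastal_to_migratory: float = 0.0
    m_migratory_to_coastal: float = 0.0


@dataclass
class SelectionEpoch:
    """Viability weights on karyotype (ANCESTRAL hom / HET / DERIVED hom)
    applied to parents in generations [gen_start, gen_end)."""

    gen_start: int
    gen_end: int
    inversion_id: str
    w_ancestral: float = 1.0
    w_het: float = 1.0
    w_derived: float = 1.0
    population: str = MIGRATORY


@dataclass
class SamplingEvent:
    year: int
    population: str
    n: int


@dataclass
class MissingnessEra:
    """Era-specific (by catch year) missing-genotype and genotype-error
    rates, emulating degraded historical material."""

    year_min: int
    year_max: int
    missing_rate: float = 0.0
    error_rate: float = 0.0


@dataclass
class AgeDistribution:
    """Truncated geometric age-at-catch (years): P(age = a_min + k)
    proportional to (1-p)^k for k = 0..(a_max - a_min)."""

    age_min: int = 0
    age_max: int = 0
    p: float = 0.5

    def draw(self, rng, size):
        k = self.age_max - self.age_min
        if k <= 0:
            return np.full(size, self.age_min, dtype=int)
        w = (1.0 - self.p) ** np.arange(k + 1)
        w /= w.sum()
        return self.age_min + rng.choice(k + 1, size=size, p=w)


@dataclass
class SimConfig:
    n_migratory: int = 500
    n_coastal: int = 500
    n_generations: int = 14
    generation_time_years: float = 8.0
    start_year: int = 1900
    n_neutral_snps: int = 5000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 5_000_000
    beta_shape: tuple = (0.8, 0.8)
    burn_in_generations: int = 20
    migration_schedule: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    selection_schedule: list = field(default_factory=list)
    sampling_schedule: list = field(default_factory=list)
    missingness_schedule: list = field(default_factory=list)
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    seed: int = 0

    # -- calendar ---------------------------------------------------------
    def year_of_generation(self, g: int) -> int:
        return int(self.start_year + round(g * self.generation_time_years))

    def generation_of_year(self, year: int) -> int:
        return int(round((year - self.start_year) / self.generation_time_years))

    def validate(self):
        if self.n_migratory <= 0 or self.n_coastal <= 0:
            raise ValueError("census sizes must be positive")
        for inv in self.inversions:
            inv.validate()
        for ep in self.migration_schedule:
            for m in (ep.m_coastal_to_migratory, ep.m_migratory_to_coastal):
                if not 0.0 <= m <= 1.0:
                    raise ValueError("migration rates must be in [0,1]")
        for ep in self.selection_schedule:
            if min(ep.w_ancestral, ep.w_het, ep.w_derived) <= 0:
                raise ValueError("fitness values must be > 0")
        for ev in self.sampling_schedule:
            g = self.generation_of_year(ev.year)
            if not 0 <= g <= self.n_generations:
                raise ValueError(
                    f"sampling year {ev.year} maps to generation {g}, outside "
                    f"[0, {self.n_generations}]")
            census = self.n_migratory if ev.population == MIGRATORY else self.n_coastal
            if ev.n > census:
                raise ValueError(f"sample of {ev.n} exceeds census {census} "
                                 f"for {ev.population}")
        for era in self.missingness_schedule:
            for r in (era.missing_rate, era.error_rate):
                if not 0.0 <= r <= 1.0:
                    raise ValueError("missingness/error rates must be in [0,1]")

    # -- (de)serialisation for config files -------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["inversions"] = [InversionSpec(**x) for x in d.get("inversions", [])]
        d["migration_schedule"] = [MigrationEpoch(**x) for x in d.get("migration_schedule", [])]
        d["selection_schedule"] = [SelectionEpoch(**x) for x in d.get("selection_schedule", [])]
        d["sampling_schedule"] = [SamplingEvent(**x) for x in d.get("sampling_schedule", [])]
        d["missingness_schedule"] = [MissingnessEra(**x) for x in d.get("missingness_schedule", [])]
        if "beta_shape" in d:
            d["beta_shape"] = tuple(d["beta_shape"])
        if isinstance(d.get("age_distribution"), dict):
            d["age_distribution"] = AgeDistribution(**d["age_distribution"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_shape"] = list(self.beta_shape)
        return d


@dataclass
class Truth:
    """Ground truth for recovery tests: per-sample karyotypes and ancestry,
    plus per-generation population allele frequencies."""

    karyotypes: pd.DataFrame       # sample_id x inversion_id -> 0/1/2 DERIVED dose
    ancestry: pd.Series            # sample_id -> true coastal-ancestry fraction
    neutral_freq: dict             # population -> (n_generations+1, L) array
    inversion_freq: pd.DataFrame   # generation, population, inversion_id, freq
    messages: list = field(default_factory=list)


class _PopState:
    """Mutable per-population state: neutral allele counts + individual
    layer (arrangement alleles, ancestry, sampled flags) per generation."""

    def __init__(self, n, counts, arr, anc):
        self.n = n
        self.counts = counts          # current-generation neutral counts (L,)
        self.arr = arr                # (N, 2, n_inv) int8 DERIVED indicator
        self.anc = anc                # (N,) float coastal-ancestry fraction
        self.hist_counts = {}         # gen -> counts snapshot
        self.hist_arr = {}
        self.hist_anc = {}
        self.sampled = {}             # gen -> bool mask over individuals
        self.pool = {}                # gen -> [n_remaining, counts_remaining]

    def snapshot(self, g):
        self.hist_counts[g] = self.counts.copy()
        self.hist_arr[g] = self.arr.copy()
        self.hist_anc[g] = self.anc.copy()
        self.sampled[g] = np.zeros(self.n, dtype=bool)

    def allele_pool(self, g):
        if g not in self.pool:
            self.pool[g] = [self.n, self.hist_counts[g].copy()]
        return self.pool[g]


def _assign_alleles(rng, x_counts, n_hap):
    """Distribute x alt alleles per locus uniformly over n_hap haplotypes.

    Returns (L, n_hap) 0/1 matrix whose row sums equal x_counts."""
    L = len(x_counts)
    u = rng.random((L, n_hap))
    ranks = np.argsort(np.argsort(u, axis=1), axis=1)
    return (ranks < x_counts[:, None]).astype(np.int8)


def _active_epochs(schedule, g):
    return [ep for ep in schedule if ep.gen_start <= g < ep.gen_end]


def _fitness(cfg, state_arr, g, population):
    """Per-individual viability weight from active selection epochs."""
    w = np.ones(state_arr.shape[0])
    inv_index = {inv.inversion_id: k for k, inv in enumerate(cfg.inversions)}
    for ep in _active_epochs(cfg.selection_schedule, g):
        if ep.population != population:
            continue
        k = inv_index[ep.inversion_id]
        dose = state_arr[:, :, k].sum(axis=1)  # 0/1/2 DERIVED alleles
        w *= np.choose(dose, [ep.w_ancestral, ep.w_het, ep.w_derived])
    return w


def _place_sites(rng, cfg):
    """Lay out neutral SNPs (outside inversions) and inversion block SNPs.

    Returns (sites DataFrame sorted by chrom/pos, neutral column index,
    dict inversion_id -> column indices)."""
    chrom_names = [f"LG{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    inv_by_chrom = {}
    for inv in cfg.inversions:
        inv_by_chrom.setdefault(inv.chromosome, []).append(inv)

    bases = np.array(list("ACGT"))
    rows = []  # (chrom, pos, kind, which)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_neutral_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_neutral_snps % cfg.n_chromosomes] += 1
    for ci, chrom in enumerate(chrom_names):
        need = per_chrom[ci]
        taken = set()
        guard = 0
        while len(taken) < need:
            cand = rng.integers(1, cfg.chromosome_length_bp + 1, size=need * 2)
            for p in cand:
                p = int(p)
                if p in taken:
                    continue
                if any(inv.start <= p <= inv.end for inv in inv_by_chrom.get(chrom, [])):
                    continue
                taken.add(p)
                if len(taken) == need:
                    break
            guard += 1
            if guard > 100:
                raise RuntimeError("cannot place neutral SNPs outside inversions")
        rows.extend((chrom, p, "neutral", None) for p in sorted(taken))
    for inv in cfg.inversions:
        if inv.chromosome not in chrom_names:
            raise ValueError(f"inversion {inv.inversion_id} on unknown "
                             f"chromosome {inv.chromosome}")
        span = inv.end - inv.start + 1
        if span < inv.n_block_snps:
            raise ValueError("inversion interval too small for its block SNPs")
        pos = rng.choice(span, size=inv.n_block_snps, replace=False) + inv.start
        rows.extend((inv.chromosome, int(p), "block", inv.inversion_id)
                    for p in sorted(pos))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "kind", "inversion_id"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ref_i = rng.integers(0, 4, size=len(df))
    alt_i = (ref_i + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = bases[ref_i]
    df["alt"] = bases[alt_i]
    neutral_cols = df.index[df["kind"] == "neutral"].to_numpy()
    block_cols = {inv.inversion_id: df.index[df["inversion_id"] == inv.inversion_id].to_numpy()
                  for inv in cfg.inversions}
    return df, neutral_cols, block_cols


def simulate_cohorts(config: SimConfig):
    """Run the forward simulation and return sampled cohorts.

    Returns
    -------
    (GenotypeMatrix, samples DataFrame, Truth)
        Genotypes for every sampled individual (neutral + inversion block
        SNPs), their metadata (sample_id, population, ecotype, catch_year,
        birth_year, age) and the simulation ground truth.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_neutral_snps
    n_inv = len(cfg.inversions)
    messages = []

    sites, neutral_cols, block_cols = _place_sites(rng, cfg)

    # ancestral frequencies + independent per-population burn-in drift
    p0 = rng.beta(cfg.beta_shape[0], cfg.beta_shape[1], size=L)
    pops = {}
    for name, N in ((MIGRATORY, cfg.n_migratory), (COASTAL, cfg.n_coastal)):
        counts = rng.binomial(2 * N, p0)
        for _ in range(cfg.burn_in_generations):
            counts = rng.binomial(2 * N, counts / (2 * N))
        arr = np.zeros((N, 2, n_inv), dtype=np.int8)
        for k, inv in enumerate(cfg.inversions):
            f = inv.init_freq_migratory if name == MIGRATORY else inv.init_freq_coastal
            arr[:, :, k] = rng.random((N, 2)) < f
        anc = np.zeros(N) if name == MIGRATORY else np.ones(N)
        pops[name] = _PopState(N, counts, arr, anc)

    # sampling events grouped by (generation, population)
    events = {}
    for ev in cfg.sampling_schedule:
        g = cfg.generation_of_year(ev.year)
        events.setdefault((g, ev.population), []).append(ev)

    sample_rows, geno_rows = [], []
    truth_karyo, truth_anc = [], []
    inv_freq_rows = []
    neutral_traj = {name: np.zeros((cfg.n_generations + 1, L)) for name in pops}

    def record_state(g):
        for name, st in pops.items():
            st.snapshot(g)
            neutral_traj[name][g] = st.counts / (2 * st.n)
            for k, inv in enumerate(cfg.inversions):
                f = st.arr[:, :, k].mean()
                inv_freq_rows.append((g, name, inv.inversion_id, float(f)))
                if g > 0 and f in (0.0, 1.0):
                    word = "fixed" if f == 1.0 else "lost"
                    msg = (f"inversion {inv.inversion_id} DERIVED arrangement "
                           f"{word} in {name} at generation {g}")
                    if msg not in messages:
                        messages.append(msg)

    def draw_samples(g):
        for (gg, popname), evs in events.items():
            if gg != g:
                continue
            st = pops[popname]
            for ev in evs:
                ages = cfg.age_distribution.draw(rng, ev.n)
                birth_gens = np.clip(
                    g - np.round(ages / cfg.generation_time_years).astype(int), 0, g)
                for gb in np.unique(birth_gens):
                    sel = birth_gens == gb
                    nb = int(sel.sum())
                    free = np.flatnonzero(~st.sampled[gb])
                    if len(free) < nb:
                        raise ValueError(
                            f"census exhausted: need {nb} unsampled fish born "
                            f"generation {gb} in {popname}")
                    chosen = rng.choice(free, size=nb, replace=False)
                    st.sampled[gb][chosen] = True
                    pool = st.allele_pool(gb)
                    n_rem, counts_rem = pool
                    # plan II: draw 2*nb alleles per locus w/o replacement
                    x = rng.hypergeometric(counts_rem, 2 * n_rem - counts_rem, 2 * nb)
                    pool[0] = n_rem - nb
                    pool[1] = counts_rem - x
                    hap = _assign_alleles(rng, x, 2 * nb)       # (L, 2nb)
                    neutral_dos = (hap[:, ::2] + hap[:, 1::2]).T  # (nb, L)
                    sub_ages = ages[sel]
                    for j, (ind, age) in enumerate(zip(chosen, sub_ages)):
                        sid = f"{popname}_{ev.year}_{len(sample_rows):04d}"
                        birth_year = ev.year - int(age)
                        sample_rows.append((sid, popname, popname, ev.year,
                                            birth_year, int(age)))
                        full = np.full(len(sites), 0, dtype=np.int8)
                        full[neutral_cols] = neutral_dos[j]
                        karyo = {}
                        for k, inv in enumerate(cfg.inversions):
                            alleles = st.hist_arr[gb][ind, :, k]  # (2,)
                            karyo[inv.inversion_id] = int(alleles.sum())
                            cols = block_cols[inv.inversion_id]
                            m = len(cols)
                            flip = rng.random((2, m)) >= inv.tag_fidelity
                            h = (alleles[:, None] ^ flip).astype(np.int8)
                            full[cols] = h.sum(axis=0)
                        geno_rows.append(full)
                        truth_karyo.append({"sample_id": sid, **karyo})
                        truth_anc.append((sid, float(st.hist_anc[gb][ind])))

    def reproduce(g):
        mig = _active_epochs(cfg.migration_schedule, g)
        m_cm = sum(ep.m_coastal_to_migratory for ep in mig)
        m_mc = sum(ep.m_migratory_to_coastal for ep in mig)
        # neutral: plan II remaining pool, deterministic mixing, binomial draw
        p_rem = {}
        for name, st in pops.items():
            if g in st.pool:
                n_rem, counts_rem = st.pool[g]
                if n_rem <= 0:
                    raise ValueError(f"entire {name} census sampled at generation {g}")
                p_rem[name] = counts_rem / (2 * n_rem)
            else:
                p_rem[name] = st.counts / (2 * st.n)
        p_eff = {
            MIGRATORY: (1 - m_cm) * p_rem[MIGRATORY] + m_cm * p_rem[COASTAL],
            COASTAL: (1 - m_mc) * p_rem[COASTAL] + m_mc * p_rem[MIGRATORY],
        }
        new_counts = {name: rng.binomial(2 * pops[name].n, p_eff[name])
                      for name in pops}

        # individual layer: parents by viability-weighted choice per pool
        pool_idx, pool_w = {}, {}
        for name, st in pops.items():
            avail = np.flatnonzero(~st.sampled[g])
            if len(avail) == 0:
                raise ValueError(f"no unsampled parents left in {name}")
            w = _fitness(cfg, st.arr[avail], g, name)
            pool_idx[name] = avail
            pool_w[name] = w / w.sum()
        new_arr, new_anc = {}, {}
        for name, st in pops.items():
            m_in = m_cm if name == MIGRATORY else m_mc
            other = COASTAL if name == MIGRATORY else MIGRATORY
            n_child = st.n
            from_other = rng.random((n_child, 2)) < m_in
            parents = np.empty((n_child, 2), dtype=int)
            src = np.empty((n_child, 2), dtype=object)
            for pname in (name, other):
                mask = from_other == (pname == other)
                cnt = int(mask.sum())
                if cnt:
                    parents[mask] = rng.choice(pool_idx[pname], size=cnt,
                                               p=pool_w[pname])
                    src[mask] = pname
            arr = np.zeros((n_child, 2, n_inv), dtype=np.int8)
            anc = np.zeros(n_child)
            which = rng.integers(0, 2, size=(n_child, 2, n_inv))
            for h in (0, 1):
                for pname in (name, other):
                    mask = src[:, h] == pname
                    if not mask.any():
                        continue
                    p_arr = pops[pname].arr[parents[mask, h]]  # (m, 2, n_inv)
                    pick = which[mask, h]                      # (m, n_inv)
                    arr[mask, h, :] = np.take_along_axis(
                        p_arr, pick[:, None, :], axis=1)[:, 0, :]
                    anc[mask] += 0.5 * pops[pname].anc[parents[mask, h]]
            new_arr[name] = arr
            new_anc[name] = anc
        for name, st in pops.items():
            st.counts = new_counts[name]
            st.arr = new_arr[name]
            st.anc = new_anc[name]

    for g in range(cfg.n_generations + 1):
        record_state(g)
        draw_samples(g)
        if g < cfg.n_generations:
            reproduce(g)

    samples = pd.DataFrame(sample_rows, columns=META_COLUMNS)
    dosage = (np.vstack(geno_rows) if geno_rows
              else np.empty((0, len(sites)), dtype=np.int8))
    gm = GenotypeMatrix(dosage, sites[["chrom", "pos", "ref", "alt"]],
                        samples["sample_id"].tolist())
    karyo_df = pd.DataFrame(truth_karyo).set_index("sample_id") if truth_karyo \
        else pd.DataFrame()
    anc_s = pd.Series(dict(truth_anc), name="coastal_ancestry")
    inv_freq = pd.DataFrame(inv_freq_rows,
                            columns=["generation", "population", "inversion_id", "freq"])
    truth = Truth(karyo_df, anc_s, neutral_traj, inv_freq, messages)
    return gm, samples, truth


def inject_missingness(gm: GenotypeMatrix, schedule, seed, metadata=None):
    """Independently set genotypes missing and perturb retained ones.

    Each sample's rates come from the MissingnessEra covering its catch
    year (rate 0 outside all eras); with no metadata a single era applies
    to every sample. Perturbation replaces a genotype by one of the other
    two dosages uniformly.
    """
    rng = np.random.default_rng(seed)
    out = gm.copy()
    if not schedule:
        return out
    years = None
    if metadata is not None:
        years = metadata.set_index("sample_id")["catch_year"]
    for i, sid in enumerate(out.samples):
        if years is not None:
            y = int(years[sid])
            eras = [e for e in schedule if e.year_min <= y <= e.year_max]
            if not eras:
                continue
            era = eras[0]
        else:
            era = schedule[0]
        row = out.dosage[i]
        if era.error_rate > 0:
            err = (rng.random(len(row)) < era.error_rate) & (row != MISSING)
            if err.any():
                shift = rng.integers(1, 3, size=int(err.sum()))
                row[err] = ((row[err] + shift) % 3).astype(np.int8)
        if era.missing_rate > 0:
            miss = rng.random(len(row)) < era.missing_rate
            row[miss] = MISSING
    return out


def inversion_bed(config: SimConfig) -> pd.DataFrame:
    """Inversion intervals as a BED frame (0-based half-open)."""
    return pd.DataFrame({
        "chrom": [inv.chromosome for inv in config.inversions],
        "start": [inv.start - 1 for inv in config.inversions],
        "end": [inv.end for inv in config.inversions],
        "name": [inv.inversion_id for inv in config.inversions],
    })


def write_outputs(gm, samples, truth, out_dir, config=None):
    """Write VCF v4.2, metadata TSV, truth TSVs (and inversion BED when a
    config is given) under out_dir; round-trips through geno_io.read_vcf."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohorts.vcf"),
        "meta": os.path.join(out_dir, "metadata.tsv"),
        "truth_samples": os.path.join(out_dir, "truth_samples.tsv"),
        "truth_invfreq": os.path.join(out_dir, "truth_inversion_freq.tsv"),
    }
    write_vcf(gm, paths["vcf"])
    write_metadata(samples, paths["meta"])
    tk = truth.karyotypes.copy()
    tk["coastal_ancestry"] = truth.ancestry
    tk.to_csv(paths["truth_samples"], sep="\t")
    truth.inversion_freq.to_csv(paths["truth_invfreq"], sep="\t", index=False)
    if config is not None and config.inversions:
        paths["inversions_bed"] = os.path.join(out_dir, "inversions.bed")
        bed = inversion_bed(config)
        write_bed(bed, paths["inversions_bed"], name=bed["name"])
    return paths
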