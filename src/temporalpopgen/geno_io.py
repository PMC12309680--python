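"""VCF/metadata I/O, genotype-level site filters, LD pruning and region masks.

Builds the "neutral" dataset used by the temporal and ancestry stages:
biallelic sites passing missingness/MAF filters, LD-pruned, with the known
inversion regions excluded. Depth- and mappability-based QC belongs to the
upstream variant-calling workflow and is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix

__all__ = [
    "FilterRules",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "ld_prune",
    "exclude_regions",
    "restrict_to_regions",
]


@dataclass
class FilterRules:
    """Genotype-level site/sample filters, applied in field order."""

    biallelic_only: bool = True
    max_site_missing: float = 1.0   # drop sites with missing fraction > this
    max_sample_missing: float = 1.0  # drop samples with missing fraction > this
    maf_min: float = 0.0            # drop sites with MAF < this
    drop_ct_ga: bool = False        # drop C/T and G/A ref-alt pairs

    def validate(self):
        if not 0.0 <= self.max_site_missing <= 1.0:
            raise ValueError("max_site_missing must be in [0,1]")
        if not 0.0 <= self.max_sample_missing <= 1.0:
            raise ValueError("max_sample_missing must be in [0,1]")
        if self.maf_min >= 0.5:
            raise ValueError("maf_min >= 0.5 removes every site")
        if self.maf_min < 0:
            raise ValueError("maf_min must be non-negative")


@dataclass
class FilterReport:
    """Counts of sites/samples removed per rule, in application order."""

    sites_in: int = 0
    samples_in: int = 0
    removed: list = field(default_factory=list)  # (rule, kind, count)
    sites_out: int = 0
    samples_out: int = 0

    def add(self, rule: str, kind: str, count: int):
        self.removed.append((rule, kind, int(count)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["rule", "kind", "removed"])


def read_vcf(path, sample_subset=None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a dosage matrix.

    Multiallelic records are dropped (the pipeline is biallelic-only);
    phased and unphased separators are both accepted; missing GT becomes
    the missing dosage.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    keep = None
    if sample_subset is not None:
        subset = list(sample_subset)
        unknown = set(subset) - set(samples)
        if unknown:
            raise KeyError(f"samples not in VCF: {sorted(unknown)}")
        keep = np.array([samples.index(s) for s in subset])
        samples = subset

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            # gts012: 0/1/2 dosage, 3 = unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
        except Exception as exc:  # malformed record
            raise ValueError(f"malformed VCF record #{i + 1} at "
                             f"{var.CHROM}:{var.POS}: {exc}") from None
        g[g == 3] = MISSING
        if keep is not None:
            g = g[keep]
        rows.append(g)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        warnings.warn(f"dropped {n_multi} multiallelic record(s)")
    dosage = (np.array(rows, dtype=np.int8).T if rows
              else np.empty((len(samples), 0), dtype=np.int8))
    sites = pd.DataFrame({"chrom": chroms, "pos": np.array(poss, dtype=np.int64),
                          "ref": refs, "alt": alts})
    return GenotypeMatrix(dosage, sites, samples)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns.

    No fileDate header line is emitted, so identical runs produce
    byte-identical files.
    """
    order = np.lexsort((gm.sites["pos"].to_numpy(),
                        gm.sites["chrom"].to_numpy().astype(str)))
    contigs = pd.unique(gm.sites["chrom"].astype(str).to_numpy()[order])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=temporalpopgen\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        for j in order:
            gts = "\t".join(_GT_STR[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


_TRANSITION_PAIRS = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}


def apply_site_filters(gm: GenotypeMatrix, rules: FilterRules):
    """Apply genotype-level filters in the order declared on FilterRules.

    Returns (filtered GenotypeMatrix, FilterReport). MAF is computed on
    non-missing alleles only.
    """
    rules.validate()
    report = FilterReport(sites_in=gm.n_sites, samples_in=gm.n_samples)
    out = gm

    if rules.biallelic_only:
        # read_vcf already drops multiallelics; drop degenerate ref==alt rows
        bad = (out.sites["ref"] == out.sites["alt"]).to_numpy()
        report.add("biallelic_only", "sites", bad.sum())
        if bad.any():
            out = out.take_sites(~bad)

    if rules.max_site_missing < 1.0 and out.n_sites:
        frac = (out.dosage == MISSING).mean(axis=0)
        bad = frac > rules.max_site_missing
        report.add("max_site_missing", "sites", bad.sum())
        if bad.any():
            out = out.take_sites(~bad)

    if rules.max_sample_missing < 1.0 and out.n_samples and out.n_sites:
        frac = (out.dosage == MISSING).mean(axis=1)
        bad = frac > rules.max_sample_missing
        report.add("max_sample_missing", "samples", bad.sum())
        if bad.any():
            out = out.take_samples(~bad)

    if rules.maf_min > 0.0 and out.n_sites:
        freq, n = out.allele_frequencies()
        maf = np.minimum(freq, 1.0 - freq)
        bad = ~(maf >= rules.maf_min)  # NaN (all-missing) sites removed too
        report.add("maf_min", "sites", bad.sum())
        if bad.any():
            out = out.take_sites(~bad)

    if rules.drop_ct_ga and out.n_sites:
        pairs = list(zip(out.sites["ref"].str.upper(), out.sites["alt"].str.upper()))
        bad = np.array([p in _TRANSITION_PAIRS for p in pairs])
        report.add("drop_ct_ga", "sites", bad.sum())
        if bad.any():
            out = out.take_sites(~bad)

    report.sites_out = out.n_sites
    report.samples_out = out.n_samples
    return out, report


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all dosage columns, each pair
    computed over its pairwise-complete samples. Pairs with < 2 complete
    samples or a constant column get r² = 0."""
    d = dosage.astype(float)
    m = (dosage != MISSING).astype(float)
    d0 = np.where(dosage == MISSING, 0.0, d)
    n = m.T @ m                      # pairwise-complete counts
    sx = d0.T @ m                    # sum of x over complete pairs
    sxx = (d0 ** 2).T @ m
    sxy = d0.T @ d0
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.maximum(n, 1.0)
        cov = sxy / nn - (sx / nn) * (sx.T / nn)
        var_x = sxx / nn - (sx / nn) ** 2
        r2 = cov ** 2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.5) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage r² (plink-style).

    Within each window of `window_snps` sites (advancing by `step_snps`),
    the later site of any still-kept pair with r² > r2_max is removed;
    windows never span chromosomes. On return every retained pair within
    any window satisfies r² <= r2_max.
    """
    if not (window_snps >= step_snps >= 1):
        raise ValueError("require window_snps >= step_snps >= 1")
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0,1)")

    keep = np.ones(gm.n_sites, dtype=bool)
    chroms = gm.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start:start + window_snps]
            alive = [k for k in win if keep[k]]
            if len(alive) > 1:
                r2 = pairwise_r2(gm.dosage[:, alive])
                for a in range(len(alive)):
                    if not keep[alive[a]]:
                        continue
                    for b in range(a + 1, len(alive)):
                        if keep[alive[b]] and r2[a, b] > r2_max:
                            keep[alive[b]] = False
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return gm.take_sites(keep)


def _region_mask(gm: GenotypeMatrix, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites whose 0-based position falls in any
    half-open BED interval."""
    mask = np.zeros(gm.n_sites, dtype=bool)
    chroms = gm.sites["chrom"].astype(str).to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1  # VCF 1-based -> BED 0-based
    known = set(chroms)
    for _, row in regions.iterrows():
        if str(row["chrom"]) not in known:
            warnings.warn(f"BED interval on unknown chromosome {row['chrom']!r} ignored")
            continue
        mask |= (chroms == str(row["chrom"])) & (pos0 >= row["start"]) & (pos0 < row["end"])
    return mask


def exclude_regions(gm: GenotypeMatrix, regions: pd.DataFrame) -> GenotypeMatrix:
    """Drop sites inside the given BED intervals (0-based half-open)."""
    if len(regions) == 0:
        return gm.copy()
    return gm.take_sites(~_region_mask(gm, regions))


def restrict_to_regions(gm: GenotypeMatrix, regions: pd.DataFrame) -> GenotypeMatrix:
    """Keep only sites inside the given BED intervals (complement of
    exclude_regions); used for inversion karyotyping."""
    return gm.take_sites(_region_mask(gm, regions))
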