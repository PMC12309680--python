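# temporalpopgen

Temporal population genomics of two interbreeding ecotypes sampled across a
century. The package is aimed at researchers analysing retrospective
(archive/otolith-era) genotype collections of a structured marine fish
population — a migratory stock receiving episodic gene flow from a
non-migratory coastal relative — and at anyone who needs a tested, seedable
implementation of the temporal toolbox:

* **Temporal allele-frequency shifts and Ne** — the Fs statistic between two
  samples of the same population taken *t* generations apart,

  ```
  Fs = Σ_i (x_i − y_i)² / Σ_i z_i (1 − z_i),   z = (x + y)/2
  ```

  corrected for finite sampling (plan II: sampled fish are removed before
  reproducing) to Fs' with E[Fs'] ≈ t/(2Ne), jackknife-over-loci 95%
  confidence intervals, and Ne = t/(2 Fs') — reported as infinity when Fs' ≤ 0.
* **Inversion karyotyping** — PCA restricted to an inversion's sites,
  three-cluster calling of ANCESTRAL / HET / DERIVED arrangements, validated
  against the per-sample fraction of heterozygous sites.
* **Differentiation scans** — per-site Weir–Cockerham variance components
  (a, b, c), weighted window FST = Σa/Σ(a+b+c) in 30-kb/15-kb sliding
  windows, per-chromosome permutation p-values and Benjamini–Hochberg
  q-values, allele-frequency-difference (AFD) quantile outliers, and
  shared-outlier intersection across year pairs.
* **Diversity scans** — windowed Tajima's D (30 kb) and π per bp (50 kb)
  from unphased genotypes, with inside-vs-outside-inversion contrasts.
* **Genotype trajectory tests** — per-year Hardy–Weinberg χ², exact tests of
  genotype-frequency homogeneity across years with Bonferroni-adjusted
  pairwise comparisons and compact letter displays, two-SNP hemoglobin β1
  diplotype calling, Kruskal–Wallis + Dunn post-hoc tests.
* **Supervised ancestry** — per-individual admixture proportions q against
  reference panels by EM on the binomial mixture likelihood
  P(g | p̃) with p̃ = Σ_k q_k p_k, aggregated by birth-year cohort.
* **A Wright–Fisher simulator** of the whole study design — two populations,
  weakly differentiated neutral SNPs, inversion supergenes with imperfect
  tag SNPs, time-varying migration, karyotype viability selection,
  plan-II temporal sampling with age structure, and era-specific
  missingness/genotyping error — with full ground truth for recovery tests.

Inputs are standard formats: VCF v4.2 with GT genotypes, a tab-separated
sample metadata table (`sample_id`, `population`, `ecotype`, `catch_year`,
`birth_year`, `age`), and BED intervals for the inversion regions.

## Worked example

The built-in demonstration mirrors the study design: two populations of 400,
5,000 neutral SNPs on 12 chromosomes, four inversions (on LG01, LG02, LG07,
LG12), seven migratory sampling years from 1908 to 2012, coastal gene flow
intensifying after the mid-century, and a late heterozygote-advantage epoch
on the LG01 inversion.

```
temporalpopgen run-all --seed 1 --out-dir runs/demo
```

runs simulate → filter/prune → PCA → karyotype → Fs' → FST scan →
diversity → genotype tests → ancestry in a few minutes and prints, among
other things:

```
[fsprime] 1908-2012: Fs=0.04053 Fs'=0.01407 [0.01232, 0.01583] N~=38.1 loci=4665 t=13 Ne=461.8
[fst_scan] 1603 windows, 111 with q<0.05
[ancestry] mean coastal q = 0.206, KW p = 1.99e-26
```

Reading these: over the 13 generations between 1908 and 2012 the
standardized allele-frequency shift on the LD-pruned, inversion-excluded
"neutral" SNP set is Fs' = 0.0141 (95% CI 0.0123–0.0158, harmonic-mean
sample size Ñ ≈ 38 diploids), giving Ne ≈ 462 — close to the configured
census of 400, with the excess drift contributed by the simulated gene
flow. The FST scan flags 111 of 1,603 windows at q < 0.05, concentrated in
the inversion intervals; the cohort table
(`runs/demo/ancestry/cohort_summary.tsv`) shows mean coastal ancestry per
3-year birth cohort rising in the late-century cohorts, and the
region contrast (`runs/demo/diversity/region_contrast.tsv`) shows window
Tajima's D elevated inside each inversion (e.g. 1.97 inside INV01 vs 1.45
outside in the 2012 cohort), the signature of a balanced arrangement
polymorphism.

Rerunning with the same seed reproduces every output byte for byte;
individual stages can also be run on external VCF/metadata files, e.g.

```
temporalpopgen fsprime --vcf neutral.vcf --meta meta.tsv \
    --pairs "1908:2012,1908:1972" --generation-time 8
```

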