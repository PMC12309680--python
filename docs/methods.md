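# Methods

## The setting

Two partially reproductively isolated ecotypes of a marine fish — a large
migratory stock and a smaller coastal one — exchange migrants at a rate
that varies over decades. Four chromosomal inversions act as supergenes:
recombination is suppressed in heterokaryotypes, so each inversion is
inherited as one Mendelian locus whose internal SNPs are in strong LD with
the arrangement. Archived tissue makes it possible to genotype samples
spanning a century and ask (i) how much genome-wide drift the migratory
population experienced (its effective size), (ii) how the inversion
karyotype frequencies moved, and (iii) how much coastal ancestry entered
the migratory gene pool, by birth cohort. The package implements that
analysis stack plus a simulator of the whole design, so every estimator can
be tested against known truth.

## Simulator (simkit)

**Neutral loci.** Each population holds an allele count K out of 2N per
SNP. Reproduction is binomial resampling: K' ~ Binomial(2N, p_eff), where
p_eff mixes the two populations' frequencies deterministically at the
migration rate active that generation. Ancestral frequencies are one
Beta(0.8, 0.8) draw per SNP, followed by independent burn-in drift per
population (default 20 generations), which produces the weak genome-wide
background differentiation characteristic of the two ecotypes outside the
inversions.

**Individual layer.** Arrangement alleles (one biallelic locus per
inversion, no recombination) and each fish's coastal-ancestry fraction
(the average of its parents', with coastal fish at 1) are tracked through
an explicit individual-based layer in both populations across all
generations. Children pick each parent from the coastal pool with
probability equal to the migration rate, otherwise from their own
population, with parents weighted by viability: active selection epochs
multiply a fitness w per karyotype (ANCESTRAL hom / HET / DERIVED hom).
Keeping the individual layer for the whole run rather than a pedigree
window around each sampling year costs nothing at desk scale and makes the
ancestry bookkeeping exact.

**Sampling (plan II).** A sampling event draws fish without replacement
from their birth generation's cohort and removes them from the breeding
pool: for neutral loci the sample's alleles are drawn hypergeometrically
from the 2N-allele pool and subtracted before the next generation is
drawn; for the individual layer, sampled fish are excluded from the parent
pool. Age at catch follows a truncated geometric distribution (configurable
minimum/maximum/decay; the demonstration config uses ages 3–15 years with
p = 0.35); birth year = catch year − age, and the fish is instantiated from
its birth generation's state. Removal is exact for fish sampled from the
current generation; older fish can no longer be removed from reproduction
that already happened, a negligible effect when samples are far smaller
than the census.

**Genotypes.** Sampled fish get neutral genotypes by randomly pairing the
drawn alleles (Hardy–Weinberg within cohort) and block-SNP genotypes by
copying each arrangement allele with probability `tag_fidelity` per
haplotype (default 0.98), emulating gene flux and genotyping error.
Era-specific missingness and dosage-error rates (keyed by catch year)
emulate degraded historical samples.

**Calendar.** Generation g maps to year `start_year + round(g·T)` with T
the generation time in years (demonstration default 8; the real value for
this kind of stock is uncertain and is a required parameter wherever years
are converted to generations).

What the simulator does *not* emulate: sequence-level reads, recombination
within chromosomes (neutral SNPs are exchangeable, so LD outside inversions
is absent), overlapping generations beyond the age-at-catch device,
selection on neutral loci, and environmental covariates. Passing recovery
tests on these simulations therefore demonstrates estimator correctness
under the model, not robustness to, e.g., background LD or reference bias
in real data.

## Temporal estimator (temporal_f)

Fs is a ratio of sums over loci (sites monomorphic in the pooled pair are
excluded): Fs = Σ(x−y)² / Σ z(1−z). The ratio-of-sums weighting, rather
than the mean of per-locus ratios, is used because low-MAF loci make the
per-locus ratio extremely noisy and the drift calibration cannot hold for
the unweighted mean; the unweighted variant remains available via
`ratio_of_sums=False`. The sampling correction is

    Fs' = [Fs·(1 − 1/(4Ñ)) − 1/Ñ] / [(1 + Fs/4)·(1 − 1/(2·n_t))]

with Ñ the harmonic mean of the two mean per-site sample sizes **in
diploid individuals** and n_t the later sample's mean size. The individuals
convention is pinned by the calibration identity: the sampling-noise term
in E[Fs] is 1/(2n₀) + 1/(2n_t) = 1/Ñ exactly when Ñ counts individuals.
With Ne = 500, t = 10, 2,000 SNPs and 50 diploids per sample, the mean Fs'
over 200 replicates lands within [0.009, 0.011] around the truth
t/(2Ne) = 0.01, and the delete-one-locus jackknife 95% CI covers the truth
in ~95% of replicates (both recomputed by the acceptance script). Ne is
t/(2Fs') for positive Fs' and infinity otherwise — two samples with no
more divergence than sampling noise carry no lower bound on Ne.

## Filters and the neutral set (geno_io)

Genotype-level filters are applied in a fixed order: biallelic-only,
per-site missingness, per-sample missingness, MAF floor (on non-missing
alleles), and an optional drop of C/T and G/A ref-alt pairs (the
transition classes inflated by post-mortem deamination in historical DNA).
Depth, mappability and repeat masking belong to the upstream variant
calling workflow and are out of scope. The "neutral" set for the temporal
and ancestry analyses excludes the inversion intervals (BED, 0-based
half-open; internal coordinates are 1-based VCF positions) and is LD-pruned
with a plink-style greedy sliding window (defaults 50 SNPs, step 5,
r² > 0.5 removes the later site; r² is squared Pearson correlation of
dosages over pairwise-complete samples). Multiallelic records are dropped,
not split, since every downstream statistic assumes biallelic sites.

## PCA and karyotype calls (pca_karyotype)

Dosages are centred by 2p̂ and scaled by sqrt(p̂(1−p̂)); missing values are
mean-imputed (zero after centring); monomorphic sites are dropped; the
decomposition is an SVD of the normalised matrix. Axis signs are fixed by
orienting each axis so the first sample (or first group) has non-positive
mean coordinate. Axis importance is reported as explained-variance
fractions, with an optional permutation test on leading eigenvalues
(independently permuting each site's dosages) in place of a
Tracy–Widom test.

Karyotype calling restricts to each inversion's sites, clusters PC1 with
1-D k-means initialised deterministically at the 10/50/90th percentiles,
labels the middle cluster HET, and orients DERIVED either by anchor
samples of known karyotype or (flagged "unanchored") by the higher mean
alt dosage. Per-call confidence is 1 − d₁/d₂ over cluster centres; calls
below threshold keep their label but are flagged ambiguous, and a whole
inversion is flagged low-confidence when the centre separation is under
twice the within-cluster spread. The HET cluster must and does show the
highest heterozygous-site fraction — the same validation plot used with
real data. At tag fidelity 0.98 with 200 block SNPs and 100 samples,
concordance with simulation truth is ≥ 99%.

## Differentiation and diversity scans (diff_scan, diversity)

Site FST uses the two-population Weir–Cockerham variance components from
genotype counts including the observed-heterozygosity term; negative
estimates are reported as-is so that window ratios stay unbiased. Windows
(1-based, anchored at position 1; defaults 30 kb / 15 kb step) take
Σa/Σ(a+b+c). Significance is assessed per chromosome by permuting group
labels and recomputing the window statistic (window-level permutation;
p = (1+#{null ≥ obs})/(n_perm+1), so p is never zero), with
Benjamini–Hochberg q-values within chromosome — a deliberately
tuning-free stand-in for the Storey q-value estimator. AFD outliers use a
genome-wide quantile (default 99.9th); `shared_outliers` intersects
outlier sets across year-pair comparisons.

Tajima's D and π are genotype-based (the pipeline never phases). Per site
the unbiased heterozygosity 2p(1−p)·n/(n−1) uses that site's non-missing
allele count n; the Tajima constants are evaluated at the window's
harmonic-mean allele count, a codified choice under era-varying
missingness (VCFtools' handling differs slightly; the oracle tests use
complete matrices where the published formulas are unambiguous). Windows
with S = 0 carry an undefined D; windows with fewer than 3 usable sites
are flagged. π is per bp of window length, so unobserved positions count
as invariant.

## Genotype tests (genotype_tests)

The HWE test is the 1-df χ² goodness of fit with expected counts from the
allele frequencies (monomorphic groups return χ² = 0; expected cells < 5
are flagged). Homogeneity of genotype classes across years uses the exact
conditional test: full enumeration for 2-row tables, Patefield Monte-Carlo
sampling of fixed-margin tables otherwise (two-sided by table
probability); pairwise tests are Bonferroni-adjusted and summarised with
an insert-and-absorb compact letter display, whose defining property —
groups share a letter iff not significantly different — is property-tested.
Hemoglobin β1 diplotypes combine the codon-55 and codon-62 genotypes into
Val-Ala / HET-HET / Met-Lys, with discordant pairs reported as "other";
which allele is Val/Ala is a polarisation flag, not a hard-coded
coordinate. Kruskal–Wallis uses the tie-corrected H; Dunn's pairwise z
statistics (tie-corrected) are Benjamini–Hochberg adjusted.

## Supervised ancestry (ancestry)

Unsupervised admixture with cross-validation is replaced by a supervised
estimator: reference panels (≥ 5 samples each) define per-site frequencies
clipped to [ε, 1−ε] with ε = 1/(2n+2), and each target genome maximises
the binomial mixture likelihood over q on the simplex by EM over the two
allele copies per site (uninformative and missing sites dropped; uniform
initialisation; stop at log-likelihood gain < 1e-8 or 1,000 iterations).
This is a deliberate modelling substitution: the quantity of interest —
coastal ancestry within the migratory stock relative to known reference
groups — is what the supervised likelihood estimates directly, with no
label switching and a fully specified, testable objective. EM guarantees a
monotone log-likelihood and exact simplex constraints; an all-het F1
between fixed-difference panels returns q = (0.5, 0.5) to machine
precision, and a backcross (q = 0.25) is recovered with mean absolute
error < 0.05 at 2,000 sites. Cohort aggregation bins birth years into
fixed-width classes (default 3 years) from the earliest birth year and
tests cohorts (≥ 2 samples) with Kruskal–Wallis.

## Pipeline and problem sizes

`run-all` chains the stages with per-stage seeds derived from one master
seed; outputs are plain TSV/VCF without timestamps, so identical seeds
give byte-identical runs, and a stage whose outputs exist is skipped. The
demonstration configuration (two populations of 400, 5,000 SNPs, four
inversions, seven sampling years, 200 FST permutations) and the
calibration experiment sizes (200 replicates for the drift calibration,
500 windows × 500 permutations for the null scan, 20 replicates for the
power-style detections) were chosen as the smallest designs that make the
expected effects unambiguous relative to Monte-Carlo error; they run in a
few minutes on one CPU.

## Known limitations

* No background LD outside inversions and no recombination map; LD pruning
  is therefore exercised mainly against the inversion blocks.
* The equation-13-style correction is implemented in the
  harmonic-mean-individuals convention fixed by the drift calibration;
  other transcriptions of the correction differ in O(1/N) terms.
* Window-level (not site-level) permutation; q-values are
  Benjamini–Hochberg, slightly conservative relative to Storey's
  estimator.
* Plan-II removal is exact only for age-0 samples (see simulator notes).
* The supervised ancestry model ignores LD between sites and treats panel
  frequencies as known; with small panels, q estimates shrink slightly
  toward the interior (visible as a nonzero baseline in pulse
  experiments).
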