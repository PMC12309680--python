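"""Temporal allele-frequency-shift estimation (Fs, Fs') and Ne inference.

The temporal method reads the variance of allele-frequency change between
two samples of the same population taken t generations apart. The raw
statistic is a ratio of sums over loci,

    Fs = sum_i (x_i - y_i)^2 / sum_i z_i (1 - z_i),   z = (x + y) / 2,

whose expectation under pure drift plus binomial sampling noise is
approximately t/(2 Ne) + 1/(2 n0) + 1/(2 nt). The corrected statistic Fs'
removes the sampling-noise part using the harmonic-mean sample size and a
plan-II correction (sampled fish are removed before reproducing), so that
E[Fs'] ~ t/(2 Ne) and Ne = t / (2 Fs'); a non-positive Fs' means the drift
signal is below sampling noise and Ne is reported as infinity.

Sample sizes enter the correction in INDIVIDUALS (diploids): the harmonic
mean n_tilde = 2 / (1/n0 + 1/nt) satisfies 1/n_tilde = 1/(2 n0) + 1/(2 nt)
in allele units, which is exactly the sampling-noise term above. This
convention is pinned by the drift-calibration test (Ne = 500, t = 10 gives
mean Fs' ~ 0.01); the allele-count convention would leave half of the
sampling noise in the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix

__all__ = ["FsResult", "allele_frequencies", "fs_prime", "estimate_ne"]


@dataclass
class FsResult:
    """Temporal shift estimate for one pair of sample years."""

    pair: tuple
    fs_raw: float
    fs_prime: float
    se: float
    ci_low: float
    ci_high: float
    n_harmonic: float       # harmonic-mean sample size, individuals
    n_loci: int
    t_generations: float
    ne_estimate: float      # diploid Ne; math.inf when fs_prime <= 0

    def summary(self) -> str:
        ne = "infinity" if math.isinf(self.ne_estimate) else f"{self.ne_estimate:.1f}"
        return (f"{self.pair[0]}-{self.pair[1]}: Fs={self.fs_raw:.5f} "
                f"Fs'={self.fs_prime:.5f} [{self.ci_low:.5f}, {self.ci_high:.5f}] "
                f"N~={self.n_harmonic:.1f} loci={self.n_loci} "
                f"t={self.t_generations:g} Ne={ne}")


def allele_frequencies(gm: GenotypeMatrix, sample_ids):
    """Alt-allele frequency and diploid non-missing count per site for the
    given samples; all-missing sites get NaN frequency."""
    if len(list(sample_ids)) == 0:
        raise ValueError("empty sample set")
    return gm.allele_frequencies(sample_ids)


def _correct(fs, n_harm, n_t):
    """Plan-II sampling correction; sizes in individuals."""
    return ((fs * (1.0 - 1.0 / (4.0 * n_harm)) - 1.0 / n_harm)
            / ((1.0 + fs / 4.0) * (1.0 - 1.0 / (2.0 * n_t))))


def fs_prime(gm: GenotypeMatrix, samples_t0, samples_t1, t_generations,
             pair=None, ratio_of_sums: bool = True) -> FsResult:
    """Estimate Fs, the corrected Fs' and its delete-one-locus jackknife CI.

    Sites monomorphic in the pooled pair are excluded (their denominator
    z(1-z) is 0 and they carry no drift information). With
    ratio_of_sums=False the unweighted mean of per-locus ratios is used
    instead (not recommended: low-MAF loci dominate the noise).
    """
    if t_generations <= 0:
        raise ValueError("t_generations must be > 0")
    x, n0 = allele_frequencies(gm, samples_t0)
    y, n1 = allele_frequencies(gm, samples_t1)

    ok = np.isfinite(x) & np.isfinite(y)
    z = (x + y) / 2.0
    denom = z * (1.0 - z)
    ok &= denom > 0
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable polymorphic loci")
    num = (x[ok] - y[ok]) ** 2
    den = denom[ok]
    L = int(ok.sum())

    n0_mean = float(n0[ok].mean())
    n1_mean = float(n1[ok].mean())
    n_harm = 2.0 / (1.0 / n0_mean + 1.0 / n1_mean)

    if ratio_of_sums:
        fs = float(num.sum() / den.sum())
        # jackknife on the ratio of sums; correction re-applied per leave-out
        num_sum, den_sum = num.sum(), den.sum()
        fs_i = (num_sum - num) / (den_sum - den)
    else:
        ratios = num / den
        fs = float(ratios.mean())
        tot = ratios.sum()
        fs_i = (tot - ratios) / (L - 1)

    fsp = float(_correct(fs, n_harm, n1_mean))
    fsp_i = _correct(fs_i, n_harm, n1_mean)
    mean_i = fsp_i.mean()
    se = float(np.sqrt((L - 1) / L * ((fsp_i - mean_i) ** 2).sum()))

    ne = estimate_ne(fsp, t_generations)
    return FsResult(
        pair=tuple(pair) if pair is not None else ("t0", "t1"),
        fs_raw=fs, fs_prime=fsp, se=se,
        ci_low=fsp - 1.96 * se, ci_high=fsp + 1.96 * se,
        n_harmonic=n_harm, n_loci=L,
        t_generations=float(t_generations), ne_estimate=ne,
    )


def estimate_ne(fs_prime_value: float, t_generations: float) -> float:
    """Ne = t / (2 Fs') for positive Fs'; infinity otherwise (no detectable
    drift over the interval)."""
    if t_generations <= 0:
        raise ValueError("t_generations must be > 0")
    if fs_prime_value <= 0:
        return math.inf
    return t_generations / (2.0 * fs_prime_value)
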