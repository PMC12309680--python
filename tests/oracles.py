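"""Independent brute-force transcriptions of the published statistics.

These deliberately use slow, scalar, formula-by-formula code paths that
share nothing with the package implementation; they are the reference the
vectorised estimators are checked against.
"""

import math

import numpy as np

MISSING = -1


def wc_components_oracle(geno_a, geno_b):
    """Two-population Weir-Cockerham variance components (a, b, c, theta)
    for one site, from the published formulas, genotype lists in {0,1,2}."""
    ga = [g for g in geno_a if g != MISSING]
    gb = [g for g in geno_b if g != MISSING]
    n1, n2 = len(ga), len(gb)
    if n1 == 0 or n2 == 0:
        return math.nan, math.nan, math.nan, math.nan
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (ssq - 1.0 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * ssq
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else math.nan
    return a, b, c, theta


def tajima_d_oracle(dosages):
    """Tajima's D for one window of complete diploid genotypes
    (n_samples x n_sites), constants written out one by one."""
    dosages = np.asarray(dosages)
    n = 2 * dosages.shape[0]  # alleles
    S = 0
    theta_pi = 0.0
    for j in range(dosages.shape[1]):
        cnt = int(dosages[:, j].sum())
        if 0 < cnt < n:
            S += 1
            p = cnt / n
            theta_pi += 2.0 * p * (1.0 - p) * n / (n - 1.0)
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (theta_pi - S / a1) / math.sqrt(var)


def pi_oracle(dosages, window_bp):
    """Per-bp nucleotide diversity for one window of complete genotypes."""
    dosages = np.asarray(dosages)
    n = 2 * dosages.shape[0]
    total = 0.0
    for j in range(dosages.shape[1]):
        p = dosages[:, j].sum() / n
        total += 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return total / window_bp


def r2_oracle(x, y):
    """Squared Pearson correlation over pairwise-complete entries."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return 0.0
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    if sxx == 0 or syy == 0:
        return 0.0
    return (sxy * sxy) / (sxx * syy)


def pca_coords_oracle(dosages, k):
    """PCA coordinates via explicit covariance eigendecomposition on the
    same normalisation (centre 2p, scale sqrt(p(1-p)), complete data)."""
    d = np.asarray(dosages, dtype=float)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x = (d[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    cov = x @ x.T
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    return v[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))


def fs_raw_oracle(x_list, y_list):
    """Ratio-of-sums Fs over loci from paired frequency lists."""
    num = den = 0.0
    for x, y in zip(x_list, y_list):
        z = (x + y) / 2.0
        if z <= 0.0 or z >= 1.0:
            continue
        num += (x - y) ** 2
        den += z * (1.0 - z)
    return num / den
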