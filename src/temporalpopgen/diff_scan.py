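"""Differentiation scans: Weir-Cockerham FST, windows, permutation nulls,
per-chromosome FDR, allele-frequency-difference outliers and their
intersection across year pairs.

The per-site estimator is the two-population Weir-Cockerham analysis of
variance on genotype counts, including the observed-heterozygosity term;
the "weighted" window statistic is the ratio of summed variance components
sum(a) / sum(a+b+c), not the mean of per-site ratios. Window significance
comes from permuting sample labels between the two groups (window-level,
per chromosome) and q-values from Benjamini-Hochberg within chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import MISSING, GenotypeMatrix

__all__ = ["site_fst", "window_fst", "permutation_q", "afd", "shared_outliers"]


def _group_stats(dosage):
    """Per-site sample size, alt frequency and het frequency for one group
    (rows = samples)."""
    ok = dosage != MISSING
    n = ok.sum(axis=0).astype(float)
    alt = np.where(ok, dosage, 0).sum(axis=0)
    het = ((dosage == 1) & ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def site_fst(gm: GenotypeMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-site Weir-Cockerham variance components for two groups.

    Returns a frame with chrom, pos, a, b, c, theta (= a/(a+b+c)) and a
    `usable` flag; sites monomorphic in the pooled sample or with an
    undefined denominator are marked unusable (theta NaN) and counted out
    downstream. Negative theta is reported as-is.
    """
    ia = gm.sample_indices(group_a)
    ib = gm.sample_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 samples")
    n1, p1, h1 = _group_stats(gm.dosage[ia])
    n2, p2, h2 = _group_stats(gm.dosage[ib])

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    usable = (np.isfinite(p1) & np.isfinite(p2) & (n1 > 0) & (n2 > 0)
              & (nbar > 1.0) & np.isfinite(denom) & (denom != 0))
    # pooled-monomorphic sites carry no information
    usable &= ~((pbar <= 0) | (pbar >= 1))
    theta = np.where(usable, theta, np.nan)

    return pd.DataFrame({
        "chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
        "a": a, "b": b, "c": c, "theta": theta, "usable": usable,
    })


def _window_edges(positions, window_bp, step_bp):
    """1-based inclusive window starts covering [1, max(pos)], anchored at
    position 1."""
    if len(positions) == 0:
        return np.array([], dtype=int)
    last = positions.max()
    return np.arange(1, last + 1, step_bp, dtype=int)


def window_fst(components: pd.DataFrame, window_bp: int = 30_000,
               step_bp: int = 15_000) -> pd.DataFrame:
    """Weighted window FST = sum(a) / sum(a+b+c) over usable sites per
    sliding window (1-based inclusive coordinates); empty windows omitted."""
    out = []
    comp = components[components["usable"]].copy()
    for chrom, sub in comp.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        a = sub["a"].to_numpy()
        abc = (sub["a"] + sub["b"] + sub["c"]).to_numpy()
        for start in _window_edges(pos, window_bp, step_bp):
            end = start + window_bp - 1
            m = (pos >= start) & (pos <= end)
            if not m.any():
                continue
            denom = abc[m].sum()
            theta = a[m].sum() / denom if denom != 0 else np.nan
            out.append((chrom, start, end, int(m.sum()), theta))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_sites", "fst"])


def permutation_q(windows: pd.DataFrame, gm: GenotypeMatrix, group_a, group_b,
                  n_perm: int = 1000, seed: int = 0,
                  window_bp: int = 30_000, step_bp: int = 15_000) -> pd.DataFrame:
    """Attach permutation p-values and per-chromosome BH q-values.

    For each chromosome, group labels are permuted across the pooled
    samples n_perm times, the window statistics recomputed, and each
    window's p is (1 + #{null >= observed}) / (n_perm + 1) against the
    chromosome's pooled null distribution. Deterministic under `seed`.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    na, nb = len(list(group_a)), len(list(group_b))
    if na < 2 or nb < 2:
        raise ValueError("groups must keep >= 2 samples")
    pooled = list(group_a) + list(group_b)
    rng = np.random.default_rng(seed)
    out = windows.copy()
    out["p"] = np.nan
    out["q"] = np.nan
    sub_gm = gm.take_samples(pooled)
    ids = np.array(sub_gm.samples, dtype=object)
    for chrom in out["chrom"].unique():
        cg = sub_gm.take_sites((sub_gm.sites["chrom"] == chrom).to_numpy())
        null = []
        for _ in range(n_perm):
            perm = rng.permutation(len(ids))
            ga, gb = ids[perm[:na]], ids[perm[na:]]
            comps = site_fst(cg, ga, gb)
            w = window_fst(comps, window_bp, step_bp)
            null.append(w["fst"].to_numpy())
        null = np.concatenate(null) if null else np.array([])
        null = null[np.isfinite(null)]
        mask = (out["chrom"] == chrom).to_numpy()
        obs = out.loc[mask, "fst"].to_numpy()
        p = np.array([
            (1.0 + (null >= o).sum()) / (len(null) + 1.0) if np.isfinite(o) else np.nan
            for o in obs])
        out.loc[mask, "p"] = p
        fin = np.isfinite(p)
        if fin.any():
            q = np.full(len(p), np.nan)
            q[fin] = multipletests(p[fin], method="fdr_bh")[1]
            out.loc[mask, "q"] = q
    return out


def afd(gm: GenotypeMatrix, group_a, group_b, quantile: float = 0.999) -> pd.DataFrame:
    """Per-site absolute allele-frequency difference |p_A - p_B|, with a
    flag for sites at or above the genome-wide `quantile` of the AFD
    distribution."""
    pa, _ = gm.allele_frequencies(group_a)
    pb, _ = gm.allele_frequencies(group_b)
    d = np.abs(pa - pb)
    fin = np.isfinite(d)
    thr = np.quantile(d[fin], quantile) if fin.any() else np.nan
    return pd.DataFrame({
        "chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
        "afd": d, "outlier": fin & (d >= thr),
    })


def shared_outliers(outlier_sets: dict, min_comparisons: int = 2) -> pd.DataFrame:
    """Intersect per-comparison outlier site sets.

    `outlier_sets` maps a comparison label to an iterable of (chrom, pos)
    sites; returns sites flagged in >= min_comparisons comparisons with
    the list of supporting comparisons.
    """
    if len(outlier_sets) < 2:
        raise ValueError("need at least 2 comparisons")
    support = {}
    for label, sites in outlier_sets.items():
        for site in sites:
            support.setdefault(tuple(site), []).append(label)
    rows = [(c, p, len(labs), sorted(labs))
            for (c, p), labs in support.items() if len(labs) >= min_comparisons]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_comparisons", "comparisons"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)
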