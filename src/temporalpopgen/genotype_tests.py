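"""Genotype/karyotype frequency trajectories and their tests.

Covers the per-year genotype tables of the retrospective design: a
Hardy-Weinberg chi-square goodness-of-fit per group, an exact test of
genotype-frequency homogeneity across years (full enumeration for 2-row
tables, Patefield Monte-Carlo otherwise) with Bonferroni-adjusted pairwise
comparisons summarised as a compact letter display, two-SNP hemoglobin
beta-1 diplotype calling, and Kruskal-Wallis with Dunn's post-hoc test
(Benjamini-Hochberg adjusted) for trait-by-genotype and ancestry-by-cohort
comparisons.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import MISSING, GenotypeMatrix

__all__ = ["TestResult", "genotype_freq_table", "hwe_chisq", "fisher_years",
           "hb_diplotype", "kruskal_dunn", "compact_letter_display"]


@dataclass
class TestResult:
    statistic: float
    p: float
    adjusted_p: object = None          # scalar or pairwise frame
    letters: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def genotype_freq_table(calls: pd.DataFrame, by: str = "catch_year",
                        call_col: str = "call") -> pd.DataFrame:
    """Counts and within-group frequencies of genotype classes per group.

    `calls` is a tidy frame (one row per sample) carrying the grouping
    column and the genotype class column; missing classes are dropped.
    """
    ok = calls[calls[call_col].notna()]
    counts = ok.groupby([by, call_col], sort=True).size().unstack(fill_value=0)
    freqs = counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    freqs.columns = [f"f_{c}" for c in freqs.columns]
    return pd.concat([counts, freqs], axis=1)


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> TestResult:
    """Hardy-Weinberg chi-square goodness of fit (1 df) for one group.

    Expected counts are (p^2, 2pq, q^2) * n with p from the allele counts.
    Monomorphic groups return chi2 = 0, p = 1. Groups with any expected
    cell < 5 are flagged (the asymptotic approximation is weak there).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty group")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p in (0.0, 1.0):
        return TestResult(0.0, 1.0, flags={"monomorphic": True, "low_expected": False})
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - exp) ** 2 / exp).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return TestResult(chi2, pval,
                      flags={"monomorphic": False,
                             "low_expected": bool((exp < 5).any())},
                      extra={"expected": exp, "allele_freq": float(p)})


def _log_table_prob(table, lr_fact, lc_fact, ln_fact):
    return lr_fact + lc_fact - ln_fact - gammaln(table + 1.0).sum()


def _exact_p_2xk(table: np.ndarray) -> float:
    """Full enumeration of 2 x k tables with fixed margins; two-sided
    probability-based p (sum of P(T) <= P(obs))."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    lr = gammaln(row + 1.0).sum()
    lc = gammaln(col + 1.0).sum()
    ln = gammaln(n + 1.0)
    obs_lp = _log_table_prob(table, lr, lc, ln)
    k = len(col)

    total = 0.0
    first_rows = [range(int(min(row[0], col[j])) + 1) for j in range(k - 1)]
    for cells in itertools.product(*first_rows):
        s = sum(cells)
        lastc = row[0] - s
        if lastc < 0 or lastc > col[k - 1]:
            continue
        t = np.array([list(cells) + [lastc],
                      list(col[:-1] - np.array(cells)) + [col[k - 1] - lastc]],
                     dtype=float)
        if (t < 0).any():
            continue
        lp = _log_table_prob(t, lr, lc, ln)
        if lp <= obs_lp + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


def _mc_p(table: np.ndarray, n_draws: int, seed: int) -> float:
    """Patefield Monte-Carlo exact test for an r x c table (plus-one rule)."""
    row = table.sum(axis=1).astype(int)
    col = table.sum(axis=0).astype(int)
    lr = gammaln(row + 1.0).sum()
    lc = gammaln(col + 1.0).sum()
    ln = gammaln(table.sum() + 1.0)
    obs_lp = _log_table_prob(table, lr, lc, ln)
    sampler = stats.random_table(row, col)
    draws = sampler.rvs(n_draws, method="patefield",
                        random_state=np.random.default_rng(seed))
    lps = lr + lc - ln - gammaln(draws + 1.0).sum(axis=(1, 2))
    hits = int((lps <= obs_lp + 1e-9).sum())
    return (1.0 + hits) / (n_draws + 1.0)


def compact_letter_display(groups, pairwise_p: pd.DataFrame, alpha: float = 0.05):
    """Greedy insert-and-absorb compact letter display.

    Two groups share a letter iff their adjusted pairwise p >= alpha.
    """
    groups = list(groups)
    sets = []  # each a set of mutually non-significant groups
    for g in groups:
        placed = False
        for s in sets:
            if all(pairwise_p.loc[g, h] >= alpha for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # absorb subsets
    sets = [s for i, s in enumerate(sets)
            if not any(s < t for j, t in enumerate(sets) if i != j)]
    letters = {g: "" for g in groups}
    for s, letter in zip(sets, string.ascii_lowercase):
        for g in sorted(s, key=groups.index):
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def fisher_years(freq_table: pd.DataFrame, alpha: float = 0.05,
                 n_draws: int = 100_000, seed: int = 0,
                 enumerate_limit: int = 200_000) -> TestResult:
    """Exact test of genotype-class homogeneity across groups.

    `freq_table` holds one row per group and the genotype-class count
    columns (columns starting with `n_`, as produced by
    genotype_freq_table, or raw counts). The overall k x c test and all
    pairwise 2 x c tests use full enumeration when the table is small,
    Monte-Carlo otherwise; pairwise p-values are Bonferroni-adjusted and
    summarised as letters (groups sharing a letter do not differ).
    """
    cols = [c for c in freq_table.columns if c.startswith("n_")]
    counts = (freq_table[cols] if cols else freq_table).copy()
    empty = counts.sum(axis=1) == 0
    if empty.any():
        import warnings
        warnings.warn(f"dropping empty group(s): {list(counts.index[empty])}")
        counts = counts[~empty]
    if len(counts) < 2:
        raise ValueError("need at least 2 non-empty groups")
    table = counts.to_numpy(dtype=float)

    def one_test(t, seed_offset):
        t = t[:, t.sum(axis=0) > 0]
        if t.shape[1] < 2 or t.shape[0] < 2:
            return 1.0
        n_enum = np.prod([min(t[0].sum(), c) + 1 for c in t.sum(axis=0)[:-1]])
        if t.shape[0] == 2 and n_enum <= enumerate_limit:
            return _exact_p_2xk(t)
        return _mc_p(t, n_draws, seed + seed_offset)

    overall_p = one_test(table, 0)

    groups = list(counts.index)
    pw = pd.DataFrame(1.0, index=groups, columns=groups)
    raw = {}
    pairs = list(itertools.combinations(range(len(groups)), 2))
    for k, (i, j) in enumerate(pairs):
        raw[(groups[i], groups[j])] = one_test(table[[i, j]], k + 1)
    m = len(pairs)
    for (gi, gj), p in raw.items():
        adj = min(1.0, p * m)
        pw.loc[gi, gj] = pw.loc[gj, gi] = adj
    letters = compact_letter_display(groups, pw, alpha)
    return TestResult(np.nan, overall_p, adjusted_p=pw, letters=letters,
                      extra={"pairwise_raw": raw, "alpha": alpha})


HB_CLASSES = {(0, 0): "Val-Ala", (1, 1): "HET-HET", (2, 2): "Met-Lys"}


def hb_diplotype(gm: GenotypeMatrix, pos55: tuple, pos62: tuple,
                 ref_is_val_ala: bool = True) -> pd.Series:
    """Two-SNP hemoglobin beta-1 diplotype per sample.

    `pos55`/`pos62` are (chrom, pos) of the codon-55 and codon-62 SNPs.
    With the reference alleles polarised to Val/Ala (default), homozygous
    ref-ref is Val-Ala, double heterozygotes HET-HET, homozygous alt-alt
    Met-Lys; discordant combinations (the two sites disagreeing in dose)
    are classed "other", and samples missing either genotype get NA.
    """
    def col(site):
        chrom, pos = site
        m = (gm.sites["chrom"].astype(str) == str(chrom)) & (gm.sites["pos"] == pos)
        idx = np.flatnonzero(m.to_numpy())
        if len(idx) != 1:
            raise ValueError(f"site {chrom}:{pos} not found uniquely")
        return gm.dosage[:, idx[0]].astype(int)

    d55, d62 = col(pos55), col(pos62)
    if not ref_is_val_ala:
        d55 = np.where(d55 == MISSING, MISSING, 2 - d55)
        d62 = np.where(d62 == MISSING, MISSING, 2 - d62)
    out = []
    for a, b in zip(d55, d62):
        if a == MISSING or b == MISSING:
            out.append(None)
        else:
            out.append(HB_CLASSES.get((a, b), "other"))
    return pd.Series(out, index=gm.samples, name="hb_diplotype")


def kruskal_dunn(values_by_group: dict, alpha: float = 0.05) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post-hoc z tests,
    Benjamini-Hochberg adjusted across pairs.

    Groups with no values are dropped with a warning; fully tied data
    return H = 0, p = 1.
    """
    groups = {}
    for g, v in values_by_group.items():
        v = np.asarray(list(v), dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            import warnings
            warnings.warn(f"dropping empty group {g!r}")
            continue
        groups[g] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    if len(all_vals) < 2:
        raise ValueError("need at least 2 values in total")
    if np.ptp(all_vals) == 0:  # degenerate: a single shared value
        return TestResult(0.0, 1.0, adjusted_p=pd.DataFrame(
            1.0, index=names, columns=names),
            letters={g: "a" for g in names})
    H, p = stats.kruskal(*[groups[g] for g in names])

    # Dunn's z on mean ranks with tie correction
    ranks = stats.rankdata(all_vals)
    N = len(all_vals)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1.0))
    mean_rank, sizes = {}, {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    pairs = list(itertools.combinations(names, 2))
    zs, ps = [], []
    for gi, gj in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(ps, method="fdr_bh")[1] if pairs else np.array([])
    pw = pd.DataFrame(1.0, index=names, columns=names)
    for (gi, gj), a in zip(pairs, adj):
        pw.loc[gi, gj] = pw.loc[gj, gi] = a
    letters = compact_letter_display(names, pw, alpha)
    return TestResult(float(H), float(p), adjusted_p=pw, letters=letters,
                      extra={"z": dict(zip(pairs, zs)),
                             "mean_rank": mean_rank})
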