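"""Supervised ancestry-proportion estimation against reference panels.

Each individual's genome is modelled as a mixture of K reference panels
with proportions q on the simplex: at a site with panel alt-allele
frequencies p_1..p_K the individual's alt alleles are
Binomial(2, p_tilde) with p_tilde = sum_k q_k p_k. The likelihood is
maximised by expectation-maximisation over the two allele copies per site
(responsibilities q_k p_k / p_tilde for an alt copy, q_k (1-p_k) /
(1-p_tilde) for a ref copy), which keeps q on the simplex and increases
the log-likelihood monotonically. Estimates are aggregated by birth-year
cohort (fixed-width classes from the earliest birth year) and compared
with a Kruskal-Wallis rank test.

This is a supervised stand-in for unsupervised admixture analysis: the
panels define what "coastal" and "migratory" ancestry mean, so q is
identified without label switching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .genotype_tests import kruskal_dunn

__all__ = ["AncestryEstimate", "panel_freqs", "fit_q", "fit_q_all", "cohort_summary"]


@dataclass
class AncestryEstimate:
    sample_id: str
    q: np.ndarray                 # proportions over panels, sums to 1
    panels: list
    loglik: float
    n_sites: int
    converged: bool


def panel_freqs(gm: GenotypeMatrix, panel_samples: dict, eps: float = None):
    """Per-panel per-site alt-allele frequencies, clipped away from 0/1.

    `panel_samples` maps panel name -> sample ids (>= 5 each). The default
    clip is 1/(2n+2) per panel, so a fixed panel never contributes a zero
    likelihood. Returns (panel name list, (K, n_sites) frequency array).
    """
    names = list(panel_samples)
    freqs = []
    for name in names:
        ids = list(panel_samples[name])
        if len(ids) < 5:
            raise ValueError(f"panel {name!r} has {len(ids)} samples; need >= 5")
        f, n = gm.allele_frequencies(ids)
        e = eps if eps is not None else 1.0 / (2.0 * len(ids) + 2.0)
        f = np.clip(f, e, 1.0 - e)
        f[~np.isfinite(f)] = 0.5  # all-missing site: uninformative
        freqs.append(f)
    return names, np.vstack(freqs)


def fit_q(genotypes: np.ndarray, freqs: np.ndarray, sample_id: str = "",
          panels=None, min_sites: int = 100, tol: float = 1e-8,
          max_iter: int = 1000) -> AncestryEstimate:
    """Maximum-likelihood mixture proportions for one individual by EM.

    `genotypes` is the dosage vector (missing dropped); `freqs` the
    (K, n_sites) panel frequencies. Starts from uniform q; converges when
    the log-likelihood gain drops below `tol`. Non-convergence returns the
    best iterate flagged.
    """
    g = np.asarray(genotypes, dtype=float)
    ok = g != MISSING
    # informative: panels actually disagree at the site
    informative = ok & (freqs.max(axis=0) - freqs.min(axis=0) > 1e-12)
    g = g[informative]
    p = freqs[:, informative]           # (K, L)
    K, L = p.shape
    if L < min_sites:
        raise ValueError(f"{L} informative non-missing sites < floor {min_sites}")

    q = np.full(K, 1.0 / K)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        pt = q @ p                       # (L,)
        pt = np.clip(pt, 1e-12, 1 - 1e-12)
        ll = float((g * np.log(pt) + (2.0 - g) * np.log1p(-pt)).sum())
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
        # responsibilities over the 2L allele copies
        r_alt = q[:, None] * p / pt      # (K, L)
        r_ref = q[:, None] * (1.0 - p) / (1.0 - pt)
        q = (r_alt * g + r_ref * (2.0 - g)).sum(axis=1) / (2.0 * L)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
    return AncestryEstimate(sample_id, q, list(panels) if panels else None,
                            ll_old if not converged else ll, int(L), converged)


def fit_q_all(gm: GenotypeMatrix, panel_samples: dict, sample_ids=None,
              min_sites: int = 100) -> pd.DataFrame:
    """Fit mixture proportions for every sample (or `sample_ids`).

    Returns a frame indexed by sample_id with one q column per panel plus
    loglik, n_sites and converged.
    """
    names, freqs = panel_freqs(gm, panel_samples)
    ids = list(sample_ids) if sample_ids is not None else list(gm.samples)
    rows = []
    for sid in ids:
        i = gm.samples.index(sid)
        est = fit_q(gm.dosage[i], freqs, sample_id=sid, panels=names,
                    min_sites=min_sites)
        row = {"sample_id": sid, **{f"q_{n}": v for n, v in zip(names, est.q)},
               "loglik": est.loglik, "n_sites": est.n_sites,
               "converged": est.converged}
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def cohort_summary(estimates: pd.DataFrame, metadata: pd.DataFrame,
                   component: str, class_width_years: int = 3,
                   alpha: float = 0.05):
    """Aggregate an ancestry component by birth-year cohort and test it.

    Cohorts are consecutive `class_width_years` bins starting at the
    earliest birth year (width 3 from 1895 puts birth year 1903 in
    1901-1903). Cohorts with < 2 samples stay in the table, flagged, but
    are excluded from the Kruskal-Wallis test.

    Returns (per-cohort summary frame, TestResult from kruskal_dunn).
    """
    meta = metadata.set_index("sample_id")
    df = estimates.join(meta["birth_year"], how="inner")
    if df["birth_year"].isna().any() or len(df) == 0:
        raise ValueError("birth years must be present for every estimate")
    y0 = int(df["birth_year"].min())
    k = ((df["birth_year"] - y0) // class_width_years).astype(int)
    lo = y0 + k * class_width_years
    df = df.assign(cohort=[f"{a}-{a + class_width_years - 1}" for a in lo])

    summary = df.groupby("cohort")[component].agg(
        n="size", mean="mean", sd="std", median="median").reset_index()
    summary["in_test"] = summary["n"] >= 2

    usable = {row["cohort"]: df.loc[df["cohort"] == row["cohort"], component]
              for _, row in summary.iterrows() if row["in_test"]}
    test = kruskal_dunn(usable, alpha=alpha) if len(usable) >= 2 else None
    return summary, test
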