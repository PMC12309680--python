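"""Windowed Tajima's D and nucleotide diversity, with inside-vs-outside
inversion contrasts.

Both statistics are computed from unphased genotypes. Per site with
alt-allele frequency p over n non-missing alleles, the unbiased pairwise
heterozygosity is 2 p (1-p) n/(n-1); summed over a window it gives
theta_pi, while the segregating-site count S gives Watterson's
theta_W = S / a1. Tajima's D is their normalised difference,

    D = (theta_pi - S/a1) / sqrt(e1 S + e2 S (S-1)),

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2 evaluated at
the window's harmonic-mean non-missing allele count (missingness varies by
era, so n differs across sites). pi is reported per base pair: window
theta_pi divided by window length, monomorphic/unobserved positions
contributing 0. A balanced inversion polymorphism keeps intermediate-
frequency variants segregating and drives window D positive inside the
inversion relative to the collinear background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = ["tajima_constants", "tajimas_d_windows", "pi_windows", "region_contrast"]


def tajima_constants(n: float) -> dict:
    """Standard Tajima constants for sample size n (alleles, may be the
    harmonic mean and so non-integer; n > 1 required)."""
    if n <= 1:
        raise ValueError("need more than one allele")
    i = np.arange(1, int(np.floor(n - 1)) + 1, dtype=float)
    # fractional tail keeps a1, a2 continuous in non-integer n
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    frac = n - 1 - len(i)
    if frac > 0:
        a1 += frac / (len(i) + 1.0)
        a2 += frac / (len(i) + 1.0) ** 2
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _site_arrays(gm: GenotypeMatrix, sample_ids):
    freq, n_dip = gm.allele_frequencies(sample_ids)
    n_alleles = 2.0 * n_dip
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            n_alleles > 1,
            2.0 * freq * (1.0 - freq) * n_alleles / np.maximum(n_alleles - 1.0, 1.0),
            np.nan)
    seg = np.isfinite(freq) & (freq > 0) & (freq < 1) & (n_alleles >= 4)
    usable = np.isfinite(freq) & (n_alleles >= 4)
    return freq, n_alleles, pi_site, seg, usable


def _windows_over(gm, sample_ids, window_bp, step_bp, per_window):
    rows = []
    freq, n_alleles, pi_site, seg, usable = _site_arrays(gm, sample_ids)
    chroms = gm.sites["chrom"].to_numpy()
    positions = gm.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        pos = positions[cmask]
        for start in np.arange(1, pos.max() + 1, step_bp, dtype=int):
            end = int(start + window_bp - 1)
            m = cmask & (positions >= start) & (positions <= end) & usable
            if not m.any():
                continue
            rows.append(per_window(chrom, int(start), end, m,
                                   pi_site, seg, n_alleles))
    return pd.DataFrame(rows)


def tajimas_d_windows(gm: GenotypeMatrix, sample_ids, window_bp: int = 30_000,
                      step_bp: int = None) -> pd.DataFrame:
    """Sliding-window Tajima's D (default 30-kb windows, half-window step).

    Windows with S = 0 are emitted with D missing; windows with fewer than
    3 usable sites are flagged low-confidence.
    """
    step_bp = step_bp or window_bp // 2

    def per_window(chrom, start, end, m, pi_site, seg, n_alleles):
        S = int(seg[m].sum())
        theta_pi = float(pi_site[m][seg[m]].sum())
        n_harm = len(n_alleles[m]) / (1.0 / n_alleles[m]).sum()
        d = np.nan
        if S > 0 and n_harm > 2:
            k = tajima_constants(n_harm)
            var = k["e1"] * S + k["e2"] * S * (S - 1.0)
            if var > 0:
                d = (theta_pi - S / k["a1"]) / np.sqrt(var)
        return {"chrom": chrom, "start": start, "end": end,
                "n_sites": int(m.sum()), "S": S, "tajima_d": d,
                "low_confidence": bool(m.sum() < 3)}

    return _windows_over(gm, sample_ids, window_bp, step_bp, per_window)


def pi_windows(gm: GenotypeMatrix, sample_ids, window_bp: int = 50_000,
               step_bp: int = None) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp (default 50-kb windows,
    half-window step)."""
    step_bp = step_bp or window_bp // 2

    def per_window(chrom, start, end, m, pi_site, seg, n_alleles):
        theta_pi = float(np.nansum(pi_site[m]))
        return {"chrom": chrom, "start": start, "end": end,
                "n_sites": int(m.sum()), "pi": theta_pi / window_bp}

    return _windows_over(gm, sample_ids, window_bp, step_bp, per_window)


def region_contrast(windows: pd.DataFrame, regions: pd.DataFrame,
                    stat: str = None) -> pd.DataFrame:
    """Mean window statistic inside vs outside each region (BED frame with a
    `name` column; a window is inside when its midpoint falls in the
    0-based half-open interval). Regions without windows get a missing
    inside mean."""
    if stat is None:
        stat = "tajima_d" if "tajima_d" in windows.columns else "pi"
    mid0 = (windows["start"] + windows["end"]) // 2 - 1  # 0-based midpoint
    rows = []
    for _, reg in regions.iterrows():
        inside = ((windows["chrom"].astype(str) == str(reg["chrom"]))
                  & (mid0 >= reg["start"]) & (mid0 < reg["end"]))
        vin = windows.loc[inside, stat].dropna()
        vout = windows.loc[~inside, stat].dropna()
        rows.append({
            "region": reg.get("name", f"{reg['chrom']}:{reg['start']}-{reg['end']}"),
            "stat": stat,
            "n_windows_inside": int(inside.sum()),
            "mean_inside": float(vin.mean()) if len(vin) else np.nan,
            "mean_outside": float(vout.mean()) if len(vout) else np.nan,
            "mean_overall": float(windows[stat].dropna().mean())
            if windows[stat].notna().any() else np.nan,
        })
    return pd.DataFrame(rows)
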