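"""Genotype PCA and three-cluster inversion karyotype calling.

An inversion suppresses recombination in heterozygotes, so its internal
SNPs travel as two deeply diverged haplotype blocks. A PCA restricted to
the inversion's sites therefore places individuals in three clusters along
PC1 — the two homokaryotypes at the ends and heterokaryotypes in the
middle — and the middle cluster is validated by its elevated fraction of
heterozygous sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .geno_io import restrict_to_regions

__all__ = ["PcaResult", "run_pca", "call_karyotypes", "het_fraction",
           "leading_axis_permutation_p"]

CALL_NAMES = {0: "ANCESTRAL", 1: "HET", 2: "DERIVED"}


@dataclass
class PcaResult:
    """Top-k principal axes of the normalised genotype matrix."""

    coords: np.ndarray            # (n_samples, k)
    explained_var: np.ndarray     # fraction per axis, non-increasing
    loadings: np.ndarray          # (n_kept_sites, k)
    kept_sites: np.ndarray        # column indices of polymorphic sites used
    p_hat: np.ndarray             # allele frequency used for normalisation
    samples: list = field(default_factory=list)


def _normalise(gm: GenotypeMatrix):
    """Centre dosages by 2*p_hat, scale by sqrt(p_hat*(1-p_hat)), mean-impute
    missing (0 after centring); drop monomorphic/all-missing sites."""
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all sites monomorphic or missing; PCA undefined")
    d = d[:, keep]
    p = p[keep]
    x = (d - 2.0 * p) / np.sqrt(p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    return x, np.flatnonzero(keep), p


def run_pca(gm: GenotypeMatrix, k: int = 10, groups=None) -> PcaResult:
    """PCA of the normalised dosage matrix via SVD.

    Axis signs are fixed deterministically: each axis is oriented so the
    mean coordinate of the first sample group (or the first sample when no
    groups are given) is <= 0.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x, kept, p = _normalise(gm)
    k = min(k, min(x.shape))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T
    total = (s ** 2).sum()
    ev = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    if groups is not None:
        first = gm.sample_indices(list(groups)[0]) if isinstance(groups[0], (list, tuple)) \
            else np.flatnonzero(np.asarray(groups) == np.asarray(groups)[0])
    else:
        first = np.array([0])
    for a in range(k):
        if coords[first, a].mean() > 0:
            coords[:, a] *= -1
            loadings[:, a] *= -1
    return PcaResult(coords, ev, loadings, kept, p, list(gm.samples))


def leading_axis_permutation_p(gm: GenotypeMatrix, k: int = 3,
                               n_perm: int = 99, seed: int = 0):
    """Permutation p-values for the top-k eigenvalues: each site's dosages
    are permuted independently to break sample structure while keeping
    site frequencies; reported as (1 + #null >= obs) / (n_perm + 1)."""
    rng = np.random.default_rng(seed)
    x, _, _ = _normalise(gm)
    k = min(k, min(x.shape))
    obs = np.linalg.svd(x, compute_uv=False)[:k] ** 2
    exceed = np.zeros(k)
    for _ in range(n_perm):
        xp = np.take_along_axis(x, rng.permuted(
            np.broadcast_to(np.arange(x.shape[0])[:, None], x.shape), axis=0), axis=0)
        null = np.linalg.svd(xp, compute_uv=False)[:k] ** 2
        exceed += null >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


def het_fraction(gm: GenotypeMatrix, region: pd.DataFrame = None, sample=None):
    """Fraction of heterozygous calls among non-missing sites, per sample.

    With `region` (BED frame) the computation is restricted to its sites.
    Returns a scalar for a single `sample`, else an array over all samples;
    NaN where every site is missing.
    """
    sub = restrict_to_regions(gm, region) if region is not None else gm
    if sub.n_sites == 0:
        raise ValueError("region contains no sites")
    d = sub.dosage
    ok = d != MISSING
    with np.errstate(invalid="ignore"):
        frac = np.where(ok.sum(1) > 0, (d == 1).sum(1) / np.maximum(ok.sum(1), 1), np.nan)
    if sample is not None:
        return float(frac[sub.samples.index(sample)])
    return frac


def _kmeans_1d(values: np.ndarray, max_iter: int = 100):
    """Three-centre 1-D k-means with deterministic initialisation at the
    10/50/90th percentiles."""
    centers = np.percentile(values, [10, 50, 90]).astype(float)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        lab = d.argmin(axis=1)
        new = centers.copy()
        for c in range(3):
            if (lab == c).any():
                new[c] = values[lab == c].mean()
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[lab], centers[order]


def call_karyotypes(gm: GenotypeMatrix, inversion_regions: pd.DataFrame,
                    anchor_samples=None, min_sites: int = 10,
                    confidence_threshold: float = 0.2,
                    separation_factor: float = 2.0) -> pd.DataFrame:
    """Call ANCESTRAL/HET/DERIVED per sample for each inversion.

    Parameters
    ----------
    inversion_regions : BED frame (chrom/start/end, 0-based half-open) with
        a `name` column giving the inversion id.
    anchor_samples : optional iterable of sample ids known to carry the
        DERIVED homokaryotype; orients which outer PC1 cluster is DERIVED.
        Without an anchor, labels are consistent (the cluster with the
        higher mean alt dosage is DERIVED) but flagged unanchored.

    Returns a tidy frame: sample_id, inversion, pc1, het_fraction, call,
    confidence, ambiguous, low_confidence, anchored. A call's confidence is
    1 - d_nearest/d_second over cluster centres; calls below
    `confidence_threshold` keep their label but are flagged ambiguous.
    """
    if "name" not in inversion_regions.columns:
        raise ValueError("inversion_regions needs a `name` column")
    anchors = set(anchor_samples) if anchor_samples is not None else None
    rows = []
    for inv_id, region in inversion_regions.groupby("name", sort=False):
        sub = restrict_to_regions(gm, region)
        freq, _ = sub.allele_frequencies()
        n_poly = int(((freq > 0) & (freq < 1)).sum())
        if n_poly < min_sites:
            raise ValueError(f"inversion {inv_id}: {n_poly} polymorphic sites "
                             f"< floor {min_sites}")
        pca = run_pca(sub, k=2)
        pc1 = pca.coords[:, 0]
        lab, centers = _kmeans_1d(pc1)

        spread = np.zeros(3)
        for c in range(3):
            if (lab == c).sum() > 1:
                spread[c] = pc1[lab == c].std()
        sep = min(centers[1] - centers[0], centers[2] - centers[1])
        low_conf = bool(sep < separation_factor * max(spread.max(), 1e-12)) \
            or len(np.unique(lab)) < 3

        # orient which outer cluster is DERIVED
        anchored = False
        if anchors:
            a_idx = [i for i, s in enumerate(sub.samples) if s in anchors]
            if a_idx:
                anchored = True
                derived_outer = 2 if abs(pc1[a_idx].mean() - centers[2]) <= \
                    abs(pc1[a_idx].mean() - centers[0]) else 0
        if not anchored:
            mean_dose = np.zeros(3)
            d = sub.dosage.astype(float)
            d[sub.dosage == MISSING] = np.nan
            for c in range(3):
                if (lab == c).any():
                    mean_dose[c] = np.nanmean(d[lab == c])
            derived_outer = 2 if mean_dose[2] >= mean_dose[0] else 0
        call_of = {1: 1, derived_outer: 2, (0 if derived_outer == 2 else 2): 0}

        dists = np.sort(np.abs(pc1[:, None] - centers[None, :]), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            conf = np.where(dists[:, 1] > 0, 1.0 - dists[:, 0] / dists[:, 1], 1.0)
        hets = het_fraction(sub)
        for i, sid in enumerate(sub.samples):
            rows.append({
                "sample_id": sid, "inversion": inv_id,
                "pc1": float(pc1[i]), "het_fraction": float(hets[i]),
                "call": CALL_NAMES[call_of[lab[i]]],
                "call_code": call_of[lab[i]],
                "confidence": float(conf[i]),
                "ambiguous": bool(conf[i] < confidence_threshold),
                "low_confidence": low_conf,
                "anchored": anchored,
            })
    return pd.DataFrame(rows)
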