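"""Core in-memory containers shared by every pipeline stage.

The substrate of the whole pipeline is a dense diploid dosage matrix
(samples x biallelic sites, values 0/1/2 with -1 for missing) plus a site
table and a sample metadata table. Positions are 1-based internally; BED
input/output is 0-based half-open with conversion at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]
META_COLUMNS = ["sample_id", "population", "ecotype", "catch_year", "birth_year", "age"]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site and sample annotations.

    Parameters
    ----------
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage in {0, 1, 2}; missing genotypes are -1.
    sites : DataFrame with columns chrom, pos (1-based int), ref, alt.
    samples : list of sample identifiers, one per dosage row.
    """

    dosage: np.ndarray
    sites: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        self.sites = self.sites.reset_index(drop=True)
        self.samples = list(self.samples)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dimension mismatch: dosage {self.dosage.shape}, "
                f"{len(self.samples)} samples, {len(self.sites)} sites"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), self.sites.copy(), list(self.samples))

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[:, index], self.sites.iloc[index], list(self.samples)
        )

    def take_samples(self, index_or_ids) -> "GenotypeMatrix":
        arr = np.asarray(index_or_ids)
        if arr.dtype.kind in "US":
            idx = self.sample_indices(index_or_ids)
        elif arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
        return GenotypeMatrix(
            self.dosage[idx, :], self.sites.copy(), [self.samples[i] for i in idx]
        )

    def allele_frequencies(self, sample_ids=None):
        """Alt-allele frequency and diploid non-missing count per site.

        Returns (freq, n) arrays of length n_sites; freq is NaN where every
        genotype is missing.
        """
        if sample_ids is None:
            d = self.dosage
        else:
            d = self.dosage[self.sample_indices(sample_ids), :]
        ok = d != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        freq[n == 0] = np.nan
        return freq, n


def make_sites(chrom, pos, ref=None, alt=None) -> pd.DataFrame:
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "C", dtype=object)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into chrom/start/end."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if (df["end"] < df["start"]).any():
        raise ValueError("BED interval with end < start")
    return df


def write_bed(df: pd.DataFrame, path, name=None) -> None:
    out = df[["chrom", "start", "end"]].copy()
    if name is not None:
        out["name"] = name
    out.to_csv(path, sep="\t", header=False, index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns: {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)
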