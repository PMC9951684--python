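"""Core genotype container shared by every analysis stage.

A :class:`GenotypeDataset` holds a samples x markers dosage matrix (copies of
the alternate allele, ``-1`` for a missing call), a physical marker map and a
breed label per sample.  All downstream statistics (coancestry, diversity
partitions, ROH, LD) consume this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Numeric chromosomes sort numerically, others lexically after them."""
    s = str(chrom)
    if s.isdigit():
        return (0, int(s))
    return (1, s)


def make_marker_map(chroms, marker_ids, positions_bp, allow_duplicate_positions: bool = False) -> pd.DataFrame:
    """Build and validate a marker map (chrom, snp, pos), sorted.

    Positions are 1-based physical coordinates; within each chromosome they
    must be strictly increasing after sorting and marker ids unique.  Raw
    array data may carry duplicated positions prior to QC; readers pass
    ``allow_duplicate_positions=True`` and the QC duplicate stage restores
    strictness.
    """
    df = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "snp": [str(m) for m in marker_ids],
            "pos": np.asarray(positions_bp, dtype=np.int64),
        }
    )
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].head(3).tolist()
        raise ValueError(f"duplicate marker ids, e.g. {dups}")
    if (df["pos"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based bp)")
    order = sorted(range(len(df)), key=lambda i: (_chrom_sort_key(df["chrom"].iat[i]), df["pos"].iat[i]))
    df = df.iloc[order].reset_index(drop=True)
    for _, sub in df.groupby("chrom", sort=False):
        diffs = np.diff(sub["pos"].to_numpy())
        limit = -1 if allow_duplicate_positions else 0
        if (diffs <= limit).any():
            raise ValueError("positions must be strictly increasing within a chromosome")
    return df


@dataclass
class GenotypeDataset:
    """Samples x markers dosage matrix with breed labels and a marker map.

    Attributes
    ----------
    markers : DataFrame with columns ``chrom`` (str), ``snp`` (str),
        ``pos`` (int, 1-based bp), sorted by (chrom, pos).
    samples : DataFrame with columns ``sample_id`` (str), ``breed`` (str).
    dosages : int8 array of shape (n_samples, n_markers) over
        {0, 1, 2, MISSING}.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids")
        if self.samples["breed"].isna().any():
            raise ValueError("every sample needs a breed label")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["breed"]))

    def breed_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each breed's samples."""
        lab = self.samples["breed"].to_numpy()
        return {b: np.flatnonzero(lab == b) for b in self.breeds}

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages != MISSING

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, rows: np.ndarray) -> "GenotypeDataset":
        rows = np.asarray(rows)
        return GenotypeDataset(
            markers=self.markers.copy(),
            samples=self.samples.iloc[rows].reset_index(drop=True),
            dosages=self.dosages[rows],
        )

    def subset_markers(self, cols: np.ndarray) -> "GenotypeDataset":
        cols = np.asarray(cols)
        return GenotypeDataset(
            markers=self.markers.iloc[cols].reset_index(drop=True),
            samples=self.samples.copy(),
            dosages=self.dosages[:, cols],
        )

    def drop_breed(self, breed: str) -> "GenotypeDataset":
        keep = np.flatnonzero(self.samples["breed"].to_numpy() != breed)
        if len(keep) == self.n_samples:
            raise KeyError(f"breed {breed!r} not in dataset")
        return self.subset_samples(keep)

    # -- allele frequencies ---------------------------------------------
    def breed_allele_freq(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Alternate-allele frequency and called-allele count per breed.

        Returns two (breeds x markers) DataFrames: frequencies (NaN where a
        breed has no called allele at a locus) and called allele counts (2
        per called diploid genotype).
        """
        freqs, counts = [], []
        for b, rows in self.breed_indices().items():
            d = self.dosages[rows].astype(np.float64)
            ok = d != MISSING
            alt = np.where(ok, d, 0.0).sum(axis=0)
            tot = 2.0 * ok.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
            freqs.append(f)
            counts.append(tot)
        idx = pd.Index(self.breeds, name="breed")
        cols = self.markers["snp"]
        return (
            pd.DataFrame(freqs, index=idx, columns=cols),
            pd.DataFrame(counts, index=idx, columns=cols, dtype=np.int64),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.markers.equals(other.markers)
            and self.samples.equals(other.samples)
            and np.array_equal(self.dosages, other.dosages)
        )
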