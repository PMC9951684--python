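"""Molecular coancestry, Nei minimum distances and diversity partitions.

Gene diversity is partitioned as HT = HS + DG with

    HS = 1 - (1/B) sum_b fbar_bb
    DG = (1/B^2) sum_b sum_b' [(fbar_bb + fbar_b'b')/2 - fbar_bb']
    HT = 1 - (1/B^2) sum_b sum_b' fbar_bb'

where fbar_bb' is the mean molecular coancestry between breeds b and b',
the within-breed mean taken over the full submatrix *including* the
diagonal so that the identity HT = HS + DG is exact.  Allelic diversity is
partitioned as AT = AS + DA, with AS the mean rarefied allelic richness
minus one and DA the mean count of alleles private to one breed of an
ordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import MISSING, GenotypeDataset


# ----------------------------------------------------------------------
# coancestry
# ----------------------------------------------------------------------
@dataclass
class CoancestryMatrix:
    """Pairwise molecular coancestry with self-coancestry on the diagonal."""

    values: np.ndarray = field(repr=False)  # (n, n), f_ij in [0, 1]
    counts: np.ndarray = field(repr=False)  # loci used per pair
    sample_ids: list[str] = field(default_factory=list)
    breeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("coancestry matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("coancestry values must lie in [0, 1]")
        d = np.diag(v)
        if (d < 0.5 - 1e-12).any():
            raise ValueError("self-coancestry must be >= 0.5")

    def subset(self, rows: np.ndarray) -> "CoancestryMatrix":
        rows = np.asarray(rows)
        return CoancestryMatrix(
            values=self.values[np.ix_(rows, rows)],
            counts=self.counts[np.ix_(rows, rows)],
            sample_ids=[self.sample_ids[i] for i in rows],
            breeds=[self.breeds[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def coancestry(ds: GenotypeDataset) -> CoancestryMatrix:
    """Molecular coancestry f_ij = mean over loci of (x_i x_j + (2-x_i)(2-x_j))/4.

    The average runs over loci where both individuals are called; a pair
    sharing no called locus is an error.
    """
    V = ds.called().astype(np.float64)
    D = ds.dosages.astype(np.float64)
    A = np.where(V > 0, D, 0.0)
    B = np.where(V > 0, 2.0 - D, 0.0)
    num = A @ A.T + B @ B.T
    cnt = V @ V.T
    if (cnt == 0).any():
        i, j = np.argwhere(cnt == 0)[0]
        raise ValueError(
            f"no shared called loci for pair "
            f"({ds.samples['sample_id'].iat[i]}, {ds.samples['sample_id'].iat[j]})"
        )
    f = num / (4.0 * cnt)
    return CoancestryMatrix(
        values=f,
        counts=cnt.astype(np.int64),
        sample_ids=ds.samples["sample_id"].tolist(),
        breeds=ds.samples["breed"].tolist(),
    )


# ----------------------------------------------------------------------
# Nei minimum distance
# ----------------------------------------------------------------------
def nei_minimum_distance(source) -> pd.DataFrame:
    """Pairwise Nei minimum distance between breeds.

    ``source`` is a :class:`GenotypeDataset` or a (breeds x markers) allele
    frequency DataFrame (NaN where a breed has no called allele).  Per
    biallelic locus D = (p_b - p_b')^2, averaged over loci called in both
    breeds of the pair.
    """
    if isinstance(source, GenotypeDataset):
        freq, _ = source.breed_allele_freq()
    else:
        freq = source
    if len(freq) < 2:
        raise ValueError("need at least two breeds")
    P = freq.to_numpy(dtype=np.float64)
    B = P.shape[0]
    D = np.zeros((B, B))
    for a in range(B):
        for b in range(a + 1, B):
            ok = ~np.isnan(P[a]) & ~np.isnan(P[b])
            if not ok.any():
                raise ValueError(f"breed pair ({freq.index[a]}, {freq.index[b]}) shares no called locus")
            D[a, b] = D[b, a] = np.mean((P[a, ok] - P[b, ok]) ** 2)
    return pd.DataFrame(D, index=freq.index, columns=freq.index)


# ----------------------------------------------------------------------
# gene diversity partition
# ----------------------------------------------------------------------
@dataclass
class DiversityPartition:
    HS: float
    DG: float
    HT: float
    per_breed_within: pd.Series  # 1 - fbar_bb per breed
    between: pd.DataFrame        # coancestry-based D_bb'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": {"HS": self.HS, "DG": self.DG, "HT": self.HT}})


def breed_mean_coancestry(co: CoancestryMatrix) -> pd.DataFrame:
    """fbar_bb' matrix; within-breed means include the diagonal."""
    breeds = list(dict.fromkeys(co.breeds))
    lab = np.asarray(co.breeds)
    B = len(breeds)
    M = np.zeros((B, B))
    for a in range(B):
        ra = lab == breeds[a]
        for b in range(B):
            rb = lab == breeds[b]
            M[a, b] = co.values[np.ix_(ra, rb)].mean()
    return pd.DataFrame(M, index=breeds, columns=breeds)


def gene_diversity_partition(
    co: CoancestryMatrix, breed_weights: pd.Series | None = None
) -> DiversityPartition:
    """Partition total gene diversity into within (HS) and between (DG) parts."""
    fbar = breed_mean_coancestry(co)
    breeds = fbar.index
    if len(breeds) < 2:
        raise ValueError("need at least two breeds")
    if breed_weights is None:
        w = np.full(len(breeds), 1.0 / len(breeds))
    else:
        w = breed_weights.reindex(breeds).to_numpy(dtype=float)
        w = w / w.sum()
    F = fbar.to_numpy()
    diag = np.diag(F)
    HS = float(np.sum(w * (1.0 - diag)))
    Dmat = (diag[:, None] + diag[None, :]) / 2.0 - F
    DG = float(w @ Dmat @ w)
    HT = float(1.0 - w @ F @ w)
    assert abs(HT - (HS + DG)) < 1e-10, "partition identity violated"
    return DiversityPartition(
        HS=HS,
        DG=DG,
        HT=HT,
        per_breed_within=pd.Series(1.0 - diag, index=breeds, name="within_gene_diversity"),
        between=pd.DataFrame(Dmat, index=breeds, columns=breeds),
    )


# ----------------------------------------------------------------------
# allelic diversity partition
# ----------------------------------------------------------------------
@dataclass
class AllelicPartition:
    AS: float
    DA: float
    AT: float
    pooled_richness_minus_1: float
    per_breed_richness_minus_1: pd.Series
    n_loci_used: int
    n_loci_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": {"AS": self.AS, "DA": self.DA, "AT": self.AT}})


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_presence_prob(n_allele: np.ndarray, n_total: np.ndarray, g: np.ndarray) -> np.ndarray:
    """P(allele appears in a sample of g of the n_total alleles) per locus."""
    absent_possible = (n_total - n_allele) >= g
    with np.errstate(invalid="ignore"):
        log_p_absent = _log_comb(n_total - n_allele, g) - _log_comb(n_total, g)
    p_absent = np.where(absent_possible, np.exp(np.where(absent_possible, log_p_absent, 0.0)), 0.0)
    return 1.0 - p_absent


def allelic_diversity_partition(ds: GenotypeDataset, rarefaction_size="auto") -> AllelicPartition:
    """AT = AS + DA from rarefied allele counts.

    Rarefaction size g is per locus: the smallest per-breed called-allele
    count (floored at 2) when ``auto``, else the given integer.  Loci where
    any breed has fewer than g called alleles are dropped everywhere and
    counted.  An allele is "present" after rarefaction when its expected
    rarefied copy number g * n_a / n_total exceeds 0.5.
    """
    freq, counts = ds.breed_allele_freq()
    if len(freq) < 2:
        raise ValueError("need at least two breeds")
    P = freq.to_numpy(dtype=np.float64)
    N_tot = counts.to_numpy(dtype=np.float64)  # called alleles per breed/locus
    B, L = P.shape
    n_alt = np.where(N_tot > 0, P * N_tot, 0.0)
    n_ref = N_tot - n_alt

    if rarefaction_size == "auto":
        g = np.maximum(2.0, N_tot.min(axis=0))
    else:
        g = np.full(L, float(int(rarefaction_size)))
    keep = (N_tot >= g[None, :]).all(axis=0)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no locus callable in every breed at the rarefaction size")
    g = g[keep]
    n_alt, n_ref, N_tot = n_alt[:, keep], n_ref[:, keep], N_tot[:, keep]

    rich = _rarefied_presence_prob(n_alt, N_tot, g[None, :]) + _rarefied_presence_prob(
        n_ref, N_tot, g[None, :]
    )
    per_breed = pd.Series(rich.mean(axis=1) - 1.0, index=freq.index, name="richness_minus_1")
    AS = float(per_breed.mean())

    # rarefied presence: expected copy number in the g-sample > 0.5
    present_alt = (g[None, :] * n_alt / N_tot) > 0.5
    present_ref = (g[None, :] * n_ref / N_tot) > 0.5
    pair_terms = []
    for a in range(B):
        for b in range(B):
            if a == b:
                continue
            uniq = (present_alt[a] & ~present_alt[b]).astype(float) + (
                present_ref[a] & ~present_ref[b]
            ).astype(float)
            pair_terms.append(uniq.mean())
    DA = float(np.mean(pair_terms))

    pooled_alt = n_alt.sum(axis=0)
    pooled_tot = N_tot.sum(axis=0)
    pooled_rich = _rarefied_presence_prob(pooled_alt, pooled_tot, g) + _rarefied_presence_prob(
        pooled_tot - pooled_alt, pooled_tot, g
    )
    return AllelicPartition(
        AS=AS,
        DA=DA,
        AT=AS + DA,
        pooled_richness_minus_1=float(pooled_rich.mean() - 1.0),
        per_breed_richness_minus_1=per_breed,
        n_loci_used=int(keep.sum()),
        n_loci_dropped=n_dropped,
    )


# ----------------------------------------------------------------------
# private alleles and per-breed indices
# ----------------------------------------------------------------------
def private_alleles(ds: GenotypeDataset) -> pd.Series:
    """Mean number of breed-private alleles per locus, per breed."""
    freq, counts = ds.breed_allele_freq()
    if len(freq) < 2:
        raise ValueError("private alleles undefined for a single breed")
    P = freq.to_numpy(dtype=np.float64)
    N_tot = counts.to_numpy(dtype=np.float64)
    obs_alt = (np.nan_to_num(P) * N_tot) > 0
    obs_ref = ((1.0 - np.nan_to_num(P, nan=1.0)) * N_tot) > 0
    B = P.shape[0]
    out = {}
    for b in range(B):
        others = [i for i in range(B) if i != b]
        priv = (obs_alt[b] & ~obs_alt[others].any(axis=0)).astype(float) + (
            obs_ref[b] & ~obs_ref[others].any(axis=0)
        ).astype(float)
        out[freq.index[b]] = float(priv.mean())
    return pd.Series(out, name="private_alleles_per_locus")


def breed_diversity_indices(co: CoancestryMatrix) -> pd.DataFrame:
    """Per-breed fii, si, dii and Gi.

    fii and dii average over ordered pairs i != j within the breed;
    d_ij = (s_i + s_j)/2 - f_ij; Gi = dii / (dii + (1 - si)), NaN when the
    denominator vanishes.
    """
    breeds = list(dict.fromkeys(co.breeds))
    lab = np.asarray(co.breeds)
    s = np.diag(co.values)
    rows = []
    for b in breeds:
        idx = np.flatnonzero(lab == b)
        if len(idx) < 2:
            raise ValueError(f"breed {b!r} needs >= 2 individuals for dii")
        sub = co.values[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        fii = float(sub[off].mean())
        si = float(s[idx].mean())
        dmat = (s[idx][:, None] + s[idx][None, :]) / 2.0 - sub
        dii = float(dmat[off].mean())
        denom = dii + (1.0 - si)
        gi = dii / denom if denom > 1e-15 else np.nan
        rows.append({"breed": b, "fii": fii, "si": si, "dii": dii, "Gi": gi})
    return pd.DataFrame(rows).set_index("breed")
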