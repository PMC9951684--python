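"""Runs-of-homozygosity detection, breed summaries and ROH islands.

Detection is a direct maximal-interval scan rather than a sliding-window
heuristic: per individual and chromosome the marker sequence is split at
inter-SNP gaps above ``max_gap_bp``; feasible intervals are contiguous SNP
stretches with at most ``max_het`` heterozygous and ``max_missing`` missing
calls; non-overlapping intervals are selected greedily, longest (in bp)
first with ties going to the leftmost start; the selection is then filtered
by minimum SNP count, length and SNP density.  The greedy pass is exactly
equivalent to ranking *all* feasible subintervals by length and picking
them greedily, which makes the detector brute-force checkable on small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ROHParams:
    """Detection constraints (defaults: 1 Mb, 100 SNPs, 1 het, 2 missing,
    0.01 SNP/kb density, 1 Mb maximum inter-SNP gap)."""

    min_length_bp: int = 1_000_000
    min_snps: int = 100
    max_het: int = 1
    max_missing: int = 2
    min_density_snp_per_kb: float = 0.01
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_gap_bp) <= 0:
            raise ValueError("length, SNP-count and gap limits must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("het/missing allowances must be >= 0")
        if self.min_density_snp_per_kb <= 0:
            raise ValueError("density must be positive")


def _passes_filters(pos: np.ndarray, l: int, r: int, params: ROHParams) -> bool:
    n = r - l + 1
    length = int(pos[r] - pos[l] + 1)
    if n < params.min_snps or length < params.min_length_bp:
        return False
    return n / (length / 1000.0) >= params.min_density_snp_per_kb


def _min_left(bad: np.ndarray, budget: int) -> np.ndarray:
    """For each right end r, the smallest l such that [l, r] holds at most
    ``budget`` flagged SNPs.  Monotone non-decreasing in r."""
    n = len(bad)
    cum = np.cumsum(bad)
    flagged = np.flatnonzero(bad)
    if len(flagged) == 0:
        return np.zeros(n, dtype=np.int64)
    k = cum - budget  # flagged SNPs that must fall left of the window
    out = np.zeros(n, dtype=np.int64)
    need = k >= 1
    out[need] = flagged[k[need] - 1] + 1
    return out


def _longest_feasible(pos, bad_het, bad_mis, lo, hi, params) -> tuple[int, int, int] | None:
    """Longest (bp) interval within [lo, hi] under the het/missing budget;
    leftmost on ties.  Returns (length_bp, l, r)."""
    if hi < lo:
        return None
    het = bad_het[lo : hi + 1]
    mis = bad_mis[lo : hi + 1]
    l = np.maximum(_min_left(het, params.max_het), _min_left(mis, params.max_missing))
    p = pos[lo : hi + 1]
    idx = np.arange(len(p))
    feasible = l <= idx  # l > r means no window ending at r fits the budget
    if not feasible.any():
        return None
    lengths = np.where(feasible, p - p[np.minimum(l, idx)] + 1, -1)
    # l(r) is monotone, so the first argmax is the leftmost-start optimum
    r = int(np.argmax(lengths))
    return (int(lengths[r]), lo + int(l[r]), lo + r)


def detect_roh(ds: GenotypeDataset, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """ROH segments per individual; columns sample_id, chrom, start_bp,
    end_bp (1-based inclusive at SNP positions), n_snps, n_het, n_missing,
    length_bp."""
    chrom_arr = ds.markers["chrom"].to_numpy()
    pos_all = ds.markers["pos"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        p = pos_all[chrom_arr == chrom]
        if (np.diff(p) <= 0).any():
            raise ValueError(f"marker map unsorted on chromosome {chrom}")

    records = []
    for i in range(ds.n_samples):
        sid = ds.samples["sample_id"].iat[i]
        row = ds.dosages[i]
        for chrom in dict.fromkeys(chrom_arr):
            idx = np.flatnonzero(chrom_arr == chrom)
            pos = pos_all[idx]
            dos = row[idx]
            bad_het = (dos == 1).astype(np.int64)
            bad_mis = (dos == MISSING).astype(np.int64)
            # split at large gaps
            brk = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
            pieces = np.split(np.arange(len(pos)), brk + 1)
            regions = [(int(p[0]), int(p[-1])) for p in pieces if len(p) > 0]

            # greedy longest-first selection over free regions
            best_of = {
                reg: _longest_feasible(pos, bad_het, bad_mis, reg[0], reg[1], params)
                for reg in regions
            }
            selected = []
            while best_of:
                reg, cand = max(
                    ((k, v) for k, v in best_of.items() if v is not None),
                    key=lambda kv: (kv[1][0], -pos[kv[1][1]]),
                    default=(None, None),
                )
                if cand is None or cand[0] < params.min_length_bp:
                    break  # nothing longer can pass the length filter
                length, l, r = cand
                selected.append((l, r))
                del best_of[reg]
                lo, hi = reg
                if l - 1 >= lo:
                    best_of[(lo, l - 1)] = _longest_feasible(pos, bad_het, bad_mis, lo, l - 1, params)
                if r + 1 <= hi:
                    best_of[(r + 1, hi)] = _longest_feasible(pos, bad_het, bad_mis, r + 1, hi, params)

            for l, r in sorted(selected):
                if not _passes_filters(pos, l, r, params):
                    continue
                records.append(
                    {
                        "sample_id": sid,
                        "chrom": chrom,
                        "start_bp": int(pos[l]),
                        "end_bp": int(pos[r]),
                        "n_snps": int(r - l + 1),
                        "n_het": int(bad_het[l : r + 1].sum()),
                        "n_missing": int(bad_mis[l : r + 1].sum()),
                        "length_bp": int(pos[r] - pos[l] + 1),
                    }
                )
    cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "n_het", "n_missing", "length_bp"]
    return pd.DataFrame(records, columns=cols)


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------
def summarize_roh(segments: pd.DataFrame, samples: pd.DataFrame, sd_ddof: int = 0) -> pd.DataFrame:
    """Per-breed SROH (Mb), NROH and MNROH +- SD (Mb).

    SD is the population SD by default (``sd_ddof=0``).  Breeds with no
    segment report NROH 0 and NaN MNROH.
    """
    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    seg = segments.copy()
    if len(seg):
        seg["breed"] = seg["sample_id"].map(breed_of)
    rows = []
    for breed in dict.fromkeys(samples["breed"]):
        n_ind = int((samples["breed"] == breed).sum())
        sub = seg[seg["breed"] == breed] if len(seg) else seg
        lengths_mb = sub["length_bp"].to_numpy(dtype=float) / 1e6 if len(sub) else np.array([])
        rows.append(
            {
                "breed": breed,
                "n_samples": n_ind,
                "sroh_mb": float(lengths_mb.sum()),
                "nroh": int(len(lengths_mb)),
                "mnroh_mb": float(lengths_mb.mean()) if len(lengths_mb) else np.nan,
                "sd_mb": float(lengths_mb.std(ddof=sd_ddof)) if len(lengths_mb) > sd_ddof else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("breed")


def aggregate_breed_roh(summary: pd.DataFrame) -> dict[str, float]:
    """Panel-level aggregates of a per-breed (sroh_mb, nroh[, mnroh_mb])
    summary table.

    Reports both MNROH conventions: the unweighted column mean of per-breed
    MNROH and the pooled mean (total SROH / total NROH).
    """
    out = {
        "total_nroh": float(summary["nroh"].sum()),
        "mean_sroh_mb": float(summary["sroh_mb"].mean()),
        "max_nroh": float(summary["nroh"].max()),
        "min_nroh": float(summary["nroh"].min()),
        "mean_nroh": float(summary["nroh"].mean()),
        "total_sroh_mb": float(summary["sroh_mb"].sum()),
    }
    if "mnroh_mb" in summary:
        out["mean_mnroh_mb"] = float(summary["mnroh_mb"].mean())
    if out["total_nroh"] > 0:
        out["pooled_mnroh_mb"] = out["total_sroh_mb"] / out["total_nroh"]
    return out


# ----------------------------------------------------------------------
# incidence and islands
# ----------------------------------------------------------------------
def snp_incidence(segments: pd.DataFrame, ds: GenotypeDataset) -> np.ndarray:
    """Fraction of all individuals whose ROH cover each SNP (bp inclusion)."""
    chrom_arr = ds.markers["chrom"].to_numpy()
    pos_all = ds.markers["pos"].to_numpy()
    counts = np.zeros(ds.n_markers, dtype=np.int64)
    offsets = {}
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        offsets[chrom] = (idx[0], pos_all[idx])
    for seg in segments.itertuples():
        off, pos = offsets[seg.chrom]
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        counts[off + lo : off + hi] += 1
    return counts / float(ds.n_samples)


def call_islands(
    incidence: np.ndarray,
    markers: pd.DataFrame,
    threshold: float = 0.30,
    min_island_snps: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Maximal runs of consecutive SNPs with incidence strictly above the
    threshold; runs shorter than ``min_island_snps`` are discarded and
    counted (second return value).  No gap-merging across dips."""
    chrom_arr = markers["chrom"].to_numpy()
    pos_all = markers["pos"].to_numpy()
    above = incidence > threshold
    rows, n_short = [], 0
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        flag = above[idx]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], flag.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):  # [s, e) runs of True
            if e - s < min_island_snps:
                n_short += 1
                continue
            sl = idx[s:e]
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(pos_all[sl[0]]),
                    "end_bp": int(pos_all[sl[-1]]),
                    "n_snps": int(e - s),
                    "mean_incidence": float(incidence[sl].mean()),
                    "max_incidence": float(incidence[sl].max()),
                }
            )
    cols = ["chrom", "start_bp", "end_bp", "n_snps", "mean_incidence", "max_incidence"]
    return pd.DataFrame(rows, columns=cols), n_short
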