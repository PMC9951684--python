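"""Pairwise genotype r2, binned LD-decay curves and a Sved-inversion Ne
trajectory.

r2 is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete samples (composite LD; no phasing).  The Ne trajectory
inverts Sved's relation E[r2] = 1/(1 + 4 Ne c) per distance bin after
subtracting the 1/n sample-size term, mapping physical distance to
recombination fraction with a constant cm-per-Mb scaling and each bin to a
past generation t = 1/(2c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


def pairwise_r2(
    ds: GenotypeDataset,
    breed: str | None = None,
    max_dist_bp: int = 2_000_000,
    max_pairs: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Marker pairs within ``max_dist_bp`` on a chromosome, with distance and
    r2; returns (pairs, n_monomorphic_excluded).

    Pairs whose r2 is undefined (either marker monomorphic over the
    pairwise-complete samples) are excluded and counted.  ``max_pairs``
    subsamples the pair list deterministically under ``seed``.
    """
    if breed is not None:
        rows = ds.breed_indices().get(breed)
        if rows is None:
            raise KeyError(f"breed {breed!r} not in dataset")
        ds = ds.subset_samples(rows)
    X = ds.dosages.astype(np.float64)
    X[ds.dosages == MISSING] = np.nan

    chrom_arr = ds.markers["chrom"].to_numpy()
    pos_all = ds.markers["pos"].to_numpy()
    dists, r2s = [], []
    n_bad = 0
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_all[idx]
        hi_of = np.searchsorted(pos, pos + max_dist_bp, side="right")
        for a in range(len(idx) - 1):
            hi = hi_of[a]
            if hi <= a + 1:
                continue
            r2, defined = _anchor_r2(X[:, idx[a]], X[:, idx[a + 1 : hi]])
            keep = defined  # undefined = monomorphic on shared samples
            n_bad += int((~keep).sum())
            dists.append((pos[a + 1 : hi] - pos[a])[keep])
            r2s.append(r2[keep])
    if dists:
        pairs = pd.DataFrame(
            {"dist_bp": np.concatenate(dists).astype(np.int64), "r2": np.concatenate(r2s)}
        )
    else:
        pairs = pd.DataFrame(columns=["dist_bp", "r2"])
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = pairs.iloc[np.sort(rng.choice(len(pairs), max_pairs, replace=False))]
        pairs = pairs.reset_index(drop=True)
    return pairs, n_bad


def _anchor_r2(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete squared correlation of one anchor column against a
    block of columns; returns (r2, defined)."""
    vx = ~np.isnan(x)
    vy = ~np.isnan(Y)
    both = vx[:, None] & vy
    n = both.sum(axis=0).astype(np.float64)
    xz = np.where(vx, x, 0.0)[:, None] * both
    yz = np.where(vy, Y, 0.0) * both
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.maximum(n, 1.0)
        mx = xz.sum(axis=0) / nn
        my = yz.sum(axis=0) / nn
        cov = (xz * yz).sum(axis=0) / nn - mx * my
        var_x = (xz**2).sum(axis=0) / nn - mx**2
        var_y = (yz**2).sum(axis=0) / nn - my**2
        denom = var_x * var_y
        defined = (denom > 0) & (n > 1)
        r2 = np.where(defined, cov**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0), defined


@dataclass
class LDCurve:
    """Binned mean r2 against physical distance."""

    bins: pd.DataFrame  # bin_lo_bp, bin_hi_bp, n_pairs, mean_r2
    width_near: int
    width_far: int
    breakpoint: int
    unit: str = "kb"


def decay_curve(
    pairs: pd.DataFrame,
    width_near: int = 500,
    width_far: int = 1100,
    breakpoint: int = 2000,
    unit: str = "kb",
) -> LDCurve:
    """Bin pair distances (narrow bins below the breakpoint, wide above) and
    average r2 per bin; empty bins report count 0 and NaN mean."""
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    scale = {"kb": 1000, "bp": 1}[unit]
    wn, wf, brk = width_near * scale, width_far * scale, breakpoint * scale
    max_d = int(pairs["dist_bp"].max())
    edges = list(range(0, brk, wn)) + [brk]
    while edges[-1] <= max_d:
        edges.append(edges[-1] + wf)
    edges = np.asarray(edges, dtype=np.int64)
    which = np.searchsorted(edges, pairs["dist_bp"].to_numpy(), side="right") - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo_bp": int(edges[b]),
                "bin_hi_bp": int(edges[b + 1]),
                "n_pairs": n,
                "mean_r2": float(pairs.loc[sel, "r2"].mean()) if n else np.nan,
            }
        )
    return LDCurve(
        bins=pd.DataFrame(rows), width_near=width_near, width_far=width_far,
        breakpoint=breakpoint, unit=unit,
    )


def ne_trajectory(
    curve: LDCurve,
    n_samples: int,
    cm_per_mb: float = 3.0,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-bin Ne = (1/r2_adj - 1)/(4c) with r2_adj = mean r2 - 1/n.

    c is the recombination fraction (Morgans) of the bin midpoint under the
    constant cm-per-Mb map; t = 1/(2c) past generations.  Bins that are
    empty or where r2_adj <= epsilon are reported with a skip reason.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rows = []
    for b in curve.bins.itertuples():
        mid_bp = (b.bin_lo_bp + b.bin_hi_bp) / 2.0
        c = mid_bp / 1e6 * cm_per_mb / 100.0  # Morgans
        row = {
            "bin_lo_bp": b.bin_lo_bp,
            "bin_hi_bp": b.bin_hi_bp,
            "c_morgan": c,
            "t_generations": 1.0 / (2.0 * c) if c > 0 else np.inf,
            "ne": np.nan,
            "skipped": "",
        }
        if b.n_pairs == 0 or np.isnan(b.mean_r2):
            row["skipped"] = "empty bin"
        else:
            r2_adj = b.mean_r2 - 1.0 / n_samples
            if r2_adj <= epsilon:
                row["skipped"] = "r2 at sampling floor"
            elif c <= 0:
                row["skipped"] = "zero recombination distance"
            else:
                row["ne"] = (1.0 / r2_adj - 1.0) / (4.0 * c)
        rows.append(row)
    out = pd.DataFrame(rows)
    bad = out["ne"].dropna() <= 0
    if bad.any():
        raise AssertionError("Ne must be positive where defined")
    return out


def sved_expected_r2(ne: float, c: float, n_samples: float = np.inf) -> float:
    """E[r2] under Sved's relation plus the 1/n sampling term."""
    base = 1.0 / (1.0 + 4.0 * ne * c)
    return base + (0.0 if np.isinf(n_samples) else 1.0 / n_samples)
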