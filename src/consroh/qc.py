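"""Quality-control filters and windowed LD pruning.

The QC stage order is fixed: duplicate markers -> non-autosomal markers ->
individual call rate -> SNP call rate.  Call rates are computed on the
markers/samples surviving the previous stage, and thresholds are inclusive
(a call rate exactly at the threshold is retained).  Order matters for the
retained counts, so it is pinned here rather than left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset


@dataclass
class QCReport:
    """Per-stage removal counts; retained + removed = input along each axis."""

    n_markers_in: int
    n_samples_in: int
    markers_removed_duplicate: int = 0
    markers_removed_nonautosomal: int = 0
    samples_removed_callrate: int = 0
    markers_removed_callrate: int = 0
    n_markers_retained: int = 0
    n_samples_retained: int = 0

    def validate(self) -> None:
        m = (
            self.markers_removed_duplicate
            + self.markers_removed_nonautosomal
            + self.markers_removed_callrate
            + self.n_markers_retained
        )
        s = self.samples_removed_callrate + self.n_samples_retained
        if m != self.n_markers_in or s != self.n_samples_in:
            raise AssertionError("QCReport counts do not add up")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(vars(self)), "count": list(vars(self).values())}
        )


def _is_autosome(chrom: str, autosome_max: int) -> bool:
    s = str(chrom)
    return s.isdigit() and 1 <= int(s) <= autosome_max


def qc_filter(
    ds: GenotypeDataset,
    min_ind_call: float = 0.95,
    min_snp_call: float = 0.99,
    autosomes_only: bool = True,
    drop_duplicates: bool = True,
    autosome_max: int = 28,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the fixed-order QC filters; raises if nothing survives."""
    if not (0.0 <= min_ind_call <= 1.0 and 0.0 <= min_snp_call <= 1.0):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    rep = QCReport(n_markers_in=ds.n_markers, n_samples_in=ds.n_samples)
    cur = ds

    if drop_duplicates:
        dup = cur.markers.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
        rep.markers_removed_duplicate = int(dup.sum())
        if dup.any():
            cur = cur.subset_markers(np.flatnonzero(~dup))

    if autosomes_only:
        auto = cur.markers["chrom"].map(lambda c: _is_autosome(c, autosome_max)).to_numpy()
        rep.markers_removed_nonautosomal = int((~auto).sum())
        if not auto.all():
            cur = cur.subset_markers(np.flatnonzero(auto))
    _check_nonempty(cur, "marker filters")

    called = cur.called()
    ind_rate = called.mean(axis=1)
    keep_s = ind_rate >= min_ind_call
    rep.samples_removed_callrate = int((~keep_s).sum())
    if not keep_s.all():
        cur = cur.subset_samples(np.flatnonzero(keep_s))
    _check_nonempty(cur, "individual call-rate filter")

    snp_rate = cur.called().mean(axis=0)
    keep_m = snp_rate >= min_snp_call
    rep.markers_removed_callrate = int((~keep_m).sum())
    if not keep_m.all():
        cur = cur.subset_markers(np.flatnonzero(keep_m))
    _check_nonempty(cur, "SNP call-rate filter")

    rep.n_markers_retained = cur.n_markers
    rep.n_samples_retained = cur.n_samples
    rep.validate()
    return cur, rep


def _check_nonempty(ds: GenotypeDataset, stage: str) -> None:
    if ds.n_markers == 0 or ds.n_samples == 0:
        raise ValueError(f"dataset empty after {stage}")


def pairwise_complete_r2(X: np.ndarray, return_defined: bool = False):
    """Pairwise-complete squared Pearson correlation between columns.

    ``X`` is (samples x markers) float with NaN for missing calls.  Pairs
    where either column is monomorphic over the shared samples get r2 = 0;
    with ``return_defined`` a boolean matrix marking genuinely defined
    pairs is returned alongside.
    """
    V = (~np.isnan(X)).astype(np.float64)
    Xz = np.where(np.isnan(X), 0.0, X)
    N = V.T @ V
    SX = Xz.T @ V          # sum of x over pairwise-complete samples
    SXY = Xz.T @ Xz
    SXX = (Xz**2).T @ V
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.maximum(N, 1.0)
        cov = SXY / n - (SX / n) * (SX.T / n)
        var_x = SXX / n - (SX / n) ** 2
        var_y = SXX.T / n - (SX.T / n) ** 2
        denom = var_x * var_y
        defined = (denom > 0) & (N > 1)
        r2 = np.where(defined, cov**2 / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(r2, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    if return_defined:
        return r2, defined
    return r2


def ld_prune(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Windowed pairwise LD pruning; returns retained marker ids in map order.

    Within each sliding window, while any retained pair has r2 strictly
    above the threshold, the member of the worst (highest-r2) pair with the
    lower minor-allele frequency is removed; MAF ties remove the later map
    position.  Monomorphic markers have r2 defined as 0 and are never
    pruned.  The window advances by ``step_snps``.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")

    dos = ds.dosages.astype(np.float64)
    dos[ds.dosages == -1] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.fmin(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)

    removed = np.zeros(ds.n_markers, dtype=bool)
    chrom_arr = ds.markers["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window_snps]
            live = win[~removed[win]]
            if len(live) >= 2:
                r2 = pairwise_complete_r2(dos[:, live])
                np.fill_diagonal(r2, 0.0)
                alive = np.ones(len(live), dtype=bool)
                while True:
                    sub = np.where(np.outer(alive, alive), r2, 0.0)
                    worst = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[worst] <= r2_threshold:
                        break
                    a, b = live[worst[0]], live[worst[1]]
                    if maf[a] < maf[b]:
                        victim = a
                    elif maf[b] < maf[a]:
                        victim = b
                    else:  # MAF tie: drop the later map position
                        victim = max(a, b)
                    removed[victim] = True
                    alive[worst[0] if victim == a else worst[1]] = False
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return ds.markers.loc[~removed, "snp"].tolist()
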