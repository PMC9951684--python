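"""Breed contributions to diversity and synthetic-pool optimization.

``leave_one_out`` recomputes the gene and allelic diversity partitions
after removing each breed in turn; a positive percentage means diversity is
lost when the breed is removed.  ``optimize_pool`` searches, by simulated
annealing with restarts plus a greedy polish, for the integer breed
composition of an N-individual synthetic pool maximizing either expected
heterozygosity (H) or the expected allele count of the pool (K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset
from .diversity import (
    allelic_diversity_partition,
    coancestry,
    gene_diversity_partition,
)


# ----------------------------------------------------------------------
# leave-one-out contributions
# ----------------------------------------------------------------------
def leave_one_out(ds: GenotypeDataset, rarefaction_size="auto") -> pd.DataFrame:
    """Percent change in each partition component when a breed is removed.

    Percentages are relative to the full-panel value:
    100 * (X_full - X_without_breed) / X_full.
    """
    breeds = ds.breeds
    if len(breeds) < 3:
        raise ValueError("need >= 3 breeds so every removal leaves >= 2")
    co_full = coancestry(ds)
    gp_full = gene_diversity_partition(co_full)
    ap_full = allelic_diversity_partition(ds, rarefaction_size)
    if gp_full.HT <= 0 or ap_full.AT <= 0:
        raise ValueError("full-panel HT or AT is zero; contributions undefined")

    lab = np.asarray(co_full.breeds)
    rows = []
    for b in breeds:
        keep = np.flatnonzero(lab != b)
        gp = gene_diversity_partition(co_full.subset(keep))
        ap = allelic_diversity_partition(ds.drop_breed(b), rarefaction_size)
        rows.append(
            {
                "breed": b,
                "dHT_pct": 100.0 * (gp_full.HT - gp.HT) / gp_full.HT,
                "dHS_pct": 100.0 * (gp_full.HS - gp.HS) / gp_full.HS if gp_full.HS > 0 else np.nan,
                "dDG_pct": 100.0 * (gp_full.DG - gp.DG) / gp_full.DG if gp_full.DG > 0 else np.nan,
                "dAT_pct": 100.0 * (ap_full.AT - ap.AT) / ap_full.AT,
                "dAS_pct": 100.0 * (ap_full.AS - ap.AS) / ap_full.AS if ap_full.AS > 0 else np.nan,
                "dDA_pct": 100.0 * (ap_full.DA - ap.DA) / ap_full.DA if ap_full.DA > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("breed")
    out["rank_gene"] = out["dHT_pct"].rank(ascending=False).astype(int)
    out["rank_allelic"] = out["dAT_pct"].rank(ascending=False).astype(int)
    return out


# ----------------------------------------------------------------------
# pool objectives
# ----------------------------------------------------------------------
def _pool_freq_matrix(ds: GenotypeDataset) -> tuple[pd.Index, np.ndarray]:
    """Breed frequency matrix over loci called in every breed."""
    freq, _ = ds.breed_allele_freq()
    P = freq.to_numpy(dtype=np.float64)
    keep = ~np.isnan(P).any(axis=0)
    if not keep.any():
        raise ValueError("no locus called in every breed")
    return freq.index, P[:, keep]


def pool_objective(P: np.ndarray, counts: np.ndarray, N: int, kind: str) -> float:
    """Objective of a pool with per-breed contribution ``counts`` (sum N).

    H: mean over loci of 2 p (1-p) * N/(N-1) at the pooled frequency
    p = sum_b (c_b/N) p_b (finite-pool correction makes H the expected
    heterozygosity of an N-individual random-mating pool).
    K: mean over loci of the expected number of alleles present in a sample
    of 2N pool gametes.
    """
    w = np.asarray(counts, dtype=np.float64) / N
    p = w @ P
    if kind == "H":
        return float(np.mean(2.0 * p * (1.0 - p)) * (N / (N - 1.0)))
    if kind == "K":
        m = 2 * N
        with np.errstate(over="ignore"):
            present = (1.0 - (1.0 - p) ** m) + (1.0 - p**m)
        return float(np.mean(present))
    raise ValueError(f"unknown objective {kind!r}")


@dataclass
class PoolSolution:
    N: int
    counts: pd.Series
    proportions: pd.Series
    objective: str
    value: float
    n_loci_used: int
    restarts: int
    trace_length: int
    seed: int
    flat: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "proportion": self.proportions}
        ).rename_axis("breed")


def _greedy_polish(P, N, kind, counts) -> tuple[np.ndarray, float]:
    """Single-unit hill climbing to a local (for these concave objectives,
    global) optimum."""
    counts = counts.copy()
    best = pool_objective(P, counts, N, kind)
    B = len(counts)
    improved = True
    while improved:
        improved = False
        move = None
        for a in range(B):
            if counts[a] == 0:
                continue
            for b in range(B):
                if a == b:
                    continue
                counts[a] -= 1
                counts[b] += 1
                v = pool_objective(P, counts, N, kind)
                counts[a] += 1
                counts[b] -= 1
                if v > best + 1e-15:
                    best, move, improved = v, (a, b), True
        if move:
            counts[move[0]] -= 1
            counts[move[1]] += 1
    return counts, best


def optimize_pool(
    ds: GenotypeDataset,
    N: int = 1000,
    objective: str = "H",
    seed: int = 0,
    restarts: int = 10,
    sa_steps: int = 2000,
    t0_frac: float = 0.02,
    cooling: float = 0.995,
) -> PoolSolution:
    """Breed composition of an N-individual pool maximizing H or K.

    Simulated annealing over integer compositions of N (geometric cooling,
    best of ``restarts`` chains) followed by single-unit hill climbing;
    deterministic under ``seed``.  A flat objective (all breeds sharing one
    frequency vector) returns the uniform composition with ``flat=True``.
    """
    breeds, P = _pool_freq_matrix(ds)
    B = len(breeds)
    if N < B:
        raise ValueError("pool size must be at least the number of breeds")
    rng = np.random.default_rng(seed)

    uniform = np.full(B, N // B, dtype=np.int64)
    uniform[: N - uniform.sum()] += 1
    if np.allclose(P, P[0:1, :], atol=1e-12):
        return PoolSolution(
            N=N,
            counts=pd.Series(uniform, index=breeds),
            proportions=pd.Series(uniform / N, index=breeds),
            objective=objective,
            value=pool_objective(P, uniform, N, objective),
            n_loci_used=P.shape[1],
            restarts=0,
            trace_length=0,
            seed=seed,
            flat=True,
        )

    candidates: list[tuple[float, np.ndarray]] = []
    # pure-breed and uniform baselines are always examined
    for b in range(B):
        pure = np.zeros(B, dtype=np.int64)
        pure[b] = N
        candidates.append((pool_objective(P, pure, N, objective), pure))
    candidates.append((pool_objective(P, uniform, N, objective), uniform))

    trace = 0
    step_size = max(1, N // 50)
    for _ in range(restarts):
        counts = rng.multinomial(N, np.full(B, 1.0 / B)).astype(np.int64)
        cur = pool_objective(P, counts, N, objective)
        best_c, best_v = counts.copy(), cur
        T = max(t0_frac * max(abs(cur), 1e-6), 1e-9)
        for _ in range(sa_steps):
            trace += 1
            donors = np.flatnonzero(counts > 0)
            a = int(rng.choice(donors))
            b = int(rng.integers(B - 1))
            b = b + 1 if b >= a else b
            m = int(rng.integers(1, min(step_size, counts[a]) + 1))
            counts[a] -= m
            counts[b] += m
            v = pool_objective(P, counts, N, objective)
            if v >= cur or rng.random() < np.exp((v - cur) / T):
                cur = v
                if v > best_v:
                    best_v, best_c = v, counts.copy()
            else:
                counts[a] += m
                counts[b] -= m
            T *= cooling
        candidates.append((best_v, best_c))

    start = max(candidates, key=lambda t: t[0])[1]
    counts, value = _greedy_polish(P, N, objective, start)
    return PoolSolution(
        N=N,
        counts=pd.Series(counts, index=breeds),
        proportions=pd.Series(counts / N, index=breeds),
        objective=objective,
        value=value,
        n_loci_used=P.shape[1],
        restarts=restarts,
        trace_length=trace,
        seed=seed,
    )


def exhaustive_pool_2breeds(ds: GenotypeDataset, N: int, objective: str) -> tuple[np.ndarray, float]:
    """Exact optimum over all N+1 compositions of a 2-breed pool."""
    breeds, P = _pool_freq_matrix(ds)
    if len(breeds) != 2:
        raise ValueError("exhaustive search implemented for exactly 2 breeds")
    best_c, best_v = None, -np.inf
    for c in range(N + 1):
        counts = np.array([c, N - c], dtype=np.int64)
        v = pool_objective(P, counts, N, objective)
        if v > best_v:
            best_v, best_c = v, counts
    return best_c, best_v
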