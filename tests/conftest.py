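"""Shared fixtures: literal-matrix dataset builder, small simulated panels,
and the independent brute-force ROH enumerator used as a detection oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from consroh.dataset import MISSING, GenotypeDataset, make_marker_map
from consroh.sim import SimConfig, simulate_dataset


def build_dataset(dosages, chroms=None, positions=None, breeds=None, sample_ids=None):
    """GenotypeDataset from a literal (samples x markers) dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if chroms is None:
        chroms = ["1"] * L
    if positions is None:
        positions = (np.arange(L) + 1) * 1000
    if breeds is None:
        breeds = ["b1"] * n
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    markers = make_marker_map(chroms, [f"m{i + 1}" for i in range(L)], positions)
    return GenotypeDataset(
        markers=markers,
        samples=pd.DataFrame({"sample_id": sample_ids, "breed": breeds}),
        dosages=dosages,
    )


@pytest.fixture
def make_ds():
    return build_dataset


@pytest.fixture(scope="session")
def small_panel():
    """Four diverged breeds with mixed autozygosity and missing calls."""
    cfg = SimConfig(
        n_breeds=4,
        breed_sizes=(6, 6, 6, 6),
        fst_per_breed=(0.05, 0.10, 0.20, 0.15),
        froh_per_breed=(0.02, 0.10, 0.25, 0.0),
        chrom_lengths_bp=(20_000_000, 15_000_000),
        n_snps=1200,
        missing_rate=0.01,
        sweep_regions=(),
        seed=20240915,
    )
    return simulate_dataset(cfg)


# ----------------------------------------------------------------------
# brute-force ROH oracle (kept independent of the package implementation)
# ----------------------------------------------------------------------
def brute_force_roh(pos, dos, params):
    """All-subinterval enumeration with greedy longest-first selection and
    post-hoc filtering; returns a set of (start_index, end_index) pairs."""
    pos = np.asarray(pos)
    dos = np.asarray(dos)
    n = len(pos)
    piece = np.zeros(n, dtype=int)
    for k in range(1, n):
        piece[k] = piece[k - 1] + (1 if pos[k] - pos[k - 1] > params.max_gap_bp else 0)

    feasible = []
    for i in range(n):
        nh = nm = 0
        for j in range(i, n):
            if piece[j] != piece[i]:
                break
            nh += dos[j] == 1
            nm += dos[j] == MISSING
            if nh > params.max_het or nm > params.max_missing:
                break
            feasible.append((int(pos[j] - pos[i] + 1), i, j))

    feasible.sort(key=lambda t: (-t[0], t[1]))
    chosen = []
    for length, i, j in feasible:
        if all(j < ci or i > cj for _, ci, cj in chosen):
            chosen.append((length, i, j))

    out = set()
    for length, i, j in chosen:
        n_snps = j - i + 1
        if n_snps < params.min_snps or length < params.min_length_bp:
            continue
        if n_snps / (length / 1000.0) < params.min_density_snp_per_kb:
            continue
        out.add((i, j))
    return out


@pytest.fixture
def roh_oracle():
    return brute_force_roh
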