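"""Coancestry, Nei distances and the two diversity partitions."""

import numpy as np
import pandas as pd
import pytest

from consroh.dataset import MISSING
from consroh.diversity import (
    allelic_diversity_partition,
    breed_diversity_indices,
    coancestry,
    gene_diversity_partition,
    nei_minimum_distance,
    private_alleles,
)
from consroh.sim import SimConfig, simulate_dataset


# ----------------------------------------------------------------------
# coancestry
# ----------------------------------------------------------------------
def test_coancestry_single_locus_identities(make_ds):
    ds = make_ds([[2], [0], [1]])
    co = coancestry(ds)
    assert co.values[0, 0] == 1.0      # self of AA
    assert co.values[2, 2] == 0.5      # self of Aa
    assert co.values[0, 1] == 0.0      # AA vs aa
    assert co.values[0, 2] == 0.5      # AA vs Aa
    ds2 = make_ds([[1], [1]])
    assert coancestry(ds2).values[0, 1] == 0.5  # Aa vs Aa


def test_coancestry_matches_per_locus_enumeration(make_ds):
    rng = np.random.default_rng(4)
    d = rng.integers(0, 3, size=(3, 4)).astype(np.int8)
    d[0, 2] = MISSING
    co = coancestry(make_ds(d))
    for i in range(3):
        for j in range(3):
            vals = []
            for l in range(4):
                xi, xj = d[i, l], d[j, l]
                if xi == MISSING or xj == MISSING:
                    continue
                vals.append((xi * xj + (2 - xi) * (2 - xj)) / 4.0)
            assert co.values[i, j] == pytest.approx(np.mean(vals))
            assert co.counts[i, j] == len(vals)


def test_coancestry_errors_on_disjoint_pair(make_ds):
    d = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
    with pytest.raises(ValueError, match="s1.*s2"):
        coancestry(make_ds(d))


# ----------------------------------------------------------------------
# Nei minimum distance
# ----------------------------------------------------------------------
def test_nei_closed_forms():
    freq = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"])
    assert nei_minimum_distance(freq).loc["a", "b"] == 1.0
    freq = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]], index=["a", "b"])
    assert nei_minimum_distance(freq).loc["a", "b"] == 0.0
    freq = pd.DataFrame([[0.5], [0.0]], index=["a", "b"])
    assert nei_minimum_distance(freq).loc["a", "b"] == pytest.approx(0.25)


def test_nei_symmetric_zero_diagonal(small_panel):
    D = nei_minimum_distance(small_panel)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert (D.to_numpy() >= 0).all()


def test_coancestry_distance_tracks_frequency_distance_as_n_grows():
    devs = {}
    for n in (10, 50, 200):
        cfg = SimConfig(
            n_breeds=2, breed_sizes=(n, n), fst_per_breed=(0.1, 0.1),
            froh_per_breed=(0.0, 0.0), chrom_lengths_bp=(10_000_000,),
            n_snps=3000, missing_rate=0.0, sweep_regions=(), seed=200 + n,
        )
        ds = simulate_dataset(cfg)
        gp = gene_diversity_partition(coancestry(ds))
        d_co = gp.between.iloc[0, 1]
        d_freq = nei_minimum_distance(ds).iloc[0, 1]
        devs[n] = abs(d_co - d_freq)
        assert devs[n] < 3.0 / n
    assert devs[200] < devs[10]


# ----------------------------------------------------------------------
# gene diversity partition
# ----------------------------------------------------------------------
def test_partition_of_two_fixed_divergent_breeds(make_ds):
    d = np.array([[2] * 4] * 3 + [[0] * 4] * 3, dtype=np.int8)
    ds = make_ds(d, breeds=["x"] * 3 + ["y"] * 3)
    gp = gene_diversity_partition(coancestry(ds))
    assert gp.HS == 0.0
    assert gp.DG == pytest.approx(0.5)
    assert gp.HT == pytest.approx(0.5)


def test_identical_breeds_have_zero_between_component(make_ds):
    rng = np.random.default_rng(1)
    block = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
    ds = make_ds(np.vstack([block, block, block]), breeds=["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    gp = gene_diversity_partition(coancestry(ds))
    assert gp.DG == pytest.approx(0.0, abs=1e-15)
    ap = allelic_diversity_partition(ds)
    assert ap.DA == 0.0
    assert ap.AT == ap.AS


def test_arbitrary_split_of_one_population_gives_small_dg():
    cfg = SimConfig(
        n_breeds=1, breed_sizes=(200,), fst_per_breed=(0.0,), froh_per_breed=(0.0,),
        chrom_lengths_bp=(10_000_000,), n_snps=4000, missing_rate=0.0,
        sweep_regions=(), seed=77,
    )
    ds = simulate_dataset(cfg)
    ds.samples["breed"] = ["p"] * 100 + ["q"] * 100
    # sampling noise floor for DG is ~E[pq]/n ~ 0.002 at n = 100 per half
    gp = gene_diversity_partition(coancestry(ds))
    assert abs(gp.DG) < 0.002
    assert gp.HT == pytest.approx(gp.HS, abs=0.002)


# ----------------------------------------------------------------------
# allelic partition
# ----------------------------------------------------------------------
def test_allelic_partition_fixed_opposite_breeds(make_ds):
    d = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
    ds = make_ds(d, breeds=["x"] * 4 + ["y"] * 4)
    ap = allelic_diversity_partition(ds)
    assert ap.AS == pytest.approx(0.0)
    assert ap.DA == pytest.approx(1.0)
    assert ap.AT == pytest.approx(1.0)


def test_allelic_partition_half_polymorphic(make_ds):
    # breed x segregates A/a at 0.5, breed y fixed for A; equal sizes
    d = np.array([[1] * 6] * 4 + [[0] * 6] * 4, dtype=np.int8)
    ds = make_ds(d, breeds=["x"] * 4 + ["y"] * 4)
    ap = allelic_diversity_partition(ds)
    assert ap.AS == pytest.approx(0.5)
    assert ap.DA == pytest.approx(0.5)
    assert ap.AT == pytest.approx(1.0)


def test_private_alleles_direct_count(make_ds):
    L = 100
    d = np.zeros((4, L), dtype=np.int8)
    d[0, :10] = 1  # breed x uniquely segregates the alternate at 10 loci
    ds = make_ds(d, breeds=["x", "x", "y", "y"])
    priv = private_alleles(ds)
    assert priv["x"] == pytest.approx(10 / 100)
    assert priv["y"] == 0.0
    with pytest.raises(ValueError):
        private_alleles(make_ds(d[:2], breeds=["x", "x"]))


# ----------------------------------------------------------------------
# per-breed indices
# ----------------------------------------------------------------------
def test_breed_indices_degenerate_and_divergent(make_ds):
    ds = make_ds(np.full((3, 5), 2, dtype=np.int8))
    idx = breed_diversity_indices(coancestry(ds))
    assert idx.loc["b1", ["fii", "si", "dii"]].tolist() == [1.0, 1.0, 0.0]
    assert np.isnan(idx.loc["b1", "Gi"])

    ds2 = make_ds(np.array([[2], [0]], dtype=np.int8))
    idx2 = breed_diversity_indices(coancestry(ds2))
    assert idx2.loc["b1", "si"] == 1.0
    assert idx2.loc["b1", "fii"] == 0.0
    assert idx2.loc["b1", "dii"] == 1.0
    assert idx2.loc["b1", "Gi"] == 1.0


def test_indices_stable_under_duplicating_individuals(make_ds):
    # si is exactly exchangeable; fii/dii average over ordered pairs of
    # distinct individuals, so duplication adds copy-pairs and shifts them
    # only at O(1/n)
    rng = np.random.default_rng(6)
    d = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
    a = breed_diversity_indices(coancestry(make_ds(d)))
    doubled = np.vstack([d, d])
    b = breed_diversity_indices(coancestry(make_ds(doubled)))
    assert a.loc["b1", "si"] == pytest.approx(b.loc["b1", "si"], abs=1e-12)
    assert a.loc["b1", "fii"] == pytest.approx(b.loc["b1", "fii"], abs=0.06)
    assert a.loc["b1", "dii"] == pytest.approx(b.loc["b1", "dii"], rel=0.08)
    assert a.loc["b1", "Gi"] == pytest.approx(b.loc["b1", "Gi"], abs=0.06)


def test_sample_permutation_changes_nothing(small_panel):
    rng = np.random.default_rng(123)
    perm = rng.permutation(small_panel.n_samples)
    shuffled = small_panel.subset_samples(perm)
    gp0 = gene_diversity_partition(coancestry(small_panel))
    gp1 = gene_diversity_partition(coancestry(shuffled))
    assert gp0.HT == pytest.approx(gp1.HT, abs=1e-12)
    assert gp0.HS == pytest.approx(gp1.HS, abs=1e-12)
    ap0 = allelic_diversity_partition(small_panel)
    ap1 = allelic_diversity_partition(shuffled)
    assert ap0.AT == pytest.approx(ap1.AT, abs=1e-12)
    D0 = nei_minimum_distance(small_panel)
    D1 = nei_minimum_distance(shuffled)
    assert np.allclose(D0.loc[D1.index, D1.columns], D1)
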