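"""ROH detection against constructed toys and the brute-force enumerator."""

import numpy as np
import pandas as pd
import pytest

from consroh.dataset import MISSING
from consroh.roh import (
    ROHParams,
    aggregate_breed_roh,
    call_islands,
    detect_roh,
    snp_incidence,
    summarize_roh,
)


def _single_sample(make_ds, dosages, positions):
    return make_ds(np.asarray([dosages], dtype=np.int8), positions=positions)


def test_uniform_homozygous_run(make_ds):
    pos = 10_000 * (np.arange(150) + 1)
    ds = _single_sample(make_ds, [0] * 150, pos)
    seg = detect_roh(ds)
    assert len(seg) == 1
    assert seg.iloc[0]["n_snps"] == 150
    assert seg.iloc[0]["length_bp"] == 1_490_001


def test_two_hets_break_the_run(make_ds):
    dos = [0] * 150
    dos[69] = dos[79] = 1  # SNPs 70 and 80 heterozygous
    pos = 10_000 * (np.arange(150) + 1)
    ds = _single_sample(make_ds, dos, pos)
    # best candidates hold <= 80 SNPs, below the 100-SNP minimum
    assert len(detect_roh(ds)) == 0


def test_snp_count_threshold_edge(make_ds):
    pos = np.linspace(1, 2_000_000, 99).astype(int)
    ds = _single_sample(make_ds, [2] * 99, pos)
    assert len(detect_roh(ds)) == 0  # 99 < 100 SNPs
    pos = np.linspace(1, 2_000_000, 100).astype(int)
    ds = _single_sample(make_ds, [2] * 100, pos)
    assert len(detect_roh(ds)) == 1


def test_gap_splits_runs(make_ds):
    pos = np.concatenate([10_000 * (np.arange(120) + 1), 10_000 * (np.arange(120) + 1) + 2_500_000])
    ds = _single_sample(make_ds, [0] * 240, pos)
    seg = detect_roh(ds)
    assert len(seg) == 2  # the 1.3 Mb gap may not be bridged
    assert (seg["n_snps"] == 120).all()


def test_unsorted_map_rejected(make_ds):
    ds = _single_sample(make_ds, [0, 0], [100, 200])
    ds.markers = ds.markers.iloc[::-1].reset_index(drop=True)  # corrupt order
    with pytest.raises(ValueError, match="unsorted"):
        detect_roh(ds)


def test_all_missing_individual_yields_no_segments(make_ds):
    ds = _single_sample(make_ds, [MISSING] * 50, 1000 * (np.arange(50) + 1))
    assert len(detect_roh(ds)) == 0


def _random_instance(rng):
    n = int(rng.integers(30, 201))
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=n, replace=False))
    dos = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=n, p=[0.42, 0.08, 0.42, 0.08]
    )
    params = ROHParams(
        min_length_bp=int(rng.integers(50_000, 600_000)),
        min_snps=int(rng.integers(5, 40)),
        max_het=int(rng.integers(0, 3)),
        max_missing=int(rng.integers(0, 4)),
        min_density_snp_per_kb=float(rng.choice([0.005, 0.01, 0.05])),
        max_gap_bp=int(rng.integers(100_000, 1_000_000)),
    )
    return pos, dos, params


def test_detection_equals_bruteforce_enumeration(make_ds, roh_oracle):
    rng = np.random.default_rng(2024)
    for _ in range(200):
        pos, dos, params = _random_instance(rng)
        ds = _single_sample(make_ds, dos, pos)
        got = detect_roh(ds, params)
        got_set = {
            (int(np.searchsorted(pos, r.start_bp)), int(np.searchsorted(pos, r.end_bp)))
            for r in got.itertuples()
        }
        assert got_set == roh_oracle(pos, dos, params)


def test_filter_threshold_monotonicity(make_ds):
    # raising any post-selection filter can only remove segments, because
    # the greedy selection itself is unchanged: exact subset relation.
    # (the het/missing budgets reshape the candidate set instead -- a
    # stricter budget can split one long run into two shorter segments --
    # and are pinned by the brute-force equivalence test above)
    rng = np.random.default_rng(7)
    for _ in range(25):
        pos, dos, params = _random_instance(rng)
        ds = _single_sample(make_ds, dos, pos)
        base = detect_roh(ds, params)
        def key(df):
            return {tuple(r) for r in df[["start_bp", "end_bp"]].to_numpy()}
        for change in (
            {"min_length_bp": params.min_length_bp * 2},
            {"min_snps": params.min_snps + 10},
            {"min_density_snp_per_kb": params.min_density_snp_per_kb * 4},
        ):
            stricter = detect_roh(ds, ROHParams(**{**params.__dict__, **change}))
            assert key(stricter) <= key(base)
        # stricter budgets never produce a segment violating them
        fewer_het = detect_roh(
            ds, ROHParams(**{**params.__dict__, "max_het": 0, "max_missing": 0})
        )
        assert (fewer_het["n_het"] == 0).all() and (fewer_het["n_missing"] == 0).all()


def test_segments_never_overlap_within_individual(small_panel):
    seg = detect_roh(small_panel, ROHParams(min_length_bp=100_000, min_snps=5))
    for (_, chrom), sub in seg.groupby(["sample_id", "chrom"]):
        sub = sub.sort_values("start_bp")
        assert (sub["start_bp"].to_numpy()[1:] > sub["end_bp"].to_numpy()[:-1]).all()


# ----------------------------------------------------------------------
# summaries, incidence, islands
# ----------------------------------------------------------------------
def _toy_segments():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1"],
            "chrom": ["1", "1"],
            "start_bp": [1, 5_000_001],
            "end_bp": [2_000_000, 9_000_000],
            "n_snps": [200, 400],
            "n_het": [0, 0],
            "n_missing": [0, 0],
            "length_bp": [2_000_000, 4_000_000],
        }
    )


def test_summary_hand_arithmetic():
    samples = pd.DataFrame({"sample_id": ["s1"], "breed": ["b1"]})
    summ = summarize_roh(_toy_segments(), samples)
    row = summ.loc["b1"]
    assert row["sroh_mb"] == pytest.approx(6.0)
    assert row["nroh"] == 2
    assert row["mnroh_mb"] == pytest.approx(3.0)
    assert row["sd_mb"] == pytest.approx(1.0)  # population SD
    sample_sd = summarize_roh(_toy_segments(), samples, sd_ddof=1)
    assert sample_sd.loc["b1", "sd_mb"] == pytest.approx(1.414, abs=1e-3)


def test_summary_empty_and_identities():
    samples = pd.DataFrame({"sample_id": ["s1", "s2"], "breed": ["b1", "b2"]})
    empty = summarize_roh(_toy_segments().iloc[:0], samples)
    assert (empty["nroh"] == 0).all() and (empty["sroh_mb"] == 0).all()
    assert empty["mnroh_mb"].isna().all()

    summ = summarize_roh(_toy_segments(), samples)
    ok = summ["nroh"] > 0
    assert np.allclose(
        summ.loc[ok, "mnroh_mb"] * summ.loc[ok, "nroh"], summ.loc[ok, "sroh_mb"]
    )
    agg = aggregate_breed_roh(summ)
    assert agg["total_sroh_mb"] == pytest.approx(summ["sroh_mb"].sum())
    assert agg["mean_sroh_mb"] == pytest.approx(summ["sroh_mb"].sum() / len(summ))


def test_incidence_fractions_and_double_counting(make_ds):
    n, L = 10, 50
    pos = 100_000 * (np.arange(L) + 1)
    ds = make_ds(np.zeros((n, L), dtype=np.int8), positions=pos)
    segments = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in (1, 2, 3, 4)],
            "chrom": ["1"] * 4,
            "start_bp": [pos[10]] * 4,
            "end_bp": [pos[20]] * 4,
            "n_snps": [11] * 4,
            "n_het": [0] * 4,
            "n_missing": [0] * 4,
            "length_bp": [int(pos[20] - pos[10] + 1)] * 4,
        }
    )
    inc = snp_incidence(segments, ds)
    assert inc[15] == pytest.approx(0.4)
    assert inc[0] == 0.0 and inc[30] == 0.0
    assert inc.sum() * n == pytest.approx(segments["n_snps"].sum())


def test_island_rules(make_ds):
    L = 300
    pos = 10_000 * (np.arange(L) + 1)
    markers = make_ds(np.zeros((2, L), dtype=np.int8), positions=pos).markers

    inc = np.zeros(L)
    inc[50:150] = 0.4
    islands, n_short = call_islands(inc, markers, threshold=0.30, min_island_snps=50)
    assert len(islands) == 1
    assert islands.iloc[0]["n_snps"] == 100
    assert islands.iloc[0]["start_bp"] == pos[50]

    # exactly at the threshold is excluded (strict inequality)
    inc_at = np.full(L, 0.30)
    assert len(call_islands(inc_at, markers, 0.30, 1)[0]) == 0

    # a one-SNP dip splits the run; no gap-merging
    inc2 = np.zeros(L)
    inc2[50:250] = 0.4
    inc2[149] = 0.2
    two, _ = call_islands(inc2, markers, 0.30, min_island_snps=99)
    assert len(two) == 2
    assert sorted(two["n_snps"]) == [99, 100]
    one, n_short = call_islands(inc2, markers, 0.30, min_island_snps=100)
    assert len(one) == 1 and n_short == 1
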