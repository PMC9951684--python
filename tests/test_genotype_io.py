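"""PLINK text/binary round-trips, QC filter semantics and LD pruning."""

import numpy as np
import pytest

from consroh.dataset import MISSING
from consroh.io_plink import (
    read_plink_binary,
    read_plink_text,
    write_plink_binary,
    write_plink_text,
)
from consroh.qc import ld_prune, qc_filter
from consroh.sim import SimConfig, simulate_dataset


def _polymorphic_panel(seed=8, missing_rate=0.02):
    cfg = SimConfig(
        n_breeds=2, breed_sizes=(5, 5), fst_per_breed=(0.05, 0.1),
        froh_per_breed=(0.0, 0.1), chrom_lengths_bp=(5_000_000, 4_000_000),
        n_snps=300, missing_rate=missing_rate, sweep_regions=(), seed=seed,
    )
    ds = simulate_dataset(cfg)
    # text round-trips are exact only where the alternate allele is observed
    keep = np.flatnonzero((ds.dosages > 0).any(axis=0))
    return ds.subset_markers(keep)


def test_ped_alt_allele_convention(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t100\n1\tm2\t0\t200\n1\tm3\t0\t300\n")
    (tmp_path / "t.ped").write_text("fam1 s1 0 0 0 -9 A A A G 0 0\n")
    ds = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
    # m1: only A observed -> alt is A -> dosage 2; m2: alt G -> het 1
    assert ds.dosages.tolist() == [[2, 1, MISSING]]
    assert ds.samples["breed"].tolist() == ["fam1"]


def test_text_round_trip(tmp_path):
    ds = _polymorphic_panel()
    write_plink_text(ds, tmp_path / "x.ped", tmp_path / "x.map")
    back = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert back == ds


def test_binary_round_trip_and_cross_format_equality(tmp_path):
    ds = _polymorphic_panel(seed=9)
    write_plink_binary(ds, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
    from_bin = read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
    assert from_bin == ds
    write_plink_text(ds, tmp_path / "x.ped", tmp_path / "x.map")
    from_text = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert np.array_equal(from_bin.dosages, from_text.dosages)


def test_binary_bit_codes(tmp_path):
    # one marker, 4 samples, byte 0b11_10_00_01:
    # sample1 -> 01 missing, sample2 -> 00 hom A1, sample3 -> 10 het,
    # sample4 -> 11 hom A2; with A1='C' (alt) hom A1 decodes to dosage 2
    (tmp_path / "t.bim").write_text("1\tm1\t0\t100\tC\tA\n")
    (tmp_path / "t.fam").write_text(
        "".join(f"b1 s{i} 0 0 0 -9\n" for i in range(1, 5))
    )
    (tmp_path / "t.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b11100001]))
    ds = read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim", tmp_path / "t.fam")
    assert ds.dosages[:, 0].tolist() == [MISSING, 2, 1, 0]


def test_malformed_inputs_rejected(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t100\n1\tm2\t0\t200\n")
    (tmp_path / "t.ped").write_text("fam1 s1 0 0 0 -9 A A A\n")  # 2L+5 fields
    with pytest.raises(ValueError, match="fields"):
        read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")

    (tmp_path / "b.bim").write_text("1\tm1\t0\t100\tC\tA\n")
    (tmp_path / "b.fam").write_text("b1 s1 0 0 0 -9\n")
    (tmp_path / "b.bed").write_bytes(bytes([0x00, 0x1B, 0x01, 0x00]))
    with pytest.raises(ValueError, match="magic"):
        read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
    (tmp_path / "b.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))  # truncated
    with pytest.raises(ValueError, match="bytes"):
        read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------
def test_individual_callrate_threshold_is_inclusive(make_ds):
    # 20 markers; 1 missing call = rate 0.95 retained, 2 missing = 0.90 removed
    d = np.ones((3, 20), dtype=np.int8)
    d[1, 0] = MISSING
    d[2, :2] = MISSING
    ds = make_ds(d)
    out, rep = qc_filter(ds, min_ind_call=0.95, min_snp_call=0.0)
    assert out.samples["sample_id"].tolist() == ["s1", "s2"]
    assert rep.samples_removed_callrate == 1


def test_snp_callrate_removal_counted(make_ds):
    d = np.ones((4, 10), dtype=np.int8)
    d[0, 3] = MISSING  # call rate 0.75 for marker m4
    ds = make_ds(d)
    out, rep = qc_filter(ds, min_ind_call=0.0, min_snp_call=0.99)
    assert rep.markers_removed_callrate == 1
    assert out.n_markers == 9
    assert "m4" not in out.markers["snp"].tolist()


def test_qc_identity_and_idempotence(small_panel):
    out, rep = qc_filter(small_panel, 0.0, 0.0, autosomes_only=False, drop_duplicates=False)
    assert out == small_panel
    assert rep.markers_removed_duplicate == rep.markers_removed_callrate == 0

    once, _ = qc_filter(small_panel)
    twice, rep2 = qc_filter(once)
    assert twice == once
    assert rep2.n_markers_retained == once.n_markers


def test_nonautosomes_dropped(make_ds):
    d = np.ones((3, 4), dtype=np.int8)
    ds = make_ds(d, chroms=["1", "1", "Z", "30"], positions=[100, 200, 100, 100])
    out, rep = qc_filter(ds, 0.0, 0.0)
    assert rep.markers_removed_nonautosomal == 2
    assert out.markers["chrom"].tolist() == ["1", "1"]


def test_qc_error_when_everything_removed(make_ds):
    d = np.full((2, 3), MISSING, dtype=np.int8)
    d[:, 0] = 1
    with pytest.raises(ValueError, match="empty"):
        qc_filter(make_ds(d), min_ind_call=0.99, min_snp_call=0.99)


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------
def test_duplicated_marker_pruned_once(make_ds):
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, size=50).astype(np.int8)
    other = rng.integers(0, 3, size=50).astype(np.int8)
    ds = make_ds(np.column_stack([col, col, other]))
    kept = ld_prune(ds, window_snps=3, step_snps=1, r2_threshold=0.2)
    assert ("m1" in kept) != ("m2" in kept)  # exactly one of the duplicates


def test_threshold_one_keeps_everything(small_panel):
    kept = ld_prune(small_panel, r2_threshold=1.0)
    assert kept == small_panel.markers["snp"].tolist()


def test_independent_markers_mostly_retained():
    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.5, size=(100, 60)).astype(np.int8)
        from conftest import build_dataset
        ds = build_dataset(d)
        kept = ld_prune(ds, window_snps=50, step_snps=5, r2_threshold=0.2)
        assert len(kept) >= 0.99 * 60


def test_prune_output_is_ordered_subset(small_panel):
    kept = ld_prune(small_panel)
    order = {m: i for i, m in enumerate(small_panel.markers["snp"])}
    idx = [order[m] for m in kept]
    assert idx == sorted(idx)
    assert set(kept) <= set(order)


def test_monomorphic_markers_never_pruned(make_ds):
    d = np.zeros((20, 3), dtype=np.int8)
    d[:, 1] = 2  # monomorphic at 2
    ds = make_ds(d)
    kept = ld_prune(ds, window_snps=3, step_snps=1, r2_threshold=0.0)
    assert kept == ["m1", "m2", "m3"]
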