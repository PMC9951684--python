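"""PLINK 1 text (PED/MAP) and binary (BED/BIM/FAM) readers and writers.

Dosages count copies of the *alternate* allele.  PED files do not name a
reference allele, so the alternate allele is fixed, deterministically, as
the lexicographically larger allele observed at the marker; the binary
reader applies the same rule to the two BIM alleles so both dialects decode
identically.  Breed labels travel in the family-ID column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, make_marker_map

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# writer allele letters: alt 'C' > ref 'A' lexicographically
_REF, _ALT = "A", "C"


def read_map(map_path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        f = line.split()
        if not f:
            continue
        if len(f) not in (3, 4):
            raise ValueError(f"{map_path}:{ln}: expected 3 or 4 MAP columns, got {len(f)}")
        rows.append((f[0], f[1], int(f[-1])))
    return pd.DataFrame(rows, columns=["chrom", "snp", "pos"])


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    ``0 0`` allele pairs (or half-missing calls) decode as MISSING.
    """
    raw_map = read_map(map_path)
    n_markers = len(raw_map)

    sample_ids, breeds = [], []
    allele_rows = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        f = line.split()
        if not f:
            continue
        if len(f) != 6 + 2 * n_markers:
            raise ValueError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_markers} fields "
                f"(6 + 2x{n_markers} markers), got {len(f)}"
            )
        breeds.append(f[0])
        sample_ids.append(f[1])
        allele_rows.append(f[6:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{ped_path}: duplicated sample id")

    n = len(sample_ids)
    a1 = np.empty((n, n_markers), dtype="U4")
    a2 = np.empty((n, n_markers), dtype="U4")
    for i, row in enumerate(allele_rows):
        a1[i] = row[0::2]
        a2[i] = row[1::2]

    dosages = np.full((n, n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        observed = sorted(set(c1[called]) | set(c2[called]))
        if not observed:
            continue
        if len(observed) > 2:
            raise ValueError(f"marker {raw_map['snp'].iat[j]}: more than two alleles {observed}")
        alt = observed[-1]  # lexicographically larger observed allele
        dosages[called, j] = (c1[called] == alt).astype(np.int8) + (c2[called] == alt).astype(np.int8)

    return _assemble(raw_map, sample_ids, breeds, dosages)


def _assemble(raw_map: pd.DataFrame, sample_ids, breeds, dosages) -> GenotypeDataset:
    """Sort markers by (chrom, pos) and permute dosage columns to match."""
    markers = make_marker_map(raw_map["chrom"], raw_map["snp"], raw_map["pos"], allow_duplicate_positions=True)
    order = raw_map.set_index("snp").index.get_indexer(markers["snp"])
    return GenotypeDataset(
        markers=markers,
        samples=pd.DataFrame({"sample_id": sample_ids, "breed": breeds}),
        dosages=dosages[:, order],
    )


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP with alleles A (reference) and C (alternate)."""
    with open(map_path, "w") as fh:
        for _, m in ds.markers.iterrows():
            fh.write(f"{m.chrom}\t{m.snp}\t0\t{m.pos}\n")
    pair = {0: f"{_REF} {_REF}", 1: f"{_REF} {_ALT}", 2: f"{_ALT} {_ALT}", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, s in ds.samples.iterrows():
            geno = " ".join(pair[int(x)] for x in ds.dosages[i])
            fh.write(f"{s.breed} {s.sample_id} 0 0 0 -9 {geno}\n")


# -- binary dialect ------------------------------------------------------

# 2-bit PLINK codes, sample-major within a byte (lowest bits first):
# 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2
_DECODE = np.zeros((256, 4), dtype=np.uint8)
for _byte in range(256):
    for _k in range(4):
        _DECODE[_byte, _k] = (_byte >> (2 * _k)) & 0b11


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset (SNP-major)."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str},
    )
    if fam["iid"].duplicated().any():
        raise ValueError(f"{fam_path}: duplicated sample id")
    n, L = len(fam), len(bim)
    blob = Path(bed_path).read_bytes()
    if blob[:2] != _MAGIC:
        raise ValueError(f"{bed_path}: bad magic bytes {blob[:2]!r}")
    if blob[2:3] != _SNP_MAJOR:
        raise ValueError(f"{bed_path}: not SNP-major mode")
    nb = (n + 3) // 4
    if len(blob) != 3 + L * nb:
        raise ValueError(f"{bed_path}: expected {3 + L * nb} bytes, found {len(blob)}")
    data = np.frombuffer(blob, dtype=np.uint8, offset=3).reshape(L, nb)
    codes = _DECODE[data].reshape(L, nb * 4)[:, :n]  # (markers, samples)

    dosages = np.empty((n, L), dtype=np.int8)
    # dosage of the lexicographically larger BIM allele
    a1_is_alt = (bim["a1"] >= bim["a2"]).to_numpy()
    hom_a1 = np.where(a1_is_alt, 2, 0).astype(np.int8)
    hom_a2 = np.where(a1_is_alt, 0, 2).astype(np.int8)
    for j in range(L):
        c = codes[j]
        col = np.full(n, MISSING, dtype=np.int8)
        col[c == 0b00] = hom_a1[j]
        col[c == 0b10] = 1
        col[c == 0b11] = hom_a2[j]
        dosages[:, j] = col

    raw_map = bim[["chrom", "snp", "pos"]].copy()
    return _assemble(raw_map, fam["iid"].tolist(), fam["fid"].tolist(), dosages)


def write_plink_binary(ds: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    """Write BED/BIM/FAM; A1 = alternate ('C'), A2 = reference ('A')."""
    with open(bim_path, "w") as fh:
        for _, m in ds.markers.iterrows():
            fh.write(f"{m.chrom}\t{m.snp}\t0\t{m.pos}\t{_ALT}\t{_REF}\n")
    with open(fam_path, "w") as fh:
        for _, s in ds.samples.iterrows():
            fh.write(f"{s.breed} {s.sample_id} 0 0 0 -9\n")

    n, L = ds.n_samples, ds.n_markers
    nb = (n + 3) // 4
    # A1 = alt: dosage 2 -> 00 (hom A1), 1 -> 10, 0 -> 11, missing -> 01
    code_of = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}
    lut = np.zeros(4, dtype=np.uint8)
    for d, c in code_of.items():
        lut[d % 4] = c  # MISSING=-1 -> index 3
    codes = lut[ds.dosages.T % 4]  # (markers, samples)
    padded = np.zeros((L, nb * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(L, nb, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())


def write_breed_table(ds: GenotypeDataset, path) -> None:
    ds.samples.to_csv(path, sep="\t", index=False)
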