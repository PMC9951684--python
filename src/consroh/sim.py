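"""Multi-breed SNP genotype simulator with known ground truth.

Breed allele frequencies follow the Balding–Nichols model: for a locus with
ancestral frequency ``p`` and a breed divergence parameter ``F``, the breed
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean ``p`` and variance
``F p (1-p)``.  The expected Nei minimum distance between two breeds with
parameters F_a, F_b is therefore (F_a + F_b) E[p(1-p)].

Autozygosity is a two-state (autozygous / outbred) mosaic along the genetic
map: tract lengths are exponential with mean ``100/(2g)`` cM for ``g``
generations of inbreeding depth, alternating with outbred tracts whose mean
is scaled so the stationary autozygous fraction equals the target ``froh``.
Inside an autozygous tract every genotype is homozygous, with the doubled
allele drawn from the breed frequency; elsewhere genotypes are
Hardy–Weinberg draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, make_marker_map


@dataclass
class SimConfig:
    """Parameters of one simulated multi-breed dataset.

    ``fst_per_breed`` and ``froh_per_breed`` are per-breed divergence and
    target autozygous genome fractions, both in [0, 1).  ``cm_per_mb``
    converts physical to genetic distance (3 cM/Mb is the genome-wide
    average for chicken).  ``inbreeding_generations`` (g) sets the mean
    autozygous tract length 100/(2g) cM.
    """

    n_breeds: int = 8
    breed_sizes: tuple[int, ...] = (18, 19, 20, 20, 20, 20, 20, 20)
    fst_per_breed: tuple[float, ...] = (0.14, 0.26, 0.22, 0.18, 0.16, 0.10, 0.15, 0.12)
    froh_per_breed: tuple[float, ...] = (0.114, 0.142, 0.121, 0.142, 0.030, 0.009, 0.137, 0.092)
    chrom_lengths_bp: tuple[int, ...] = (60_000_000, 50_000_000, 40_000_000, 35_000_000, 30_000_000, 25_000_000)
    n_snps: int = 30_000
    cm_per_mb: float = 3.0
    inbreeding_generations: float = 8.0
    missing_rate: float = 0.005
    maf_range: tuple[float, float] = (0.05, 0.95)
    # selection-signature emulation: (chrom, start_bp, end_bp, prob) regions
    # where each individual carries an autozygous tract with probability
    # prob, producing population-shared ROH islands; default five regions
    # with sharing between roughly a third and two thirds of the panel
    sweep_regions: tuple[tuple[str, int, int, float], ...] = (
        ("1", 20_000_000, 22_600_000, 0.45),
        ("2", 10_000_000, 13_000_000, 0.40),
        ("3", 5_000_000, 7_000_000, 0.70),
        ("4", 15_000_000, 17_700_000, 0.40),
        ("5", 8_000_000, 9_400_000, 0.35),
    )
    # optional finite founder-haplotype pool per breed: individuals copy
    # from K founder haplotypes with recombination-like switching every
    # ``switch_cm`` on average, creating distance-decaying LD whose
    # strength scales like 1/K (small pool = strong drift).  None keeps
    # the default model: independent Hardy-Weinberg draws per locus.
    n_founder_haplotypes: int | None = None
    switch_cm: float = 10.0
    breed_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 1:
            raise ValueError("need at least one breed")
        for name in ("breed_sizes", "fst_per_breed", "froh_per_breed"):
            vals = getattr(self, name)
            if len(vals) != self.n_breeds:
                raise ValueError(f"{name} must have n_breeds={self.n_breeds} entries")
        if any(n < 2 for n in self.breed_sizes):
            raise ValueError("breed_sizes must be >= 2")
        if any(not (0.0 <= f < 1.0) for f in self.fst_per_breed):
            raise ValueError("fst_per_breed must lie in [0, 1)")
        if any(not (0.0 <= f < 1.0) for f in self.froh_per_breed):
            raise ValueError("froh_per_breed must lie in [0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if any(L < 2_000_000 for L in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be >= 2 Mb")
        if self.n_snps < len(self.chrom_lengths_bp):
            raise ValueError("need at least one SNP per chromosome")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo < hi < 1")
        if self.inbreeding_generations <= 0:
            raise ValueError("inbreeding_generations must be positive")
        self.sweep_regions = tuple(tuple(r) for r in self.sweep_regions)
        for chrom, start, end, prob in self.sweep_regions:
            n_chrom = len(self.chrom_lengths_bp)
            if not (str(chrom).isdigit() and 1 <= int(chrom) <= n_chrom):
                raise ValueError(f"sweep region on unknown chromosome {chrom!r}")
            if not (1 <= start < end <= self.chrom_lengths_bp[int(chrom) - 1]):
                raise ValueError("sweep region out of chromosome bounds")
            if not (0.0 <= prob <= 1.0):
                raise ValueError("sweep probability must lie in [0, 1]")
        if self.n_founder_haplotypes is not None and self.n_founder_haplotypes < 2:
            raise ValueError("need >= 2 founder haplotypes")
        if self.switch_cm <= 0:
            raise ValueError("switch_cm must be positive")
        if self.breed_names is None:
            self.breed_names = tuple(f"breed{i + 1}" for i in range(self.n_breeds))
        elif len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length mismatch")


@dataclass
class SimTruth:
    """Ground truth recorded during simulation.

    ``tracts`` maps sample_id -> list of (chrom, start_bp, end_bp) autozygous
    tracts (1-based, inclusive, clipped to the chromosome).
    ``snp_autozygous`` is a boolean (samples x markers) matrix marking SNPs
    inside autozygous tracts. ``ancestral_freq`` and ``breed_freq`` are the
    simulated allele frequencies.
    """

    tracts: dict[str, list[tuple[str, int, int]]]
    snp_autozygous: np.ndarray = field(repr=False)
    ancestral_freq: np.ndarray = field(repr=False)
    breed_freq: pd.DataFrame = field(repr=False)

    def autozygous_genome_fraction(self, chrom_lengths: dict[str, int]) -> pd.Series:
        """Per-sample fraction of the genome inside true autozygous tracts."""
        total = float(sum(chrom_lengths.values()))
        out = {}
        for sid, tr in self.tracts.items():
            covered = 0
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, s, e in tr:
                by_chrom.setdefault(chrom, []).append((s, e))
            for ivs in by_chrom.values():  # merge overlaps (sweeps may overlap mosaic tracts)
                ivs.sort()
                cur_s, cur_e = ivs[0]
                for s, e in ivs[1:]:
                    if s <= cur_e + 1:
                        cur_e = max(cur_e, e)
                    else:
                        covered += cur_e - cur_s + 1
                        cur_s, cur_e = s, e
                covered += cur_e - cur_s + 1
            out[sid] = covered / total
        return pd.Series(out, name="froh_true")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Breed frequency draws; F = 0 degenerates to an exact copy of p."""
    if fst >= 1.0:
        raise ValueError("fst must be < 1")
    if fst == 0.0:
        return p.copy()
    lam = (1.0 - fst) / fst
    return rng.beta(p * lam, (1.0 - p) * lam)


def _copy_path(
    rng: np.random.Generator, cm_pos: np.ndarray, chrom_cm: float, k: int, switch_cm: float
) -> np.ndarray:
    """Founder index per SNP for one copying haplotype: the index switches
    at exponential(switch_cm) intervals along the genetic map."""
    bounds = []
    t = rng.exponential(switch_cm)
    while t < chrom_cm:
        bounds.append(t)
        t += rng.exponential(switch_cm)
    founder_per_seg = rng.integers(k, size=len(bounds) + 1)
    seg = np.searchsorted(np.asarray(bounds), cm_pos, side="right")
    return founder_per_seg[seg]


def _mosaic_tracts(
    rng: np.random.Generator, length_cm: float, froh: float, mean_auto_cm: float
) -> list[tuple[float, float]]:
    """Autozygous tract intervals (cM) on one chromosome.

    Alternating exponential segments with stationary autozygous fraction
    ``froh``; returns [] when froh == 0.
    """
    if froh <= 0.0:
        return []
    mean_out_cm = mean_auto_cm * (1.0 - froh) / froh
    tracts: list[tuple[float, float]] = []
    pos = 0.0
    auto = bool(rng.random() < froh)
    while pos < length_cm:
        mean = mean_auto_cm if auto else mean_out_cm
        seg = rng.exponential(mean)
        end = min(pos + seg, length_cm)
        if auto and end > pos:
            tracts.append((pos, end))
        pos = end
        auto = not auto
    return tracts


def simulate_dataset(cfg: SimConfig, return_truth: bool = False):
    """Simulate a multi-breed genotype dataset.

    Returns the :class:`GenotypeDataset`, or ``(dataset, SimTruth)`` when
    ``return_truth`` is set.  Identical config + seed gives bit-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    n_chrom = len(cfg.chrom_lengths_bp)
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=np.int64)

    # markers: proportional allocation, uniform positions, unique + sorted
    weights = lengths / lengths.sum()
    alloc = np.maximum(1, np.floor(cfg.n_snps * weights).astype(int))
    while alloc.sum() < cfg.n_snps:
        alloc[np.argmax(weights - alloc / cfg.n_snps)] += 1
    while alloc.sum() > cfg.n_snps:
        alloc[np.argmax(alloc)] -= 1
    chroms, positions = [], []
    for c in range(n_chrom):
        want = alloc[c]
        pos = np.unique(rng.integers(1, lengths[c] + 1, size=want))
        while len(pos) < want:  # re-draw collisions (rare)
            extra = rng.integers(1, lengths[c] + 1, size=want - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([str(c + 1)] * want)
        positions.append(np.sort(pos[:want]))
    positions = np.concatenate(positions)
    ids = [f"snp{c}_{p}" for c, p in zip(chroms, positions)]
    markers = make_marker_map(chroms, ids, positions)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    L = len(markers)

    # ancestral and breed frequencies
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=L)
    breed_freq = np.vstack(
        [_balding_nichols(rng, p_anc, f) for f in cfg.fst_per_breed]
    )

    chrom_len_map = {str(c + 1): int(lengths[c]) for c in range(n_chrom)}
    mean_auto_cm = 100.0 / (2.0 * cfg.inbreeding_generations)
    cm_per_bp = cfg.cm_per_mb / 1e6

    sample_ids, breed_labels = [], []
    dosage_rows = []
    tracts_by_sample: dict[str, list[tuple[str, int, int]]] = {}
    auto_mask_rows = []
    chrom_slices = {}
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_arr == str(c + 1))
        chrom_slices[str(c + 1)] = idx

    for b in range(cfg.n_breeds):
        pb = breed_freq[b]
        froh = cfg.froh_per_breed[b]
        founders = None
        if cfg.n_founder_haplotypes is not None:
            founders = {
                name: rng.random((cfg.n_founder_haplotypes, len(idx))) < pb[idx]
                for name, idx in chrom_slices.items()
            }
        for i in range(cfg.breed_sizes[b]):
            sid = f"{cfg.breed_names[b]}_{i + 1:03d}"
            sample_ids.append(sid)
            breed_labels.append(cfg.breed_names[b])
            auto = np.zeros(L, dtype=bool)
            tr_list: list[tuple[str, int, int]] = []

            def _add_tract(name: str, s_bp: int, e_bp: int) -> None:
                tr_list.append((name, s_bp, e_bp))
                idx = chrom_slices[name]
                sub = pos_arr[idx]
                lo = np.searchsorted(sub, s_bp, side="left")
                hi = np.searchsorted(sub, e_bp, side="right")
                auto[idx[lo:hi]] = True

            for c in range(n_chrom):
                name = str(c + 1)
                clen_cm = chrom_len_map[name] * cm_per_bp
                for s_cm, e_cm in _mosaic_tracts(rng, clen_cm, froh, mean_auto_cm):
                    s_bp = max(1, int(np.floor(s_cm / cm_per_bp)) + 1)
                    e_bp = min(chrom_len_map[name], int(np.ceil(e_cm / cm_per_bp)))
                    if e_bp >= s_bp:
                        _add_tract(name, s_bp, e_bp)
            for chrom_s, s_bp, e_bp, prob in cfg.sweep_regions:
                if rng.random() < prob:
                    _add_tract(str(chrom_s), int(s_bp), int(e_bp))
            tracts_by_sample[sid] = tr_list
            auto_mask_rows.append(auto)
            if founders is None:
                # genotypes: HW outside tracts, doubled draw inside
                g = rng.binomial(2, pb).astype(np.int8)
                if auto.any():
                    hom = (rng.random(int(auto.sum())) < pb[auto]).astype(np.int8) * 2
                    g[auto] = hom
            else:
                g = np.empty(L, dtype=np.int8)
                for name, idx in chrom_slices.items():
                    cm_pos = pos_arr[idx] * cm_per_bp
                    chrom_cm = chrom_len_map[name] * cm_per_bp
                    k = cfg.n_founder_haplotypes
                    p1 = _copy_path(rng, cm_pos, chrom_cm, k, cfg.switch_cm)
                    p2 = _copy_path(rng, cm_pos, chrom_cm, k, cfg.switch_cm)
                    cols = np.arange(len(idx))
                    h1 = founders[name][p1, cols].astype(np.int8)
                    h2 = founders[name][p2, cols].astype(np.int8)
                    gi = h1 + h2
                    a = auto[idx]
                    gi[a] = 2 * h1[a]  # doubled copy keeps founder LD in ROH
                    g[idx] = gi
            dosage_rows.append(g)

    dosages = np.vstack(dosage_rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    ds = GenotypeDataset(
        markers=markers,
        samples=pd.DataFrame({"sample_id": sample_ids, "breed": breed_labels}),
        dosages=dosages,
    )
    if not return_truth:
        return ds
    truth = SimTruth(
        tracts=tracts_by_sample,
        snp_autozygous=np.vstack(auto_mask_rows),
        ancestral_freq=p_anc,
        breed_freq=pd.DataFrame(
            breed_freq, index=pd.Index(cfg.breed_names, name="breed"), columns=markers["snp"]
        ),
    )
    return ds, truth


def simulate_annotation(
    cfg: SimConfig,
    n_genes: int,
    n_qtl: int,
    trait_classes: tuple[str, ...] = ("meat", "egg", "fat", "immunity", "other"),
    mean_length_bp: int = 200_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random gene/QTL interval fixture matching the simulated genome.

    Intervals are 0-based half-open, non-degenerate and clipped to the
    chromosome; each QTL carries one trait class drawn uniformly.
    Deterministic under ``seed`` (defaults to ``cfg.seed + 1``).
    """
    if n_genes < 0 or n_qtl < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=np.int64)
    weights = lengths / lengths.sum()
    records = []
    for kind, count in (("gene", n_genes), ("qtl", n_qtl)):
        for i in range(count):
            c = rng.choice(len(lengths), p=weights)
            span = max(1, int(rng.exponential(mean_length_bp)))
            span = min(span, int(lengths[c]) - 1)
            start = int(rng.integers(0, lengths[c] - span))
            cls = str(rng.choice(trait_classes)) if kind == "qtl" else ""
            records.append(
                {
                    "chrom": str(c + 1),
                    "start": start,
                    "end": start + span,
                    "name": f"{kind}{i + 1}",
                    "kind": kind,
                    "trait_class": cls,
                }
            )
    cols = ["chrom", "start", "end", "name", "kind", "trait_class"]
    return pd.DataFrame(records, columns=cols)
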