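"""End-to-end pipeline: simulate/load -> QC -> prune -> diversity ->
priority -> ROH -> islands -> annotate -> LD -> Ne, with one global seed.

The run configuration is a nested mapping validated strictly (unknown keys
are rejected) and serialized verbatim into the output directory.  The
global seed fans out to per-stage seeds through ``numpy``'s SeedSequence
spawning, keyed by a fixed stage order, so toggling one stage never shifts
the randomness of another.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import classify_traits, load_annotation, overlap, validate_annotation
from .dataset import GenotypeDataset
from .diversity import (
    allelic_diversity_partition,
    breed_diversity_indices,
    coancestry,
    gene_diversity_partition,
    nei_minimum_distance,
    private_alleles,
)
from .io_plink import (
    read_plink_binary,
    read_plink_text,
    write_breed_table,
    write_plink_text,
)
from .ldne import decay_curve, ne_trajectory, pairwise_r2
from .priority import leave_one_out, optimize_pool
from .qc import ld_prune, qc_filter
from .roh import (
    ROHParams,
    aggregate_breed_roh,
    call_islands,
    detect_roh,
    snp_incidence,
    summarize_roh,
)
from .sim import SimConfig, simulate_annotation, simulate_dataset

log = logging.getLogger("consroh")

_STAGE_ORDER = (
    "simulate", "qc", "prune", "diversity", "priority",
    "roh", "islands", "annotate", "ld", "ne",
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "consroh_run",
    "stages": {name: True for name in _STAGE_ORDER},
    "inputs": {"ped": None, "map": None, "bed": None, "bim": None, "fam": None},
    "sim": {},  # SimConfig field overrides
    "qc": {
        "min_ind_call": 0.95,
        "min_snp_call": 0.99,
        "autosomes_only": True,
        "drop_duplicates": True,
    },
    "prune": {"window_snps": 50, "step_snps": 5, "r2_threshold": 0.2},
    "roh": {
        "min_length_bp": 1_000_000,
        "min_snps": 100,
        "max_het": 1,
        "max_missing": 2,
        "min_density_snp_per_kb": 0.01,
        "max_gap_bp": 1_000_000,
    },
    "islands": {"threshold": 0.30, "min_island_snps": 50},
    "pool": {"N": 1000, "objectives": ["H", "K"], "restarts": 10, "sa_steps": 2000},
    "annotation": {"path": None, "class_map": None, "n_genes": 300, "n_qtl": 200},
    "ld": {
        "breeds": None,
        "max_dist_kb": 2000,
        "width_near": 500,
        "width_far": 1100,
        "breakpoint": 2000,
        "max_pairs_per_breed": 200_000,
    },
    "ne": {"cm_per_mb": 3.0, "epsilon": 1e-6},
}


def _merge_strict(base: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in base and path != "sim":
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base.get(key), dict) and isinstance(val, dict):
            out[key] = _merge_strict(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


class RunConfig:
    """Validated pipeline configuration (strict keys, YAML round-trip)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge_strict(DEFAULT_CONFIG, overrides or {})
        bad = set(self.data["sim"]) - set(SimConfig.__dataclass_fields__)
        if bad:
            raise KeyError(f"unknown sim config keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def hash(self) -> str:
        # identifies the scientific configuration; the output location is
        # excluded so identical analyses hash identically
        payload = {k: v for k, v in self.data.items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def __getitem__(self, key):
        return self.data[key]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_ORDER))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_ORDER, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# consroh {__version__} stage={stage} seed={cfg['seed']} "
            f"config={cfg.hash()}\n"
        )
        df.to_csv(fh, sep="\t", index=index)


def _load_inputs(cfg: RunConfig) -> GenotypeDataset:
    inp = cfg["inputs"]
    if inp["ped"] and inp["map"]:
        return read_plink_text(inp["ped"], inp["map"])
    if inp["bed"] and inp["bim"] and inp["fam"]:
        return read_plink_binary(inp["bed"], inp["bim"], inp["fam"])
    raise ValueError("simulate stage disabled and no PED/MAP or BED/BIM/FAM inputs given")


def run_pipeline(cfg: RunConfig, write_genotypes: bool = False) -> dict:
    """Run the enabled stages in fixed order; returns a result bundle dict
    and writes TSV outputs plus a text summary to the output directory."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(cfg["seed"])
    on = cfg["stages"]
    results: dict = {"config_hash": cfg.hash()}
    summary_lines = [f"consroh {__version__} run, seed {cfg['seed']}, config {cfg.hash()}"]

    def stage(name):
        def deco(fn):
            if not on.get(name, False):
                log.info("stage %s skipped", name)
                summary_lines.append(f"[{name}] skipped")
                return None
            log.info("stage %s started", name)
            try:
                return fn()
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # -- simulate / load -------------------------------------------------
    @stage("simulate")
    def _sim():
        sim_cfg = SimConfig(**{**cfg["sim"], "seed": cfg["sim"].get("seed", seeds["simulate"])})
        ds = simulate_dataset(sim_cfg)
        write_breed_table(ds, outdir / "breeds.tsv")
        if write_genotypes:
            write_plink_text(ds, outdir / "sim.ped", outdir / "sim.map")
        summary_lines.append(
            f"[simulate] {ds.n_samples} samples / {len(ds.breeds)} breeds / {ds.n_markers} SNPs"
        )
        return ds, sim_cfg

    if _sim is not None:
        ds, sim_cfg = _sim
    else:
        ds, sim_cfg = _load_inputs(cfg), None
    results["dataset"] = ds

    # -- qc ---------------------------------------------------------------
    @stage("qc")
    def _qc():
        filtered, rep = qc_filter(ds, **cfg["qc"])
        _write_tsv(rep.to_frame(), outdir / "qc_report.tsv", cfg, "qc", index=False)
        summary_lines.append(
            f"[qc] retained {rep.n_samples_retained} samples, {rep.n_markers_retained} SNPs"
        )
        return filtered
    if _qc is not None:
        ds = _qc
        results["dataset"] = ds

    # -- prune ------------------------------------------------------------
    @stage("prune")
    def _prune():
        kept = ld_prune(ds, **cfg["prune"])
        removed = sorted(set(ds.markers["snp"]) - set(kept))
        pd.Series(removed, name="snp").to_csv(outdir / "pruned_out_markers.tsv", sep="\t", index=False)
        summary_lines.append(f"[prune] {len(kept)} of {ds.n_markers} SNPs retained")
        return kept
    results["pruned_markers"] = _prune

    # -- diversity --------------------------------------------------------
    @stage("diversity")
    def _div():
        co = coancestry(ds)
        gp = gene_diversity_partition(co)
        ap = allelic_diversity_partition(ds)
        nei = nei_minimum_distance(ds)
        idx = breed_diversity_indices(co)
        priv = private_alleles(ds)
        _write_tsv(nei, outdir / "nei_distance.tsv", cfg, "diversity")
        _write_tsv(idx, outdir / "breed_indices.tsv", cfg, "diversity")
        _write_tsv(priv.to_frame(), outdir / "private_alleles.tsv", cfg, "diversity")
        part = pd.DataFrame(
            {"value": {"HS": gp.HS, "DG": gp.DG, "HT": gp.HT, "AS": ap.AS, "DA": ap.DA, "AT": ap.AT}}
        )
        _write_tsv(part, outdir / "diversity_partition.tsv", cfg, "diversity")
        summary_lines.append(
            f"[diversity] HT={gp.HT:.4f} (HS={gp.HS:.4f} DG={gp.DG:.4f}) "
            f"AT={ap.AT:.4f} (AS={ap.AS:.4f} DA={ap.DA:.4f})"
        )
        return {"coancestry": co, "gene": gp, "allelic": ap, "nei": nei, "indices": idx, "private": priv}
    results["diversity"] = _div

    # -- priority ---------------------------------------------------------
    @stage("priority")
    def _prio():
        contrib = leave_one_out(ds)
        _write_tsv(contrib, outdir / "contributions.tsv", cfg, "priority")
        pools = {}
        for kind in cfg["pool"]["objectives"]:
            sol = optimize_pool(
                ds, N=cfg["pool"]["N"], objective=kind, seed=seeds["priority"],
                restarts=cfg["pool"]["restarts"], sa_steps=cfg["pool"]["sa_steps"],
            )
            pools[kind] = sol
            _write_tsv(sol.to_frame(), outdir / f"pool_{kind}.tsv", cfg, "priority")
            summary_lines.append(
                f"[priority] pool {kind}: value={sol.value:.4f} "
                f"top={sol.proportions.idxmax()} ({sol.proportions.max():.1%})"
            )
        top = contrib["dHT_pct"].idxmax()
        summary_lines.append(f"[priority] largest gene-diversity loss on removal: {top}")
        return {"contributions": contrib, "pools": pools}
    results["priority"] = _prio

    # -- roh --------------------------------------------------------------
    @stage("roh")
    def _roh():
        params = ROHParams(**cfg["roh"])
        segments = detect_roh(ds, params)
        _write_tsv(segments, outdir / "roh_segments.tsv", cfg, "roh", index=False)
        summ = summarize_roh(segments, ds.samples)
        _write_tsv(summ, outdir / "roh_summary.tsv", cfg, "roh")
        agg = aggregate_breed_roh(summ)
        summary_lines.append(
            f"[roh] {int(agg['total_nroh'])} segments; per-breed NROH "
            f"{int(agg['min_nroh'])}-{int(agg['max_nroh'])}"
        )
        return {"segments": segments, "summary": summ, "aggregate": agg, "params": params}
    results["roh"] = _roh

    # -- islands ----------------------------------------------------------
    @stage("islands")
    def _isl():
        if results.get("roh") is None:
            raise ValueError("islands stage needs the roh stage")
        inc = snp_incidence(results["roh"]["segments"], ds)
        islands, n_short = call_islands(
            inc, ds.markers, threshold=cfg["islands"]["threshold"],
            min_island_snps=cfg["islands"]["min_island_snps"],
        )
        _write_tsv(islands, outdir / "roh_islands.tsv", cfg, "islands", index=False)
        bed = islands.assign(start0=islands["start_bp"] - 1)[["chrom", "start0", "end_bp"]]
        bed.to_csv(outdir / "roh_islands.bed", sep="\t", header=False, index=False)
        summary_lines.append(f"[islands] {len(islands)} islands ({n_short} short runs discarded)")
        return {"incidence": inc, "islands": islands, "n_short": n_short}
    results["islands"] = _isl

    # -- annotate ---------------------------------------------------------
    @stage("annotate")
    def _ann():
        if results.get("islands") is None:
            raise ValueError("annotate stage needs the islands stage")
        ann_cfg = cfg["annotation"]
        if ann_cfg["path"]:
            table = load_annotation(ann_cfg["path"])
        elif sim_cfg is not None:
            table = simulate_annotation(
                sim_cfg, n_genes=ann_cfg["n_genes"], n_qtl=ann_cfg["n_qtl"],
                seed=seeds["annotate"],
            )
        else:
            raise ValueError("no annotation table available")
        rep = overlap(results["islands"]["islands"], table)
        classes = classify_traits(rep, ann_cfg["class_map"])
        _write_tsv(rep.per_island, outdir / "island_annotation.tsv", cfg, "annotate", index=False)
        _write_tsv(classes, outdir / "trait_classes.tsv", cfg, "annotate", index=False)
        summary_lines.append(
            f"[annotate] {int(rep.per_island['n_genes'].sum())} gene and "
            f"{int(rep.per_island['n_qtl'].sum())} QTL overlaps"
        )
        return {"report": rep, "classes": classes}
    results["annotate"] = _ann

    # -- ld / ne ----------------------------------------------------------
    @stage("ld")
    def _ld():
        breeds = cfg["ld"]["breeds"] or ds.breeds
        curves = {}
        for breed in breeds:
            pairs, n_bad = pairwise_r2(
                ds, breed=breed, max_dist_bp=cfg["ld"]["max_dist_kb"] * 1000,
                max_pairs=cfg["ld"]["max_pairs_per_breed"], seed=seeds["ld"],
            )
            curve = decay_curve(
                pairs, width_near=cfg["ld"]["width_near"],
                width_far=cfg["ld"]["width_far"], breakpoint=cfg["ld"]["breakpoint"],
            )
            curves[breed] = curve
            _write_tsv(curve.bins, outdir / f"ld_decay_{breed}.tsv", cfg, "ld", index=False)
        summary_lines.append(f"[ld] decay curves for {len(curves)} breeds")
        return curves
    results["ld"] = _ld

    @stage("ne")
    def _ne():
        if results.get("ld") is None:
            raise ValueError("ne stage needs the ld stage")
        sizes = ds.samples["breed"].value_counts()
        traj = {}
        for breed, curve in results["ld"].items():
            t = ne_trajectory(
                curve, n_samples=int(sizes[breed]),
                cm_per_mb=cfg["ne"]["cm_per_mb"], epsilon=cfg["ne"]["epsilon"],
            )
            traj[breed] = t
            _write_tsv(t, outdir / f"ne_trajectory_{breed}.tsv", cfg, "ne", index=False)
        summary_lines.append(f"[ne] trajectories for {len(traj)} breeds")
        return traj
    results["ne"] = _ne

    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    log.removeHandler(handler)
    handler.close()
    return results
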