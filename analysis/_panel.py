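"""Shared eight-breed panel definition for the numbered analysis scripts.

The panel emulates a 157-bird, eight-breed indigenous chicken SNP-array
study: per-breed divergence (pairwise Nei distances ~0.03-0.10), per-breed
autozygosity spanning a ~15-fold range, five swept regions that surface as
population ROH islands, and sporadic missing calls.  All scripts share one
seed so every stage sees the same genotypes.
"""

from pathlib import Path

from consroh.qc import qc_filter
from consroh.sim import SimConfig, simulate_dataset

SEED = 1
N_SNPS = 20_000

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

BREED_NAMES = (
    "Baihe", "Cholu", "Fengma", "Guxiang", "Lanshou", "Wanhu", "Wulong", "Xiangshan",
)  # synthetic breeds; sizes and diversity profiles emulate the real panel


def panel_config(seed: int = SEED, n_snps: int = N_SNPS) -> SimConfig:
    return SimConfig(seed=seed, n_snps=n_snps, breed_names=BREED_NAMES)


def simulate_panel(seed: int = SEED, n_snps: int = N_SNPS):
    return simulate_dataset(panel_config(seed, n_snps))


def load_qc_panel(seed: int = SEED, n_snps: int = N_SNPS):
    """The panel after the standard QC filters (call rates 95%/99%)."""
    ds, report = qc_filter(simulate_panel(seed, n_snps))
    return ds, report
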