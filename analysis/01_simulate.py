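"""Simulate the eight-breed panel and export it in PLINK dialects.

Writes the genotypes to scratch/ (they are large and regenerable from the
seed) and a small panel summary to results/.
"""

import pandas as pd

from _panel import RESULTS, SCRATCH, panel_config, simulate_panel
from consroh.io_plink import write_breed_table, write_plink_binary, write_plink_text

ds = simulate_panel()
cfg = panel_config()

RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)
write_plink_text(ds, SCRATCH / "panel.ped", SCRATCH / "panel.map")
write_plink_binary(ds, SCRATCH / "panel.bed", SCRATCH / "panel.bim", SCRATCH / "panel.fam")
write_breed_table(ds, RESULTS / "panel_breeds.tsv")

summary = pd.DataFrame(
    {
        "breed": ds.breeds,
        "n": [int((ds.samples["breed"] == b).sum()) for b in ds.breeds],
        "fst": cfg.fst_per_breed,
        "froh_target": cfg.froh_per_breed,
    }
)
summary.to_csv(RESULTS / "panel_summary.tsv", sep="\t", index=False)

print(f"simulated {ds.n_samples} birds / {len(ds.breeds)} breeds / {ds.n_markers} SNPs")
print(f"genome: {len(cfg.chrom_lengths_bp)} autosomes, {sum(cfg.chrom_lengths_bp)/1e6:.0f} Mb")
print(f"missing call rate {(ds.dosages == -1).mean():.4f}")
print(summary.to_string(index=False))
print(f"PED/MAP + BED/BIM/FAM in {SCRATCH}, summary tables in {RESULTS}")
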