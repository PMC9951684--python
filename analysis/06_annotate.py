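"""Overlap the ROH islands with a simulated gene/QTL annotation and tally
QTL trait classes.  Run 05_roh_islands.py first."""

import pandas as pd

from _panel import RESULTS, SEED, panel_config
from consroh.annotate import aggregate_island_annotation, classify_traits, overlap
from consroh.sim import simulate_annotation

islands = pd.read_csv(RESULTS / "roh_islands.tsv", sep="\t", dtype={"chrom": str})
table = simulate_annotation(panel_config(), n_genes=300, n_qtl=200, seed=SEED + 1000)
table.to_csv(RESULTS / "annotation_table.tsv", sep="\t", index=False)

report = overlap(islands, table)
report.per_island.to_csv(RESULTS / "island_annotation.tsv", sep="\t", index=False)
classes = classify_traits(report)
classes.to_csv(RESULTS / "trait_classes.tsv", sep="\t", index=False)

agg = aggregate_island_annotation(report.per_island)
print("per-island gene/QTL overlaps:")
print(report.per_island.to_string(index=False))
print(f"totals: {int(agg['total_genes'])} genes and {int(agg['total_qtl'])} QTLs "
      f"across {int(agg['n_islands'])} islands spanning {agg['total_span_mb']:.2f} Mb")
if len(classes):
    print("QTL trait classes:")
    print(classes.to_string(index=False))
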