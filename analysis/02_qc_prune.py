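"""Apply the standard QC filters and windowed LD pruning to the panel.

QC: duplicate markers -> non-autosomes -> individual call rate >= 95% ->
SNP call rate >= 99%.  Pruning: 50-SNP windows, step 5, r2 > 0.2.
"""

import pandas as pd

from _panel import RESULTS, load_qc_panel
from consroh.qc import ld_prune

ds, report = load_qc_panel()
report.to_frame().to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)
print("QC stage counts:")
print(report.to_frame().to_string(index=False))

kept = ld_prune(ds)
removed = sorted(set(ds.markers["snp"]) - set(kept))
pd.Series(removed, name="snp").to_csv(RESULTS / "pruned_out_markers.tsv", sep="\t", index=False)
print(
    f"LD pruning retained {len(kept)} of {ds.n_markers} SNPs "
    f"({100 * len(kept) / ds.n_markers:.1f}%); independent-marker panels keep "
    "nearly everything because the generator draws loci independently"
)
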