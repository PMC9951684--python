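"""Conservation priority: leave-one-out contributions to gene and allelic
diversity, and the optimal breed composition of an N = 1000 synthetic pool
under both objectives (H = expected heterozygosity, K = allele count)."""

from _panel import RESULTS, SEED, load_qc_panel
from consroh.priority import leave_one_out, optimize_pool

ds, _ = load_qc_panel()

contrib = leave_one_out(ds)
contrib.round(3).to_csv(RESULTS / "contributions.tsv", sep="\t")
print("leave-one-out contributions (% of full-panel value lost on removal):")
print(contrib.round(3).to_string())
print(f"top gene-diversity breed: {contrib['dHT_pct'].idxmax()}; "
      f"top allelic-diversity breed: {contrib['dAT_pct'].idxmax()}")

for kind in ("H", "K"):
    sol = optimize_pool(ds, N=1000, objective=kind, seed=SEED)
    sol.to_frame().to_csv(RESULTS / f"pool_{kind}.tsv", sep="\t")
    top = sol.proportions.sort_values(ascending=False)
    print(f"pool objective {kind}: optimum {sol.value:.4f} over {sol.n_loci_used} loci; "
          f"top contributors: "
          + ", ".join(f"{b} {p:.1%}" for b, p in top.head(3).items()))
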