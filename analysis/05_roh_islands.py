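"""Runs of homozygosity: per-individual detection (1 Mb / 100 SNPs / 1 het /
2 missing / 0.01 SNP-per-kb / 1 Mb gap), per-breed summaries, and the
>30%-incidence ROH islands."""

from _panel import RESULTS, load_qc_panel
from consroh.roh import (
    ROHParams,
    aggregate_breed_roh,
    call_islands,
    detect_roh,
    snp_incidence,
    summarize_roh,
)

ds, _ = load_qc_panel()
segments = detect_roh(ds, ROHParams())
segments.to_csv(RESULTS / "roh_segments.tsv", sep="\t", index=False)

summary = summarize_roh(segments, ds.samples)
summary.round(3).to_csv(RESULTS / "roh_summary.tsv", sep="\t")
agg = aggregate_breed_roh(summary)
print("per-breed ROH summary (SROH Mb / NROH / MNROH Mb):")
print(summary.round(3).to_string())
print(f"panel: {int(agg['total_nroh'])} segments, total {agg['total_sroh_mb']:.1f} Mb; "
      f"per-breed NROH range {int(agg['min_nroh'])}-{int(agg['max_nroh'])}; "
      f"longest segment {segments['length_bp'].max() / 1e6:.2f} Mb")

incidence = snp_incidence(segments, ds)
islands, n_short = call_islands(incidence, ds.markers, threshold=0.30, min_island_snps=50)
islands.round(3).to_csv(RESULTS / "roh_islands.tsv", sep="\t", index=False)
bed = islands.assign(start0=islands["start_bp"] - 1)[["chrom", "start0", "end_bp"]]
bed.to_csv(RESULTS / "roh_islands.bed", sep="\t", header=False, index=False)
print(f"{len(islands)} ROH islands (> 30% of the {ds.n_samples} birds; "
      f"{n_short} short runs discarded):")
print(islands.round(3).to_string(index=False))
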