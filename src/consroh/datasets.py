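"""Published summary tables for the eight-breed Chinese indigenous chicken
panel (157 birds, high-density SNP array).

These are *inputs* to the report-aggregation paths: the per-breed ROH
summary (SROH = total ROH length, NROH = ROH count, MNROH = mean ROH
length) and the five ROH islands with their gene/QTL annotation counts.
They let the aggregation code be exercised against published panel-level
statistics without access to the underlying genotypes.
"""

from __future__ import annotations

import pandas as pd


def chicken8_roh_summary() -> pd.DataFrame:
    """Per-breed ROH summary of the eight-breed chicken panel."""
    rows = [
        # breed, n_samples, sroh_mb, nroh, mnroh_mb, sd_mb
        ("Baier", 18, 1977.998, 686, 2.845, 0.645),
        ("Chahua", 19, 2698.555, 837, 3.227, 0.405),
        ("Fighting", 20, 2328.759, 975, 2.353, 0.401),
        ("Gushi", 20, 2745.876, 886, 3.006, 0.643),
        ("Langshan", 20, 571.271, 296, 1.921, 0.303),
        ("WanTy", 20, 181.114, 91, 2.010, 0.692),
        ("Wugu", 20, 2645.142, 917, 2.885, 0.576),
        ("Xiaoshan", 20, 1775.372, 554, 2.989, 0.724),
    ]
    return pd.DataFrame(
        rows, columns=["breed", "n_samples", "sroh_mb", "nroh", "mnroh_mb", "sd_mb"]
    ).set_index("breed")


def chicken8_roh_islands() -> pd.DataFrame:
    """The five published ROH islands with annotation counts."""
    rows = [
        # chrom, n_snps, start_bp, end_bp, n_genes, n_qtl
        ("1", 469, 73_276_840, 75_884_166, 18, 55),
        ("2", 671, 51_100_728, 54_046_793, 13, 30),
        ("5", 400, 1_912_343, 3_909_043, 18, 16),
        ("8", 638, 8_946_537, 11_679_072, 11, 54),
        ("11", 343, 2_365_463, 3_771_468, 20, 55),
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "n_snps", "start_bp", "end_bp", "n_genes", "n_qtl"]
    )
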