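"""Overlap of ROH islands with gene/QTL interval tables and trait tallies.

Annotation tables are BED-like: 0-based half-open intervals with columns
chrom, start, end, name, kind ("gene" or "qtl") and trait_class.  Islands
arrive in the 1-based inclusive SNP coordinates produced by the ROH module
and are converted to half-open internally, so an annotation record abutting
an island end-to-start does not count as overlapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

ANNOTATION_COLUMNS = ["chrom", "start", "end", "name", "kind", "trait_class"]


def load_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["trait_class"] = df["trait_class"].fillna("")
    if (df["start"] >= df["end"]).any():
        raise ValueError("annotation intervals must satisfy start < end (0-based half-open)")
    if (df["start"] < 0).any():
        raise ValueError("annotation starts must be >= 0")
    if not df["kind"].isin(["gene", "qtl"]).all():
        raise ValueError("kind must be 'gene' or 'qtl'")
    return df


@dataclass
class OverlapReport:
    """Per-island overlap counts plus the full island x record match list."""

    per_island: pd.DataFrame
    matches: pd.DataFrame = field(repr=False)
    excluded_chroms: list[str] = field(default_factory=list)
    min_overlap_bp: int = 1


def overlap(islands: pd.DataFrame, table: pd.DataFrame, min_overlap_bp: int = 1) -> OverlapReport:
    """Count annotation records intersecting each island by >= min_overlap_bp.

    ``islands`` uses 1-based inclusive start_bp/end_bp; ``table`` is a
    validated annotation table.  Records on chromosomes absent from the
    island set's chromosome vocabulary are excluded with a warning.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    table = validate_annotation(table)
    known = set(islands["chrom"].astype(str))
    unknown = sorted(set(table["chrom"]) - known)
    if unknown:
        warnings.warn(f"annotation chromosomes not in island set, excluded: {unknown}")
        table = table[table["chrom"].isin(known)]

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in table.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), r.Index) for r in sub.itertuples()
        )

    island_rows, match_rows = [], []
    for i, isl in enumerate(islands.itertuples()):
        s0, e0 = int(isl.start_bp) - 1, int(isl.end_bp)  # to 0-based half-open
        hits = trees.get(str(isl.chrom), IntervalTree()).overlap(s0, e0)
        n_gene = n_qtl = 0
        for hit in sorted(hits):
            ov = min(hit.end, e0) - max(hit.begin, s0)
            if ov < min_overlap_bp:
                continue
            rec = table.loc[hit.data]
            if rec["kind"] == "gene":
                n_gene += 1
            else:
                n_qtl += 1
            match_rows.append(
                {
                    "island": i,
                    "chrom": str(isl.chrom),
                    "record": rec["name"],
                    "kind": rec["kind"],
                    "trait_class": rec["trait_class"],
                    "overlap_bp": int(ov),
                }
            )
        island_rows.append(
            {
                "island": i,
                "chrom": str(isl.chrom),
                "start_bp": int(isl.start_bp),
                "end_bp": int(isl.end_bp),
                "n_genes": n_gene,
                "n_qtl": n_qtl,
            }
        )
    return OverlapReport(
        per_island=pd.DataFrame(
            island_rows, columns=["island", "chrom", "start_bp", "end_bp", "n_genes", "n_qtl"]
        ),
        matches=pd.DataFrame(
            match_rows,
            columns=["island", "chrom", "record", "kind", "trait_class", "overlap_bp"],
        ),
        excluded_chroms=unknown,
        min_overlap_bp=min_overlap_bp,
    )


def classify_traits(report: OverlapReport, class_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Trait-class percentages over the distinct QTL records hit by islands.

    ``class_map`` routes trait labels to classes; unmapped labels fall into
    "other" with a warning.  Percentages are rounded to 2 decimals and sum
    to 100 over classified QTLs (an empty report gives an empty table).
    """
    qtl = report.matches[report.matches["kind"] == "qtl"]
    qtl = qtl.drop_duplicates(subset=["record"])
    if len(qtl) == 0:
        return pd.DataFrame(columns=["trait_class", "count", "pct"])
    labels = qtl["trait_class"].tolist()
    if class_map is not None:
        unmapped = sorted({t for t in labels if t not in class_map})
        if unmapped:
            warnings.warn(f"trait labels without a class, routed to 'other': {unmapped}")
        labels = [class_map.get(t, "other") for t in labels]
    counts = pd.Series(labels).value_counts()
    out = counts.rename_axis("trait_class").reset_index(name="count")
    out["pct"] = (100.0 * out["count"] / out["count"].sum()).round(2)
    return out


def aggregate_island_annotation(per_island: pd.DataFrame) -> dict[str, float]:
    """Panel totals for an island annotation table (gene/QTL counts, span)."""
    return {
        "n_islands": float(len(per_island)),
        "total_genes": float(per_island["n_genes"].sum()),
        "total_qtl": float(per_island["n_qtl"].sum()),
        "total_span_mb": float(
            ((per_island["end_bp"] - per_island["start_bp"] + 1) / 1e6).sum()
        ),
    }
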