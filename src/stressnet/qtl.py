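"""Gene-to-QTL mapping by strict interval containment.

A gene maps to a quantitative trait locus only when its genomic span is
entirely inside the QTL interval (same chromosome, QTL start <= gene
start and gene end <= QTL end, endpoint equality allowed).  All
coordinates are normalized to 0-based half-open at load time; strand is
ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd


class IntervalError(ValueError):
    pass


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        first = bad.iloc[0]
        raise IntervalError(
            f"inverted or empty {what} interval: "
            f"{first.get('gene', first.get('qtl_id', '?'))} "
            f"[{first['start']}, {first['end']})"
        )
    if df["chrom"].astype(str).str.len().eq(0).any():
        raise IntervalError(f"{what} table contains an empty chromosome name")


def load_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read gene loci from BED (chrom, start, end, name; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
    )
    df = df[["gene", "chrom", "start", "end"]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _check_intervals(df, "gene locus")
    return df


def load_qtl_table(path: str | Path) -> pd.DataFrame:
    """Read a QTL table (qtl_id, chrom, start, end, trait, trait_class
    [, coord_convention]).

    ``coord_convention`` may be ``zero_half_open`` (default) or
    ``one_based_inclusive``; the latter is converted on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["qtl_id", "chrom", "start", "end", "trait", "trait_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntervalError(f"QTL table lacks column(s): {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "coord_convention" in df.columns:
        conv = df["coord_convention"].fillna("zero_half_open")
        unknown = set(conv) - {"zero_half_open", "one_based_inclusive"}
        if unknown:
            raise IntervalError(f"unknown coordinate convention(s): {sorted(unknown)}")
        one_based = conv == "one_based_inclusive"
        df.loc[one_based, "start"] -= 1
        df = df.drop(columns=["coord_convention"])
    _check_intervals(df, "QTL")
    return df[required]


def map_genes(
    loci: pd.DataFrame,
    qtls: pd.DataFrame,
    genes: set[str] | None = None,
) -> pd.DataFrame:
    """Strict-containment hits; columns gene, qtl_id, trait, trait_class.

    A gene may hit several QTLs.  If ``genes`` is supplied, members without
    a locus row are reported with a warning (they cannot be mapped).
    """
    _check_intervals(loci, "gene locus")
    _check_intervals(qtls, "QTL")
    if genes is not None:
        unlocated = sorted(set(genes) - set(loci["gene"]))
        if unlocated:
            warnings.warn(
                f"{len(unlocated)} gene(s) have no locus and stay unmapped: "
                f"{', '.join(unlocated[:5])}",
                stacklevel=2,
            )
        loci = loci[loci["gene"].isin(genes)]

    merged = loci.merge(qtls, on="chrom", suffixes=("_gene", "_qtl"))
    contained = merged[
        (merged["start_qtl"] <= merged["start_gene"])
        & (merged["end_gene"] <= merged["end_qtl"])
    ]
    out = contained[["gene", "qtl_id", "trait", "trait_class"]].copy()
    return out.sort_values(["gene", "qtl_id"], ignore_index=True)


def filter_trait_class(
    hits: pd.DataFrame, class_set: set[str]
) -> tuple[pd.DataFrame, int]:
    """Hits restricted to the given trait classes, plus the number of
    distinct genes among them."""
    kept = hits[hits["trait_class"].isin(set(class_set))].reset_index(drop=True)
    return kept, int(kept["gene"].nunique())
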