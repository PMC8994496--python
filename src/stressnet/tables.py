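"""Transcriptions of the original study's printed summary tables.

The raw arrays behind the original cattle pre-slaughter stress experiment
(GEO accession GSE119912) are not redistributed here, but the published
per-gene and per-module summary tables are shipped as small TSV files so
the integration operations (Venn partitions, TF flagging, module
intersection, QTL trait filtering) can be exercised and checked against
the printed list arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

MEAT_QUALITY_TRAITS = frozenset(
    {
        "Shear force",
        "Muscle compression",
        "Tenderness score",
        "Muscle pH",
        "Juiciness",
        "Marbling score",
    }
)

FATTY_ACID_TRAITS = frozenset(
    {
        "Saturated fatty acid content",
        "Conjugated linoleic acid content",
        "Omega-6 to omega-3 fatty acid ratio",
    }
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("stressnet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def published_deg_table() -> pd.DataFrame:
    """Per-gene summary: response_type, gene, regulator flag, QTL traits."""
    return _read("published_degs.tsv")


def published_module_table() -> pd.DataFrame:
    """Per-muscle over-represented promoter modules with p, occurrence,
    target-gene count and the comma-separated target gene list."""
    df = _read("published_modules.tsv")
    return df


def deg_names(muscle: str) -> set[str]:
    """Unique differential gene names for one muscle (specific + common)."""
    if muscle not in ("LT", "ST"):
        raise ValueError(f"muscle must be 'LT' or 'ST', got {muscle!r}")
    df = published_deg_table()
    keep = df["response_type"].isin([f"{muscle}-specific DEG", "Common DEG"])
    return set(df.loc[keep, "gene"])


def regulator_flags() -> tuple[set[str], set[str]]:
    """(transcription factors, transcriptional modulators) over all rows."""
    df = published_deg_table()
    tf = set(df.loc[df["regulator"] == "TF", "gene"])
    tm = set(df.loc[df["regulator"] == "TM", "gene"])
    return tf, tm


def response_gene_set(response_type: str) -> set[str]:
    df = published_deg_table()
    genes = set(df.loc[df["response_type"] == response_type, "gene"])
    if not genes:
        known = sorted(df["response_type"].unique())
        raise ValueError(f"unknown response type {response_type!r}; known: {known}")
    return genes


def published_qtl_hits() -> pd.DataFrame:
    """Long-format (gene, trait, trait_class) rows from the QTL column.

    Trait classes follow the study's grouping: the six meat-quality traits
    versus fatty-acid-composition traits.
    """
    df = published_deg_table()
    rows = []
    for r in df.itertuples(index=False):
        if not r.qtl_traits:
            continue
        for i, trait in enumerate(str(r.qtl_traits).split(";")):
            trait = trait.strip()
            if trait in MEAT_QUALITY_TRAITS:
                cls = "meat-quality"
            elif trait in FATTY_ACID_TRAITS:
                cls = "fatty-acid"
            else:
                cls = "other"
            rows.append(
                {"gene": r.gene, "qtl_id": f"{r.gene}_qtl{i + 1}", "trait": trait,
                 "trait_class": cls}
            )
    return pd.DataFrame(rows, columns=["gene", "qtl_id", "trait", "trait_class"])


def module_hit_table(muscle: str) -> pd.DataFrame:
    """Re-expand a muscle's printed module/target-gene lists into hit rows
    compatible with :mod:`stressnet.cismods` (one promoter per gene; match
    positions unknown from the print, recorded as 1)."""
    df = published_module_table()
    df = df[df["muscle"] == muscle]
    if df.empty:
        raise ValueError(f"no module rows for muscle {muscle!r}")
    rows = []
    for r in df.itertuples(index=False):
        for gene in str(r.genes).split(","):
            rows.append((r.module, gene, f"{gene}_p1", 1))
    return pd.DataFrame(rows, columns=["module", "gene", "promoter_id", "n_positions"])


def module_query_genes(muscle: str) -> set[str]:
    """All genes appearing in a muscle's printed module target lists —
    the promoter-bearing differential genes for that muscle."""
    hits = module_hit_table(muscle)
    return set(hits["gene"])
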