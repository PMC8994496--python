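"""Promoter cis-module over-representation among differential genes.

A cis-transcriptional module is a framework of co-occurring transcription
factor binding sites found in a promoter.  Given a table of (module, gene,
promoter, match-position count) hits covering the whole array, each module
is tested for over-representation in the query gene set versus the array
universe with a one-sided Fisher exact test.  The counting unit is the
gene: a gene counts once no matter how many of its promoters match, while
the reported ``occurrence`` sums match positions over the query's
promoters (so occurrence can exceed the target-gene count).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

HIT_COLUMNS = ("module", "gene", "promoter_id", "n_positions")


class CisModuleError(ValueError):
    pass


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail (over-representation) Fisher exact p for the table
    [[a, b], [c, d]] = [[query-hit, query-miss], [rest-hit, rest-miss]]."""
    if min(a, b, c, d) < 0:
        raise CisModuleError(f"negative count in 2x2 table: {(a, b, c, d)}")
    # identical to the hypergeometric upper tail with the observed margins
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def tabulate(
    hits: pd.DataFrame, query: set[str], universe: set[str]
) -> pd.DataFrame:
    """Per-module 2x2 tables, occurrence and target-gene lists.

    ``a`` counts query genes with >= 1 hit, ``c`` non-query universe genes
    with >= 1 hit; occurrence sums ``n_positions`` over all query-gene
    promoter hits.  Modules with no query hit are excluded.  Genes without
    a retrievable promoter should already be absent from both query and
    universe.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise CisModuleError(f"query gene(s) not in universe: {', '.join(stray[:5])}")
    missing_cols = set(HIT_COLUMNS) - set(hits.columns)
    if missing_cols:
        raise CisModuleError(f"hit table lacks column(s): {sorted(missing_cols)}")

    hits = hits[hits["gene"].isin(universe)]
    n_query = len(query)
    n_universe = len(universe)
    rows = []
    for module, sub in hits.groupby("module", sort=True):
        genes_hit = set(sub["gene"])
        target_genes = sorted(genes_hit & query)
        a = len(target_genes)
        if a == 0:
            continue
        c = len(genes_hit - query)
        b = n_query - a
        d = n_universe - n_query - c
        occurrence = int(sub.loc[sub["gene"].isin(query), "n_positions"].sum())
        rows.append(
            {
                "module": module,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "occurrence": occurrence,
                "n_target_genes": a,
                "target_genes": ",".join(target_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["module", "a", "b", "c", "d", "occurrence",
                 "n_target_genes", "target_genes"],
    )


def enrich_modules(
    hits: pd.DataFrame, query: set[str], universe: set[str]
) -> pd.DataFrame:
    """Tabulate then attach the one-sided Fisher p per module."""
    tab = tabulate(hits, query, universe)
    tab["p"] = [
        fisher_one_sided(r.a, r.b, r.c, r.d) for r in tab.itertuples(index=False)
    ]
    return tab


def select_modules(enr: pd.DataFrame, p_cut: float = 0.1) -> pd.DataFrame:
    """Over-represented modules at strict p < p_cut, sorted by target-gene
    count (descending) then p (ascending)."""
    sel = enr[enr["p"] < p_cut].copy()
    return sel.sort_values(
        ["n_target_genes", "p", "module"], ascending=[False, True, True],
        ignore_index=True,
    )


def common_modules(list_a: pd.DataFrame, list_b: pd.DataFrame) -> list[str]:
    """Module ids present in both selected lists."""
    return sorted(set(list_a["module"]) & set(list_b["module"]))


def module_target_union(selected: pd.DataFrame, min_targets: int = 1) -> set[str]:
    """Union of target genes over selected modules with at least
    ``min_targets`` target genes — the seed set for network extraction."""
    keep = selected[selected["n_target_genes"] >= min_targets]
    out: set[str] = set()
    for gl in keep["target_genes"]:
        if gl:
            out.update(gl.split(","))
    return out
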