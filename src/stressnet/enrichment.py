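"""Annotation-term over-representation against the array background.

One-sided hypergeometric tests per term, restricted to the gene universe
actually represented on the array, with Benjamini-Hochberg control applied
within each annotation namespace (biological process and molecular
function are reported separately).  Significance is declared at
FDR < 0.08 by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh


class EnrichmentError(ValueError):
    pass


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): upper-tail over-representation."""
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    background: set[str],
    annotations: pd.DataFrame,
    fdr_cut: float = 0.08,
) -> pd.DataFrame:
    """Term over-representation of ``query`` within ``background``.

    ``annotations`` columns: gene, term_id, term_name, namespace.  Query
    genes absent from the background are dropped with a warning; an empty
    query after restriction is an error.  Terms with no query gene are
    skipped.  Returns one row per tested term with the 2x2 ingredients
    (k, K, n, N), p, within-namespace FDR, -log10 p and a significance flag.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) absent from the background were dropped: "
            f"{', '.join(sorted(stray)[:5])}",
            stacklevel=2,
        )
        query = query & background
    if not query:
        raise EnrichmentError("query is empty after restriction to the background")

    ann = annotations[annotations["gene"].isin(background)]
    N = len(background)
    n = len(query)
    rows = []
    grouped = ann.groupby(["namespace", "term_id"], sort=True)
    for (ns, term_id), sub in grouped:
        genes = set(sub["gene"])
        k = len(genes & query)
        if k == 0:
            continue
        K = len(genes)
        p = hypergeom_tail(k, K, n, N)
        rows.append(
            {
                "term_id": term_id,
                "term_name": sub["term_name"].iloc[0],
                "namespace": ns,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "genes": ",".join(sorted(genes & query)),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "namespace", "k", "K", "n", "N", "p", "genes"],
    )
    if res.empty:
        res["fdr"] = pd.Series(dtype=float)
        res["neg_log10_p"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
        return res
    res["fdr"] = np.nan
    for ns, idx in res.groupby("namespace").groups.items():
        res.loc[idx, "fdr"] = adjust_bh(res.loc[idx, "p"].to_numpy())
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = np.where(res["p"] > 0, -np.log10(res["p"]), np.inf)
    res["significant"] = res["fdr"] < fdr_cut
    return res.sort_values(["namespace", "p"], ignore_index=True)


def common_terms(res_a: pd.DataFrame, res_b: pd.DataFrame) -> pd.DataFrame:
    """Terms significant in both result sets, with per-side query-hit counts."""
    sig_a = res_a[res_a["significant"]]
    sig_b = res_b[res_b["significant"]]
    shared = sorted(set(sig_a["term_id"]) & set(sig_b["term_id"]))
    if not shared:
        return pd.DataFrame(columns=["term_id", "term_name", "namespace", "k_a", "k_b"])
    a = sig_a.set_index("term_id").loc[shared]
    b = sig_b.set_index("term_id").loc[shared]
    return pd.DataFrame(
        {
            "term_id": shared,
            "term_name": a["term_name"].to_numpy(),
            "namespace": a["namespace"].to_numpy(),
            "k_a": a["k"].to_numpy(),
            "k_b": b["k"].to_numpy(),
        }
    )
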