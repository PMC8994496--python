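"""Integration layer: Venn partitions, TF flagging and the summary table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class VennPartition:
    """Exact two-set partition; the three parts are pairwise disjoint and
    their union is A | B."""

    only_a: set[str]
    only_b: set[str]
    both: set[str]
    labels: tuple[str, str] = ("A", "B")

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"only_{self.labels[0]}": len(self.only_a),
            f"only_{self.labels[1]}": len(self.only_b),
            "both": len(self.both),
        }


def venn(set_a: set[str], set_b: set[str],
         labels: tuple[str, str] = ("A", "B")) -> VennPartition:
    a, b = set(set_a), set(set_b)
    return VennPartition(only_a=a - b, only_b=b - a, both=a & b, labels=labels)


def flag_tfs(
    genes: set[str] | list[str], tf: set[str], tm: set[str] = frozenset()
) -> pd.DataFrame:
    """Label genes as transcription factor (TF), transcriptional modulator
    (TM) or none.  The two dictionaries must be disjoint."""
    overlap = set(tf) & set(tm)
    if overlap:
        raise ValueError(
            f"gene(s) present in both TF and TM tables: {', '.join(sorted(overlap)[:5])}"
        )
    rows = [
        {
            "gene": g,
            "flag": "TF" if g in tf else ("TM" if g in tm else "none"),
        }
        for g in sorted(set(genes))
    ]
    return pd.DataFrame(rows, columns=["gene", "flag"])


def build_summary(
    deg_lt: set[str],
    deg_st: set[str],
    tf: set[str],
    tm: set[str],
    regulators: set[str],
    targets: set[str],
    qtl_hits: pd.DataFrame | None = None,
    modules_lt: list[str] | None = None,
    modules_st: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One row per (response type, gene) with TF flag and QTL traits, plus
    a machine-readable count report.

    ``qtl_hits`` is optional (columns gene, trait, trait_class); when
    missing the trait column is left empty.
    """
    part = venn(deg_lt, deg_st, labels=("LT", "ST"))
    groups = [
        ("LT-specific DEG", sorted(part.only_a)),
        ("ST-specific DEG", sorted(part.only_b)),
        ("Common DEG", sorted(part.both)),
        ("Common main regulator", sorted(regulators)),
        ("Common main target", sorted(targets)),
    ]
    traits_of: dict[str, list[str]] = {}
    if qtl_hits is not None and len(qtl_hits):
        for gene, sub in qtl_hits.groupby("gene"):
            traits_of[gene] = sorted(set(sub["trait"]))

    rows = []
    for rtype, genes in groups:
        flags = flag_tfs(genes, tf, tm).set_index("gene")["flag"]
        for g in genes:
            rows.append(
                {
                    "response_type": rtype,
                    "gene": g,
                    "tf_flag": flags[g],
                    "qtl_traits": ";".join(traits_of.get(g, [])),
                }
            )
    summary = pd.DataFrame(
        rows, columns=["response_type", "gene", "tf_flag", "qtl_traits"]
    )

    common_tfs = part.both & set(tf)
    mod_common = (
        sorted(set(modules_lt) & set(modules_st))
        if modules_lt is not None and modules_st is not None
        else []
    )
    annotated = summary[summary["qtl_traits"] != ""]
    report = {
        "n_deg_lt": len(deg_lt),
        "n_deg_st": len(deg_st),
        "n_deg_common": len(part.both),
        "n_deg_lt_specific": len(part.only_a),
        "n_deg_st_specific": len(part.only_b),
        "n_common_tfs": len(common_tfs),
        "common_tfs": sorted(common_tfs),
        "n_modules_lt": len(modules_lt) if modules_lt is not None else None,
        "n_modules_st": len(modules_st) if modules_st is not None else None,
        "n_modules_common": len(mod_common) if modules_lt is not None else None,
        "common_modules": mod_common,
        "n_regulators": len(regulators),
        "n_targets": len(targets),
        "n_qtl_genes": int(annotated["gene"].nunique()),
    }
    return summary, report
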