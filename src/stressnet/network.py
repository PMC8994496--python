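"""Regulator/target extraction from a curated interaction database.

The database is a directed edge list: Regulation edges point
regulator -> gene, Expression edges point gene -> expression target; every
edge carries a bibliographic reference count, and a node's "known
relations" is its total incident edge count in the database.

Starting from a seed gene set (differential genes targeted by
over-represented promoter modules), the extraction adds:

* candidate regulators — non-seed nodes with Regulation edges into at
  least ``min_connected`` seeds, a qualifying edge with >= 3 references,
  and database degree >= 2 (>= 5 under the stricter ``common`` profile
  used for the cross-muscle core network);
* candidate expression targets — non-seed nodes receiving Expression
  edges from at least ``min_connected`` seeds, a qualifying edge with
  >= 3 references, and database degree >= 6.

Intersecting role sets across the muscle-specific and core networks gives
the major regulators / major targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

RELATION_TYPES = ("Regulation", "Expression")


class InteractionDBError(ValueError):
    pass


@dataclass
class FilterParams:
    min_refs_target: int = 3
    min_degree_target: int = 6
    min_refs_regulator: int = 3
    min_degree_regulator: int = 2
    min_degree_regulator_common: int = 5
    min_connected: int = 2

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")


@dataclass
class InteractionDB:
    """Merged edge list plus a degree index (total incident relations)."""

    edges: pd.DataFrame  # source, target, relation_type, n_references
    degree: pd.Series

    @property
    def nodes(self) -> set[str]:
        return set(self.degree.index)


def load_db(source: str | Path | pd.DataFrame) -> InteractionDB:
    """Build an :class:`InteractionDB` from a TSV path or a DataFrame.

    Duplicate (source, target, relation_type) rows are merged by summing
    their reference counts; self-loops and malformed rows are rejected
    with the offending line number.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.insert(0, "_line", range(2, len(df) + 2))
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
        df.insert(0, "_line", range(2, len(df) + 2))
    required = ["source", "target", "relation_type", "n_references"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InteractionDBError(f"edge list lacks column(s): {missing}")

    if df.empty:
        empty = pd.DataFrame(columns=required)
        return InteractionDB(edges=empty, degree=pd.Series(dtype=int))

    for row in df.itertuples(index=False):
        line = row._0 if hasattr(row, "_0") else row._line
        try:
            refs = int(row.n_references)
        except (TypeError, ValueError):
            raise InteractionDBError(
                f"line {line}: non-integer n_references {row.n_references!r}"
            ) from None
        if refs < 1:
            raise InteractionDBError(f"line {line}: n_references must be >= 1")
        if not row.source or not row.target or pd.isna(row.source) or pd.isna(row.target):
            raise InteractionDBError(f"line {line}: empty source or target")
        if row.source == row.target:
            raise InteractionDBError(f"line {line}: self-loop on {row.source!r}")
        if row.relation_type not in RELATION_TYPES:
            raise InteractionDBError(
                f"line {line}: unknown relation_type {row.relation_type!r}"
            )

    df["n_references"] = df["n_references"].astype(int)
    merged = (
        df.groupby(["source", "target", "relation_type"], sort=True)["n_references"]
        .sum()
        .reset_index()
    )
    incident = pd.concat([merged["source"], merged["target"]])
    degree = incident.value_counts().sort_index()
    degree.index.name = None
    return InteractionDB(edges=merged, degree=degree)


@dataclass
class NetworkExtract:
    seeds: set[str]
    regulators: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    profile: str = "muscle"

    @property
    def nodes(self) -> set[str]:
        return self.seeds | self.regulators | self.targets


def extract_network(
    db: InteractionDB,
    seeds: set[str],
    params: FilterParams | None = None,
    profile: str = "muscle",
) -> NetworkExtract:
    """Add admissible common regulators and expression targets to a seed set."""
    if profile not in ("muscle", "common"):
        raise ValueError(f"profile must be 'muscle' or 'common', got {profile!r}")
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    params = params or FilterParams()
    min_deg_reg = (
        params.min_degree_regulator_common if profile == "common"
        else params.min_degree_regulator
    )

    e = db.edges
    regulators: set[str] = set()
    targets: set[str] = set()
    if not e.empty:
        reg_edges = e[
            (e["relation_type"] == "Regulation")
            & e["target"].isin(seeds)
            & ~e["source"].isin(seeds)
        ]
        for cand, sub in reg_edges.groupby("source"):
            if sub["target"].nunique() < params.min_connected:
                continue
            if sub["n_references"].max() < params.min_refs_regulator:
                continue
            if int(db.degree.get(cand, 0)) < min_deg_reg:
                continue
            regulators.add(cand)

        tgt_edges = e[
            (e["relation_type"] == "Expression")
            & e["source"].isin(seeds)
            & ~e["target"].isin(seeds)
        ]
        for cand, sub in tgt_edges.groupby("target"):
            if sub["source"].nunique() < params.min_connected:
                continue
            if sub["n_references"].max() < params.min_refs_target:
                continue
            if int(db.degree.get(cand, 0)) < params.min_degree_target:
                continue
            targets.add(cand)

    nodes = seeds | regulators | targets
    sub_edges = subnetwork(db, seeds, nodes - seeds)
    return NetworkExtract(
        seeds=seeds, regulators=regulators, targets=targets,
        edges=sub_edges, profile=profile,
    )


def major_nodes(extracts: list[NetworkExtract], role: str) -> set[str]:
    """Intersection of a role set (``regulator`` or ``target``) across
    >= 2 network extracts."""
    if role not in ("regulator", "target"):
        raise ValueError(f"role must be 'regulator' or 'target', got {role!r}")
    if len(extracts) < 2:
        raise ValueError("need at least two network extracts to intersect")
    sets = [
        ext.regulators if role == "regulator" else ext.targets for ext in extracts
    ]
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def subnetwork(db: InteractionDB, seeds: set[str], nodes: set[str]) -> pd.DataFrame:
    """All database edges with both endpoints inside ``seeds | nodes``."""
    keep = set(seeds) | set(nodes)
    unknown = set(nodes) - db.nodes - set(seeds)
    if unknown:
        raise ValueError(
            f"node(s) absent from database: {', '.join(sorted(unknown)[:5])}"
        )
    e = db.edges
    if e.empty:
        return e.copy()
    return e[e["source"].isin(keep) & e["target"].isin(keep)].reset_index(drop=True)


def to_graphml(extract: NetworkExtract, path: str | Path) -> None:
    """Export an extract with node-role attributes for graph viewers."""
    g = nx.DiGraph()
    for n in extract.seeds:
        g.add_node(n, role="seed")
    for n in extract.regulators:
        g.add_node(n, role="regulator")
    for n in extract.targets:
        g.add_node(n, role="target")
    for row in extract.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, relation_type=row.relation_type,
                   n_references=int(row.n_references))
    nx.write_graphml(g, path)
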