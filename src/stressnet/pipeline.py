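"""End-to-end orchestration: simulate/load -> normalize -> differential
expression per muscle -> GO and cis-module over-representation -> network
extraction (two muscle profiles + core) -> QTL mapping -> summary report.

:func:`analyze_bundle` holds the stage logic and works entirely in memory;
:func:`run_pipeline` wraps it with input loading, per-stage file output, a
checksum manifest and the final ``report.json``, which is a pure function
of (inputs, config, seed) — re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cismods, diffexpr, enrichment, io, network, preprocess, qtl, report
from .simulate import (
    GroundTruth,
    ProbeMatrix,
    SimConfig,
    config_from_dict,
    generate_all,
    write_all,
)

log = logging.getLogger("stressnet")

DEFAULTS: dict = {
    "de": {"alpha": 0.10, "min_frac": 0.80, "interaction": True},
    "enrichment": {"fdr": 0.08},
    "modules": {"p_cut": 0.1, "min_targets": {"LT": 5, "ST": 4}},
    "network": {},
    "qtl": {"trait_classes": ["meat-quality"]},
}


class PipelineError(RuntimeError):
    pass


def _merged(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class AnalysisResult:
    """Everything the analysis stages produce, keyed by muscle where
    applicable."""

    norm: preprocess.NormalizedMatrix
    stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    calls: dict[str, pd.DataFrame] = field(default_factory=dict)
    degs: dict[str, set[str]] = field(default_factory=dict)
    go: dict[str, pd.DataFrame] = field(default_factory=dict)
    modules: dict[str, pd.DataFrame] = field(default_factory=dict)
    common_modules: list[str] = field(default_factory=list)
    extracts: list[network.NetworkExtract] = field(default_factory=list)
    regulators: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    qtl_hits: pd.DataFrame | None = None
    n_qtl_genes: int | None = None


def analyze_bundle(
    pm: ProbeMatrix,
    probe_map: pd.Series,
    module_hits: pd.DataFrame,
    interactions: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    gene_loci: pd.DataFrame | None = None,
    qtls: pd.DataFrame | None = None,
    config: dict | None = None,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs."""
    cfg = _merged(config)
    muscles = sorted(pm.design["muscle"].unique())

    norm = preprocess.normalize(preprocess.qc_filter(pm))
    res = AnalysisResult(norm=norm)
    log.info("normalize: %d probes retained on %d arrays", *norm.log2.shape)

    de_cfg = cfg["de"]
    for muscle in muscles:
        spec = diffexpr.DesignSpec(muscle=muscle,
                                   interaction=bool(de_cfg["interaction"]))
        fit = diffexpr.fit_linear_models(norm, spec)
        stats = diffexpr.moderate(fit)
        calls = diffexpr.call_genes(
            stats, probe_map, alpha=de_cfg["alpha"],
            min_frac=de_cfg["min_frac"], muscle=muscle,
        )
        res.stats[muscle] = stats
        res.calls[muscle] = calls
        res.degs[muscle] = diffexpr.deg_set(calls)
        log.info("de[%s]: %d/%d genes called", muscle,
                 len(res.degs[muscle]), len(calls))

    array_genes = set(probe_map.unique())

    if annotations is not None:
        for muscle in muscles:
            if res.degs[muscle]:
                res.go[muscle] = enrichment.enrich(
                    res.degs[muscle], array_genes, annotations,
                    fdr_cut=cfg["enrichment"]["fdr"],
                )

    mod_cfg = cfg["modules"]
    empty_sel = pd.DataFrame(
        columns=["module", "a", "b", "c", "d", "occurrence", "n_target_genes",
                 "target_genes", "p"]
    )
    for muscle in muscles:
        if not res.degs[muscle]:
            res.modules[muscle] = empty_sel.copy()
            continue
        enr = cismods.enrich_modules(module_hits, res.degs[muscle], array_genes)
        res.modules[muscle] = cismods.select_modules(enr, p_cut=mod_cfg["p_cut"])
    if len(muscles) >= 2:
        res.common_modules = cismods.common_modules(
            res.modules[muscles[0]], res.modules[muscles[1]])

    db = network.load_db(interactions)
    params = network.FilterParams(**cfg["network"])
    min_targets = mod_cfg["min_targets"]
    for muscle in muscles:
        seeds = cismods.module_target_union(
            res.modules[muscle], min_targets=min_targets.get(muscle, 1))
        if not seeds:
            seeds = res.degs[muscle]
        if seeds:
            res.extracts.append(
                network.extract_network(db, seeds, params, profile="muscle"))
    if len(muscles) >= 2 and res.common_modules:
        common_seeds: set[str] = set()
        for muscle in muscles:
            sel = res.modules[muscle]
            common_seeds |= cismods.module_target_union(
                sel[sel["module"].isin(res.common_modules)])
        if common_seeds:
            res.extracts.append(
                network.extract_network(db, common_seeds, params, profile="common"))
    if len(res.extracts) >= 2:
        res.regulators = network.major_nodes(res.extracts, "regulator")
        res.targets = network.major_nodes(res.extracts, "target")

    all_genes = set().union(*res.degs.values()) | res.regulators | res.targets
    if gene_loci is not None and qtls is not None and all_genes:
        hits = qtl.map_genes(gene_loci, qtls, genes=all_genes)
        res.qtl_hits, res.n_qtl_genes = qtl.filter_trait_class(
            hits, set(cfg["qtl"]["trait_classes"]))
    return res


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run every stage, write per-stage outputs and the run report.

    ``config['simulate']`` requests synthetic inputs; otherwise
    ``config['inputs']`` must name the input files.  A missing QTL input is
    tolerated: the report then omits QTL counts with a warning.
    """
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    gene_loci = qtls = annotations = None
    if "simulate" in cfg:
        sim_params = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_params["seed"] = seed
        sim_cfg: SimConfig = config_from_dict(sim_params)
        log.info("simulate: seed=%d, %d probes, %d genes",
                 sim_cfg.seed, sim_cfg.n_probes, sim_cfg.n_genes)
        sim = generate_all(sim_cfg)
        write_all(sim, outdir / "simulated")
        pm, probe_map, truth = sim.probes, sim.probe_map, sim.truth
        module_hits, interactions = sim.module_hits, sim.interactions
        gene_loci, qtls, annotations = sim.gene_loci, sim.qtls, sim.annotations
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        pm = io.read_probe_matrix(inp["probe_matrix"], inp["design"],
                                  inp.get("qc_flags"))
        probe_map = io.read_probe_map(inp["probe_map"])
        module_hits = pd.read_csv(inp["module_hits"], sep="\t")
        interactions = pd.read_csv(inp["interactions"], sep="\t")
        if "annotations" in inp:
            annotations = pd.read_csv(inp["annotations"], sep="\t")
        if "gene_loci" in inp and "qtls" in inp:
            gene_loci = qtl.load_gene_bed(inp["gene_loci"])
            qtls = qtl.load_qtl_table(inp["qtls"])
        else:
            warnings.warn("no QTL inputs configured; QTL columns omitted",
                          stacklevel=2)
    else:
        raise PipelineError("config must contain a 'simulate' or an 'inputs' section")

    res = analyze_bundle(
        pm, probe_map, module_hits, interactions,
        annotations=annotations, gene_loci=gene_loci, qtls=qtls, config=cfg,
    )

    io.write_tsv(res.norm.log2, outdir / "normalized_log2.tsv", index=True)
    muscles = sorted(res.degs)
    for muscle in muscles:
        io.write_tsv(res.stats[muscle], outdir / f"probe_stats_{muscle}.tsv",
                     index=True)
        io.write_tsv(res.calls[muscle], outdir / f"gene_calls_{muscle}.tsv",
                     index=True)
        io.write_tsv(res.modules[muscle], outdir / f"modules_{muscle}.tsv")
        if muscle in res.go:
            io.write_tsv(res.go[muscle], outdir / f"enrichment_{muscle}.tsv")
    for i, ext in enumerate(res.extracts):
        network.to_graphml(ext, outdir / f"network_{i}_{ext.profile}.graphml")
    if res.qtl_hits is not None:
        io.write_tsv(res.qtl_hits, outdir / "qtl_hits.tsv")

    lt, st = muscles[0], muscles[-1]
    summary, run_report = report.build_summary(
        res.degs[lt], res.degs[st], tf=set(), tm=set(),
        regulators=res.regulators, targets=res.targets,
        qtl_hits=res.qtl_hits,
        modules_lt=list(res.modules[lt]["module"]),
        modules_st=list(res.modules[st]["module"]),
    )
    io.write_tsv(summary, outdir / "summary.tsv")
    if truth is not None:
        run_report["recovery"] = recovery_stats(
            truth, res.degs, res.modules, res.regulators, res.targets)
    run_report["n_qtl_genes"] = res.n_qtl_genes

    manifest: dict[str, str] = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "report.json":
            manifest[str(p.relative_to(outdir))] = _sha256(p)
    run_report["manifest"] = manifest
    (outdir / "report.json").write_text(
        json.dumps(run_report, indent=1, sort_keys=True) + "\n")
    return run_report


def recovery_stats(
    truth: GroundTruth,
    degs: dict[str, set[str]],
    selected: dict[str, pd.DataFrame],
    regulators: set[str],
    targets: set[str],
) -> dict:
    """Compare pipeline output against the planted ground truth."""
    out: dict = {}
    all_called = set().union(*degs.values()) if degs else set()
    planted = set(truth.de_genes)
    sens_parts = []
    for muscle, called in degs.items():
        truth_m = truth.de_genes_for(muscle)
        if truth_m:
            sens_parts.append(len(called & truth_m) / len(truth_m))
    out["de_sensitivity"] = min(sens_parts) if sens_parts else None
    out["de_false_genes"] = sorted(all_called - planted)
    out["de_gene_fdr"] = (
        len(all_called - planted) / len(all_called) if all_called else 0.0
    )
    planted_mods = set(truth.enriched_modules)
    found_mods = set()
    for sel in selected.values():
        found_mods |= set(sel["module"])
    out["module_recovery"] = (
        len(planted_mods & found_mods) / len(planted_mods) if planted_mods else None
    )
    out["regulator_recovery"] = (
        len(regulators & truth.planted_regulators) / len(truth.planted_regulators)
        if truth.planted_regulators else None
    )
    out["target_recovery"] = (
        len(targets & truth.planted_targets) / len(truth.planted_targets)
        if truth.planted_targets else None
    )
    out["decoys_admitted"] = sorted(
        g for g in (regulators | targets) if g.startswith("DECOY")
    )
    return out
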