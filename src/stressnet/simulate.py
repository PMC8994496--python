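"""Synthetic generator for every input the pipeline consumes.

Emulates a two-muscle bovine stress experiment measured on a custom
oligonucleotide array: ~10k probes (of which ~1.6k are non-biological
controls) covering ~4.2k genes with multiple probes per gene, a
2 muscle x 2 stress x 2 diet design over 32 animals, planted
differentially expressed genes with known signed log2 effects, planted
promoter cis-module enrichments, planted network regulators/targets with
literature-evidence counts, and QTL intervals that fully contain a known
subset of gene loci.

Intensities are log-normal: Gaussian on the log2 scale with an additive
group effect for planted genes and a per-array multiplicative scale
(additive on log2).  Control probes receive the array scale and noise but
never a biological effect, so they can serve for ratio normalization
exactly as on the real platform.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn`` — one child stream per generated
artefact — so each output is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MEAT_QUALITY_TRAITS = (
    "Shear force",
    "Muscle compression",
    "Tenderness score",
    "Muscle pH",
    "Juiciness",
    "Marbling score",
)

FATTY_ACID_TRAITS = (
    "Saturated fatty acid content",
    "Conjugated linoleic acid content",
    "Omega-6 to omega-3 fatty acid ratio",
)


class SimConfigError(ValueError):
    """Raised when a :class:`SimConfig` field violates its contract."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real platform and design: 10,064 probes of which
    1,614 are controls, 4,210 genes, 32 animals split 16 stressed / 16
    limited-stress (8 per diet within each stress group), both muscles
    sampled on every animal.
    """

    n_probes: int = 10_064
    n_control_probes: int = 1_614
    n_genes: int = 4_210
    probes_per_gene: tuple[int, int] = (1, 4)
    n_animals_per_group: int = 8  # per stress x diet cell
    stress_levels: tuple[str, str] = ("stress", "limited")
    diet_levels: tuple[str, str] = ("control", "EP")
    muscles: tuple[str, ...] = ("LT", "ST")
    n_de_genes: int = 40
    frac_de_common: float = 0.4  # planted in both muscles
    frac_de_lt_only: float = 0.4  # remainder is ST-only
    lfc_range: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.2
    array_effect_sd: float = 0.1
    frac_probe_dropout: float = 0.001
    # promoter cis-module layer
    n_modules: int = 40
    n_planted_modules: int = 5
    module_background_rate: float = 0.01
    # interaction-database layer
    n_regulators: int = 4
    n_targets: int = 4
    n_decoys: int = 6
    # genomic layer
    n_qtl_genes: int = 10
    # annotation layer
    n_go_terms: int = 40
    go_background_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_probes >= self.n_probes:
            raise SimConfigError(
                "n_control_probes must be < n_probes "
                f"({self.n_control_probes} >= {self.n_probes})"
            )
        if self.n_de_genes > self.n_genes:
            raise SimConfigError(
                f"n_de_genes exceeds n_genes ({self.n_de_genes} > {self.n_genes})"
            )
        n_gene_probes = self.n_probes - self.n_control_probes
        if n_gene_probes < self.n_genes:
            raise SimConfigError(
                "n_probes - n_control_probes must be >= n_genes so every gene "
                f"has a probe ({n_gene_probes} < {self.n_genes})"
            )
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise SimConfigError(f"probes_per_gene bounds invalid: {self.probes_per_gene}")
        if self.n_genes * hi < n_gene_probes:
            raise SimConfigError(
                "probes_per_gene upper bound too small to place "
                f"{n_gene_probes} gene probes on {self.n_genes} genes"
            )
        if self.lfc_range[0] <= 0 or self.lfc_range[0] > self.lfc_range[1]:
            raise SimConfigError(f"lfc_range lower bound must be > 0: {self.lfc_range}")
        if self.noise_sd <= 0:
            raise SimConfigError(f"noise_sd must be > 0: {self.noise_sd}")
        if self.array_effect_sd < 0:
            raise SimConfigError(f"array_effect_sd must be >= 0: {self.array_effect_sd}")
        if not 0.0 <= self.frac_probe_dropout < 1.0:
            raise SimConfigError(
                f"frac_probe_dropout must be in [0, 1): {self.frac_probe_dropout}"
            )
        if self.n_animals_per_group < 1:
            raise SimConfigError(
                f"n_animals_per_group must be >= 1: {self.n_animals_per_group}"
            )
        if not 0.0 <= self.frac_de_common + self.frac_de_lt_only <= 1.0:
            raise SimConfigError("frac_de_common + frac_de_lt_only must be in [0, 1]")
        if self.n_planted_modules > self.n_modules:
            raise SimConfigError("n_planted_modules exceeds n_modules")
        if self.n_de_genes and self.n_qtl_genes > self.n_de_genes:
            raise SimConfigError("n_qtl_genes exceeds n_de_genes")


@dataclass
class GroundTruth:
    """Planted signal: what a perfect pipeline should recover.

    ``de_genes`` maps gene -> (muscles carrying the effect, signed log2
    effect).  Planted regulators/targets are deliberately *not* DE genes —
    they are the network neighbourhood the extraction stage must add.
    """

    de_genes: dict[str, tuple[frozenset[str], float]] = field(default_factory=dict)
    enriched_modules: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    planted_regulators: set[str] = field(default_factory=set)
    planted_targets: set[str] = field(default_factory=set)
    qtl_spanning_genes: set[str] = field(default_factory=set)

    def de_genes_for(self, muscle: str) -> set[str]:
        return {g for g, (ms, _) in self.de_genes.items() if muscle in ms}

    @property
    def common_de_genes(self) -> set[str]:
        out: set[str] = set()
        for g, (ms, _) in self.de_genes.items():
            if len(ms) >= 2:
                out.add(g)
        return out

    def to_json(self) -> str:
        obj = {
            "de_genes": {
                g: {"muscles": sorted(ms), "lfc": lfc}
                for g, (ms, lfc) in sorted(self.de_genes.items())
            },
            "enriched_modules": {
                m: {mus: sorted(gs) for mus, gs in per.items()}
                for m, per in sorted(self.enriched_modules.items())
            },
            "planted_regulators": sorted(self.planted_regulators),
            "planted_targets": sorted(self.planted_targets),
            "qtl_spanning_genes": sorted(self.qtl_spanning_genes),
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            de_genes={
                g: (frozenset(d["muscles"]), float(d["lfc"]))
                for g, d in obj["de_genes"].items()
            },
            enriched_modules={
                m: {mus: set(gs) for mus, gs in per.items()}
                for m, per in obj["enriched_modules"].items()
            },
            planted_regulators=set(obj["planted_regulators"]),
            planted_targets=set(obj["planted_targets"]),
            qtl_spanning_genes=set(obj["qtl_spanning_genes"]),
        )


@dataclass
class ProbeMatrix:
    """Probe x sample intensities with control flags and per-cell QC."""

    intensity: pd.DataFrame  # probes x samples, positive floats
    is_control: pd.Series  # bool per probe
    qc_pass: pd.DataFrame  # bool, same shape as intensity
    design: pd.DataFrame  # index sample -> muscle, stress, diet, animal

    def copy(self) -> "ProbeMatrix":
        return ProbeMatrix(
            self.intensity.copy(), self.is_control.copy(),
            self.qc_pass.copy(), self.design.copy(),
        )


@dataclass
class SimOutput:
    """Everything :func:`generate_all` produces."""

    probes: ProbeMatrix
    probe_map: pd.Series  # probe_id -> gene (gene probes only)
    design: pd.DataFrame
    truth: GroundTruth
    module_hits: pd.DataFrame
    interactions: pd.DataFrame
    gene_loci: pd.DataFrame
    qtls: pd.DataFrame
    annotations: pd.DataFrame


def _streams(cfg: SimConfig, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _gene_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def _assign_probes(cfg: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Distribute the non-control probes over genes, each gene >= 1 probe."""
    genes = _gene_ids(cfg)
    n_gene_probes = cfg.n_probes - cfg.n_control_probes
    lo, hi = cfg.probes_per_gene
    counts = np.full(cfg.n_genes, max(lo, 1), dtype=int)
    remaining = n_gene_probes - counts.sum()
    if remaining < 0:
        raise SimConfigError("probes_per_gene lower bound exceeds available probes")
    # spread the remainder one probe at a time over genes still below the cap
    while remaining > 0:
        open_idx = np.flatnonzero(counts < hi)
        take = min(remaining, len(open_idx))
        chosen = rng.choice(open_idx, size=take, replace=False)
        counts[chosen] += 1
        remaining -= take
    gene_of_probe = np.repeat(np.arange(cfg.n_genes), counts)
    probe_ids = [f"P{i:05d}" for i in range(1, n_gene_probes + 1)]
    return pd.Series([genes[g] for g in gene_of_probe], index=probe_ids, name="gene")


def _build_design(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    animal = 0
    for stress in cfg.stress_levels:
        for diet in cfg.diet_levels:
            for _ in range(cfg.n_animals_per_group):
                animal += 1
                for muscle in cfg.muscles:
                    sample = f"A{animal:02d}_{muscle}"
                    rows.append(
                        {"sample": sample, "animal": f"A{animal:02d}",
                         "muscle": muscle, "stress": stress, "diet": diet}
                    )
    return pd.DataFrame(rows).set_index("sample")


def _plant_de(cfg: SimConfig, rng: np.random.Generator,
              genes: list[str]) -> dict[str, tuple[frozenset[str], float]]:
    chosen = rng.choice(len(genes), size=cfg.n_de_genes, replace=False)
    de: dict[str, tuple[frozenset[str], float]] = {}
    for i, gi in enumerate(sorted(chosen)):
        u = rng.random()
        if u < cfg.frac_de_common:
            ms = frozenset(cfg.muscles)
        elif u < cfg.frac_de_common + cfg.frac_de_lt_only:
            ms = frozenset({cfg.muscles[0]})
        else:
            ms = frozenset({cfg.muscles[-1]})
        mag = rng.uniform(*cfg.lfc_range)
        sign = 1.0 if rng.random() < 0.6 else -1.0  # stress responses skew up
        de[genes[gi]] = (ms, sign * mag)
    return de


def generate_expression(
    cfg: SimConfig,
) -> tuple[ProbeMatrix, pd.Series, pd.DataFrame, GroundTruth]:
    """Generate intensities, probe->gene map, design table and ground truth.

    The planted effect is added on the log2 scale to every non-control probe
    of a DE gene, in the stressed samples of the designated muscle(s) only.
    """
    cfg.validate()
    rng_assign, rng_de, rng_noise, rng_qc = _streams(cfg, 6)[:4]

    probe_map = _assign_probes(cfg, rng_assign)
    design = _build_design(cfg)
    genes = _gene_ids(cfg)
    de = _plant_de(cfg, rng_de, genes)

    ctrl_ids = [f"CTRL{i:04d}" for i in range(1, cfg.n_control_probes + 1)]
    probe_ids = list(probe_map.index) + ctrl_ids
    is_control = pd.Series(
        [False] * len(probe_map) + [True] * len(ctrl_ids),
        index=probe_ids, name="is_control",
    )

    n_samples = len(design)
    baseline = rng_noise.uniform(6.0, 12.0, size=len(probe_ids))
    array_log = rng_noise.normal(0.0, cfg.array_effect_sd, size=n_samples)
    log2 = (
        baseline[:, None]
        + array_log[None, :]
        + rng_noise.normal(0.0, cfg.noise_sd, size=(len(probe_ids), n_samples))
    )

    stressed = design["stress"].to_numpy() == cfg.stress_levels[0]
    muscle_of = design["muscle"].to_numpy()
    gene_probe_pos = {p: i for i, p in enumerate(probe_map.index)}
    probes_by_gene = probe_map.groupby(probe_map.values).groups
    for gene, (ms, lfc) in de.items():
        rows = [gene_probe_pos[p] for p in probes_by_gene[gene]]
        cols = np.flatnonzero(stressed & np.isin(muscle_of, sorted(ms)))
        log2[np.ix_(rows, cols)] += lfc

    intensity = pd.DataFrame(
        np.exp2(log2), index=probe_ids, columns=design.index
    )
    qc = pd.DataFrame(
        rng_qc.random(intensity.shape) >= cfg.frac_probe_dropout,
        index=probe_ids, columns=design.index,
    )

    truth = GroundTruth(de_genes=de)
    pm = ProbeMatrix(intensity=intensity, is_control=is_control, qc_pass=qc,
                     design=design)
    return pm, probe_map, design, truth


def generate_module_hits(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Fabricate a promoter module-hit table over *all* array genes.

    Planted modules hit their designated target sets (all common DE genes
    plus a couple of muscle-specific ones) at certainty; every module also
    hits random genes at ``module_background_rate``.  Columns: module,
    gene, promoter_id, n_positions.
    """
    cfg.validate()
    rng = _streams(cfg, 6)[4]
    genes = _gene_ids(cfg)
    modules = [f"MOD_{i:03d}" for i in range(1, cfg.n_modules + 1)]
    planted = modules[: cfg.n_planted_modules] if truth.de_genes else []

    common = sorted(truth.common_de_genes)
    per_muscle_specific = {
        m: sorted(truth.de_genes_for(m) - truth.common_de_genes)
        for m in cfg.muscles
    }

    rows: list[tuple[str, str, str, int]] = []
    truth.enriched_modules = {}
    for mod in planted:
        targets: dict[str, set[str]] = {m: set(common) for m in cfg.muscles}
        for m in cfg.muscles:
            extra = per_muscle_specific[m]
            if extra:
                k = min(len(extra), 2)
                picked = rng.choice(extra, size=k, replace=False)
                targets[m].update(picked)
        truth.enriched_modules[mod] = targets
        for gene in sorted(set().union(*targets.values())):
            rows.append((mod, gene, f"{gene}_p1", 1 + int(rng.poisson(0.5))))

    # background hits for every module, DEG-independent
    bg = rng.random((len(modules), len(genes))) < cfg.module_background_rate
    for mi, mod in enumerate(modules):
        hit_set = {r[1] for r in rows if r[0] == mod}
        for gi in np.flatnonzero(bg[mi]):
            gene = genes[gi]
            if gene in hit_set:
                continue
            rows.append((mod, gene, f"{gene}_p1", 1))

    return pd.DataFrame(
        rows, columns=["module", "gene", "promoter_id", "n_positions"]
    ).sort_values(["module", "gene"], ignore_index=True)


def _shifted_geometric(rng: np.random.Generator, minimum: int, p: float = 0.5) -> int:
    """Heavy-tailed literature-evidence count, >= minimum."""
    return minimum + int(rng.geometric(p)) - 1


def generate_interaction_db(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Fabricate a curated-interaction edge list around the planted DE genes.

    Planted regulators point Regulation edges at several common DE genes
    (references >= 3) and carry filler relations so their total degree
    clears both the muscle-profile (>=2) and common-profile (>=5) cuts.
    Planted targets receive Expression edges from common DE genes and reach
    total degree >= 6.  Decoys each violate exactly one admission filter.
    Columns: source, target, relation_type, n_references.
    """
    cfg.validate()
    rng = _streams(cfg, 6)[5]
    common = sorted(truth.common_de_genes)
    rows: list[tuple[str, str, str, int]] = []

    def seeds_for(n: int) -> list[str]:
        if not common:
            return []
        k = min(n, len(common))
        return list(rng.choice(common, size=k, replace=False))

    regulators = [f"REG{i:02d}" for i in range(1, cfg.n_regulators + 1)]
    targets = [f"TGT{i:02d}" for i in range(1, cfg.n_targets + 1)]
    if not truth.de_genes:
        regulators, targets = [], []

    filler = 0
    for reg in regulators:
        linked = seeds_for(6)
        for g in linked:
            rows.append((reg, g, "Regulation", _shifted_geometric(rng, 3)))
        while len(linked) < 6:  # degree floor clears both profiles
            filler += 1
            rows.append((reg, f"FIL{filler:03d}", "Regulation", 1))
            linked.append(f"FIL{filler:03d}")
    for tgt in targets:
        linked = seeds_for(6)
        for g in linked:
            rows.append((g, tgt, "Expression", _shifted_geometric(rng, 3)))
        while len(linked) < 6:
            filler += 1
            rows.append((f"FIL{filler:03d}", tgt, "Expression", 1))
            linked.append(f"FIL{filler:03d}")

    truth.planted_regulators = set(regulators)
    truth.planted_targets = set(targets)

    # decoys: each fails exactly one admission rule
    decoy_kinds = ["reg_low_refs", "reg_one_seed", "tgt_low_degree",
                   "tgt_low_refs", "tgt_one_seed", "reg_wrong_type"]
    for i in range(cfg.n_decoys):
        kind = decoy_kinds[i % len(decoy_kinds)]
        name = f"DECOY{i + 1:02d}"
        linked = seeds_for(3)
        if not linked:
            continue
        if kind == "reg_low_refs":
            for g in linked:
                rows.append((name, g, "Regulation", 2))
            for _ in range(4):
                filler += 1
                rows.append((name, f"FIL{filler:03d}", "Regulation", 1))
        elif kind == "reg_one_seed":
            rows.append((name, linked[0], "Regulation", 5))
            for _ in range(5):
                filler += 1
                rows.append((name, f"FIL{filler:03d}", "Regulation", 2))
        elif kind == "tgt_low_degree":
            for g in linked[:2]:
                rows.append((g, name, "Expression", 4))
            # total degree stays below the target floor of 6
        elif kind == "tgt_low_refs":
            for g in linked:
                rows.append((g, name, "Expression", 2))
            for _ in range(4):
                filler += 1
                rows.append((f"FIL{filler:03d}", name, "Expression", 1))
        elif kind == "tgt_one_seed":
            rows.append((linked[0], name, "Expression", 5))
            for _ in range(6):
                filler += 1
                rows.append((f"FIL{filler:03d}", name, "Expression", 1))
        elif kind == "reg_wrong_type":
            # touches seeds only through Expression edges: never a regulator
            for g in linked:
                rows.append((name, g, "Expression", 5))

    # a few inter-DEG edges so extracted subgraphs are non-trivial
    if len(common) >= 2:
        for _ in range(min(5, len(common))):
            a, b = rng.choice(common, size=2, replace=False)
            if a != b:
                rows.append((a, b, "Regulation", _shifted_geometric(rng, 1)))

    return pd.DataFrame(
        rows, columns=["source", "target", "relation_type", "n_references"]
    )


def generate_loci_and_qtls(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene loci (0-based half-open) and QTL intervals with trait labels.

    Each QTL-spanning gene sits fully inside one meat-quality QTL; all
    other gene loci are placed clear of every QTL, and a handful of
    boundary-straddling loci exercise the strict-containment rule.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[6])
    genes = _gene_ids(cfg)
    de_genes = sorted(truth.de_genes)
    spanning = sorted(
        rng.choice(de_genes, size=min(cfg.n_qtl_genes, len(de_genes)), replace=False)
    ) if de_genes else []
    truth.qtl_spanning_genes = set(spanning)

    qtl_rows, locus_rows = [], []
    qtl_zone = 50_000_000  # QTLs live at >= 50 Mb; other genes below 40 Mb
    for i, gene in enumerate(spanning):
        chrom = str((i % 29) + 1)
        q_start = qtl_zone + (i // 29) * 5_000_000
        q_end = q_start + 2_000_000
        g_start = q_start + int(rng.integers(100_000, 1_500_000))
        g_end = g_start + int(rng.integers(5_000, 300_000))
        trait = MEAT_QUALITY_TRAITS[i % len(MEAT_QUALITY_TRAITS)]
        qtl_rows.append(
            {"qtl_id": f"QTL{i + 1:03d}", "chrom": chrom, "start": q_start,
             "end": q_end, "trait": trait, "trait_class": "meat-quality"}
        )
        locus_rows.append({"gene": gene, "chrom": chrom, "start": g_start, "end": g_end})

    # a non-meat-quality QTL, to exercise trait-class filtering
    qtl_rows.append(
        {"qtl_id": "QTL900", "chrom": "1", "start": qtl_zone + 20_000_000,
         "end": qtl_zone + 22_000_000, "trait": FATTY_ACID_TRAITS[0],
         "trait_class": "fatty-acid"}
    )

    placed = set(spanning)
    for gi, gene in enumerate(genes):
        if gene in placed:
            continue
        chrom = str((gi % 29) + 1)
        start = int(rng.integers(1_000, 39_000_000))
        end = start + int(rng.integers(5_000, 300_000))
        locus_rows.append({"gene": gene, "chrom": chrom, "start": start, "end": end})

    # boundary straddlers: overlap a QTL but are not contained
    for j, q in enumerate(qtl_rows[: min(3, len(qtl_rows))]):
        locus_rows.append(
            {"gene": f"STRADDLE{j + 1}", "chrom": q["chrom"],
             "start": q["start"] - 50_000, "end": q["start"] + 50_000}
        )

    loci = pd.DataFrame(locus_rows, columns=["gene", "chrom", "start", "end"])
    qtls = pd.DataFrame(
        qtl_rows, columns=["qtl_id", "chrom", "start", "end", "trait", "trait_class"]
    )
    return loci, qtls


def generate_annotations(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene -> GO-style term table with one planted stress term.

    The planted term annotates every planted DE gene plus a
    ``go_background_rate`` fraction of the remaining genes; all other terms
    annotate random gene sets.  Columns: gene, term_id, term_name, namespace.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    genes = np.array(_gene_ids(cfg))
    rows: list[tuple[str, str, str, str]] = []

    de_genes = sorted(truth.de_genes)
    if de_genes:
        term_genes = set(de_genes)
        others = [g for g in genes if g not in term_genes]
        bg = rng.random(len(others)) < cfg.go_background_rate
        term_genes.update(np.array(others)[bg])
        for g in sorted(term_genes):
            rows.append((g, "GO:9990001", "response to stress (planted)", "BP"))

    for t in range(cfg.n_go_terms):
        term_id = f"GO:{1000001 + t}"
        ns = "BP" if t % 2 == 0 else "MF"
        size = int(np.clip(rng.lognormal(3.5, 0.8), 5, len(genes) // 4))
        members = rng.choice(genes, size=size, replace=False)
        for g in sorted(members):
            rows.append((g, term_id, f"random process {t + 1}", ns))

    return pd.DataFrame(rows, columns=["gene", "term_id", "term_name", "namespace"])


def generate_all(cfg: SimConfig) -> SimOutput:
    """Run every generator off one seed and return the full bundle."""
    pm, probe_map, design, truth = generate_expression(cfg)
    hits = generate_module_hits(cfg, truth)
    edges = generate_interaction_db(cfg, truth)
    loci, qtls = generate_loci_and_qtls(cfg, truth)
    ann = generate_annotations(cfg, truth)
    return SimOutput(pm, probe_map, design, truth, hits, edges, loci, qtls, ann)


def write_all(out: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns path per artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    probe_tsv = out.probes.intensity.copy()
    probe_tsv.insert(0, "is_control", out.probes.is_control.astype(int))
    paths["probe_matrix"] = outdir / "probe_matrix.tsv"
    probe_tsv.to_csv(paths["probe_matrix"], sep="\t", index_label="probe_id",
                     float_format="%.6f")

    qc = out.probes.qc_pass.astype(int)
    paths["qc_flags"] = outdir / "qc_flags.tsv"
    qc.to_csv(paths["qc_flags"], sep="\t", index_label="probe_id")

    paths["probe_map"] = outdir / "probe_map.tsv"
    out.probe_map.rename("gene").to_csv(paths["probe_map"], sep="\t",
                                        index_label="probe_id")

    paths["design"] = outdir / "design.tsv"
    out.design.to_csv(paths["design"], sep="\t", index_label="sample")

    paths["module_hits"] = outdir / "module_hits.tsv"
    out.module_hits.to_csv(paths["module_hits"], sep="\t", index=False)

    paths["interactions"] = outdir / "interactions.tsv"
    out.interactions.to_csv(paths["interactions"], sep="\t", index=False)

    paths["gene_loci"] = outdir / "gene_loci.bed"
    bed = out.gene_loci[["chrom", "start", "end", "gene"]]
    bed.to_csv(paths["gene_loci"], sep="\t", index=False, header=False)

    paths["qtls"] = outdir / "qtls.tsv"
    qtls = out.qtls.copy()
    qtls["coord_convention"] = "zero_half_open"
    qtls.to_csv(paths["qtls"], sep="\t", index=False)

    paths["annotations"] = outdir / "annotations.tsv"
    out.annotations.to_csv(paths["annotations"], sep="\t", index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(out.truth.to_json() + "\n")
    return paths


def config_to_yaml_dict(cfg: SimConfig) -> dict:
    """Plain dict form of a config, for YAML round-tripping in the CLI."""
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(d: dict) -> SimConfig:
    fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise SimConfigError(f"unknown simulation config field: {k}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg
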