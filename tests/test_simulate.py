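"""Generator contracts: planted signal, determinism, config validation."""

import numpy as np
import pytest
from scipy import stats as sps

import stressnet.simulate as sim


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_control_probes": 700}, "n_control_probes"),
            ({"n_de_genes": 500}, "n_de_genes"),
            ({"lfc_range": (0.0, 1.0)}, "lfc_range"),
            ({"noise_sd": 0.0}, "noise_sd"),
            ({"frac_probe_dropout": 1.0}, "frac_probe_dropout"),
            ({"probes_per_gene": (3, 2)}, "probes_per_gene"),
        ],
    )
    def test_invalid_config_names_offending_field(self, small_cfg, kwargs, field):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, **kwargs)
        with pytest.raises(sim.SimConfigError, match=field):
            cfg.validate()


class TestExpression:
    def test_default_dimensions_match_platform(self, default_sim):
        """10,064 probes of which 1,614 are flagged control."""
        pm = default_sim.probes
        assert pm.intensity.shape[0] == 10_064
        assert int(pm.is_control.sum()) == 1_614
        assert pm.intensity.shape[1] == 64  # 32 animals x 2 muscles
        assert (pm.intensity.to_numpy() > 0).all()

    def test_every_gene_has_a_probe(self, default_sim):
        assert default_sim.probe_map.nunique() == 4_210

    def test_no_planted_effect_means_equal_group_means(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(
            small_cfg, n_de_genes=0, noise_sd=1e-12, array_effect_sd=0.0,
            frac_probe_dropout=0.0, n_qtl_genes=0,
        )
        pm, _, design, _ = sim.generate_expression(cfg)
        log2 = np.log2(pm.intensity)
        stressed = design["stress"] == "stress"
        diff = log2.loc[:, stressed.to_numpy()].mean(axis=1) - log2.loc[
            :, (~stressed).to_numpy()].mean(axis=1)
        assert np.allclose(diff, 0.0, atol=1e-9)

    def test_control_probes_carry_no_group_effect(self, small_sim, small_cfg):
        pm, design = small_sim.probes, small_sim.design
        log2 = np.log2(pm.intensity.loc[pm.is_control])
        stressed = (design["stress"] == "stress").to_numpy()
        diff = log2.loc[:, stressed].mean(axis=1) - log2.loc[:, ~stressed].mean(axis=1)
        # per-probe mean difference is pure noise: sd = noise_sd * sqrt(2/n)
        se = small_cfg.noise_sd * np.sqrt(2 / stressed.sum())
        assert np.abs(diff).max() < 5 * se

    def test_planted_effect_recovered_at_analytic_rate(self):
        """Mean stress-limited log2 ratio of a +1.0 planted gene matches the
        generative model's analytic mean within Monte-Carlo error."""
        diffs = []
        for seed in range(300):
            cfg = sim.SimConfig(
                n_probes=40, n_control_probes=10, n_genes=15, n_de_genes=1,
                frac_de_common=0.0, frac_de_lt_only=1.0, muscles=("LT",),
                lfc_range=(1.0, 1.0), noise_sd=0.2, array_effect_sd=0.0,
                frac_probe_dropout=0.0, n_animals_per_group=8,
                n_qtl_genes=1, seed=seed,
            )
            pm, pmap, design, truth = sim.generate_expression(cfg)
            (gene,) = truth.de_genes
            lfc = truth.de_genes[gene][1]
            probes = pmap.index[pmap == gene]
            log2 = np.log2(pm.intensity.loc[probes])
            stressed = (design["stress"] == "stress").to_numpy()
            d = (log2.loc[:, stressed].mean(axis=1)
                 - log2.loc[:, ~stressed].mean(axis=1)).mean()
            diffs.append(d - lfc)  # sign of the plant is random
        # each diff ~ N(0, noise_sd^2 * 2/16 / n_probes); the 300-rep mean
        # should sit within 4 standard errors of zero
        se = 0.2 * np.sqrt(2 / 16) / np.sqrt(300)
        assert abs(np.mean(diffs)) < 4 * se

    def test_identical_seed_gives_byte_identical_outputs(self, small_cfg, tmp_path):
        a = sim.generate_all(small_cfg)
        b = sim.generate_all(small_cfg)
        pa = sim.write_all(a, tmp_path / "a")
        pb = sim.write_all(b, tmp_path / "b")
        assert set(pa) == set(pb)
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes(), name


class TestModuleHits:
    def test_no_background_yields_exactly_planted_hits(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, module_background_rate=0.0)
        _, _, _, truth = sim.generate_expression(cfg)
        hits = sim.generate_module_hits(cfg, truth)
        for mod, per_muscle in truth.enriched_modules.items():
            expected = set().union(*per_muscle.values())
            assert set(hits.loc[hits["module"] == mod, "gene"]) == expected
        planted = set(truth.enriched_modules)
        assert set(hits["module"]) == planted

    def test_empty_truth_gives_background_only(self, small_cfg):
        truth = sim.GroundTruth()
        hits = sim.generate_module_hits(small_cfg, truth)
        assert truth.enriched_modules == {}
        # background rate ~1%: every module hits only a few genes
        per_mod = hits.groupby("module").size()
        assert per_mod.max() < 0.05 * small_cfg.n_genes

    def test_background_count_within_binomial_interval(self, small_cfg):
        """Pooled background hits across seeds follow Binomial(n, rate)."""
        import dataclasses

        total, trials = 0, 0
        for seed in range(20):
            cfg = dataclasses.replace(small_cfg, seed=seed, n_de_genes=0)
            _, _, _, truth = sim.generate_expression(cfg)
            hits = sim.generate_module_hits(cfg, truth)
            total += len(hits)
            trials += cfg.n_modules * cfg.n_genes
        lo, hi = sps.binom.interval(0.999, trials, small_cfg.module_background_rate)
        assert lo <= total <= hi

    def test_planted_hits_have_promoter_and_positions(self, small_sim):
        hits = small_sim.module_hits
        assert (hits["n_positions"] >= 1).all()
        assert hits["promoter_id"].str.len().gt(0).all()
        assert not hits.duplicated(["module", "gene", "promoter_id"]).any()


class TestInteractionDB:
    def test_planted_regulators_by_construction(self, small_sim):
        edges, truth = small_sim.interactions, small_sim.truth
        common = truth.common_de_genes
        for reg in truth.planted_regulators:
            sub = edges[(edges["source"] == reg)
                        & (edges["relation_type"] == "Regulation")]
            seed_edges = sub[sub["target"].isin(common)]
            assert seed_edges["target"].nunique() >= 2
            assert seed_edges["n_references"].max() >= 3
            incident = ((edges["source"] == reg) | (edges["target"] == reg)).sum()
            assert incident >= 5

    def test_planted_targets_by_construction(self, small_sim):
        edges, truth = small_sim.interactions, small_sim.truth
        common = truth.common_de_genes
        for tgt in truth.planted_targets:
            sub = edges[(edges["target"] == tgt)
                        & (edges["relation_type"] == "Expression")]
            seed_edges = sub[sub["source"].isin(common)]
            assert seed_edges["source"].nunique() >= 2
            assert seed_edges["n_references"].max() >= 3
            incident = ((edges["source"] == tgt) | (edges["target"] == tgt)).sum()
            assert incident >= 6

    def test_planted_nodes_are_not_de_genes(self, small_sim):
        truth = small_sim.truth
        de = set(truth.de_genes)
        assert not (truth.planted_regulators & de)
        assert not (truth.planted_targets & de)

    def test_empty_truth_gives_decoys_only(self, small_cfg):
        edges = sim.generate_interaction_db(small_cfg, sim.GroundTruth())
        nodes = set(edges["source"]) | set(edges["target"])
        assert not any(n.startswith(("REG", "TGT")) for n in nodes)


class TestLociAndQtls:
    def test_spanning_genes_contained_in_meat_quality_qtl(self, small_sim):
        loci = small_sim.gene_loci.set_index("gene")
        qtls = small_sim.qtls
        for gene in small_sim.truth.qtl_spanning_genes:
            g = loci.loc[gene]
            match = qtls[
                (qtls["chrom"] == g["chrom"])
                & (qtls["start"] <= g["start"]) & (g["end"] <= qtls["end"])
                & (qtls["trait_class"] == "meat-quality")
            ]
            assert len(match) >= 1, gene

    def test_other_genes_never_fully_contained(self, small_sim):
        truth = small_sim.truth
        loci = small_sim.gene_loci
        qtls = small_sim.qtls
        others = loci[~loci["gene"].isin(truth.qtl_spanning_genes)]
        merged = others.merge(qtls, on="chrom", suffixes=("_g", "_q"))
        contained = merged[(merged["start_q"] <= merged["start_g"])
                           & (merged["end_g"] <= merged["end_q"])]
        assert contained.empty

    def test_straddlers_overlap_but_are_not_contained(self, small_sim):
        loci = small_sim.gene_loci
        straddle = loci[loci["gene"].str.startswith("STRADDLE")]
        assert len(straddle) >= 1
        merged = straddle.merge(small_sim.qtls, on="chrom", suffixes=("_g", "_q"))
        overlap = merged[(merged["start_g"] < merged["end_q"])
                         & (merged["start_q"] < merged["end_g"])]
        assert len(overlap) >= 1


class TestGroundTruthRoundTrip:
    def test_json_round_trip(self, small_sim):
        truth = small_sim.truth
        back = sim.GroundTruth.from_json(truth.to_json())
        assert back.de_genes == truth.de_genes
        assert back.enriched_modules == truth.enriched_modules
        assert back.planted_regulators == truth.planted_regulators
        assert back.qtl_spanning_genes == truth.qtl_spanning_genes
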