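"""Linear models, variance moderation, BH adjustment and gene calls."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats as sps

from stressnet import diffexpr
from stressnet.diffexpr import (
    DesignError,
    DesignSpec,
    adjust_bh,
    call_genes,
    estimate_prior,
    fit_linear_models,
    moderate,
    trigamma_inverse,
)

from conftest import make_norm, two_group_design


class TestFitLinearModels:
    def test_balanced_two_group_effect_is_difference_of_means(self):
        design = two_group_design(8)
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, size=(20, 16))
        norm = make_norm(y, design)
        fit = fit_linear_models(norm, DesignSpec(muscle="LT"))
        stressed = (design["stress"] == "stress").to_numpy()
        expected = y[:, stressed].mean(axis=1) - y[:, ~stressed].mean(axis=1)
        np.testing.assert_allclose(fit["log2_ratio"], expected, atol=1e-10)

    def test_constant_probe_has_zero_variance_and_effect(self):
        design = two_group_design(8)
        y = np.vstack([np.full(16, 3.0), np.random.default_rng(1).normal(size=16)])
        fit = fit_linear_models(make_norm(y, design), DesignSpec(muscle="LT"))
        assert fit["s2"].iloc[0] == pytest.approx(0.0, abs=1e-18)
        assert fit["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_effect_estimate_sampling_distribution(self):
        """Estimates of a planted 1.0 effect (noise 0.2, 16/group) fall
        within +-0.15 in at least 95% of replicates — each probe row is an
        independent replicate of the same experiment."""
        design = two_group_design(16)  # 16 per stress group
        rng = np.random.default_rng(42)
        n_rep = 1_000
        y = rng.normal(0, 0.2, size=(n_rep, 32))
        stressed = (design["stress"] == "stress").to_numpy()
        y[:, stressed] += 1.0
        fit = fit_linear_models(make_norm(y, design), DesignSpec(muscle="LT"))
        frac_ok = np.mean(np.abs(fit["log2_ratio"] - 1.0) <= 0.15)
        # analytic: se = 0.2*sqrt(2/16) = 0.0707 -> P(|err|<=0.15) ~ 0.966
        assert frac_ok >= 0.95

    def test_rank_deficient_design_reports_confounded_factors(self):
        design = two_group_design(8)
        design["diet"] = np.where(design["stress"] == "stress", "control", "EP")
        y = np.random.default_rng(2).normal(size=(12, 16))
        with pytest.raises(DesignError, match="confounded"):
            fit_linear_models(make_norm(y, design), DesignSpec(muscle="LT"))

    def test_unknown_muscle_raises(self):
        design = two_group_design(8)
        y = np.zeros((3, 16))
        with pytest.raises(DesignError, match="no samples"):
            fit_linear_models(make_norm(y, design), DesignSpec(muscle="XX"))


class TestModeration:
    @pytest.fixture()
    def fitted(self):
        design = two_group_design(8)
        rng = np.random.default_rng(3)
        sd = np.sqrt(sps.invgamma.rvs(4, scale=0.3, size=200, random_state=rng))
        y = rng.normal(0, sd[:, None], size=(200, 16))
        return fit_linear_models(make_norm(y, design), DesignSpec(muscle="LT"))

    def test_d0_zero_recovers_ordinary_t(self, fitted):
        out = moderate(fitted, d0=0.0, s0_sq=1.0)
        t_ord = fitted["log2_ratio"] / np.sqrt(
            fitted["s2"] * fitted["v_unscaled"])
        np.testing.assert_allclose(out["t_mod"], t_ord, atol=1e-10)
        assert (out["df_total"] == fitted["df_residual"]).all()

    def test_d0_infinite_shrinks_every_variance_to_prior(self, fitted):
        out = moderate(fitted, d0=np.inf, s0_sq=0.25)
        z = fitted["log2_ratio"] / np.sqrt(0.25 * fitted["v_unscaled"])
        np.testing.assert_allclose(out["t_mod"], z, rtol=1e-4)

    def test_prior_estimate_recovers_generating_parameters(self):
        # variances ~ s0^2 * d0 / chi2_d0 with d0=8, s0^2=0.3; sample
        # variances then scaled-chi2 around them, df=12
        rng = np.random.default_rng(7)
        d0_true, s0_true, df = 8.0, 0.3, 12
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=20_000)
        s2 = sigma2 * rng.chisquare(df, size=20_000) / df
        d0, s0 = estimate_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_homogeneous_variances_clamp_prior_df(self):
        fit = pd.DataFrame(
            {
                "log2_ratio": np.zeros(50),
                "s2": np.full(50, 0.04),
                "df_residual": np.full(50, 12.0),
                "v_unscaled": np.full(50, 0.125),
            }
        )
        out = moderate(fit)
        assert out["d0"].iloc[0] == diffexpr.D0_CLAMP

    def test_all_zero_variances_is_an_error(self):
        fit = pd.DataFrame(
            {
                "log2_ratio": np.zeros(20),
                "s2": np.zeros(20),
                "df_residual": np.full(20, 12.0),
                "v_unscaled": np.full(20, 0.125),
            }
        )
        with pytest.raises(ValueError, match="no variance information"):
            moderate(fit)

    def test_trigamma_inverse_round_trip(self):
        for x in (0.01, 0.5, 1.0, 5.0, 42.0, 1e4):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_matches_limma_reference(self, tmp_path):
        """Moderated t, p, and the estimated prior agree with the
        R/limma implementation on the same data and contrast."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available; limma cross-check cannot run")
        design = two_group_design(8)
        rng = np.random.default_rng(42)
        sd = np.sqrt(sps.invgamma.rvs(5, scale=0.5, size=60, random_state=rng))
        y = rng.normal(0, sd[:, None], size=(60, 16))
        y[:5, (design["stress"] == "stress").to_numpy()] += 1.0
        fit = fit_linear_models(make_norm(y, design), DesignSpec(muscle="LT"))
        out = moderate(fit)

        np.savetxt(tmp_path / "y.tsv", y, delimiter="\t")
        design.to_csv(tmp_path / "design.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            Y <- as.matrix(read.table(file.path(args[1], "y.tsv"), sep="\\t"))
            des <- read.table(file.path(args[1], "design.tsv"), sep="\\t",
                              header=TRUE, row.names=1)
            stress <- factor(des$stress, levels=c("limited", "stress"))
            diet <- factor(des$diet, levels=c("control", "EP"))
            X <- model.matrix(~ stress * diet)
            fit <- lmFit(Y, X)
            eb <- eBayes(contrasts.fit(fit, c(0, 1, 0, 0.5)))
            out <- data.frame(effect=eb$coefficients[,1], t=eb$t[,1],
                              p=eb$p.value[,1], d0=eb$df.prior, s0=eb$s2.prior)
            write.table(out, file.path(args[1], "limma.tsv"), sep="\\t",
                        quote=FALSE, row.names=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R"), str(tmp_path)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        np.testing.assert_allclose(out["log2_ratio"], ref["effect"], atol=1e-8)
        np.testing.assert_allclose(out["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(out["p"], ref["p"], rtol=1e-6)
        assert out["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert out["s0_sq"].iloc[0] == pytest.approx(ref["s0"].iloc[0], rel=1e-4)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert (adjust_bh(np.ones(10)) == 1.0).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            adjust_bh(bad)


class TestCallGenes:
    def make_stats(self, ratios, p_adj):
        probes = [f"P{i}" for i in range(len(ratios))]
        return (
            pd.DataFrame({"log2_ratio": ratios, "p_adj": p_adj}, index=probes),
            pd.Series(["GENE"] * len(ratios), index=probes),
        )

    def test_four_of_five_significant_all_up_is_deg(self):
        stats, pmap = self.make_stats(
            [0.5, 0.6, 0.4, 0.7, 0.2], [0.01, 0.02, 0.05, 0.09, 0.5]
        )
        calls = call_genes(stats, pmap)
        assert bool(calls.loc["GENE", "is_deg"])  # 0.8 >= 0.8 boundary
        assert calls.loc["GENE", "direction"] == "up"

    def test_one_discordant_ratio_blocks_the_call(self):
        stats, pmap = self.make_stats(
            [0.5, 0.6, 0.4, -0.1, 0.2], [0.01, 0.02, 0.05, 0.09, 0.5]
        )
        calls = call_genes(stats, pmap)
        assert not bool(calls.loc["GENE", "is_deg"])
        assert calls.loc["GENE", "direction"] == ""

    def test_two_of_three_significant_is_below_threshold(self):
        stats, pmap = self.make_stats([0.5, 0.6, 0.4], [0.01, 0.02, 0.5])
        calls = call_genes(stats, pmap)
        assert not bool(calls.loc["GENE", "is_deg"])  # 0.667 < 0.8

    def test_gene_effect_is_median_and_fold_change_signed(self):
        stats, pmap = self.make_stats([-1.0, -2.0, -1.5], [0.01, 0.01, 0.01])
        calls = call_genes(stats, pmap)
        assert calls.loc["GENE", "gene_log2_ratio"] == pytest.approx(-1.5)
        assert calls.loc["GENE", "fold_change"] == pytest.approx(-(2**1.5))
        assert calls.loc["GENE", "direction"] == "down"

    def test_duplicate_probe_mapping_raises(self):
        stats, _ = self.make_stats([0.5, 0.6], [0.01, 0.02])
        pmap = pd.Series(["A", "B"], index=["P0", "P0"])
        with pytest.raises(ValueError, match="not functional"):
            call_genes(stats, pmap)

    def test_alpha_monotonicity_never_grows_deg_set(self, small_sim):
        from stressnet import preprocess

        norm = preprocess.normalize(preprocess.qc_filter(small_sim.probes))
        fit = fit_linear_models(norm, DesignSpec(muscle="LT"))
        stats = moderate(fit)
        previous = None
        for alpha in (0.20, 0.10, 0.05, 0.01):
            degs = set(
                call_genes(stats, small_sim.probe_map, alpha=alpha).query(
                    "is_deg").index
            )
            if previous is not None:
                assert degs <= previous
            previous = degs


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
)
def test_bh_is_monotone_capped_and_dominates_p(p):
    adj = adjust_bh(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj <= 1.0).all()
    assert (adj >= np.asarray(p) - 1e-12).all()
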