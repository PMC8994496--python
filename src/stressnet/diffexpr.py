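"""Per-probe linear models, empirical-Bayes moderated t, and gene calls.

Each muscle is analysed separately.  Every probe gets an ordinary
least-squares fit of its log2 values on stress, diet and (optionally)
their interaction; the contrast of interest is the stress main effect
(stressed minus limited-stress), averaged over diets.

Variances are then moderated: the per-probe residual variances s_g^2 with
d_g residual degrees of freedom are assumed to follow a scaled F prior
(s0^2, d0), estimated by moment-matching the log sample variances against
the theoretical scaled-F distribution via digamma/trigamma identities.
The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields a moderated t with d0 + d_g degrees of freedom.  Benjamini-Hochberg
adjustment is applied across probes, and genes are called differentially
expressed when at least 80% of their probes are significant at adjusted
p < 0.10 AND every probe ratio points the same way (all up or all down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

#: prior df beyond this are treated as effectively infinite (normal reference)
D0_CLAMP = 1e6


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Which samples to fit and which model to fit them with."""

    muscle: str | None = None
    stress_factor: str = "stress"
    stress_levels: tuple[str, str] = ("stress", "limited")  # (test, reference)
    diet_factor: str = "diet"
    interaction: bool = True
    covariates: tuple[str, ...] = ()


def build_design_matrix(
    design: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Treatment-coded model matrix and the stress main-effect contrast.

    With the interaction present, the contrast averages the stress effect
    over the two diets: c = stress + 0.5 * stress:diet.
    """
    for col in (spec.stress_factor, spec.diet_factor, *spec.covariates):
        if col not in design.columns:
            raise DesignError(f"design table lacks column '{col}'")
    levels = set(design[spec.stress_factor])
    if not levels == set(spec.stress_levels):
        raise DesignError(
            f"stress factor levels {sorted(levels)} != expected {sorted(spec.stress_levels)}"
        )

    stress = (design[spec.stress_factor] == spec.stress_levels[0]).to_numpy(float)
    diet_levels = sorted(set(design[spec.diet_factor]))
    if len(diet_levels) != 2:
        raise DesignError(f"diet factor must have two levels, got {diet_levels}")
    diet = (design[spec.diet_factor] == diet_levels[1]).to_numpy(float)

    cols = [np.ones(len(design)), stress, diet]
    names = ["intercept", "stress", "diet"]
    contrast = [0.0, 1.0, 0.0]
    if spec.interaction:
        cols.append(stress * diet)
        names.append("stress:diet")
        contrast.append(0.5)
    for cov in spec.covariates:
        v = design[cov]
        if v.dtype.kind in "OUS":
            lv = sorted(set(v))
            for level in lv[1:]:
                cols.append((v == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
                contrast.append(0.0)
        else:
            cols.append(v.to_numpy(float))
            names.append(cov)
            contrast.append(0.0)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        confounded = _confounded_columns(X, names)
        raise DesignError(
            "rank-deficient design; confounded terms: " + ", ".join(confounded)
        )
    return X, np.asarray(contrast), names


def _confounded_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.allclose(others @ beta, X[:, j], atol=1e-8):
            bad.append(names[j])
    return bad or names[1:]


def fit_linear_models(norm: NormalizedMatrix, spec: DesignSpec) -> pd.DataFrame:
    """OLS per probe; returns effect, residual variance, df and the
    unscaled contrast variance c'(X'X)^-1 c."""
    design = norm.design
    if spec.muscle is not None:
        design = design[design["muscle"] == spec.muscle]
        if design.empty:
            raise DesignError(f"no samples for muscle '{spec.muscle}'")
    Y = norm.log2[design.index].to_numpy()
    X, c, _ = build_design_matrix(design, spec)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DesignError(f"not enough samples: n={n}, parameters={p}")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T  # probes x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    effect = beta @ c
    v_unscaled = float(c @ xtx_inv @ c)

    return pd.DataFrame(
        {
            "probe_id": norm.log2.index,
            "log2_ratio": effect,
            "s2": s2,
            "df_residual": df_resid,
            "v_unscaled": v_unscaled,
        }
    ).set_index("probe_id")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing, convex-in-1/x shape of trigamma; the
    iteration is on x with the update written in terms of 1/trigamma to
    keep it stable over many orders of magnitude.
    """
    if y <= 0:
        raise ValueError(f"trigamma inverse requires y > 0, got {y}")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F variance prior.

    Works on log variances: if s^2 | sigma^2 ~ sigma^2 chi^2_d / d and
    1/sigma^2 ~ chi^2_d0 / (d0 s0^2), then
    e = log s^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) over trigamma(d/2).  Probes with zero sample variance
    carry no information about the prior and are excluded.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("no variance information: all residual variances are zero")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 > D0_CLAMP:
            d0 = D0_CLAMP
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # variances essentially homogeneous: infinite prior df (clamped)
        d0 = D0_CLAMP
        s0_sq = float(np.exp(emean))
    return float(d0), s0_sq


def moderate(fit: pd.DataFrame, d0: float | None = None,
             s0_sq: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics and BH-adjusted p-values.

    ``d0``/``s0_sq`` may be supplied (e.g. d0=0 recovers the ordinary t);
    by default both are estimated from the data.  Needs >= 10 probes for a
    stable prior estimate.
    """
    s2 = fit["s2"].to_numpy(float)
    df = fit["df_residual"].to_numpy(float)
    v = fit["v_unscaled"].to_numpy(float)
    effect = fit["log2_ratio"].to_numpy(float)

    if d0 is None or s0_sq is None:
        if len(fit) < 10:
            raise ValueError(
                f"need >= 10 probes to estimate the variance prior, got {len(fit)}"
            )
        est_d0, est_s0 = estimate_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if d0 < 0:
        raise ValueError(f"prior df must be >= 0, got {d0}")

    if np.isinf(d0):
        d0 = D0_CLAMP
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / np.sqrt(s2_post * v)
    t_mod = np.where(s2_post * v == 0, 0.0, t_mod)
    df_total = np.minimum(d0 + df, 1e9)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = fit.copy()
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p"] = p
    out["p_adj"] = adjust_bh(p)
    out["d0"] = d0
    out["s0_sq"] = s0_sq
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneCallParams:
    alpha: float = 0.10  # adjusted-p threshold, strict <
    min_frac: float = 0.80  # fraction of significant probes, inclusive >=


def call_genes(
    stats_df: pd.DataFrame,
    probe_map: pd.Series,
    alpha: float = 0.10,
    min_frac: float = 0.80,
    muscle: str | None = None,
) -> pd.DataFrame:
    """Probe-consistency gene calls.

    A gene is differentially expressed iff (i) at least ``min_frac`` of its
    probes have adjusted p < ``alpha`` and (ii) every probe log2 ratio has
    the same strict sign.  The gene-level effect is the median probe log2
    ratio; the fold change is reported on the linear scale with a sign
    convention (negative = down-regulated: -2^|median ratio|).
    """
    dup = probe_map.index[probe_map.index.duplicated()]
    if len(dup):
        raise ValueError(
            f"probe->gene mapping is not functional; duplicated probes: "
            f"{', '.join(map(str, dup[:5]))}"
        )
    missing = stats_df.index.difference(probe_map.index)
    if len(missing):
        raise ValueError(
            f"probes without gene mapping: {', '.join(map(str, missing[:5]))}"
        )

    df = pd.DataFrame(
        {
            "gene": probe_map.reindex(stats_df.index).to_numpy(),
            "sig": (stats_df["p_adj"] < alpha).to_numpy(),
            "ratio": stats_df["log2_ratio"].to_numpy(),
        },
        index=stats_df.index,
    )
    g = df.groupby("gene", sort=True)
    agg = g.agg(
        n_probes=("ratio", "size"),
        n_significant=("sig", "sum"),
        gene_log2_ratio=("ratio", "median"),
        min_ratio=("ratio", "min"),
        max_ratio=("ratio", "max"),
    )
    agg["frac_significant"] = agg["n_significant"] / agg["n_probes"]
    agg["sign_consistent"] = (agg["min_ratio"] > 0) | (agg["max_ratio"] < 0)
    agg["direction"] = np.where(
        agg["sign_consistent"], np.where(agg["min_ratio"] > 0, "up", "down"), ""
    )
    glr = agg["gene_log2_ratio"].to_numpy()
    agg["fold_change"] = np.where(glr >= 0, 2.0**glr, -(2.0 ** (-glr)))
    agg["is_deg"] = (agg["frac_significant"] >= min_frac) & agg["sign_consistent"]
    agg["muscle"] = muscle if muscle is not None else ""
    agg = agg.drop(columns=["min_ratio", "max_ratio"])
    return agg[
        [
            "muscle", "n_probes", "n_significant", "frac_significant",
            "sign_consistent", "direction", "gene_log2_ratio", "fold_change",
            "is_deg",
        ]
    ]


def deg_set(calls: pd.DataFrame) -> set[str]:
    """Convenience: genes flagged differentially expressed."""
    return set(calls.index[calls["is_deg"]])
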