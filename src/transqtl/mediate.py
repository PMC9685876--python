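"""Causal mediation of a SNP's trans effect through a cis gene.

For a (SNP g, cis gene M, trans gene Y) triple the linear structural model is

    M = a*g + covariates + error          (mediator model)
    Y = c'*g + b*M + covariates + error   (outcome model)

with no exposure-mediator interaction. Inference is quasi-Bayesian Monte
Carlo: coefficient vectors are drawn from each model's asymptotic normal
sampling distribution; each draw yields an average causal mediation effect
(ACME) a*b, an average direct effect (ADE) c', and a total effect
ACME + ADE. Point estimates are means over draws, intervals are percentile
intervals, and p-values are fraction-based two-sided Monte Carlo p-values
floored at 1/(n_sims + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_stream
from .errors import TransQTLError
from .simulate import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MediationResult",
    "fit_mediation",
    "mediation_screen",
    "coexpression_contrast",
    "CoexpressionContrast",
    "effect_size_contrast",
]


@dataclass
class MediationResult:
    """Quasi-Bayesian mediation estimates for one SNP-mediator-target triple.

    ``acme`` is in trans-expression SD per dosage unit when expression is
    inverse-normal transformed. In the linear no-interaction model
    ``total ~= acme + ade`` up to Monte-Carlo error.
    """

    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_p: float
    ade_p: float
    total_p: float
    ci: tuple[float, float]
    n_sims: int


def _ols(y: np.ndarray, design: np.ndarray):
    """OLS fit returning (coefficients, coefficient covariance)."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise TransQTLError("design matrix is rank deficient")
    resid = y - design @ coef
    df = len(y) - design.shape[1]
    if df <= 0:
        raise TransQTLError("zero residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return coef, cov


def _mc_p(draws: np.ndarray) -> float:
    n = draws.size
    p = 2.0 * min(np.mean(draws <= 0.0), np.mean(draws >= 0.0))
    return float(np.clip(p, 1.0 / (n + 1), 1.0))


def fit_mediation(
    g,
    y_cis,
    y_trans,
    covariates=None,
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Estimate ACME / ADE / total effect for one triple.

    Fits the mediator and outcome models by OLS, then draws ``n_sims``
    coefficient vectors from each model's asymptotic multivariate normal.
    Raises when the exposure and mediator are numerically collinear
    (|r| > 0.999), where the direct and mediated paths are not identifiable.
    """
    if n_sims < 100:
        raise TransQTLError("n_sims must be >= 100")
    g = np.asarray(g, dtype=float)
    y_cis = np.asarray(y_cis, dtype=float)
    y_trans = np.asarray(y_trans, dtype=float)
    n = g.size
    if y_cis.size != n or y_trans.size != n:
        raise TransQTLError("g, y_cis and y_trans must be aligned")
    r_gm = np.corrcoef(g, y_cis)[0, 1]
    if abs(r_gm) > 0.999:
        raise TransQTLError("exposure and mediator are collinear; mediation not identifiable")

    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    ones = np.ones((n, 1))
    design_m = np.column_stack([ones, g[:, None], c])
    design_y = np.column_stack([ones, g[:, None], y_cis[:, None], c])

    coef_m, cov_m = _ols(y_cis, design_m)
    coef_y, cov_y = _ols(y_trans, design_y)

    rng = rng_stream(seed, "mediation")
    draws_m = rng.multivariate_normal(coef_m, cov_m, size=n_sims, method="svd")
    draws_y = rng.multivariate_normal(coef_y, cov_y, size=n_sims, method="svd")
    a = draws_m[:, 1]
    c_dir = draws_y[:, 1]
    b = draws_y[:, 2]

    acme_draws = a * b
    ade_draws = c_dir
    total_draws = acme_draws + ade_draws
    acme = float(acme_draws.mean())
    ade = float(ade_draws.mean())
    total = float(total_draws.mean())
    ci = tuple(np.percentile(acme_draws, [2.5, 97.5]))
    prop = acme / total if abs(total) > 1e-12 else np.nan
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_p=_mc_p(acme_draws), ade_p=_mc_p(ade_draws), total_p=_mc_p(total_draws),
        ci=(float(ci[0]), float(ci[1])), n_sims=n_sims,
    )


def mediation_screen(
    coloc_pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run :func:`fit_mediation` over colocalized (cis gene, trans gene) pairs.

    Each pair row must carry ``lead_variant_id``, ``cis_gene_id`` and
    ``trans_gene_id``. Pairs with ACME p < ``alpha`` are labeled mediated and
    signed by the ACME. Per-pair failures are logged and reported as NaN
    rows, not raised. Returns (table, summary) where summary holds the
    mediated fraction and the positive/negative sign counts.
    """
    cov = None
    if covariates is not None and covariates.shape[1]:
        cov = covariates.loc[expr.sample_ids].to_numpy(dtype=float)
    rows = []
    for _, pair in coloc_pairs.iterrows():
        vid = pair["lead_variant_id"]
        cis_gene, trans_gene = pair["cis_gene_id"], pair["trans_gene_id"]
        row = {"lead_variant_id": vid, "cis_gene_id": cis_gene, "trans_gene_id": trans_gene}
        try:
            res = fit_mediation(
                genotypes.dosage.loc[expr.sample_ids, vid].to_numpy(),
                expr.values.loc[cis_gene].to_numpy(),
                expr.values.loc[trans_gene].to_numpy(),
                covariates=cov,
                n_sims=n_sims,
                seed=rng_stream(seed, "screen", vid, cis_gene, trans_gene).integers(2 ** 31),
            )
        except TransQTLError as exc:
            logger.warning("mediation failed for (%s, %s, %s): %s", vid, cis_gene, trans_gene, exc)
            row.update({"acme": np.nan, "ade": np.nan, "total": np.nan,
                        "prop_mediated": np.nan, "acme_p": np.nan,
                        "mediated": False, "sign": 0})
            rows.append(row)
            continue
        row.update({
            "acme": res.acme, "ade": res.ade, "total": res.total,
            "prop_mediated": res.prop_mediated, "acme_p": res.acme_p,
            "mediated": res.acme_p < alpha,
            "sign": int(np.sign(res.acme)),
        })
        rows.append(row)
    table = pd.DataFrame(rows) if rows else pd.DataFrame(columns=[
        "lead_variant_id", "cis_gene_id", "trans_gene_id", "acme", "ade",
        "total", "prop_mediated", "acme_p", "mediated", "sign",
    ])
    n_tested = int(table["acme_p"].notna().sum()) if len(table) else 0
    mediated = table.loc[table.get("mediated", pd.Series(dtype=bool)) == True]  # noqa: E712
    summary = {
        "n_pairs": len(table),
        "n_tested": n_tested,
        "n_mediated": len(mediated),
        "mediated_fraction": len(mediated) / n_tested if n_tested else np.nan,
        "n_positive": int((mediated["sign"] > 0).sum()) if len(mediated) else 0,
        "n_negative": int((mediated["sign"] < 0).sum()) if len(mediated) else 0,
    }
    return table, summary


@dataclass
class CoexpressionContrast:
    """Absolute co-expression of mediated, coloc-only and matched random pairs."""

    mediated_r: np.ndarray
    coloc_only_r: np.ndarray
    random_r: np.ndarray
    tests: pd.DataFrame

    def median(self, group: str) -> float:
        return float(np.median(getattr(self, f"{group}_r")))


def _abs_pair_correlations(pairs, expr: ExpressionMatrix) -> np.ndarray:
    values = expr.values
    out = []
    for g1, g2 in pairs:
        x = values.loc[g1].to_numpy(dtype=float)
        y = values.loc[g2].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            logger.warning("constant gene in pair (%s, %s); dropped", g1, g2)
            continue
        out.append(abs(np.corrcoef(x, y)[0, 1]))
    return np.asarray(out)


def coexpression_contrast(
    mediation_pairs,
    coloc_only_pairs,
    expr: ExpressionMatrix,
    n_random_sets: int = 10,
    seed: int = 0,
    n_bins: int = 10,
) -> CoexpressionContrast:
    """Contrast |Pearson r| of mediated pairs vs coloc-only and random pairs.

    ``mediation_pairs`` and ``coloc_only_pairs`` are iterables of
    (cis gene, trans gene). The random group draws, for every mediated pair,
    ``n_random_sets`` gene pairs matched to the two genes' mean-expression
    deciles. Group contrasts use the two-sample Wilcoxon rank-sum test with
    the direction of the difference reported.
    """
    mediation_pairs = list(mediation_pairs)
    coloc_only_pairs = list(coloc_only_pairs)
    means = expr.values.mean(axis=1)
    deciles = pd.qcut(means, n_bins, labels=False, duplicates="drop")
    by_decile = {d: list(idx) for d, idx in means.groupby(deciles).groups.items()}

    rng = rng_stream(seed, "coexpression_random")
    random_pairs = []
    for g1, g2 in mediation_pairs:
        d1, d2 = deciles.loc[g1], deciles.loc[g2]
        for _ in range(n_random_sets):
            r1 = by_decile[d1][rng.integers(len(by_decile[d1]))]
            r2 = by_decile[d2][rng.integers(len(by_decile[d2]))]
            if r1 == r2:
                continue
            random_pairs.append((r1, r2))

    groups = {
        "mediated": _abs_pair_correlations(mediation_pairs, expr),
        "coloc_only": _abs_pair_correlations(coloc_only_pairs, expr),
        "random": _abs_pair_correlations(random_pairs, expr),
    }
    rows = []
    names = list(groups)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            a, b = groups[n1], groups[n2]
            if a.size == 0 or b.size == 0:
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({
                "group1": n1, "group2": n2, "statistic": float(stat), "p": float(p),
                "median1": float(np.median(a)), "median2": float(np.median(b)),
                "direction": n1 if np.median(a) > np.median(b) else n2,
            })
    return CoexpressionContrast(
        mediated_r=groups["mediated"],
        coloc_only_r=groups["coloc_only"],
        random_r=groups["random"],
        tests=pd.DataFrame(rows),
    )


def effect_size_contrast(group_assignments: dict, effect_sizes: dict) -> pd.DataFrame:
    """Pairwise Kolmogorov-Smirnov contrasts of |effect size| between groups.

    ``group_assignments`` maps gene -> group label; ``effect_sizes`` maps
    gene -> beta. Groups smaller than 5 are flagged low power with a warning.
    """
    groups: dict[str, list[float]] = {}
    for gene, label in group_assignments.items():
        if gene in effect_sizes:
            groups.setdefault(label, []).append(abs(effect_sizes[gene]))
    names = sorted(groups)
    if sum(1 for n in names if groups[n]) < 2:
        raise TransQTLError("need at least two non-empty groups")
    rows = []
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            a, b = np.asarray(groups[n1]), np.asarray(groups[n2])
            low_power = min(a.size, b.size) < 5
            if low_power:
                logger.warning("group pair (%s, %s) has < 5 members; low power", n1, n2)
            d, p = stats.ks_2samp(a, b)
            rows.append({"group1": n1, "group2": n2, "D": float(d), "p": float(p),
                         "n1": a.size, "n2": b.size, "low_power": low_power})
    return pd.DataFrame(rows)
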