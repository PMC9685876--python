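"""Trans-eQTL hotspots and their co-regulation test.

A hotspot is an independent trans-eSNP associated with three or more
distinct trans-eGenes. If the targets of a hotspot share an upstream
regulator they should be co-expressed, so the observed mean absolute
pairwise Pearson correlation of the target genes is compared against
resampled null gene sets matched to the targets' mean-expression deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import rng_stream
from .errors import TransQTLError
from .simulate import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["Hotspot", "detect_hotspots", "coregulation_test"]


@dataclass
class Hotspot:
    """One trans-eSNP with >= 3 distinct trans target genes."""

    variant_id: str
    target_genes: frozenset[str]
    mean_abs_r: float | None = None
    null_quantile: float | None = None
    empirical_p: float | None = None


def detect_hotspots(qtl_records: pd.DataFrame, min_targets: int = 3) -> pd.DataFrame:
    """Group trans records by variant; emit variants with >= min_targets genes.

    Expects the LD-pruned significant trans list, so each eSNP is
    independent. Duplicate (variant, gene) records count once. Returns a
    DataFrame (variant_id, n_targets, target_genes) sorted by descending
    target count.
    """
    if min_targets < 1:
        raise TransQTLError("min_targets must be >= 1")
    if len(qtl_records) == 0:
        return pd.DataFrame(columns=["variant_id", "n_targets", "target_genes"])
    grouped = qtl_records.groupby("variant_id")["gene_id"].agg(lambda g: frozenset(g))
    rows = [
        {"variant_id": vid, "n_targets": len(targets), "target_genes": tuple(sorted(targets))}
        for vid, targets in grouped.items()
        if len(targets) >= min_targets
    ]
    out = pd.DataFrame(rows, columns=["variant_id", "n_targets", "target_genes"])
    return out.sort_values(["n_targets", "variant_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def _mean_abs_corr(values: np.ndarray) -> float:
    """Mean |Pearson r| over all gene pairs of a (genes x samples) block."""
    r = np.corrcoef(values)
    iu = np.triu_indices_from(r, k=1)
    return float(np.mean(np.abs(r[iu])))


def coregulation_test(
    hotspots: pd.DataFrame,
    expr: ExpressionMatrix,
    n_random: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Expression-matched resampling test of hotspot target co-regulation.

    Per hotspot the observed statistic is the mean absolute pairwise Pearson
    correlation of its targets. The null draws ``n_random`` gene sets of the
    same size, each member matched to one target's mean-expression decile
    (targets themselves excluded; sampling without replacement within a
    set); empirical p = (1 + #{null mean >= observed}) / (n_random + 1).
    Also returns a pooled summary comparing the mean of hotspot statistics
    to the mean of the draw-wise null statistics across hotspots.
    """
    means = expr.values.mean(axis=1)
    deciles = pd.qcut(means, n_bins, labels=False, duplicates="drop")
    gene_ids = set(expr.values.index)
    values = expr.values

    rows = []
    null_by_hotspot = []
    for _, hs in hotspots.iterrows():
        targets = [g for g in hs["target_genes"]]
        missing = [g for g in targets if g not in gene_ids]
        if missing:
            logger.warning("hotspot %s dropped: targets %s missing from expression",
                           hs["variant_id"], missing)
            continue
        observed = _mean_abs_corr(values.loc[targets].to_numpy(dtype=float))
        target_deciles = sorted(deciles.loc[targets])
        pools = {
            d: [g for g in deciles.index[deciles == d] if g not in set(targets)]
            for d in set(target_deciles)
        }
        for d in set(target_deciles):
            if len(pools[d]) < target_deciles.count(d):
                raise TransQTLError(
                    f"decile {d} has too few non-target genes to match; use fewer bins"
                )
        rng = rng_stream(seed, "hotspot_null", hs["variant_id"])
        null_means = np.empty(n_random)
        for k in range(n_random):
            chosen: list[str] = []
            used: set[str] = set()
            for d in target_deciles:
                pool = pools[d]
                g = pool[rng.integers(len(pool))]
                while g in used:
                    g = pool[rng.integers(len(pool))]
                used.add(g)
                chosen.append(g)
            assert sorted(deciles.loc[chosen]) == target_deciles  # decile composition preserved
            null_means[k] = _mean_abs_corr(values.loc[chosen].to_numpy(dtype=float))
        emp_p = (1.0 + np.sum(null_means >= observed)) / (n_random + 1.0)
        rows.append({
            "variant_id": hs["variant_id"],
            "n_targets": hs["n_targets"],
            "target_genes": hs["target_genes"],
            "mean_abs_r": observed,
            "null_quantile": float(np.mean(null_means < observed)),
            "empirical_p": float(emp_p),
        })
        null_by_hotspot.append(null_means)

    table = pd.DataFrame(rows, columns=[
        "variant_id", "n_targets", "target_genes", "mean_abs_r",
        "null_quantile", "empirical_p",
    ])
    pooled: dict = {"n_hotspots": len(table)}
    if null_by_hotspot:
        observed_mean = float(table["mean_abs_r"].mean())
        null_mat = np.vstack(null_by_hotspot)  # hotspots x n_random
        pooled_null = null_mat.mean(axis=0)
        pooled.update({
            "observed_mean": observed_mean,
            "null_mean": float(pooled_null.mean()),
            "pooled_empirical_p": float(
                (1.0 + np.sum(pooled_null >= observed_mean)) / (n_random + 1.0)
            ),
        })
    return table, pooled
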