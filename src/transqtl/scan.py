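"""Nominal cis/trans association scanning and multiple-testing machinery.

The association model is the eQTL-standard ordinary least squares fit of
(inverse-normal) expression on dosage plus covariates and an intercept, with
a two-sided t-test on the dosage coefficient. The scan is computed through
the Frisch-Waugh projection: expression and dosage are residualized on the
covariates once, after which every (gene, variant) pair reduces to a simple
regression with df = n - n_covariates - 2. This is algebraically identical
to refitting the full model per pair.

Multiple-testing schemes provided: pooled Benjamini-Hochberg over the
(LD-pruned) record list, hierarchical gene-level correction (per-gene Sidak
then BH across genes) and a permutation-based gene-level scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_qvalues, residualize, rng_stream
from .errors import TransQTLError
from .normalize import inverse_normal_rows
from .simulate import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "QTLList",
    "SplitHalfResult",
    "nominal_scan",
    "cross_map_filter",
    "ld_prune",
    "pooled_fdr",
    "hierarchical_gene_fdr",
    "permutation_gene_fdr",
    "split_half_replication",
    "element_enrichment",
]

RECORD_COLUMNS = ["variant_id", "gene_id", "beta", "se", "p", "df", "label"]


@dataclass(frozen=True)
class AssociationRecord:
    """One (variant, gene) association test.

    Bulk operations exchange DataFrames with :data:`RECORD_COLUMNS`; this
    dataclass names the per-record contract (p consistent with t = beta/se
    at df; label in {cis, trans}).
    """

    variant_id: str
    gene_id: str
    beta: float
    se: float
    p: float
    df: int
    label: str


@dataclass
class QTLList:
    """Significant associations under one multiple-testing scheme.

    ``records`` carries the retained rows plus a ``q`` column; all q-values
    are below ``threshold``. ``scheme`` is one of pooled / hierarchical_gene
    / permutation.
    """

    records: pd.DataFrame
    scheme: str
    threshold: float


@dataclass
class SplitHalfResult:
    """Replication of QTL calls between two disjoint sample folds."""

    overlap: float
    n_fold1: int
    n_fold2: int
    n_common: int
    fold1_samples: tuple[str, ...]
    fold2_samples: tuple[str, ...]


def _aligned_arrays(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                    covariates: pd.DataFrame | None):
    samples = expr.sample_ids
    if list(genotypes.dosage.index) != samples:
        dosage = genotypes.dosage.loc[samples]
    else:
        dosage = genotypes.dosage
    c = None
    n_cov = 0
    if covariates is not None and covariates.shape[1]:
        c = covariates.loc[samples].to_numpy(dtype=float)
        n_cov = c.shape[1]
    return dosage, c, n_cov


def _pair_mask(mode: str, genes: pd.DataFrame, variants: pd.DataFrame,
               cis_window_bp: float, trans_min_bp: float) -> np.ndarray:
    """Boolean (gene x variant) matrix of pairs tested under ``mode``."""
    same_chrom = genes["chrom"].to_numpy()[:, None] == variants["chrom"].to_numpy()[None, :]
    dist = np.abs(genes["tss"].to_numpy(dtype=float)[:, None]
                  - variants["pos"].to_numpy(dtype=float)[None, :])
    if mode == "cis":
        return same_chrom & (dist <= cis_window_bp)
    if mode == "trans":
        return (~same_chrom) | (dist > trans_min_bp)
    raise TransQTLError(f"unknown scan mode {mode!r}")


def nominal_scan(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    mode: str = "trans",
    cis_window_bp: float = 1_000_000,
    trans_min_bp: float = 5_000_000,
) -> pd.DataFrame:
    """OLS association scan over all in-window (variant, gene) pairs.

    cis pairs lie within ``cis_window_bp`` of the gene TSS on the same
    chromosome; trans pairs are on a different chromosome or more than
    ``trans_min_bp`` from the TSS (pairs in between are tested in neither
    mode). Monomorphic variants are skipped with a logged count. Returns a
    DataFrame with :data:`RECORD_COLUMNS`.
    """
    dosage, c, n_cov = _aligned_arrays(expr, genotypes, covariates)
    n = len(expr.sample_ids)
    df = n - n_cov - 2
    if df <= 0:
        raise TransQTLError("zero residual degrees of freedom")

    g_mat = dosage.to_numpy(dtype=float)
    poly = g_mat.min(axis=0) < g_mat.max(axis=0)
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("nominal_scan: skipped %d monomorphic variants", n_skipped)
    variants = genotypes.variants.loc[dosage.columns[poly]]
    g_res = residualize(g_mat[:, poly], c)
    y_res = residualize(expr.values.to_numpy(dtype=float).T, c)

    g_norm = np.linalg.norm(g_res, axis=0)
    y_norm = np.linalg.norm(y_res, axis=0)
    degenerate = g_norm <= 1e-12
    if degenerate.any():
        n_skipped += int(degenerate.sum())
        logger.info("nominal_scan: skipped %d variants constant after residualization",
                    int(degenerate.sum()))
        keep = ~degenerate
        g_res, g_norm = g_res[:, keep], g_norm[keep]
        variants = variants.loc[variants.index[keep]]
    y_norm = np.where(y_norm > 0, y_norm, np.nan)

    r = (y_res / y_norm).T @ (g_res / g_norm)  # genes x variants
    r = np.clip(r, -1.0, 1.0)
    mask = _pair_mask(mode, expr.genes, variants, cis_window_bp, trans_min_bp)

    gi, vi = np.nonzero(mask)
    rv = r[gi, vi]
    one_minus_r2 = np.maximum(1.0 - rv * rv, np.finfo(float).tiny)
    beta = rv * y_norm[gi] / g_norm[vi]
    se = y_norm[gi] * np.sqrt(one_minus_r2) / (g_norm[vi] * np.sqrt(df))
    t = rv * np.sqrt(df / one_minus_r2)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)

    return pd.DataFrame({
        "variant_id": variants.index.to_numpy()[vi],
        "gene_id": expr.values.index.to_numpy()[gi],
        "beta": beta,
        "se": se,
        "p": p,
        "df": df,
        "label": mode,
    })


def cross_map_filter(
    records: pd.DataFrame,
    blacklist,
    variant_table: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Drop records whose (variant locus, gene locus) hits a blacklist pair.

    ``blacklist`` is an iterable of unordered interval pairs
    ``((chrom, start, end), (chrom, start, end))`` marking loci with RNA-seq
    read cross-mappability; a record matches when its variant falls in one
    interval and its gene TSS in the other (either orientation).
    """
    if len(records) == 0:
        return records.copy()
    v_chrom = variant_table.loc[records["variant_id"], "chrom"].to_numpy()
    v_pos = variant_table.loc[records["variant_id"], "pos"].to_numpy(dtype=float)
    g_chrom = gene_table.loc[records["gene_id"], "chrom"].to_numpy()
    g_pos = gene_table.loc[records["gene_id"], "tss"].to_numpy(dtype=float)

    def _inside(chrom, pos, interval):
        c, start, end = interval
        return (chrom == c) & (pos >= start) & (pos < end)

    drop = np.zeros(len(records), dtype=bool)
    for locus_a, locus_b in blacklist:
        drop |= _inside(v_chrom, v_pos, locus_a) & _inside(g_chrom, g_pos, locus_b)
        drop |= _inside(v_chrom, v_pos, locus_b) & _inside(g_chrom, g_pos, locus_a)
    if drop.any():
        logger.info("cross_map_filter: removed %d records", int(drop.sum()))
    return records.loc[~drop].reset_index(drop=True)


def _greedy_keep_variants(order: list[str], genotypes: GenotypeMatrix,
                          r2_threshold: float) -> set[str]:
    """Greedy independent-variant selection in the given priority order."""
    variants = genotypes.variants
    by_chrom: dict[str, list[str]] = {}
    for vid in order:
        by_chrom.setdefault(variants.at[vid, "chrom"], []).append(vid)

    kept: set[str] = set()
    for chrom, vids in by_chrom.items():
        dos = genotypes.dosage[vids].to_numpy(dtype=float)
        dos = dos - dos.mean(axis=0)
        norms = np.linalg.norm(dos, axis=0)
        norms[norms == 0] = np.nan
        unit = dos / norms
        kept_cols: list[int] = []
        for j in range(len(vids)):
            if kept_cols:
                r = unit[:, kept_cols].T @ unit[:, j]
                if np.nanmax(r * r) > r2_threshold:
                    continue
            kept_cols.append(j)
            kept.add(vids[j])
    return kept


def ld_prune(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.6,
) -> pd.DataFrame:
    """Greedy LD pruning of the record list at the variant level.

    Records are visited in ascending p (ties: ascending variant id, then
    gene id). A variant's fate is decided at its best record: it is kept
    unless its squared dosage correlation with an already-kept variant on
    the same chromosome exceeds ``r2_threshold``. All records of a kept
    variant survive (so one independent eSNP may retain several target
    genes); all records of a dropped variant are removed.
    """
    if len(records) == 0:
        return records.copy()
    best = (records.sort_values(["p", "variant_id", "gene_id"], kind="mergesort")
            .drop_duplicates("variant_id"))
    kept = _greedy_keep_variants(list(best["variant_id"]), genotypes, r2_threshold)
    out = records.loc[records["variant_id"].isin(kept)].reset_index(drop=True)
    logger.info("ld_prune: %d -> %d records (%d independent variants)",
                len(records), len(out), len(kept))
    return out


def pooled_fdr(records: pd.DataFrame, alpha: float) -> QTLList:
    """Benjamini-Hochberg over the pooled nominal p of all records.

    Returns the records with q < ``alpha``; an empty input yields an empty
    list, not an error.
    """
    out = records.copy().reset_index(drop=True)
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        return QTLList(records=out, scheme="pooled", threshold=alpha)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out = out.loc[out["q"] < alpha].reset_index(drop=True)
    return QTLList(records=out, scheme="pooled", threshold=alpha)


def sidak_correction(p_min, m):
    """Per-gene Sidak correction 1 - (1 - p_min)^m, computed in log space."""
    p_min = np.asarray(p_min, dtype=float)
    m = np.asarray(m, dtype=float)
    return -np.expm1(m * np.log1p(-np.minimum(p_min, 1.0 - 1e-16)))


def hierarchical_gene_fdr(
    records: pd.DataFrame,
    tests_per_gene: dict[str, int],
    alpha: float,
) -> pd.DataFrame:
    """Hierarchical gene-level FDR: per-gene Sidak, then BH across genes.

    For each gene the minimum nominal p over its records is corrected for
    the gene's number of tests ``m`` via 1 - (1 - p_min)^m; BH is applied
    across genes and genes with q < ``alpha`` are flagged eGenes. Returns a
    per-gene table (gene_id, lead variant, p_min, m, p_gene, q, is_egene).
    """
    idx = records.sort_values(["p", "variant_id"], kind="mergesort").drop_duplicates("gene_id")
    rows = []
    for _, rec in idx.iterrows():
        gene = rec["gene_id"]
        if gene not in tests_per_gene:
            raise TransQTLError(f"gene {gene} missing from tests_per_gene")
        m = int(tests_per_gene[gene])
        if m <= 0:
            raise TransQTLError(f"gene {gene} has records but m={m} tests")
        rows.append((gene, rec["variant_id"], rec["p"], m))
    table = pd.DataFrame(rows, columns=["gene_id", "lead_variant_id", "p_min", "m"])
    table["p_gene"] = sidak_correction(table["p_min"].to_numpy(), table["m"].to_numpy())
    table["q"] = bh_qvalues(table["p_gene"].to_numpy())
    table["is_egene"] = table["q"] < alpha
    return table.sort_values("q", kind="mergesort").reset_index(drop=True)


def permutation_gene_fdr(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    mode: str = "trans",
    n_perm: int = 1000,
    alpha: float = 0.25,
    seed: int = 0,
    cis_window_bp: float = 1_000_000,
    trans_min_bp: float = 5_000_000,
) -> QTLList:
    """Permutation-based hierarchical gene-level FDR.

    Per gene: the covariate-residualized expression vector is permuted
    ``n_perm`` times (one shared set of permutations across genes) and the
    minimum nominal p over the gene's tested variants recomputed; the
    empirical gene-level p is (1 + #{perm min-p <= observed}) / (n_perm + 1).
    BH is applied across genes. For significant genes, associations whose
    nominal p falls at or below the alpha-quantile of the gene's permutation
    min-p distribution are reported.
    """
    if n_perm < 100:
        raise TransQTLError("n_perm must be >= 100")
    if 1.0 / (n_perm + 1) > alpha:
        warnings.warn("n_perm too small to resolve the requested alpha", stacklevel=2)

    dosage, c, n_cov = _aligned_arrays(expr, genotypes, covariates)
    n = len(expr.sample_ids)
    df = n - n_cov - 2
    if df <= 0:
        raise TransQTLError("zero residual degrees of freedom")

    g_mat = dosage.to_numpy(dtype=float)
    poly = g_mat.min(axis=0) < g_mat.max(axis=0)
    variants = genotypes.variants.loc[dosage.columns[poly]]
    g_res = residualize(g_mat[:, poly], c)
    g_norm = np.linalg.norm(g_res, axis=0)
    g_unit = g_res / np.where(g_norm > 0, g_norm, np.nan)
    y_res = residualize(expr.values.to_numpy(dtype=float).T, c)
    y_norm = np.linalg.norm(y_res, axis=0)
    y_unit = (y_res / np.where(y_norm > 0, y_norm, np.nan)).T  # genes x n

    mask = _pair_mask(mode, expr.genes, variants, cis_window_bp, trans_min_bp)
    rng = rng_stream(seed, "permutation_fdr")
    perm_idx = np.vstack([rng.permutation(n) for _ in range(n_perm)])

    def _min_p(max_abs_r: np.ndarray) -> np.ndarray:
        r2 = np.minimum(max_abs_r * max_abs_r, 1.0 - np.finfo(float).eps)
        t = max_abs_r * np.sqrt(df / (1.0 - r2))
        return np.clip(2.0 * stats.t.sf(t, df), np.finfo(float).tiny, 1.0)

    gene_rows = []
    sig_records = []
    genes_arr = expr.values.index.to_numpy()
    for gi in range(len(genes_arr)):
        cols = np.flatnonzero(mask[gi])
        if cols.size == 0:
            continue
        gw = g_unit[:, cols]  # n x w
        obs_r = gw.T @ y_unit[gi]
        obs_abs = np.abs(obs_r)
        obs_minp = float(_min_p(np.array([obs_abs.max()]))[0])
        y_perm = y_unit[gi][perm_idx]  # n_perm x n
        perm_max = np.abs(y_perm @ gw).max(axis=1)
        perm_minp = _min_p(perm_max)
        emp_p = (1.0 + np.sum(perm_minp <= obs_minp)) / (n_perm + 1.0)
        nominal_thresh = float(np.quantile(perm_minp, alpha))
        gene_rows.append((genes_arr[gi], obs_minp, emp_p, nominal_thresh, gi, cols, obs_r))

    gene_table = pd.DataFrame(
        [(g, mp, ep, nt) for g, mp, ep, nt, _, _, _ in gene_rows],
        columns=["gene_id", "p_min", "p_empirical", "nominal_threshold"],
    )
    gene_table["q"] = bh_qvalues(gene_table["p_empirical"].to_numpy())
    significant = set(gene_table.loc[gene_table["q"] < alpha, "gene_id"])

    for gene, _mp, _ep, nt, gi, cols, obs_r in gene_rows:
        if gene not in significant:
            continue
        p_all = _min_p(np.abs(obs_r))
        sel = p_all <= nt
        if not sel.any():
            continue
        rv = obs_r[sel]
        one_minus_r2 = np.maximum(1.0 - rv * rv, np.finfo(float).tiny)
        beta = rv * y_norm[gi] / g_norm[cols[sel]]
        se = y_norm[gi] * np.sqrt(one_minus_r2) / (g_norm[cols[sel]] * np.sqrt(df))
        sig_records.append(pd.DataFrame({
            "variant_id": variants.index.to_numpy()[cols[sel]],
            "gene_id": gene,
            "beta": beta,
            "se": se,
            "p": p_all[sel],
            "df": df,
            "label": mode,
            "q": float(gene_table.loc[gene_table["gene_id"] == gene, "q"].iloc[0]),
        }))

    records = (pd.concat(sig_records, ignore_index=True) if sig_records
               else pd.DataFrame(columns=RECORD_COLUMNS + ["q"]))
    result = QTLList(records=records, scheme="permutation", threshold=alpha)
    result.gene_table = gene_table  # per-gene empirical p-values
    return result


def _subset_samples(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                    covariates: pd.DataFrame | None, samples: list[str]):
    sub_expr = ExpressionMatrix(values=expr.values[samples], genes=expr.genes)
    sub_geno = GenotypeMatrix(dosage=genotypes.dosage.loc[samples],
                              variants=genotypes.variants)
    sub_cov = None if covariates is None else covariates.loc[samples]
    return sub_expr, sub_geno, sub_cov


def split_half_replication(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    mode: str = "trans",
    folds: tuple[list[str], list[str]] | None = None,
    prune: bool = True,
    renormalize: bool = True,
    r2_threshold: float = 0.6,
    **scan_kwargs,
) -> SplitHalfResult:
    """Internal replication: disjoint half-splits scanned independently.

    The samples are split into two disjoint, (near-)equal folds (or the
    explicit ``folds`` are used); each fold is rescanned (with per-fold
    re-application of the inverse normal transform when ``renormalize``),
    LD-pruned and thresholded at pooled FDR < ``alpha``. The overlap is
    |pairs in both lists| / |smaller list| — intersection over the smaller
    fold's list, since the two folds need not yield equally sized lists.
    """
    samples = expr.sample_ids
    if folds is None:
        if len(samples) < 4:
            raise TransQTLError("need at least 4 samples to split")
        rng = rng_stream(seed, "split_half")
        perm = rng.permutation(len(samples))
        half = len(samples) // 2
        folds = ([samples[i] for i in perm[:half]],
                 [samples[i] for i in perm[half:2 * half]])
    fold1, fold2 = folds
    if set(fold1) & set(fold2):
        raise TransQTLError("folds must be disjoint")

    pair_sets = []
    for fold in (fold1, fold2):
        sub_expr, sub_geno, sub_cov = _subset_samples(expr, genotypes, covariates, list(fold))
        if renormalize:
            sub_expr = inverse_normal_rows(sub_expr)
        recs = nominal_scan(sub_expr, sub_geno, sub_cov, mode=mode, **scan_kwargs)
        if prune:
            recs = ld_prune(recs, sub_geno, r2_threshold=r2_threshold)
        qtl = pooled_fdr(recs, alpha)
        pair_sets.append(set(zip(qtl.records["variant_id"], qtl.records["gene_id"])))

    n1, n2 = len(pair_sets[0]), len(pair_sets[1])
    n_common = len(pair_sets[0] & pair_sets[1])
    overlap = n_common / min(n1, n2) if min(n1, n2) > 0 else 0.0
    return SplitHalfResult(overlap=overlap, n_fold1=n1, n_fold2=n2, n_common=n_common,
                           fold1_samples=tuple(fold1), fold2_samples=tuple(fold2))


def _in_intervals(chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Point-in-interval membership against 0-based half-open intervals."""
    hit = np.zeros(len(chrom), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        starts = sub["start"].to_numpy(dtype=float)
        ends = sub["end"].to_numpy(dtype=float)
        sel = chrom == c
        if not sel.any():
            continue
        pts = pos[sel][:, None]
        hit[sel] = ((pts >= starts[None, :]) & (pts < ends[None, :])).any(axis=1)
    return hit


def element_enrichment(
    qtl_variants,
    background_variants,
    elements: dict[str, pd.DataFrame],
    variant_table: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher enrichment of QTL variants in genomic elements vs background.

    For each named element set (DataFrame with chrom/start/end intervals) a
    2x2 table of (inside/outside element) x (QTL / background-minus-QTL) is
    tested with a two-sided Fisher exact test. Also reports the proportion
    of QTL (and background) variants inside the element.
    """
    qtl = sorted(set(qtl_variants))
    background = sorted(set(background_variants))
    if not set(qtl) <= set(background):
        warnings.warn("QTL variants are not a subset of the background", stacklevel=2)
    non_qtl = sorted(set(background) - set(qtl))

    def _members(ids, intervals):
        chrom = variant_table.loc[ids, "chrom"].to_numpy()
        pos = variant_table.loc[ids, "pos"].to_numpy(dtype=float)
        return _in_intervals(chrom, pos, intervals)

    rows = []
    for name, intervals in elements.items():
        if len(intervals) == 0:
            warnings.warn(f"element set {name!r} is empty; skipped", stacklevel=2)
            continue
        q_in = int(_members(qtl, intervals).sum())
        b_in = int(_members(non_qtl, intervals).sum())
        table = [[q_in, len(qtl) - q_in], [b_in, len(non_qtl) - b_in]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "element": name,
            "n_qtl_in": q_in,
            "n_background_in": b_in,
            "odds_ratio": odds,
            "p": p,
            "proportion_qtl": q_in / len(qtl) if qtl else np.nan,
            "proportion_background": (q_in + b_in) / len(background) if background else np.nan,
        })
    return pd.DataFrame(rows)
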