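"""GWAS integration: locus definition, QTL-GWAS colocalization, gene-set tests.

Genome-wide significant (GWS) loci are built by iterative LD clumping of the
GWAS summary statistics; trans- (or cis-) eQTL traces are colocalized with
the GWAS trace over each locus's member variants; colocalized genes are the
trait's risk-gene calls. Characterization statistics: Fisher exact tests of
risk genes against annotation gene sets, and rank-sum contrasts of network
centrality (kME, co-expression module membership) between gene groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import DEFAULT_W, coloc_posteriors, wakefield_abf
from .errors import TransQTLError
from .simulate import GenotypeMatrix, GWASSummary

logger = logging.getLogger(__name__)

__all__ = [
    "GWSLocus",
    "FisherResult",
    "define_gws_loci",
    "gwas_coloc",
    "summarize_locus_annotation",
    "gene_set_fisher",
    "centrality_contrast",
]


@dataclass
class GWSLocus:
    """A genome-wide significant GWAS locus defined by LD with its index SNP."""

    index_variant: str
    member_variants: tuple[str, ...]
    chrom: str
    start: int
    end: int


def define_gws_loci(
    gwas: GWASSummary,
    genotypes: GenotypeMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.6,
) -> list[GWSLocus]:
    """Iterative clumping of genome-wide significant variants into loci.

    Repeatedly takes the smallest-p unassigned significant variant as the
    index and assigns every significant variant with dosage r^2 above
    ``r2_threshold`` (same chromosome) to its locus, so each significant
    variant lands in exactly one locus. Returns an empty list when nothing
    reaches the threshold.
    """
    table = gwas.table
    sig = table.loc[table["p"] < p_threshold].sort_values(
        ["p", "pos"], kind="mergesort")
    if len(sig) == 0:
        return []
    dosage = genotypes.dosage
    centered = {vid: None for vid in sig.index}

    def _vec(vid):
        if centered[vid] is None:
            v = dosage[vid].to_numpy(dtype=float)
            v = v - v.mean()
            centered[vid] = (v, np.linalg.norm(v))
        return centered[vid]

    unassigned = list(sig.index)
    loci: list[GWSLocus] = []
    while unassigned:
        index_variant = unassigned[0]
        chrom = table.at[index_variant, "chrom"]
        iv, inorm = _vec(index_variant)
        members = [index_variant]
        rest = []
        for vid in unassigned[1:]:
            if table.at[vid, "chrom"] != chrom:
                rest.append(vid)
                continue
            v, vnorm = _vec(vid)
            r = float(iv @ v / (inorm * vnorm)) if inorm > 0 and vnorm > 0 else 0.0
            if r * r > r2_threshold:
                members.append(vid)
            else:
                rest.append(vid)
        positions = table.loc[members, "pos"]
        loci.append(GWSLocus(
            index_variant=index_variant,
            member_variants=tuple(members),
            chrom=chrom,
            start=int(positions.min()),
            end=int(positions.max()),
        ))
        unassigned = rest
    return loci


def gwas_coloc(
    qtl_records: pd.DataFrame,
    gwas: GWASSummary,
    loci: list[GWSLocus],
    qtl_p_max: float = 1e-5,
    pp4_threshold: float = 0.6,
    mode: str = "trans",
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W_qtl: float = DEFAULT_W,
    W_gwas: float = DEFAULT_W,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Colocalize eQTL traces with the GWAS trace at each GWS locus.

    A gene enters a locus when it has a QTL record with p < ``qtl_p_max`` on
    a member variant; its full trace over the shared member variants is then
    colocalized with the GWAS. Calls with PP4 > ``pp4_threshold`` are
    returned (gene_id, locus index variant, posteriors, mode). (gene, locus)
    pairs with fewer than ``min_shared`` shared variants are skipped with a
    warning.
    """
    strong = qtl_records.loc[qtl_records["p"] < qtl_p_max]
    gwas_table = gwas.table
    rows = []
    for locus in loci:
        members = set(locus.member_variants)
        in_locus = strong.loc[strong["variant_id"].isin(members)]
        if len(in_locus) == 0:
            continue
        for gene in sorted(in_locus["gene_id"].unique()):
            trace = qtl_records.loc[
                (qtl_records["gene_id"] == gene) & qtl_records["variant_id"].isin(members)
            ].drop_duplicates("variant_id").set_index("variant_id")
            shared = [v for v in locus.member_variants if v in trace.index]
            if len(shared) < min_shared:
                logger.warning("locus %s x gene %s: only %d shared variants; skipped",
                               locus.index_variant, gene, len(shared))
                continue
            labf_qtl = wakefield_abf(trace.loc[shared, "beta"], trace.loc[shared, "se"], W_qtl)
            labf_gwas = wakefield_abf(
                gwas_table.loc[shared, "beta"], gwas_table.loc[shared, "se"], W_gwas)
            res = coloc_posteriors(labf_qtl, labf_gwas, p1=p1, p2=p2, p12=p12, W=W_qtl)
            if res.pp4 > pp4_threshold:
                rows.append({
                    "gene_id": gene, "locus": locus.index_variant, "mode": mode,
                    "n_shared": len(shared),
                    "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                    "pp3": res.pp3, "pp4": res.pp4,
                })
    return pd.DataFrame(rows, columns=[
        "gene_id", "locus", "mode", "n_shared", "pp0", "pp1", "pp2", "pp3", "pp4",
    ])


def summarize_locus_annotation(
    loci: list[GWSLocus],
    cis_calls: pd.DataFrame | None = None,
    trans_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label each locus cis-only / trans-only / both / unannotated.

    The both + cis_only + trans_only counts partition the annotated loci.
    """
    cis_loci = set(cis_calls["locus"]) if cis_calls is not None and len(cis_calls) else set()
    trans_loci = set(trans_calls["locus"]) if trans_calls is not None and len(trans_calls) else set()
    rows = []
    for locus in loci:
        has_cis = locus.index_variant in cis_loci
        has_trans = locus.index_variant in trans_loci
        if has_cis and has_trans:
            label = "both"
        elif has_cis:
            label = "cis_only"
        elif has_trans:
            label = "trans_only"
        else:
            label = "unannotated"
        rows.append({"locus": locus.index_variant, "annotation": label})
    return pd.DataFrame(rows)


@dataclass
class FisherResult:
    """Two-sided Fisher exact test of two gene sets against a background."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def gene_set_fisher(egene_set, annotation_set, background) -> FisherResult:
    """Fisher exact test for overlap of an eGene set with an annotation set.

    Builds the 2x2 membership table over the background. The p-value is the
    exact two-sided Fisher p on the raw table; the sample odds ratio uses
    the Haldane-Anscombe 0.5 correction when any cell is zero, and the 95%
    CI is the Woolf log-odds normal interval on the (corrected) cells.
    """
    background = set(background)
    if not background:
        raise TransQTLError("background gene set is empty")
    egenes = set(egene_set) & background
    annot = set(annotation_set) & background
    if set(egene_set) - background or set(annotation_set) - background:
        logger.warning("gene_set_fisher: genes outside the background were dropped")
    a = len(egenes & annot)
    b = len(egenes - annot)
    c = len(annot - egenes)
    d = len(background - egenes - annot)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    log_se = float(np.sqrt((1.0 / cells).sum()))
    ci_low = float(np.exp(np.log(odds) - 1.959963984540054 * log_se))
    ci_high = float(np.exp(np.log(odds) + 1.959963984540054 * log_se))
    return FisherResult(odds_ratio=float(odds), ci_low=ci_low, ci_high=ci_high,
                        p=float(p), table=((a, b), (c, d)))


def centrality_contrast(kme: dict, groups: dict) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum contrasts of network centrality (kME).

    ``kme`` maps gene -> module-membership value; ``groups`` maps gene ->
    group label (e.g. trans / cis / all). Genes without a kME value are
    dropped with a warning. Returns one row per group pair with the
    two-sided rank-sum p and the group medians.
    """
    values: dict[str, list[float]] = {}
    n_dropped = 0
    for gene, label in groups.items():
        if gene in kme:
            values.setdefault(label, []).append(kme[gene])
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("centrality_contrast: dropped %d genes without kME", n_dropped)
    names = sorted(values)
    if len(names) < 2:
        raise TransQTLError("need at least two non-empty groups")
    rows = []
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            a, b = np.asarray(values[n1]), np.asarray(values[n2])
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({
                "group1": n1, "group2": n2, "statistic": float(stat), "p": float(p),
                "median1": float(np.median(a)), "median2": float(np.median(b)),
                "n1": a.size, "n2": b.size,
            })
    return pd.DataFrame(rows)
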