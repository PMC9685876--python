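"""Approximate-Bayes-factor colocalization of two association traces.

Implements the single-causal-variant colocalization model: per-variant
Wakefield approximate Bayes factors computed from (beta, se), combined over
the five hypotheses (no association / trait 1 only / trait 2 only / two
distinct causal variants / one shared causal variant) with per-variant
priors p1, p2, p12. All hypothesis sums are evaluated in log space.

The default priors (p1 = p2 = 1e-4, p12 = 1e-5) and the default prior
effect variance W = 0.15^2 for a quantitative trait on the standardized
scale match the conventional defaults for this model; inverse-normal
expression has unit variance, so W needs no rescaling for eQTL traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import TransQTLError
from .simulate import GenotypeMatrix

__all__ = [
    "DEFAULT_W",
    "ColocResult",
    "wakefield_abf",
    "coloc_posteriors",
    "colocalize_cis_trans",
]

DEFAULT_W = 0.15 ** 2


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    p1: float
    p2: float
    p12: float
    W: float

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_abf(beta, se, W: float = DEFAULT_W) -> np.ndarray:
    """Log approximate Bayes factor of association vs the null at one variant.

    With shrinkage r = W / (W + se^2) and z = beta / se:
    log ABF = 0.5 * log(1 - r) + 0.5 * z^2 * r. W = 0 collapses the prior to
    the null and gives log ABF = 0 everywhere.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise TransQTLError("standard errors must be positive")
    if W < 0:
        raise TransQTLError("prior effect variance W must be >= 0")
    r = W / (W + se ** 2)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    labf1,
    labf2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W: float = DEFAULT_W,
) -> ColocResult:
    """Combine two per-variant log-ABF traces into hypothesis posteriors.

    Sums over single-causal-variant configurations are done with
    log-sum-exp: H1 and H2 sum each trait's ABFs, H4 sums the per-variant
    products, H3 is the cross product minus the same-variant terms. With all
    log-ABFs zero the posteriors reduce to the normalized prior weights.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape:
        raise TransQTLError("trait traces must cover the same variants")
    if labf1.size == 0:
        raise TransQTLError("need at least one variant")

    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    lh = np.array([
        0.0,
        np.log(p1) + l1,
        np.log(p2) + l2,
        np.log(p1) + np.log(p2) + _logdiffexp(l1 + l2, l12),
        np.log(p12) + l12,
    ])
    post = np.exp(lh - logsumexp(lh))
    post = post / post.sum()
    return ColocResult(*post, n_variants=labf1.size, p1=p1, p2=p2, p12=p12, W=W)


def _ld_partners(genotypes: GenotypeMatrix, variant_id: str, r2_threshold: float) -> list[str]:
    """Variants on the lead's chromosome with dosage r^2 above threshold."""
    chrom = genotypes.variants.at[variant_id, "chrom"]
    same = genotypes.variants.index[genotypes.variants["chrom"] == chrom]
    dos = genotypes.dosage[same].to_numpy(dtype=float)
    dos = dos - dos.mean(axis=0)
    norms = np.linalg.norm(dos, axis=0)
    lead = genotypes.dosage[variant_id].to_numpy(dtype=float)
    lead = lead - lead.mean()
    lead_norm = np.linalg.norm(lead)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = dos.T @ lead / (norms * lead_norm)
    keep = (r * r) > r2_threshold
    return list(same[keep])


def colocalize_cis_trans(
    cis_records: pd.DataFrame,
    trans_records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    independent_trans: pd.DataFrame | None = None,
    r2_threshold: float = 0.6,
    pp4_threshold: float = 0.5,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W: float = DEFAULT_W,
    region: str = "ld",
    window_bp: float = 500_000,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Colocalize cis and trans association traces around independent trans-eSNPs.

    For each independent trans-eQTL record (pass the LD-pruned significant
    list as ``independent_trans``; defaults to ``trans_records``), the region
    is the lead eSNP's LD-partner set (r^2 > ``r2_threshold``), or a fixed
    window around the eSNP when ``region="window"``. Every cis gene with
    associations on those variants is tested against the trans gene's trace
    over the shared variants; pairs with PP4 above ``pp4_threshold`` are
    returned. Pairs with fewer than ``min_shared`` shared variants are
    skipped (the posterior is degenerate there).
    """
    if independent_trans is None:
        independent_trans = trans_records
    if len(independent_trans) == 0 or len(cis_records) == 0:
        return _empty_pairs()

    trans_by_pair = trans_records.set_index(["gene_id", "variant_id"])

    rows = []
    partner_cache: dict[str, list[str]] = {}
    for _, lead in independent_trans.iterrows():
        lead_id, trans_gene = lead["variant_id"], lead["gene_id"]
        if lead_id not in partner_cache:
            if region == "ld":
                partner_cache[lead_id] = _ld_partners(genotypes, lead_id, r2_threshold)
            elif region == "window":
                vt = genotypes.variants
                chrom = vt.at[lead_id, "chrom"]
                pos = vt.at[lead_id, "pos"]
                sel = (vt["chrom"] == chrom) & (np.abs(vt["pos"] - pos) <= window_bp)
                partner_cache[lead_id] = list(vt.index[sel])
            else:
                raise TransQTLError(f"unknown region mode {region!r}")
        partners = partner_cache[lead_id]

        trans_sub = trans_by_pair.loc[
            [(trans_gene, v) for v in partners if (trans_gene, v) in trans_by_pair.index]
        ] if partners else pd.DataFrame()
        if len(trans_sub) < min_shared:
            continue
        trans_sub = trans_sub.reset_index()

        cis_sub_all = cis_records[cis_records["variant_id"].isin(partners)]
        if len(cis_sub_all) == 0:
            continue
        for cis_gene, cis_sub in cis_sub_all.groupby("gene_id"):
            merged = trans_sub.merge(cis_sub, on="variant_id", suffixes=("_trans", "_cis"))
            if len(merged) < min_shared:
                continue
            labf_c = wakefield_abf(merged["beta_cis"], merged["se_cis"], W)
            labf_t = wakefield_abf(merged["beta_trans"], merged["se_trans"], W)
            res = coloc_posteriors(labf_c, labf_t, p1=p1, p2=p2, p12=p12, W=W)
            if res.pp4 > pp4_threshold:
                rows.append({
                    "cis_gene_id": cis_gene,
                    "trans_gene_id": trans_gene,
                    "lead_variant_id": lead_id,
                    "n_shared": len(merged),
                    "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                    "pp3": res.pp3, "pp4": res.pp4,
                })
    if not rows:
        return _empty_pairs()
    return pd.DataFrame(rows)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "cis_gene_id", "trans_gene_id", "lead_variant_id", "n_shared",
        "pp0", "pp1", "pp2", "pp3", "pp4",
    ])
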