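"""Synthetic genotype-expression cohorts with planted regulatory architecture.

The generator emulates the statistical structure a trans-eQTL study assumes:

* genotype dosages under Hardy-Weinberg with block-structured LD,
* gene expression driven by shared hidden factors, planted cis effects
  (SNP -> proximal gene), cis-mediated trans effects
  (SNP -> cis gene -> distal gene) and direct trans effects (SNP -> distal
  gene),
* an interchromosomal Hi-C contact matrix with enriched contacts at the
  planted SNP-gene bin pairs,
* GWAS summary statistics whose causal variants are shared with planted
  trans effects, with LD partners showing attenuated signal.

Every artifact is deterministic given the configuration seed; each artifact
draws from its own named substream of the root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_stream
from .errors import ConfigurationError

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "RegulatoryTruth",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "ContactMatrix",
    "GWASSummary",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_contact_matrix",
    "simulate_gwas_summary",
]

_EFFECT_KINDS = ("cis", "mediated_trans", "direct_trans")


@dataclass(frozen=True)
class PlantedEffect:
    """One planted regulatory path.

    ``kind`` is one of ``cis`` (SNP -> proximal gene, strength ``a``),
    ``mediated_trans`` (SNP -> cis gene -> distal gene; ``a`` records the
    SNP->cis strength of the companion cis effect, ``b`` the cis->trans
    strength, ``c`` an optional residual direct path) or ``direct_trans``
    (SNP -> distal gene, strength ``c``, no cis gene).
    """

    kind: str
    variant_id: str
    cis_gene_id: str | None = None
    trans_gene_id: str | None = None
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self):
        if self.kind not in _EFFECT_KINDS:
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        for name in ("a", "b", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"effect coefficient {name} must be finite")
        if self.kind == "cis":
            if self.cis_gene_id is None or self.a == 0:
                raise ConfigurationError("cis effect requires cis_gene_id and a != 0")
        elif self.kind == "mediated_trans":
            if self.cis_gene_id is None or self.trans_gene_id is None:
                raise ConfigurationError(
                    "mediated_trans effect requires both cis_gene_id and trans_gene_id"
                )
            if self.a == 0 or self.b == 0:
                raise ConfigurationError("mediated_trans effect requires a != 0 and b != 0")
        else:  # direct_trans
            if self.trans_gene_id is None or self.c == 0:
                raise ConfigurationError("direct_trans effect requires trans_gene_id and c != 0")
            if self.cis_gene_id is not None:
                raise ConfigurationError("direct_trans effect carries no cis gene")


@dataclass
class SimulationConfig:
    """Cohort-scale parameters of the synthetic study.

    Defaults describe a desk-scale cohort (hundreds of samples, a few
    thousand variants) with the same qualitative architecture as a large
    brain eQTL study: block LD, shared hidden expression factors, and a
    100-kb Hi-C resolution.
    """

    n_samples: int = 500
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    n_variants_per_chrom: int = 750
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 25
    ld_within_block_r: float = 0.95
    n_genes_per_chrom: int = 150
    noise_sd: float = 1.0
    n_hidden_factors: int = 5
    factor_sd: float = 0.3
    effects: tuple[PlantedEffect, ...] = field(default_factory=tuple)
    hic_resolution_bp: int = 100_000
    hic_baseline_mean: float = 5.0
    hic_enrichment_factor: float = 5.0
    gwas_n: int = 20_000
    gwas_effect_size: float = 0.08
    gwas_causal_variants: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        self.effects = tuple(self.effects)
        counts = {
            "n_samples": self.n_samples,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_variants_per_chrom": self.n_variants_per_chrom,
            "ld_block_size": self.ld_block_size,
            "n_genes_per_chrom": self.n_genes_per_chrom,
            "hic_resolution_bp": self.hic_resolution_bp,
            "gwas_n": self.gwas_n,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_within_block_r <= 1.0):
            raise ConfigurationError("ld_within_block_r must lie in [0, 1]")
        if self.n_hidden_factors < 0:
            raise ConfigurationError("n_hidden_factors must be >= 0")
        if self.noise_sd < 0 or self.factor_sd < 0:
            raise ConfigurationError("noise_sd and factor_sd must be >= 0")
        if self.hic_enrichment_factor < 1.0:
            raise ConfigurationError("hic_enrichment_factor must be >= 1")
        if self.hic_baseline_mean < 0:
            raise ConfigurationError("hic_baseline_mean must be >= 0")

    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    def with_effects(self, effects) -> "SimulationConfig":
        return replace(self, effects=tuple(effects))


@dataclass
class RegulatoryTruth:
    """Ground truth exported with a simulated cohort.

    ``hotspot_variants`` are variants with >= 3 distinct planted trans
    targets; ``enriched_contact_pairs`` are the interchromosomal
    (chrom, bin) pairs of planted SNP/trans-gene couples; both are derived
    from ``effects`` so they stay consistent by construction.
    """

    effects: tuple[PlantedEffect, ...]
    hotspot_variants: frozenset[str]
    enriched_contact_pairs: frozenset[tuple[tuple[str, int], tuple[str, int]]]
    gwas_causal_variants: frozenset[str]

    def trans_pairs(self) -> list[tuple[str, str]]:
        """All planted (variant, trans gene) pairs."""
        return [
            (e.variant_id, e.trans_gene_id)
            for e in self.effects
            if e.kind in ("mediated_trans", "direct_trans")
        ]

    def mediated_triples(self) -> list[tuple[str, str, str]]:
        """All planted (variant, cis gene, trans gene) mediation paths."""
        return [
            (e.variant_id, e.cis_gene_id, e.trans_gene_id)
            for e in self.effects
            if e.kind == "mediated_trans"
        ]


@dataclass
class GenotypeMatrix:
    """Dosages (samples x variants, values in [0, 2]) plus a variant table.

    ``dosage`` is a DataFrame indexed by sample id with variant-id columns;
    ``variants`` is indexed by variant id with columns
    (chrom, pos, ref, alt, maf).
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[variant_id].to_numpy()


@dataclass
class ExpressionMatrix:
    """Expression values (genes x samples) plus a gene coordinate table.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``genes`` is indexed by gene id with columns (chrom, tss, strand).
    """

    values: pd.DataFrame
    genes: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


class ContactMatrix:
    """A normalized interchromosomal contact map at fixed resolution.

    Entries are stored once per unordered bin pair under a canonical
    chromosome order; :meth:`lookup` is symmetric under pair swap.
    """

    def __init__(self, resolution_bp: int, entries: pd.DataFrame):
        if resolution_bp <= 0:
            raise ConfigurationError("resolution_bp must be positive")
        self.resolution_bp = int(resolution_bp)
        self.entries = entries.reset_index(drop=True)
        self._index: dict[tuple[str, int, str, int], float] = {
            (ca, int(ba), cb, int(bb)): float(f)
            for ca, ba, cb, bb, f in zip(
                entries["chrom_a"], entries["bin_a"],
                entries["chrom_b"], entries["bin_b"], entries["freq"],
            )
        }
        bins: dict[str, set[int]] = {}
        for ca, ba, cb, bb in zip(
            entries["chrom_a"], entries["bin_a"], entries["chrom_b"], entries["bin_b"]
        ):
            bins.setdefault(ca, set()).add(int(ba))
            bins.setdefault(cb, set()).add(int(bb))
        self.bins_by_chrom = {c: np.array(sorted(b)) for c, b in bins.items()}

    def lookup(self, chrom_a: str, bin_a: int, chrom_b: str, bin_b: int) -> float:
        key = canonical_pair((chrom_a, int(bin_a)), (chrom_b, int(bin_b)))
        return self._index.get((key[0][0], key[0][1], key[1][0], key[1][1]), 0.0)


@dataclass
class GWASSummary:
    """Per-variant GWAS summary statistics for one trait.

    ``table`` is indexed by variant id with columns
    (chrom, pos, beta, se, p, n); p is the two-sided normal tail of beta/se.
    """

    trait: str
    table: pd.DataFrame


def canonical_pair(a: tuple[str, int], b: tuple[str, int]) -> tuple[tuple[str, int], tuple[str, int]]:
    """Order an unordered (chrom, bin) pair canonically."""
    return (a, b) if a <= b else (b, a)


def position_to_bin(pos: int, resolution_bp: int) -> int:
    """0-based half-open genomic bin of a position: floor(pos / resolution)."""
    if pos < 0:
        raise ConfigurationError(f"negative genomic position {pos}")
    return int(pos) // int(resolution_bp)


# ---------------------------------------------------------------------------
# genotypes


def _variant_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing positions: an even grid with sub-spacing jitter."""
    v = cfg.n_variants_per_chrom
    spacing = cfg.chrom_length_bp // (v + 1)
    if spacing < 4:
        raise ConfigurationError("chromosome too short for the requested variant count")
    base = spacing * np.arange(1, v + 1)
    jitter = rng.integers(-(spacing // 4), spacing // 4 + 1, size=v)
    return base + jitter


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw dosages under Hardy-Weinberg with block-structured LD.

    Each variant's two haplotype alleles are indicators of a latent Gaussian
    falling below the MAF quantile. Within an LD block all variants share a
    latent haplotype signal with weight ``ld_within_block_r``, so pairwise
    dosage correlation approximates the configured target (it is attenuated
    somewhat by the threshold step; ``ld_within_block_r=1`` with a constant
    MAF gives identical columns). Monomorphic draws are rejected and the
    whole block redrawn, keeping determinism.
    """
    rng = rng_stream(config.seed, "genotypes")
    n = config.n_samples
    rho = config.ld_within_block_r
    lo, hi = config.maf_range

    columns, ids, rows = [], [], []
    for chrom in config.chromosomes():
        mafs = rng.uniform(lo, hi, size=config.n_variants_per_chrom)
        positions = _variant_positions(config, rng)
        bases = rng.choice(["A", "C", "G", "T"], size=(config.n_variants_per_chrom, 2))
        for start in range(0, config.n_variants_per_chrom, config.ld_block_size):
            stop = min(start + config.ld_block_size, config.n_variants_per_chrom)
            thr = stats.norm.ppf(mafs[start:stop])  # (block,)
            block = stop - start
            for _attempt in range(100):
                latent = rng.normal(size=(n, 2, 1))
                noise = rng.normal(size=(n, 2, block))
                x = math.sqrt(rho) * latent + math.sqrt(1.0 - rho) * noise
                alleles = x < thr[None, None, :]
                dosage = alleles.sum(axis=1).astype(float)  # (n, block)
                if np.all(dosage.min(axis=0) < dosage.max(axis=0)):
                    break
            else:
                raise ConfigurationError(
                    "could not draw a polymorphic LD block; increase n_samples or MAF"
                )
            columns.append(dosage)
        for i, pos in enumerate(positions):
            ids.append(f"var_{chrom}_{i:05d}")
            rows.append((chrom, int(pos), bases[i, 0], bases[i, 1], float(mafs[i])))

    dosage = np.concatenate(columns, axis=1)
    sample_ids = [f"sample_{i:05d}" for i in range(n)]
    variants = pd.DataFrame(rows, index=pd.Index(ids, name="variant_id"),
                            columns=["chrom", "pos", "ref", "alt", "maf"])
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=pd.Index(sample_ids, name="sample_id"), columns=ids),
        variants=variants,
    )


# ---------------------------------------------------------------------------
# expression


def _gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    rows, ids = [], []
    spacing = cfg.chrom_length_bp // (cfg.n_genes_per_chrom + 1)
    for chrom in cfg.chromosomes():
        for i in range(cfg.n_genes_per_chrom):
            ids.append(f"gene_{chrom}_{i:04d}")
            rows.append((chrom, spacing * (i + 1), "+" if i % 2 == 0 else "-"))
    return pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"),
                        columns=["chrom", "tss", "strand"])


def _derive_truth(cfg: SimulationConfig, genotypes: GenotypeMatrix,
                  genes: pd.DataFrame) -> RegulatoryTruth:
    trans_targets: dict[str, set[str]] = {}
    enriched: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    trans_variants: list[str] = []
    for e in cfg.effects:
        if e.kind == "cis":
            continue
        trans_targets.setdefault(e.variant_id, set()).add(e.trans_gene_id)
        trans_variants.append(e.variant_id)
        v_chrom = genotypes.variants.at[e.variant_id, "chrom"]
        g_chrom = genes.at[e.trans_gene_id, "chrom"]
        if v_chrom != g_chrom:
            v_bin = position_to_bin(genotypes.variants.at[e.variant_id, "pos"],
                                    cfg.hic_resolution_bp)
            g_bin = position_to_bin(genes.at[e.trans_gene_id, "tss"], cfg.hic_resolution_bp)
            enriched.add(canonical_pair((v_chrom, v_bin), (g_chrom, g_bin)))
    hotspots = frozenset(v for v, targets in trans_targets.items() if len(targets) >= 3)
    if cfg.gwas_causal_variants is not None:
        causal = frozenset(cfg.gwas_causal_variants)
    else:
        causal = frozenset(trans_variants)
    return RegulatoryTruth(
        effects=cfg.effects,
        hotspot_variants=hotspots,
        enriched_contact_pairs=frozenset(enriched),
        gwas_causal_variants=causal,
    )


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, RegulatoryTruth]:
    """Generate expression from hidden factors, noise and planted effects.

    Structural model per sample: a cis gene gets ``a * dosage`` on top of its
    factor + noise background; a mediated trans gene gets
    ``b * y_cis + c * dosage``; a direct trans gene gets ``c * dosage``.
    Mediated effects read the *realized* cis-gene expression, so the implied
    SNP -> trans path coefficient is ``a * b (+ c)``. A mediated effect
    requires its cis gene to carry a planted cis effect for the same variant;
    chains (a trans target acting as another path's mediator) are not
    supported.
    """
    genes = _gene_table(config)
    _validate_effects(config, genotypes, genes)
    rng = rng_stream(config.seed, "expression")
    n, g = config.n_samples, len(genes)

    loadings = rng.normal(0.0, config.factor_sd, size=(g, config.n_hidden_factors))
    scores = rng.normal(size=(config.n_hidden_factors, n))
    values = loadings @ scores if config.n_hidden_factors else np.zeros((g, n))
    values = values + rng.normal(0.0, config.noise_sd, size=(g, n))

    gene_pos = {gid: i for i, gid in enumerate(genes.index)}
    dosage = genotypes.dosage
    for e in config.effects:
        if e.kind == "cis":
            values[gene_pos[e.cis_gene_id]] += e.a * dosage[e.variant_id].to_numpy()
    for e in config.effects:
        if e.kind == "mediated_trans":
            values[gene_pos[e.trans_gene_id]] += (
                e.b * values[gene_pos[e.cis_gene_id]]
                + e.c * dosage[e.variant_id].to_numpy()
            )
        elif e.kind == "direct_trans":
            values[gene_pos[e.trans_gene_id]] += e.c * dosage[e.variant_id].to_numpy()

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes.index.copy(), columns=dosage.index),
        genes=genes,
    )
    return expr, _derive_truth(config, genotypes, genes)


def _validate_effects(cfg: SimulationConfig, genotypes: GenotypeMatrix,
                      genes: pd.DataFrame) -> None:
    variant_ids = set(genotypes.variants.index)
    gene_ids = set(genes.index)
    cis_planted = {(e.variant_id, e.cis_gene_id) for e in cfg.effects if e.kind == "cis"}
    for e in cfg.effects:
        if e.variant_id not in variant_ids:
            raise ConfigurationError(f"planted effect references unknown variant {e.variant_id}")
        for gid in (e.cis_gene_id, e.trans_gene_id):
            if gid is not None and gid not in gene_ids:
                raise ConfigurationError(f"planted effect references unknown gene {gid}")
        if e.kind == "mediated_trans" and (e.variant_id, e.cis_gene_id) not in cis_planted:
            raise ConfigurationError(
                f"mediated effect on {e.trans_gene_id} requires a planted cis effect "
                f"for ({e.variant_id}, {e.cis_gene_id})"
            )


# ---------------------------------------------------------------------------
# Hi-C contacts


def simulate_contact_matrix(truth: RegulatoryTruth, config: SimulationConfig) -> ContactMatrix:
    """Poisson interchromosomal contacts with planted enrichment.

    Baseline frequencies are Poisson(``hic_baseline_mean``); bin pairs listed
    in ``truth.enriched_contact_pairs`` are redrawn from
    Poisson(mean * ``hic_enrichment_factor``). Only interchromosomal pairs
    are generated; lookups are symmetric.
    """
    rng = rng_stream(config.seed, "hic")
    chroms = config.chromosomes()
    n_bins = -(-config.chrom_length_bp // config.hic_resolution_bp)
    total = n_bins * n_bins * len(chroms) * (len(chroms) - 1) // 2
    if total > 5_000_000:
        raise ConfigurationError("contact matrix too large; coarsen hic_resolution_bp")

    frames = []
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            freq = rng.poisson(config.hic_baseline_mean, size=(n_bins, n_bins)).astype(float)
            ba, bb = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
            frames.append(pd.DataFrame({
                "chrom_a": ca, "bin_a": ba.ravel(),
                "chrom_b": cb, "bin_b": bb.ravel(),
                "freq": freq.ravel(),
            }))
    entries = pd.concat(frames, ignore_index=True)

    enrich_rng = rng_stream(config.seed, "hic", "enriched")
    index = pd.MultiIndex.from_frame(entries[["chrom_a", "bin_a", "chrom_b", "bin_b"]])
    lookup = pd.Series(np.arange(len(entries)), index=index)
    for (a, b) in sorted(truth.enriched_contact_pairs):
        key = (a[0], a[1], b[0], b[1])
        if key in lookup.index:
            entries.loc[lookup[key], "freq"] = float(
                enrich_rng.poisson(config.hic_baseline_mean * config.hic_enrichment_factor)
            )
    return ContactMatrix(config.hic_resolution_bp, entries)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_summary(
    genotypes: GenotypeMatrix, truth: RegulatoryTruth, config: SimulationConfig
) -> GWASSummary:
    """Single-causal-variant GWAS summary statistics.

    Each causal variant receives a latent standardized effect of magnitude
    ``gwas_effect_size`` (random sign), i.e. an expected z-score of
    ``gwas_effect_size * sqrt(gwas_n)``. Non-causal variants inherit the
    causal z scaled by their empirical dosage correlation (the standard
    single-causal-variant approximation), plus unit Gaussian noise;
    beta = z / sqrt(n), se = 1 / sqrt(n), p the two-sided normal tail.
    """
    rng = rng_stream(config.seed, "gwas")
    variants = genotypes.variants
    v = len(variants)
    missing = truth.gwas_causal_variants - set(variants.index)
    if missing:
        raise ConfigurationError(f"GWAS causal variants not in the cohort: {sorted(missing)}")

    z = rng.normal(size=v)
    dosage = genotypes.dosage.to_numpy()
    centered = dosage - dosage.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    chrom_arr = variants["chrom"].to_numpy()
    col_of = {vid: i for i, vid in enumerate(variants.index)}
    for vid in sorted(truth.gwas_causal_variants):
        j = col_of[vid]
        lam = config.gwas_effect_size * math.sqrt(config.gwas_n) * rng.choice([-1.0, 1.0])
        same = np.flatnonzero(chrom_arr == chrom_arr[j])
        r = centered[:, same].T @ centered[:, j] / (norms[same] * norms[j])
        z[same] = z[same] + r * lam

    se = 1.0 / math.sqrt(config.gwas_n)
    beta = z * se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "n": config.gwas_n,
        },
        index=variants.index.copy(),
    )
    return GWASSummary(trait="synthetic_trait", table=table)
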