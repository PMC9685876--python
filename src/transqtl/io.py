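"""Plain-text readers and writers for the cohort artifacts.

Formats: dosage TSV and minimal VCF (GT:DS) for genotypes, genes x samples
TSV for expression and covariates, BED6 for gene TSS anchors (0-based
half-open), 5-column TSV for interchromosomal contacts, TSV for GWAS
summary statistics and for the ground-truth tables, and a two-interval TSV
for cross-mappability blacklist pairs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError
from .simulate import (
    ContactMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    GWASSummary,
    RegulatoryTruth,
)

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf",
    "write_expression_tsv", "read_expression_tsv",
    "write_covariates_tsv", "read_covariates_tsv",
    "write_gene_bed",
    "write_contacts_tsv", "read_contacts_tsv",
    "write_gwas_tsv", "read_gwas_tsv",
    "write_truth_tables",
    "read_blacklist_tsv",
]


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Variants as rows: id, chrom, pos, ref, alt, maf, then sample columns."""
    out = pd.concat([genotypes.variants, genotypes.dosage.T], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    meta_cols = ["chrom", "pos", "ref", "alt", "maf"]
    variants = df[meta_cols].copy()
    dosage = df.drop(columns=meta_cols).T.astype(float)
    dosage.index.name = "sample_id"
    return GenotypeMatrix(dosage=dosage, variants=variants)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT:DS fields; GT is the rounded dosage."""
    variants = genotypes.variants
    samples = genotypes.sample_ids
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in variants["chrom"].unique():
            length = int(variants.loc[variants["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dosage = genotypes.dosage.to_numpy(dtype=float)
        for j, (vid, row) in enumerate(variants.iterrows()):
            calls = [
                f"{gt_codes[int(round(min(max(d, 0.0), 2.0)))]}:{d:.3f}"
                for d in dosage[:, j]
            ]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n")


def write_expression_tsv(expr: ExpressionMatrix, path, gene_table_path=None) -> None:
    """Genes x samples TSV (header = sample ids); optional gene table TSV."""
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    if gene_table_path is not None:
        expr.genes.to_csv(gene_table_path, sep="\t", index_label="gene_id")


def read_expression_tsv(path, gene_table_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    if gene_table_path is not None:
        genes = pd.read_csv(gene_table_path, sep="\t", index_col="gene_id")
    else:
        genes = pd.DataFrame(index=values.index)
    return ExpressionMatrix(values=values, genes=genes)


def write_covariates_tsv(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """BED6 of TSS anchors: 0-based half-open single-base intervals."""
    with open(path, "w") as fh:
        for gid, row in genes.iterrows():
            tss = int(row["tss"])
            fh.write(f"{row['chrom']}\t{tss}\t{tss + 1}\t{gid}\t0\t{row['strand']}\n")


def write_contacts_tsv(contacts: ContactMatrix, path) -> None:
    """5-column TSV: chrom_a, bin_a, chrom_b, bin_b, freq."""
    contacts.entries.to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path, resolution_bp: int) -> ContactMatrix:
    entries = pd.read_csv(path, sep="\t")
    expected = ["chrom_a", "bin_a", "chrom_b", "bin_b", "freq"]
    if list(entries.columns) != expected:
        raise ParseError(f"contact TSV must have columns {expected}")
    return ContactMatrix(resolution_bp, entries)


def write_gwas_tsv(gwas: GWASSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index_label="variant_id")


def read_gwas_tsv(path, trait: str = "trait") -> GWASSummary:
    table = pd.read_csv(path, sep="\t", index_col="variant_id")
    return GWASSummary(trait=trait, table=table)


def write_truth_tables(truth: RegulatoryTruth, outdir) -> None:
    """Export the planted ground truth as TSVs (effects, hotspots, contacts, GWAS)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effects = pd.DataFrame([
        {
            "kind": e.kind, "variant_id": e.variant_id,
            "cis_gene_id": e.cis_gene_id or "", "trans_gene_id": e.trans_gene_id or "",
            "a": e.a, "b": e.b, "c": e.c,
        }
        for e in truth.effects
    ])
    effects.to_csv(outdir / "planted_effects.tsv", sep="\t", index=False)
    pd.DataFrame({"variant_id": sorted(truth.hotspot_variants)}).to_csv(
        outdir / "hotspot_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom_a": a[0], "bin_a": a[1], "chrom_b": b[0], "bin_b": b[1]}
            for a, b in sorted(truth.enriched_contact_pairs)
        ],
        columns=["chrom_a", "bin_a", "chrom_b", "bin_b"],
    ).to_csv(outdir / "enriched_contact_pairs.tsv", sep="\t", index=False)
    pd.DataFrame({"variant_id": sorted(truth.gwas_causal_variants)}).to_csv(
        outdir / "gwas_causal_variants.tsv", sep="\t", index=False)


def read_blacklist_tsv(path):
    """Cross-mappability pairs: chrom_a start_a end_a chrom_b start_b end_b.

    Returns a list of interval pairs for :func:`transqtl.scan.cross_map_filter`.
    Raises :class:`ParseError` with the line number on malformed rows.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError("blacklist rows need 6 tab-separated fields", line=lineno)
            try:
                pairs.append((
                    (fields[0], int(fields[1]), int(fields[2])),
                    (fields[3], int(fields[4]), int(fields[5])),
                ))
            except ValueError as exc:
                raise ParseError(f"bad interval coordinates: {exc}", line=lineno) from None
    return pairs
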