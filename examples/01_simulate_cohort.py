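"""Simulate a cohort with planted regulatory architecture and export it.

Builds a small genotype-expression cohort in which every cis effect,
cis-mediated trans effect, direct trans effect, hotspot, enriched Hi-C
contact and GWAS causal variant is known, then writes all artifacts as
plain-text files under ./cohort_out.
"""

from pathlib import Path

import transqtl as tq
from transqtl import io

cfg = tq.planted_cohort_config(seed=1, n_samples=300, n_hotspots=2,
                               hotspot_targets=3, n_single_mediated=3,
                               n_direct=4)
cohort = tq.simulate_cohort(cfg)

outdir = Path("cohort_out")
outdir.mkdir(exist_ok=True)
io.write_dosage_tsv(cohort.genotypes, outdir / "dosage.tsv")
io.write_vcf(cohort.genotypes, outdir / "genotypes.vcf")
io.write_expression_tsv(cohort.expression, outdir / "expression.tsv",
                        outdir / "genes.tsv")
io.write_gene_bed(cohort.expression.genes, outdir / "genes.bed")
io.write_contacts_tsv(cohort.contacts, outdir / "contacts.tsv")
io.write_gwas_tsv(cohort.gwas, outdir / "gwas.tsv")
io.write_truth_tables(cohort.truth, outdir / "truth")

n_trans = len(cohort.truth.trans_pairs())
print(f"samples:            {cfg.n_samples}")
print(f"variants:           {len(cohort.genotypes.variant_ids)}")
print(f"genes:              {len(cohort.expression.gene_ids)}")
print(f"planted effects:    {len(cfg.effects)} ({n_trans} trans pairs)")
print(f"planted hotspots:   {sorted(cohort.truth.hotspot_variants)}")
print(f"GWAS causal SNPs:   {sorted(cohort.truth.gwas_causal_variants)}")
print(f"artifacts written to {outdir}/")
# Each planted trans pair couples a SNP to a gene on another chromosome;
# the truth/ tables let any downstream caller score recovery exactly.
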