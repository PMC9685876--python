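"""Association scanning, filtering, LD pruning and the three FDR schemes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import transqtl as tq
from transqtl.errors import TransQTLError
from transqtl.scan import sidak_correction

from conftest import expression_from_values, genotypes_from_dosage


def _unit(v):
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    return v / np.linalg.norm(v)


def correlated_column(base, r, rng):
    """A column with exact sample correlation r to ``base`` (Gram-Schmidt)."""
    u = _unit(base)
    e = rng.normal(size=len(base))
    e = _unit(e - (e @ u) * u - e.mean())
    return r * u + np.sqrt(1 - r * r) * e


class TestNominalScan:
    def test_matches_textbook_simple_regression(self):
        # 5-sample toy, no covariates: closed-form normal equations
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        geno = genotypes_from_dosage(g[:, None], chrom="chr1")
        expr = expression_from_values(y[None, :], chrom="chr2")
        rec = tq.nominal_scan(expr, geno, mode="trans").iloc[0]

        gc = g - g.mean()
        beta_hat = (gc @ y) / (gc @ gc)
        resid = y - y.mean() - beta_hat * gc
        se_hat = np.sqrt((resid @ resid) / 3.0 / (gc @ gc))
        t = beta_hat / se_hat
        p_hat = 2 * stats.t.sf(abs(t), 3)
        assert rec["beta"] == pytest.approx(beta_hat, rel=1e-10)
        assert rec["se"] == pytest.approx(se_hat, rel=1e-10)
        assert rec["p"] == pytest.approx(p_hat, rel=1e-8)
        assert rec["df"] == 3
        # record invariant: p consistent with t = beta/se at df
        assert rec["p"] == pytest.approx(
            2 * stats.t.sf(abs(rec["beta"] / rec["se"]), rec["df"]), rel=1e-8)

    def test_matches_full_model_with_covariates(self):
        # Frisch-Waugh shortcut equals the full multiple regression
        rng = np.random.default_rng(4)
        n = 80
        g = rng.binomial(2, 0.4, size=n).astype(float)
        c = rng.normal(size=(n, 3))
        y = 0.3 * g + c @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        geno = genotypes_from_dosage(g[:, None], chrom="chr1")
        expr = expression_from_values(y[None, :], chrom="chr2")
        cov = pd.DataFrame(c, index=geno.sample_ids, columns=list("abc"))
        rec = tq.nominal_scan(expr, geno, cov, mode="trans").iloc[0]

        design = np.column_stack([np.ones(n), g, c])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sigma2 = resid @ resid / (n - design.shape[1])
        cov_beta = sigma2 * np.linalg.inv(design.T @ design)
        assert rec["beta"] == pytest.approx(coef[1], rel=1e-8)
        assert rec["se"] == pytest.approx(np.sqrt(cov_beta[1, 1]), rel=1e-8)
        assert rec["df"] == n - 3 - 2

    def test_window_definitions(self):
        # gene at 6 Mb on chr1; variants at 4.9 Mb (mid-zone), 5.5 Mb (cis),
        # 11.5 Mb (trans by distance), plus one on chr2 (trans)
        geno = genotypes_from_dosage(
            np.random.default_rng(0).binomial(2, 0.4, size=(50, 4)).astype(float))
        geno.variants.loc[:, "chrom"] = ["chr1", "chr1", "chr1", "chr2"]
        geno.variants.loc[:, "pos"] = [1_100_000, 5_500_000, 11_500_000, 200_000]
        expr = expression_from_values(
            np.random.default_rng(1).normal(size=(1, 50)), chrom="chr1")
        expr.genes.loc[:, "tss"] = [6_000_000]
        trans = tq.nominal_scan(expr, geno, mode="trans")
        assert set(trans["variant_id"]) == {"v2", "v3"}  # 4.9 Mb apart is excluded
        cis = tq.nominal_scan(expr, geno, mode="cis")
        assert set(cis["variant_id"]) == {"v1"}

    def test_monomorphic_variants_skipped(self):
        dosage = np.ones((30, 2))
        dosage[:, 1] = np.random.default_rng(0).binomial(2, 0.5, 30)
        geno = genotypes_from_dosage(dosage, chrom="chr1")
        expr = expression_from_values(
            np.random.default_rng(1).normal(size=(2, 30)), chrom="chr2")
        recs = tq.nominal_scan(expr, geno, mode="trans")
        assert set(recs["variant_id"]) == {"v1"}

    def test_null_pvalues_uniform(self):
        # pure-null cohort with hidden factors included as covariates
        cfg = tq.SimulationConfig(
            n_samples=200, n_chromosomes=2, n_variants_per_chrom=25,
            n_genes_per_chrom=20, ld_block_size=1, ld_within_block_r=0.0,
            chrom_length_bp=5_000_000, seed=23,
        )
        geno = tq.simulate_genotypes(cfg)
        expr, _ = tq.simulate_expression(geno, cfg)
        expr = tq.inverse_normal_rows(tq.quantile_normalize(expr))
        cov = tq.build_covariates(expr, geno, n_factors=5, n_pcs=0)
        recs = tq.nominal_scan(expr, geno, cov, mode="trans")
        # one pair per gene, each with its own variant, to keep the KS
        # sample (approximately) independent
        genes = sorted(recs["gene_id"].unique())
        keyed = recs.set_index(["gene_id", "variant_id"])
        pvals = []
        for i, g in enumerate(genes):
            other = "chr2" if "chr1" in g else "chr1"
            v = f"var_{other}_{i % 25:05d}"
            if (g, v) in keyed.index:
                pvals.append(keyed.at[(g, v), "p"])
        assert len(pvals) >= 30
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCrossMapFilter:
    def _toy(self):
        rng = np.random.default_rng(0)
        geno = genotypes_from_dosage(rng.binomial(2, 0.4, (20, 10)).astype(float),
                                     chrom="chr1", spacing=100_000)
        expr = expression_from_values(rng.normal(size=(10, 20)), chrom="chr2",
                                      spacing=100_000)
        recs = tq.nominal_scan(expr, geno, mode="trans")
        return geno, expr, recs

    def test_matching_records_removed(self):
        geno, expr, recs = self._toy()
        recs = recs.head(10).reset_index(drop=True)
        # blacklist intervals covering the first 3 records' loci
        pairs = []
        for i in range(3):
            vp = geno.variants.at[recs.at[i, "variant_id"], "pos"]
            gp = expr.genes.at[recs.at[i, "gene_id"], "tss"]
            pairs.append((("chr1", vp, vp + 1), ("chr2", gp, gp + 1)))
        out = tq.cross_map_filter(recs, pairs, geno.variants, expr.genes)
        assert len(out) == 7
        # unordered: swapped orientation removes the same records
        swapped = [(b, a) for a, b in pairs]
        out2 = tq.cross_map_filter(recs, swapped, geno.variants, expr.genes)
        assert len(out2) == 7

    def test_empty_blacklist_is_identity(self):
        geno, expr, recs = self._toy()
        out = tq.cross_map_filter(recs, [], geno.variants, expr.genes)
        pd.testing.assert_frame_equal(out, recs.reset_index(drop=True))


class TestLDPrune:
    def _records(self, pvals, variant_ids):
        return pd.DataFrame({
            "variant_id": variant_ids,
            "gene_id": [f"g{i}" for i in range(len(pvals))],
            "beta": 1.0, "se": 1.0, "p": pvals, "df": 10, "label": "trans",
        })

    def test_duplicate_variant_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=40)
        dosage = np.column_stack([base, base])  # r^2 = 1
        geno = genotypes_from_dosage(dosage)
        recs = self._records([0.01, 0.002], ["v0", "v1"])
        out = tq.ld_prune(recs, geno, r2_threshold=0.6)
        assert list(out["variant_id"]) == ["v1"]

    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(1)
        geno = genotypes_from_dosage(rng.normal(size=(60, 4)))
        recs = self._records([0.04, 0.01, 0.03, 0.02], ["v0", "v1", "v2", "v3"])
        out = tq.ld_prune(recs, geno, r2_threshold=0.6)
        assert len(out) == 4

    def test_chain_keeps_first_and_third(self):
        # A-B r2=0.8, B-C r2=0.7, A-C r2=0.3, p(A)<p(B)<p(C): B is pruned by
        # A, C is independent of A (0.3 <= 0.6) so the greedy keeps A and C
        rng = np.random.default_rng(2)
        a = _unit(rng.normal(size=200))
        b = correlated_column(a, np.sqrt(0.8), rng)
        rb = b - (b @ a) * a
        rb /= np.linalg.norm(rb)
        x = np.sqrt(0.3)
        y = (np.sqrt(0.7) - x * (a @ b)) / (rb @ b)
        e = rng.normal(size=200)
        e = _unit(e - (e @ a) * a - (e @ rb) * rb)
        c = x * a + y * rb + np.sqrt(1 - x ** 2 - y ** 2) * e
        geno = genotypes_from_dosage(np.column_stack([a, b, c]))
        assert np.corrcoef(a, b)[0, 1] ** 2 == pytest.approx(0.8, abs=1e-9)
        assert np.corrcoef(b, c)[0, 1] ** 2 == pytest.approx(0.7, abs=1e-9)
        assert np.corrcoef(a, c)[0, 1] ** 2 == pytest.approx(0.3, abs=1e-9)
        recs = self._records([0.001, 0.01, 0.02], ["v0", "v1", "v2"])
        out = tq.ld_prune(recs, geno, r2_threshold=0.6)
        assert list(out["variant_id"]) == ["v0", "v2"]

    def test_kept_records_of_one_variant_survive_together(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        geno = genotypes_from_dosage(base[:, None])
        recs = pd.DataFrame({
            "variant_id": ["v0", "v0", "v0"],
            "gene_id": ["g1", "g2", "g3"],
            "beta": 1.0, "se": 1.0, "p": [0.01, 0.02, 0.03], "df": 10,
            "label": "trans",
        })
        out = tq.ld_prune(recs, geno)
        assert len(out) == 3  # one independent eSNP with three target genes

    def test_max_pairwise_r2_below_threshold(self):
        cfg = tq.SimulationConfig(n_samples=300, n_chromosomes=1,
                                  n_variants_per_chrom=40, n_genes_per_chrom=5,
                                  ld_block_size=8, ld_within_block_r=0.97,
                                  chrom_length_bp=4_000_000, seed=7)
        geno = tq.simulate_genotypes(cfg)
        recs = pd.DataFrame({
            "variant_id": geno.variant_ids,
            "gene_id": "g_far",
            "beta": 1.0, "se": 1.0,
            "p": np.random.default_rng(0).uniform(size=40),
            "df": 10, "label": "trans",
        })
        out = tq.ld_prune(recs, geno, r2_threshold=0.6)
        kept = out["variant_id"].unique()
        dos = geno.dosage[kept].to_numpy()
        r2 = np.corrcoef(dos.T) ** 2
        np.fill_diagonal(r2, 0.0)
        assert r2.max() <= 0.6 + 1e-12


class TestPooledFDR:
    def _records(self, pvals):
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(len(pvals))],
            "gene_id": "g0", "beta": 1.0, "se": 1.0, "p": pvals, "df": 10,
            "label": "trans",
        })

    def test_brute_force_bh_on_four_pvalues(self):
        # BH by hand: q_i = min_{j>=i} p_(j) * m / j -> (0.04, 0.04, 0.04, 0.04)
        out = tq.pooled_fdr(self._records([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert len(out.records) == 4
        np.testing.assert_allclose(out.records["q"], [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_rejected_and_single_record(self):
        assert len(tq.pooled_fdr(self._records([1.0, 1.0, 1.0]), 0.9999).records) == 0
        single = tq.pooled_fdr(self._records([0.2]), alpha=0.25)
        assert len(single.records) == 1 and single.records.at[0, "q"] == 0.2

    def test_monotone_in_alpha_and_alpha_one_returns_all(self):
        rng = np.random.default_rng(0)
        recs = self._records(rng.uniform(size=100))
        sizes = [len(tq.pooled_fdr(recs, a).records) for a in (0.05, 0.25, 0.5, 1.0000001)]
        assert sizes == sorted(sizes)
        assert sizes[-1] == 100

    def test_empty_input_is_empty_list(self):
        out = tq.pooled_fdr(self._records([]).iloc[:0], alpha=0.05)
        assert len(out.records) == 0 and out.scheme == "pooled"


class TestHierarchicalGeneFDR:
    def test_sidak_formula(self):
        assert sidak_correction(0.001, 100) == pytest.approx(1 - 0.999 ** 100, rel=1e-12)
        assert sidak_correction(0.001, 100) == pytest.approx(0.0952, abs=5e-4)
        # non-decreasing in m
        ms = np.array([1, 10, 100, 1000])
        vals = sidak_correction(0.001, ms)
        assert np.all(np.diff(vals) > 0)

    def test_single_gene_single_snp_reduces_to_p(self):
        recs = pd.DataFrame({
            "variant_id": ["v0"], "gene_id": ["g0"], "beta": [1.0],
            "se": [1.0], "p": [0.03], "df": 10, "label": "trans",
        })
        out = tq.hierarchical_gene_fdr(recs, {"g0": 1}, alpha=0.05)
        assert out.at[0, "p_gene"] == pytest.approx(0.03)
        assert out.at[0, "q"] == pytest.approx(0.03)
        assert bool(out.at[0, "is_egene"])

    def test_missing_or_zero_m_raises(self):
        recs = pd.DataFrame({
            "variant_id": ["v0"], "gene_id": ["g0"], "beta": [1.0],
            "se": [1.0], "p": [0.03], "df": 10, "label": "trans",
        })
        with pytest.raises(TransQTLError):
            tq.hierarchical_gene_fdr(recs, {}, alpha=0.05)
        with pytest.raises(TransQTLError):
            tq.hierarchical_gene_fdr(recs, {"g0": 0}, alpha=0.05)


class TestPermutationFDR:
    def _cohort(self, seed=31, effects=()):
        cfg = tq.SimulationConfig(
            n_samples=300, n_chromosomes=2, n_variants_per_chrom=10,
            n_genes_per_chrom=5, ld_block_size=1, ld_within_block_r=0.0,
            chrom_length_bp=2_000_000, noise_sd=0.5, n_hidden_factors=0,
            maf_range=(0.3, 0.4), seed=seed, effects=effects,
        )
        geno = tq.simulate_genotypes(cfg)
        expr, _ = tq.simulate_expression(geno, cfg)
        return geno, tq.inverse_normal_rows(expr)

    def test_strong_cis_effect_beats_all_permutations(self):
        # plant on the variant nearest the gene's TSS so it is in-window
        probe_geno = tq.simulate_genotypes(tq.SimulationConfig(
            n_samples=10, n_chromosomes=2, n_variants_per_chrom=10,
            n_genes_per_chrom=5, ld_block_size=1, ld_within_block_r=0.0,
            chrom_length_bp=2_000_000, maf_range=(0.3, 0.4), seed=31))
        tss = 2_000_000 // 6 * 3
        sub = probe_geno.variants[probe_geno.variants["chrom"] == "chr1"]
        vid = (sub["pos"] - tss).abs().idxmin()
        effects = (tq.PlantedEffect("cis", vid, cis_gene_id="gene_chr1_0002", a=2.0),)
        geno, expr = self._cohort(effects=effects)
        out = tq.permutation_gene_fdr(expr, geno, mode="cis", n_perm=1000,
                                      alpha=0.25, seed=1)
        gt = out.gene_table.set_index("gene_id")
        assert gt.at["gene_chr1_0002", "p_empirical"] == pytest.approx(1.0 / 1001.0)
        assert "gene_chr1_0002" in set(out.records["gene_id"])

    def test_null_empirical_p_uniform(self):
        # across many null genes the empirical gene-level p is uniform on its
        # discrete support
        pvals = []
        for seed in (41, 42):
            geno, expr = self._cohort(seed=seed)
            out = tq.permutation_gene_fdr(expr, geno, mode="trans", n_perm=300,
                                          alpha=0.25, seed=seed)
            pvals.extend(out.gene_table["p_empirical"].tolist())
        assert len(pvals) == 20
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_identical_seed_identical_output(self):
        geno, expr = self._cohort()
        a = tq.permutation_gene_fdr(expr, geno, mode="trans", n_perm=200, seed=5)
        b = tq.permutation_gene_fdr(expr, geno, mode="trans", n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a.gene_table, b.gene_table)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestSplitHalf:
    def test_duplicated_data_overlaps_fully(self):
        effects = (
            tq.PlantedEffect("cis", "var_chr1_00002", cis_gene_id="gene_chr1_0002", a=1.5),
            tq.PlantedEffect("direct_trans", "var_chr1_00002",
                             trans_gene_id="gene_chr2_0002", c=1.5),
        )
        cfg = tq.SimulationConfig(
            n_samples=150, n_chromosomes=2, n_variants_per_chrom=10,
            n_genes_per_chrom=5, ld_block_size=1, ld_within_block_r=0.0,
            chrom_length_bp=5_000_000, noise_sd=0.5, n_hidden_factors=0,
            maf_range=(0.3, 0.4), seed=2, effects=effects,
        )
        geno = tq.simulate_genotypes(cfg)
        expr, _ = tq.simulate_expression(geno, cfg)
        # duplicate every sample so the two folds carry identical data
        dup_ids = [f"{s}_dup" for s in geno.sample_ids]
        dosage2 = pd.DataFrame(geno.dosage.to_numpy(), index=dup_ids,
                               columns=geno.dosage.columns)
        geno2 = tq.GenotypeMatrix(dosage=pd.concat([geno.dosage, dosage2]),
                                  variants=geno.variants)
        values2 = pd.DataFrame(expr.values.to_numpy(), index=expr.values.index,
                               columns=dup_ids)
        expr2 = tq.ExpressionMatrix(values=pd.concat([expr.values, values2], axis=1),
                                    genes=expr.genes)
        res = tq.split_half_replication(
            expr2, geno2, alpha=0.05, folds=(geno.sample_ids, dup_ids))
        assert res.overlap == 1.0
        assert res.n_fold1 == res.n_fold2 > 0

    def test_random_folds_disjoint(self, tiny_cohort):
        geno, expr, _ = tiny_cohort
        res = tq.split_half_replication(tq.inverse_normal_rows(expr), geno,
                                        alpha=0.05, seed=3)
        assert not set(res.fold1_samples) & set(res.fold2_samples)
        assert len(res.fold1_samples) == len(res.fold2_samples)

    def test_null_cohorts_rarely_replicate(self):
        overlaps = []
        for seed in range(10):
            cfg = tq.SimulationConfig(
                n_samples=120, n_chromosomes=2, n_variants_per_chrom=40,
                n_genes_per_chrom=15, ld_block_size=1, ld_within_block_r=0.0,
                chrom_length_bp=5_000_000, n_hidden_factors=0, seed=100 + seed,
            )
            geno = tq.simulate_genotypes(cfg)
            expr, _ = tq.simulate_expression(geno, cfg)
            res = tq.split_half_replication(tq.inverse_normal_rows(expr), geno,
                                            alpha=0.05, seed=seed)
            overlaps.append(res.overlap)
        assert np.mean(overlaps) < 0.05


class TestElementEnrichment:
    def test_fisher_against_hypergeometric_oracle(self):
        # table (a=8, b=2, c=10, d=80): OR = 32; two-sided Fisher p equals the
        # sum of hypergeometric tail probabilities no more likely than observed
        variant_ids = [f"v{i}" for i in range(100)]
        table = pd.DataFrame({
            "chrom": "chr1",
            "pos": 1000 * (np.arange(100) + 1),
            "ref": "A", "alt": "G", "maf": 0.3,
        }, index=pd.Index(variant_ids, name="variant_id"))
        qtl = variant_ids[:10]                # 8 inside the element
        inside = variant_ids[:8] + variant_ids[10:20]  # and 10 background inside
        starts = [table.at[v, "pos"] for v in inside]
        elements = {"enh": pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": [s + 1 for s in starts]})}
        out = tq.element_enrichment(qtl, variant_ids, elements, table)
        row = out.iloc[0]
        assert row["odds_ratio"] == pytest.approx(32.0)
        assert row["proportion_qtl"] == pytest.approx(0.8)

        m, n_, k = 18, 82, 10  # hypergeometric enumeration
        probs = {x: stats.hypergeom.pmf(x, 100, m, k) for x in range(0, 11)}
        p_two = sum(v for v in probs.values() if v <= probs[8] * (1 + 1e-9))
        assert row["p"] == pytest.approx(p_two, rel=1e-8)

    def test_identical_proportions_give_null(self):
        variant_ids = [f"v{i}" for i in range(40)]
        table = pd.DataFrame({
            "chrom": "chr1", "pos": 1000 * (np.arange(40) + 1),
            "ref": "A", "alt": "G", "maf": 0.3,
        }, index=pd.Index(variant_ids, name="variant_id"))
        qtl = variant_ids[:10]
        inside = variant_ids[:5] + variant_ids[10:25]  # 50% of each group
        starts = [table.at[v, "pos"] for v in inside]
        elements = {"e": pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": [s + 1 for s in starts]})}
        row = tq.element_enrichment(qtl, variant_ids, elements, table).iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)
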