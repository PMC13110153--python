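"""Generator-level checks: genome validity, spectrum/density/segregation
recovery, copy-number-dependent coverage and bulk pileup dosages."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from tillmap.config import DEFAULT_SPECTRUM, SPECTRUM_CLASSES, GenomeSpec, TraitModel
from tillmap.synthetic import (
    build_toy_genome,
    gene_copy_multipliers,
    simulate_bulk_pileups,
    simulate_coverage,
    simulate_ems_variants,
    simulate_f2_cohort,
)
from tillmap.variant_qc import cds_sequence

from conftest import tiny_sim_config


class TestToyGenome:
    def test_gene_records_within_bounds(self, tiny_genome, tiny_config):
        genes = tiny_genome.genes
        assert len(genes) == 80
        for chrom, length in tiny_config.genome_spec.chrom_lengths.items():
            sub = genes[genes.chrom == chrom]
            assert len(sub) == 40
            assert (sub.start >= 1).all() and (sub.end <= length).all()
            # non-overlapping
            assert (sub.start.to_numpy()[1:] > sub.end.to_numpy()[:-1]).all()

    def test_every_cds_has_valid_start_and_stop(self, tiny_genome):
        for gene_id in tiny_genome.genes.gene_id:
            cds = cds_sequence(tiny_genome, gene_id)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            prot = str(Seq(cds).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]

    def test_same_seed_is_reproducible(self):
        cfg = tiny_sim_config(seed=3)
        g1 = build_toy_genome(cfg)
        g2 = build_toy_genome(cfg)
        assert g1.seqs == g2.seqs
        pd.testing.assert_frame_equal(g1.genes, g2.genes)

    def test_infeasible_packing_raises(self):
        cfg = tiny_sim_config(
            genome_spec=GenomeSpec(
                chrom_lengths={"A1": 12_000}, genes_per_chrom={"A1": 200}
            ),
            hnrt_spec=None,
        )
        with pytest.raises(ValueError, match="packing"):
            build_toy_genome(cfg)


class TestEmsVariants:
    def test_spectrum_recovered_within_3_se(self, tiny_genome):
        cfg = tiny_sim_config(n_dh_lines=1, n_shared_artifacts=0)
        cfg.ems_dose_labels = {k: 10_000 / (tiny_genome.total_length / 1e6)
                               for k in cfg.ems_dose_labels}
        variants, _ = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(5))
        snps = pd.concat(variants.values())
        snps = snps[~snps.is_indel]
        n = len(snps)
        assert n > 5000
        from tillmap.variant_qc import classify_substitution

        freq = (
            pd.Series([classify_substitution(r, a) for r, a in zip(snps.ref, snps.alt)])
            .value_counts(normalize=True)
            .reindex(SPECTRUM_CLASSES, fill_value=0.0)
        )
        for p_exp, p_obs in zip(DEFAULT_SPECTRUM, freq):
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs(p_obs - p_exp) < 3 * se

    def test_degenerate_spectrum_only_transitions(self, tiny_genome):
        cfg = tiny_sim_config(spectrum_probs=(1.0, 0, 0, 0, 0, 0), n_shared_artifacts=0)
        variants, _ = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(6))
        snps = pd.concat(variants.values())
        snps = snps[~snps.is_indel]
        assert set(zip(snps.ref, snps.alt)) <= {("C", "T"), ("G", "A")}

    def test_density_rate_recovered(self, tiny_genome):
        # 200 replicate lines at a single dose of 155 SNPs/Mb
        cfg = tiny_sim_config(n_dh_lines=200, n_shared_artifacts=0, indel_snp_ratio=0.0)
        cfg.ems_dose_labels = {k: 155.0 for k in cfg.ems_dose_labels}
        variants, truth = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(7))
        mb = tiny_genome.total_length / 1e6
        mean_count = truth.n_snps.mean()
        expected = 155.0 * mb
        se = np.sqrt(expected / len(truth))  # Poisson
        assert abs(mean_count - expected) < 3 * se

    def test_unknown_dose_label_raises(self, tiny_genome):
        cfg = tiny_sim_config()
        cfg.ems_dose_labels = {"0.1%": 100.0}  # missing the other dose groups
        with pytest.raises(ValueError, match="dose"):
            simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(0))


class TestF2Cohort:
    def test_segregation_1_2_1(self):
        cfg = tiny_sim_config(n_f2=500)
        gt, _, _ = simulate_f2_cohort(cfg, np.random.default_rng(1))
        for col in ("d_copies", "p_copies"):
            obs = gt[col].value_counts().reindex([0, 1, 2], fill_value=0)
            chi2, p = stats.chisquare(obs, f_exp=[125, 250, 125])
            assert p > 0.001

    def test_d_and_p_states_independent(self):
        cfg = tiny_sim_config(n_f2=500)
        gt, _, _ = simulate_f2_cohort(cfg, np.random.default_rng(2))
        table = pd.crosstab(gt.d_copies, gt.p_copies)
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_deletion_pair_shares_indicator(self, tiny_genome, tiny_config):
        gt, _, _ = simulate_f2_cohort(tiny_config, np.random.default_rng(3))
        samples, mult = gene_copy_multipliers(tiny_genome, tiny_config, gt)
        d1, d2 = tiny_config.hnrt_spec.deletions
        genes = tiny_genome.genes
        for seg_a, seg_b in [(d1, d2)]:
            in_a = ((genes.chrom == seg_a.chrom) & (genes["rank"] >= seg_a.start_gene)
                    & (genes["rank"] <= seg_a.end_gene)).to_numpy()
            in_b = ((genes.chrom == seg_b.chrom) & (genes["rank"] >= seg_b.start_gene)
                    & (genes["rank"] <= seg_b.end_gene)).to_numpy()
            assert (mult[in_a].min(axis=0) == mult[in_b].min(axis=0)).all()

    def test_row_count_matches_design(self):
        cfg = tiny_sim_config(n_f2=184)
        _, pheno, _ = simulate_f2_cohort(cfg, np.random.default_rng(4))
        assert len(pheno) == 184 * 2 * 2

    def test_zero_effect_null_distribution(self):
        cfg = tiny_sim_config(n_f2=500)
        cfg.trait_spec.traits = {
            "meal_adf": TraitModel(baseline=18.0, del_effect_hom=0.0, v_polygenic=0.3,
                                   h2_target=0.5)
        }
        gt, pheno, _ = simulate_f2_cohort(cfg, np.random.default_rng(5))
        em = pheno.groupby("line_id").meal_adf.mean()
        groups = [em[gt.set_index("line_id").d_copies == k] for k in (0, 2)]
        _, p = stats.ks_2samp(groups[0], groups[1])
        assert p > 0.001

    def test_invalid_h2_target_raises(self):
        with pytest.raises(ValueError, match="h2_target"):
            TraitModel(baseline=1.0, h2_target=1.5)

    def test_too_few_individuals_raises(self):
        cfg = tiny_sim_config(n_f2=3)
        with pytest.raises(ValueError, match="n_f2"):
            simulate_f2_cohort(cfg, np.random.default_rng(0))


class TestCoverage:
    def test_hom_deletion_genes_are_zero(self, tiny_genome, tiny_config):
        gt, _, _ = simulate_f2_cohort(tiny_config, np.random.default_rng(6))
        cov = simulate_coverage(gt, tiny_genome, tiny_config, np.random.default_rng(6))
        d1 = tiny_config.hnrt_spec.deletions[0]
        hom = gt[gt.d_copies == 2].line_id
        assert len(hom) > 0
        genes = tiny_genome.genes
        mask = ((genes.chrom == d1.chrom) & (genes["rank"] >= d1.start_gene)
                & (genes["rank"] <= d1.end_gene))
        assert (cov.loc[mask.to_numpy(), hom].to_numpy() == 0).all()

    def test_normal_gene_mean_matches_expectation(self, tiny_genome):
        cfg = tiny_sim_config(n_f2=100)
        gt, _, _ = simulate_f2_cohort(cfg, np.random.default_rng(7))
        cov = simulate_coverage(gt, tiny_genome, cfg, np.random.default_rng(7))
        # C1 genes outside the duplication are copy-normal for everyone
        p1 = cfg.hnrt_spec.duplication
        genes = tiny_genome.genes
        normal = ((genes.chrom == "C1")
                  & ~genes["rank"].between(p1.start_gene, p1.end_gene)).to_numpy()
        lengths = (genes.end - genes.start + 1).to_numpy()[normal]
        expected = cfg.mean_depth * lengths / cfg.read_length
        obs = cov.loc[normal, gt.line_id].mean(axis=1).to_numpy()
        disp = cfg.coverage_dispersion
        var = expected + expected**2 / disp
        se = np.sqrt(var / len(gt))
        assert (np.abs(obs - expected) < 3.5 * se).mean() > 0.98

    def test_hemi_dup_ratio_near_1_5(self, tiny_genome):
        cfg = tiny_sim_config(n_f2=200)
        gt, _, _ = simulate_f2_cohort(cfg, np.random.default_rng(8))
        cov = simulate_coverage(gt, tiny_genome, cfg, np.random.default_rng(8))
        p1 = cfg.hnrt_spec.duplication
        genes = tiny_genome.genes
        in_dup = ((genes.chrom == p1.chrom)
                  & genes["rank"].between(p1.start_gene, p1.end_gene)).to_numpy()
        hemi = gt[gt.p_copies == 1].line_id
        normal = gt[gt.p_copies == 0].line_id
        assert len(hemi) >= 50
        ratio = cov.loc[in_dup, hemi].mean(axis=1) / cov.loc[in_dup, normal].mean(axis=1)
        assert abs(ratio.mean() - 1.5) < 0.1


class TestBulkPileups:
    def test_exact_dosage_without_noise(self, tiny_genome, tiny_config):
        gt, _, _ = simulate_f2_cohort(tiny_config, np.random.default_rng(9))
        cfg = tiny_sim_config(mean_depth=10.0)
        pu = simulate_bulk_pileups(gt, tiny_genome, cfg, np.random.default_rng(9),
                                   sampling_noise=False)
        from tillmap.synthetic import causal_interval

        chrom, lo, hi = causal_interval(tiny_genome, cfg)
        causal = pu[(pu.chrom == chrom) & pu.pos.between(lo, hi)]
        assert len(causal) > 0
        hom = set(gt[gt.d_copies == 2].line_id)
        sub = causal[causal["sample"].isin(hom)]
        assert (sub.alt_count == 10).all() and (sub.ref_count == 0).all()

    def test_het_alt_fraction_binomial(self, tiny_genome):
        cfg = tiny_sim_config(n_loci_per_chrom=500)
        gt, _, _ = simulate_f2_cohort(cfg, np.random.default_rng(10))
        pu = simulate_bulk_pileups(gt, tiny_genome, cfg, np.random.default_rng(10))
        pu["total"] = pu.ref_count + pu.alt_count
        # population alt-allele frequency at unlinked loci ~ 0.5
        from tillmap.synthetic import causal_interval

        chrom, lo, hi = causal_interval(tiny_genome, cfg)
        unlinked = pu[(pu.chrom != chrom) & (pu.total > 0)]
        frac = unlinked.alt_count.sum() / unlinked.total.sum()
        se = 0.5 / np.sqrt(len(gt) * 500)  # binomial on individuals x loci
        assert abs(frac - 0.5) < 5 * se

    def test_locus_outside_genome_raises(self, tiny_genome, tiny_config):
        gt, _, _ = simulate_f2_cohort(tiny_config, np.random.default_rng(11))
        bad = pd.DataFrame(dict(chrom=["A1"], pos=[10**9]))
        with pytest.raises(ValueError, match="outside"):
            simulate_bulk_pileups(gt, tiny_genome, tiny_config,
                                  np.random.default_rng(11), loci=bad)


def test_cohort_outputs_byte_identical(tmp_path):
    import hashlib

    cfg = tiny_sim_config(seed=12)
    digests = []
    for sub in ("a", "b"):
        from tillmap.synthetic import simulate_cohort

        out = tmp_path / sub
        simulate_cohort(cfg, out)
        d = {}
        for p in sorted(out.rglob("*")):
            if p.is_file():
                d[p.relative_to(out)] = hashlib.sha256(p.read_bytes()).hexdigest()
        digests.append(d)
    assert digests[0] == digests[1]
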