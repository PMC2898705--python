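import numpy as np
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from hccsig.diffexp import two_way_anova
from hccsig.io_formats import ValidationError
from hccsig.preprocessing import DetectionThresholds, detect_calls, log2_transform
from hccsig.qpcr import delta_delta_ct
from hccsig.synthetic import (
    GeneratorParams,
    generate_cna_bed,
    generate_ct_table,
    generate_human_datasets,
    generate_ortholog_table,
    generate_rat_experiment,
)

NULL_CLASSES = dict(n_hcc_up=0, n_hcc_down=0, n_reg_specific=0, n_age_only=0, n_interaction=0)


class TestRatGenerator:
    def test_same_seed_is_bit_identical(self, default_params):
        exp1, truth1 = generate_rat_experiment(default_params)
        exp2, truth2 = generate_rat_experiment(GeneratorParams(seed=default_params.seed))
        assert_frame_equal(exp1.intensities, exp2.intensities)
        assert_frame_equal(exp1.snr, exp2.snr)
        assert_frame_equal(truth1.table, truth2.table)

    def test_noise_free_fold_change_is_exact(self):
        params = GeneratorParams(
            seed=1, n_genes=10, noise_sd=0.0, effect_log2=2.0,
            n_hcc_up=1, n_hcc_down=0, n_reg_specific=0, n_age_only=0, n_interaction=0,
            detection_dropout_rate=0.0,
        )
        exp, truth = generate_rat_experiment(params)
        gene = truth.genes_in_class("HCC_UP")[0]
        hcc = exp.design.samples(treatment="HCC")
        norm = exp.design.samples(treatment="NORM")
        ratio = exp.intensities.loc[gene, hcc].mean() / exp.intensities.loc[gene, norm].mean()
        assert ratio == 4.0

    def test_planted_class_counts_and_balanced_design(self, rat_run, default_params):
        exp, truth = rat_run
        counts = truth.table["gene_class"].value_counts()
        assert counts["HCC_UP"] == default_params.n_hcc_up
        assert counts["HCC_DOWN"] == default_params.n_hcc_down
        cells = exp.design.table.groupby(["treatment", "age"]).size()
        assert (cells == default_params.n_per_cell).all() and len(cells) == 6

    def test_class_counts_exceeding_n_genes_rejected(self):
        with pytest.raises(ValidationError, match="n_genes"):
            GeneratorParams(seed=1, n_genes=10, n_hcc_up=20)

    def test_interaction_genes_perturb_one_non_tumor_cell(self, rat_run):
        _, truth = rat_run
        cells = truth.table.loc[
            truth.table["gene_class"] == "INTERACTION", "interaction_cell"
        ]
        assert cells.str.match(r"^(REG|NORM):(YOUNG|OLD)$").all()

    def test_dropout_rate_is_respected(self, rat_run, default_params):
        exp, _ = rat_run
        detected = detect_calls(exp, DetectionThresholds())
        observed = 1.0 - detected.to_numpy().mean()
        assert observed == pytest.approx(default_params.detection_dropout_rate, abs=0.01)

    def test_all_null_generator_gives_uniform_treatment_pvalues(self):
        params = GeneratorParams(seed=23, **NULL_CLASSES)
        exp, _ = generate_rat_experiment(params)
        anova = two_way_anova(log2_transform(exp), exp.design)
        ks = stats.kstest(anova["p_treatment"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01


class TestHumanGenerator:
    def test_conserved_genes_shifted_in_named_datasets_only(self, small_rat):
        params, _, truth = small_rat
        ortho = generate_ortholog_table(truth, params)
        cohorts, de_truth = generate_human_datasets(truth, ortho, params)
        for cohort in cohorts:
            expected = {
                ortho.mapping[g]
                for g in truth.hcc_genes
                if cohort.name in truth.conserved_in(g) and g in ortho.mapping
            }
            assert de_truth[cohort.name] == expected
            assert set(cohort.gene_ids) == ortho.targets

    def test_no_conservation_means_no_planted_de(self, small_rat):
        params, _, truth = small_rat
        null = GeneratorParams(
            **{**params.to_dict(), "conservation_fractions": (0.0, 0.0, 0.0)}
        )
        _, truth0 = generate_rat_experiment(null)
        ortho = generate_ortholog_table(truth0, null)
        _, de_truth = generate_human_datasets(truth0, ortho, null)
        assert all(len(v) == 0 for v in de_truth.values())

    def test_degenerate_group_sizes_rejected(self, small_rat):
        params, _, truth = small_rat
        bad = GeneratorParams(**{**params.to_dict(), "human_cases": (0, 16, 20)})
        ortho = generate_ortholog_table(truth, bad)
        with pytest.raises(ValidationError, match=">= 2 cases"):
            generate_human_datasets(truth, ortho, bad)


class TestCnaGenerator:
    def test_regions_cover_exactly_the_flagged_loci(self, small_rat):
        params, _, truth = small_rat
        bed = generate_cna_bed(truth, params)
        flagged = set(truth.cna_genes)
        for gene, locus in truth.loci().items():
            covered = any(locus.overlaps(region) for region in bed)
            assert covered == (gene in flagged)

    def test_zero_cover_fraction_gives_empty_bed(self, small_rat):
        params, _, _ = small_rat
        zero = GeneratorParams(**{**params.to_dict(), "cna_cover_fraction": 0.0})
        _, truth0 = generate_rat_experiment(zero)
        assert generate_cna_bed(truth0, zero) == []

    def test_zero_margin_reproduces_the_locus(self, small_rat):
        params, _, _ = small_rat
        tight = GeneratorParams(**{**params.to_dict(), "cna_margin": 0})
        _, truth0 = generate_rat_experiment(tight)
        loci = truth0.loci()
        for region in generate_cna_bed(truth0, tight):
            # region name is cna_<k>; find the matching flagged locus
            match = [g for g in truth0.cna_genes
                     if loci[g].start == region.start and loci[g].end == region.end]
            assert match, f"region {region} does not coincide with a flagged locus"


class TestCtGenerator:
    def test_noise_free_closed_form(self, small_rat):
        params, _, truth = small_rat
        quiet = GeneratorParams(**{**params.to_dict(), "ct_noise_sd": 0.0})
        _, truth0 = generate_rat_experiment(quiet)
        gene = truth0.genes_in_class("HCC_UP")[0]
        ct = generate_ct_table(truth0, [gene], quiet)
        res = delta_delta_ct(ct)
        effect = truth0.table.loc[gene, "effect_log2"]
        assert res.loc[gene, "ddct"] == pytest.approx(-effect, abs=1e-12)
        assert res.loc[gene, "log2fc"] == pytest.approx(effect, abs=1e-12)
        assert res.loc[quiet.reference_gene, "fold"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_subset_rejected(self, small_rat):
        params, _, truth = small_rat
        with pytest.raises(ValidationError, match="empty"):
            generate_ct_table(truth, [], params)

    def test_unknown_gene_rejected(self, small_rat):
        params, _, truth = small_rat
        with pytest.raises(ValidationError, match="not in truth"):
            generate_ct_table(truth, ["nope"], params)
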