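import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_design, make_experiment
from hccsig.diffexp import (
    fold_change,
    one_way_anova,
    template_match,
    two_way_anova,
    unpaired_t,
)
from hccsig.io_formats import SampleDesign, ValidationError
from oracles import brute_two_way_anova


def _log_matrix(rng, n_genes, design):
    cols = design.sample_ids
    return pd.DataFrame(
        rng.normal(8, 1, (n_genes, len(cols))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )


class TestTwoWayAnova:
    def test_matches_cell_means_oracle_on_balanced_design(self):
        rng = np.random.default_rng(42)
        design = make_design(3)
        lm = _log_matrix(rng, 200, design)
        res = two_way_anova(lm, design)
        treatment = design.table["treatment"].to_numpy()
        age = design.table["age"].to_numpy()
        for gi in range(200):
            expected = brute_two_way_anova(lm.iloc[gi].to_numpy(), treatment, age)
            for key, value in expected.items():
                assert res.iloc[gi][key] == pytest.approx(value, rel=1e-10, abs=1e-300)

    def test_ss_decomposition_on_balanced_design(self):
        rng = np.random.default_rng(7)
        design = make_design(4)
        res = two_way_anova(_log_matrix(rng, 50, design), design)
        parts = res[["ss_treatment", "ss_age", "ss_interaction", "ss_residual"]].sum(axis=1)
        assert np.allclose(parts, res["ss_total"], rtol=1e-8)

    def test_zero_within_cell_variance_limits(self):
        design = make_design(2)
        means = design.table["treatment"].map({"HCC": 10.0, "REG": 8.0, "NORM": 6.0})
        lm = pd.DataFrame([means.to_numpy()], index=["g1"], columns=design.sample_ids)
        res = two_way_anova(lm, design)
        assert res.loc["g1", "p_treatment"] == 0.0
        assert res.loc["g1", "p_age"] == 1.0
        assert res.loc["g1", "p_interaction"] == 1.0

    def test_constant_gene_is_untestable_not_p_one(self):
        design = make_design(2)
        lm = pd.DataFrame([[5.0] * 12], index=["g1"], columns=design.sample_ids)
        res = two_way_anova(lm, design)
        assert np.isnan(res.loc["g1", "p_treatment"])
        assert np.isnan(res.loc["g1", "F_treatment"])

    def test_single_replicate_cells_flagged_untestable(self):
        design = make_design(1)
        lm = _log_matrix(np.random.default_rng(0), 3, design)
        res = two_way_anova(lm, design)
        assert res["p_treatment"].isna().all()

    def test_single_factor_level_rejected(self):
        design = make_design(2)
        young = design.subset(design.samples(age="YOUNG"))
        lm = _log_matrix(np.random.default_rng(0), 2, young)
        with pytest.raises(ValidationError, match="levels"):
            two_way_anova(lm, young)

    def test_unbalanced_design_matches_type_two_model_comparison(self):
        # cross-check against statsmodels' Type II ANOVA on a handful of genes
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        design = make_design(3)
        ids = design.sample_ids
        keep = [s for s in ids if s not in (ids[-1], ids[-4])]  # 2 cells lose a replicate
        sub = design.subset(keep)
        lm = _log_matrix(rng, 5, sub)
        res = two_way_anova(lm, sub)
        for gi in range(5):
            frame = pd.DataFrame(
                {
                    "y": lm.iloc[gi].to_numpy(),
                    "treatment": sub.table["treatment"].to_numpy(),
                    "age": sub.table["age"].to_numpy(),
                }
            )
            tab = sm.stats.anova_lm(smf.ols("y ~ C(treatment)*C(age)", frame).fit(), typ=2)
            assert res.iloc[gi]["F_treatment"] == pytest.approx(
                tab.loc["C(treatment)", "F"], rel=1e-8
            )
            assert res.iloc[gi]["F_interaction"] == pytest.approx(
                tab.loc["C(treatment):C(age)", "F"], rel=1e-8
            )

    def test_permuting_samples_jointly_changes_nothing(self):
        rng = np.random.default_rng(9)
        design = make_design(3)
        lm = _log_matrix(rng, 20, design)
        res = two_way_anova(lm, design)
        perm = rng.permutation(lm.columns)
        res_perm = two_way_anova(
            lm[perm], SampleDesign(design.table.loc[perm].copy())
        )
        assert np.allclose(res["F_treatment"], res_perm["F_treatment"])
        assert np.allclose(res["F_interaction"], res_perm["F_interaction"])


class TestOneWayAnova:
    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        rows = [(f"s{i}", "HCC" if i < 4 else "NORM", "YOUNG") for i in range(8)]
        df = pd.DataFrame(rows, columns=["sample_id", "treatment", "age"]).set_index("sample_id")
        design = SampleDesign(df)
        lm = _log_matrix(rng, 30, design)
        res = one_way_anova(lm, design)
        tt = unpaired_t(lm, design.samples(treatment="HCC"), design.samples(treatment="NORM"),
                        equal_var=True)
        assert np.allclose(res["F"], tt["t"] ** 2, rtol=1e-10)
        assert np.allclose(res["p"], tt["p"], rtol=1e-10)

    def test_hand_computed_three_group_instance(self):
        # groups (1,2), (3,5), (8,10): grand mean 29/6; SSB = 2*((1.5-29/6)^2 +
        # (4-29/6)^2 + (9-29/6)^2) = 347/6... computed with exact fractions below
        design = make_design(2)
        young = design.subset(design.samples(age="YOUNG"))
        values = {"HCC": [1.0, 2.0], "REG": [3.0, 5.0], "NORM": [8.0, 10.0]}
        row = [values[young.table.loc[s, "treatment"]].pop(0) for s in young.sample_ids]
        lm = pd.DataFrame([row], index=["g1"], columns=young.sample_ids)
        res = one_way_anova(lm, young)
        ssb = 2 * ((1.5 - 29 / 6) ** 2 + (4 - 29 / 6) ** 2 + (9 - 29 / 6) ** 2)
        ssw = (0.25 + 0.25) + (1.0 + 1.0) + (1.0 + 1.0)
        f_expected = (ssb / 2) / (ssw / 3)
        assert res.loc["g1", "F"] == pytest.approx(f_expected, rel=1e-12)
        assert res.loc["g1", "p"] == pytest.approx(stats.f.sf(f_expected, 2, 3), rel=1e-12)

    def test_single_sample_group_rejected(self):
        design = make_design(2)
        ids = design.samples(age="YOUNG")[:-1]  # NORM loses a replicate
        sub = design.subset(ids)
        lm = _log_matrix(np.random.default_rng(0), 2, sub)
        with pytest.raises(ValidationError, match="< 2 samples"):
            one_way_anova(lm, sub)


class TestUnpairedT:
    def test_identical_groups_give_t_zero_p_one(self):
        lm = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"],
                          columns=[f"s{i}" for i in range(6)])
        res = unpaired_t(lm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.loc["g", "t"] == 0.0
        assert res.loc["g", "p"] == 1.0

    def test_swapping_groups_negates_t_keeps_p(self):
        rng = np.random.default_rng(2)
        lm = pd.DataFrame(rng.normal(size=(10, 8)), columns=[f"s{i}" for i in range(8)])
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        fwd = unpaired_t(lm, a, b)
        rev = unpaired_t(lm, b, a)
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_small_groups_rejected(self):
        lm = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            unpaired_t(lm, ["a"], ["b", "c"])


class TestFoldChange:
    def test_directions_and_magnitudes(self):
        lm = pd.DataFrame(
            [[9.0, 9.0, 3.0, 3.0], [3.0, 3.0, 9.0, 9.0], [5.0, 5.0, 5.0, 5.0]],
            index=["up", "down", "flat"],
            columns=["a1", "a2", "b1", "b2"],
        )
        fc = fold_change(lm, ["a1", "a2"], ["b1", "b2"])
        assert fc.loc["up", "ratio"] == 3.0 and fc.loc["up", "direction"] == "UP"
        assert fc.loc["down", "ratio"] == pytest.approx(1 / 3)
        assert fc.loc["down", "abs_fc"] == pytest.approx(3.0)
        assert fc.loc["down", "direction"] == "DOWN"
        assert fc.loc["flat", "abs_fc"] == 1.0

    def test_non_positive_mean_rejected(self):
        lm = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], columns=["a1", "a2", "b1", "b2"])
        with pytest.raises(ValidationError):
            fold_change(lm, ["a1", "a2"], ["b1", "b2"])


class TestTemplateMatch:
    def test_perfect_and_anti_match(self):
        template = [1, 1, 0, 0, 0, 0]
        lm = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0, 1.0, 1.0]],
            index=["match", "anti"],
            columns=[f"s{i}" for i in range(6)],
        )
        res = template_match(lm, template)
        assert res.loc["match", "r"] == pytest.approx(1.0)
        assert res.loc["match", "p"] < 1e-20  # minimal attainable at this n
        assert res.loc["match", "direction"] == "UP"
        assert res.loc["anti", "r"] == pytest.approx(-1.0)
        assert res.loc["anti", "direction"] == "DOWN"

    def test_p_matches_t_transform_closed_form(self):
        # engineer a profile with r = 0.5 against a 24-sample template
        n = 24
        template = np.array([1.0] * 8 + [0.0] * 16)
        tc = template - template.mean()
        rng = np.random.default_rng(0)
        noise = rng.normal(size=n)
        noise -= noise.mean()
        noise -= tc * (noise @ tc) / (tc @ tc)  # orthogonal to template
        r_target = 0.5
        profile = tc / np.linalg.norm(tc) * r_target + noise / np.linalg.norm(noise) * np.sqrt(
            1 - r_target**2
        )
        lm = pd.DataFrame([profile], index=["g"], columns=[f"s{i}" for i in range(n)])
        res = template_match(lm, template)
        assert res.loc["g", "r"] == pytest.approx(0.5, abs=1e-12)
        t_stat = 0.5 * np.sqrt((n - 2) / (1 - 0.25))
        assert res.loc["g", "p"] == pytest.approx(2 * stats.t.sf(t_stat, n - 2), rel=1e-12)

    def test_affine_rescaling_of_profile_preserves_p(self):
        rng = np.random.default_rng(5)
        lm = pd.DataFrame(rng.normal(size=(10, 12)), columns=[f"s{i}" for i in range(12)])
        template = [1] * 4 + [0] * 8
        base = template_match(lm, template)
        scaled = template_match(lm * 3.7 + 11.0, template)
        assert np.allclose(base["p"], scaled["p"])
        assert np.allclose(base["r"], scaled["r"])

    def test_constant_profile_untestable_and_constant_template_rejected(self):
        lm = pd.DataFrame([[2.0] * 6], index=["flat"], columns=[f"s{i}" for i in range(6)])
        res = template_match(lm, [1, 0, 0, 1, 0, 0])
        assert np.isnan(res.loc["flat", "r"]) and np.isnan(res.loc["flat", "p"])
        with pytest.raises(ValidationError, match="constant"):
            template_match(lm, [1, 1, 1, 1, 1, 1])
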