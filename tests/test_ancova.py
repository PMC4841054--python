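import numpy as np
import pandas as pd
import pytest

import craniodim as cd
from craniodim.ancova import AncovaEstimationError, ancova_table
from oracles import ancova_normal_equations, classic_cohens_d


def _fixture_12():
    """Printed 12-subject worked example: 6 per sex, fixed covariates."""
    sex = np.array(["M"] * 6 + ["F"] * 6)
    height = np.array([150.0, 155.0, 160.0, 165.0, 170.0, 175.0,
                       148.0, 152.0, 158.0, 163.0, 168.0, 172.0])
    age = np.array([10.1, 10.9, 11.5, 12.0, 12.4, 12.9,
                    10.3, 10.8, 11.2, 12.1, 12.6, 12.8])
    values = np.array([101.2, 104.8, 107.5, 110.1, 113.9, 116.2,
                       99.5, 101.9, 105.2, 108.8, 111.4, 114.0])
    return values, sex, height, age


class TestAncovaSexTest:
    def test_matches_normal_equations_oracle(self):
        values, sex, height, age = _fixture_12()
        m_m, m_f, p, ms, n_m, n_f = cd.ancova_sex_test(values, sex, height, age)
        o_m, o_f, o_p, o_ms = ancova_normal_equations(values, sex, height, age)
        assert m_m == pytest.approx(o_m, abs=1e-8)
        assert m_f == pytest.approx(o_f, abs=1e-8)
        assert p == pytest.approx(o_p, abs=1e-8)
        assert ms == pytest.approx(o_ms, abs=1e-8)
        assert (n_m, n_f) == (6, 6)

    def test_matches_oracle_on_random_20_subject_fixtures(self):
        rng = np.random.default_rng(314)
        for _ in range(10):
            n = int(rng.integers(8, 21))
            n_m = int(rng.integers(3, n - 2))
            sex = np.array(["M"] * n_m + ["F"] * (n - n_m))
            height = rng.normal(160, 10, n)
            age = rng.uniform(6, 20, n)
            values = 50 + 0.3 * height + 0.8 * age + rng.normal(0, 2, n)
            got = cd.ancova_sex_test(values, sex, height, age)
            want = ancova_normal_equations(values, sex, height, age)
            np.testing.assert_allclose(got[:4], want, atol=1e-8)

    def test_no_effect_when_sexes_identical(self):
        values = np.tile([10.0, 11.0, 12.0, 13.0], 2)
        sex = np.array(["M"] * 4 + ["F"] * 4)
        height = np.tile([150.0, 157.0, 151.0, 165.0], 2)
        age = np.tile([10.0, 11.5, 12.0, 13.0], 2)
        m_m, m_f, p, ms, *_ = cd.ancova_sex_test(values, sex, height, age)
        assert m_m == pytest.approx(m_f, abs=1e-9)
        assert cd.modified_cohens_d(m_m, m_f, max(ms, 1e-30)) == pytest.approx(0, abs=1e-6)

    def test_covariate_shift_and_rescale_invariance(self):
        values, sex, height, age = _fixture_12()
        base = cd.ancova_sex_test(values, sex, height, age)
        shifted = cd.ancova_sex_test(values, sex, height + 1000.0, age)
        rescaled = cd.ancova_sex_test(values, sex, height / 100.0, age)  # cm -> m
        for other in (shifted, rescaled):
            assert other[0] - other[1] == pytest.approx(base[0] - base[1], abs=1e-8)
            assert other[2] == pytest.approx(base[2], abs=1e-10)
            assert other[3] == pytest.approx(base[3], rel=1e-10)

    def test_rank_deficient_design_reported(self):
        values, sex, height, age = _fixture_12()
        with pytest.raises(AncovaEstimationError, match="height is constant"):
            cd.ancova_sex_test(values, sex, np.full_like(height, 160.0), age)

    def test_too_few_subjects_per_sex(self):
        with pytest.raises(AncovaEstimationError, match=">= 2"):
            cd.ancova_sex_test(
                np.arange(4.0), np.array(["M", "F", "F", "F"]),
                np.arange(4.0) + 150, np.arange(4.0) + 10,
            )

    def test_reduces_to_classic_cohens_d_without_covariate_effects(self):
        """With covariates independent of sex and outcome, the adjusted d
        approaches the textbook pooled-SD d in large samples."""
        rng = np.random.default_rng(99)
        n = 2000
        sex = np.array(["M", "F"] * (n // 2))
        height = rng.normal(160, 10, n)
        age = rng.uniform(5, 25, n)
        values = rng.normal(100, 5, n) + 2.0 * (sex == "M")
        m_m, m_f, _, ms, *_ = cd.ancova_sex_test(values, sex, height, age)
        adjusted_d = cd.modified_cohens_d(m_m, m_f, ms)
        assert adjusted_d == pytest.approx(classic_cohens_d(values, sex), abs=0.05)


class TestEffectSize:
    @pytest.mark.parametrize(
        "m_m,m_f,ms,expected",
        [(10.0, 10.0, 4.0, 0.0), (12.0, 10.0, 4.0, 1.0), (10.0, 12.0, 4.0, -1.0)],
    )
    def test_modified_cohens_d(self, m_m, m_f, ms, expected):
        assert cd.modified_cohens_d(m_m, m_f, ms) == pytest.approx(expected)

    def test_zero_variance_nonzero_difference_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cd.modified_cohens_d(12.0, 10.0, 0.0)
        assert cd.modified_cohens_d(10.0, 10.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "d,label",
        [
            (0.19, "very_small"), (-0.13, "very_small"), (0.20, "small"),
            (0.49, "small"), (0.50, "moderate"), (0.73, "moderate"),
            (0.79, "moderate"), (0.80, "moderate"), (0.81, "large"),
            (1.10, "large"), (-2.0, "large"),
        ],
    )
    def test_magnitude_boundaries(self, d, label):
        assert cd.classify_effect_size(d) == label


class TestSummaries:
    def test_regional_mean_is_unweighted_mean_of_signed_d(self):
        table = pd.DataFrame({
            "measurement": ["a", "b", "c"],
            "region": ["nose", "nose", "eye"],
            "age_group": ["adult"] * 3,
            "d": [0.2, 0.4, -0.1],
        })
        out = cd.regional_mean_effects(table)
        assert out.loc["adult", "nose"] == pytest.approx(0.3)
        assert out.loc["adult", "eye"] == pytest.approx(-0.1)

    def test_regional_mean_rejects_duplicates(self):
        table = pd.DataFrame({
            "measurement": ["a", "a"], "region": ["nose", "nose"],
            "age_group": ["adult", "adult"], "d": [0.1, 0.2],
        })
        with pytest.raises(ValueError, match="duplicate"):
            cd.regional_mean_effects(table)

    def test_full_synthetic_regional_means_match_per_measurement_oracle(self):
        cohort = cd.simulate_cohort(cd.default_spec(
            n_per_cell={("adult", "M"): 25, ("adult", "F"): 25,
                        ("puberty", "M"): 20, ("puberty", "F"): 20},
            seed=21,
        ))
        table = ancova_table(cd.compute_measurements(cohort), cohort)
        fitted = table.dropna(subset=["d"])
        out = cd.regional_mean_effects(table)
        for (group, region), sub in fitted.groupby(["age_group", "region"]):
            assert out.loc[group, region] == pytest.approx(sub["d"].mean(), abs=1e-12)

    def test_growth_attainment_scales(self):
        """Groups at exactly the adult mean give 100%; at half, 50%."""
        rows, subjects = [], []
        for i, (group_age, factor) in enumerate([(23.0, 1.0), (10.0, 0.5)]):
            for j in range(3):
                for sex in "MF":
                    sid = f"s{i}{j}{sex}"
                    subjects.append(cd.SubjectRecord(sid, sex, group_age, 150.0))
                    rows.append({"subject_id": sid,
                                 **{name: 100.0 * factor for name in cd.MEASUREMENT_NAMES}})
        table = pd.DataFrame(rows).set_index("subject_id")
        cohort = cd.Cohort(subjects, {})
        out = cd.growth_attainment(table, cohort)
        assert np.allclose(out.loc[("M", "adult")], 100.0)
        assert np.allclose(out.loc[("F", "late_childhood")], 50.0)

    def test_growth_attainment_recovers_generative_growth_curve(self):
        spec = cd.default_spec(
            n_per_cell={("early_childhood", "M"): 10, ("early_childhood", "F"): 10,
                        ("adult", "M"): 10, ("adult", "F"): 10},
            effect_scale=0.0, noise_sd=0.0, caliper_noise_sd=0.0,
            allometry_slope=0.0, height_size_coupling=0.0, seed=17,
        )
        cohort = cd.simulate_cohort(spec)
        out = cd.growth_attainment(cd.compute_measurements(cohort), cohort)
        # early-childhood faces are built at 80% of adult scale
        assert np.allclose(out.loc[("M", "early_childhood")], 80.0, atol=1e-6)
        assert np.allclose(out.loc[("F", "early_childhood")], 80.0, atol=1e-6)

    def test_growth_attainment_requires_adult_reference(self):
        subjects = [cd.SubjectRecord(f"s{i}", "M" if i % 2 else "F", 10.0, 150.0)
                    for i in range(4)]
        table = pd.DataFrame(
            {name: 100.0 for name in cd.MEASUREMENT_NAMES},
            index=pd.Index([s.subject_id for s in subjects], name="subject_id"),
        )
        with pytest.raises(ValueError, match="adult"):
            cd.growth_attainment(table, cd.Cohort(subjects, {}))


class TestAncovaTable:
    def test_29_measurements_per_group_with_skip_reasons(self):
        cohort = cd.simulate_cohort(cd.default_spec(
            n_per_cell={("adult", "M"): 10, ("adult", "F"): 10}, seed=33))
        table = ancova_table(cd.compute_measurements(cohort), cohort)
        assert len(table) == 6 * 29
        adult = table[table["age_group"] == "adult"]
        assert adult["d"].notna().all()
        empty = table[table["age_group"] == "puberty"]
        assert (empty["skipped"].str.len() > 0).all()

    def test_fdr_column_is_monotone_transform_of_p(self):
        cohort = cd.simulate_cohort(cd.default_spec(
            n_per_cell={("adult", "M"): 15, ("adult", "F"): 15}, seed=34))
        table = ancova_table(cd.compute_measurements(cohort), cohort, fdr=True)
        sub = table.dropna(subset=["p_value"])
        assert (sub["p_value_fdr"] >= sub["p_value"] - 1e-12).all()
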