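"""Nonparametric test layer against exact and permutation oracles."""

import numpy as np
import pandas as pd
import pytest

from mandifrac.errors import InsufficientDataError, InvalidParameterError
from mandifrac.group_stats import (
    anova_power,
    cohens_f,
    compare_all,
    comparisons_to_frame,
    covariate_regression,
    dunn_bonferroni,
    eta_squared_from_h,
    group_from_cholesterol,
    kruskal_wallis,
)
from mandifrac.synthetic import CohortParams, make_cohort


class TestKruskalWallis:
    def test_textbook_example_h_is_7_point_2(self):
        h, df, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2

    def test_constant_dataset_defined_as_h_zero(self):
        h, _, p = kruskal_wallis([5, 5], [5, 5], [5, 5])
        assert h == 0.0
        assert p == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            kruskal_wallis([1.0], [2, 3], [4, 5])

    def test_chi_square_p_matches_permutation_oracle(self, rng):
        """On a small fixed dataset, P(H >= observed) under label shuffling
        agrees with the chi-square upper-tail p within Monte-Carlo error."""
        groups = [[2.1, 3.3, 1.8, 4.0], [3.9, 5.2, 4.8, 4.4], [5.0, 6.1, 4.1, 5.5]]
        h_obs, _, p_chi2 = kruskal_wallis(*groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm = 4000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h, _, _ = kruskal_wallis(*parts)
            if h >= h_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # chi-square is an approximation: allow MC error plus a small bias
        assert abs(p_perm - p_chi2) < 4 * se + 0.02

    def test_heavy_ties_keep_h_finite_and_p_valid(self):
        h, _, p = kruskal_wallis([1, 1, 2, 2], [1, 2, 2, 3], [2, 3, 3, 3])
        assert np.isfinite(h)
        assert 0 < p <= 1


class TestDunnBonferroni:
    def test_identical_groups_all_adjusted_p_one(self):
        table = dunn_bonferroni([1, 2, 3], [2, 1, 3], [3, 2, 1])
        assert all(t.p_adjusted == 1.0 for t in table)

    def test_extreme_pair_has_largest_z(self):
        table = dunn_bonferroni([1, 2, 3], [4, 5, 6], [7, 8, 9])
        by_pair = {(t.group_a, t.group_b): abs(t.z) for t in table}
        assert by_pair[("normal", "high")] == max(by_pair.values())

    def test_adjusted_p_bounded_by_raw_times_three(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        for t in dunn_bonferroni(*groups):
            assert t.p_adjusted >= t.p_raw
            assert t.p_adjusted == pytest.approx(min(1.0, 3 * t.p_raw))


class TestEffectSizeChain:
    def test_eta_squared_from_printed_h(self):
        assert eta_squared_from_h(6.104, 92) == pytest.approx(0.0671, abs=5e-5)

    def test_eta_squared_edge_cases(self):
        assert eta_squared_from_h(0.0, 92) == 0.0
        assert eta_squared_from_h(91.0, 92) == pytest.approx(1.0)

    def test_adjusted_convention_is_smaller(self):
        default = eta_squared_from_h(6.104, 92)
        adjusted = eta_squared_from_h(6.104, 92, convention="adjusted")
        assert adjusted == pytest.approx((6.104 - 2) / 89, abs=1e-12)
        assert adjusted < default

    def test_cohens_f_values(self):
        assert cohens_f(0.0671) == pytest.approx(0.268, abs=5e-4)
        assert cohens_f(0.0) == 0.0
        assert cohens_f(0.5) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            cohens_f(1.0)

    def test_power_reproduces_achieved_value(self):
        assert anova_power(0.27, k=3, n_total=92, alpha=0.05) == pytest.approx(
            0.62, abs=0.02
        )

    def test_zero_effect_power_equals_alpha(self):
        assert anova_power(0.0, k=3, n_total=92, alpha=0.05) == 0.05

    def test_power_increases_with_sample_size(self):
        powers = [anova_power(0.27, 3, n) for n in (30, 60, 92, 200)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_invalid_degrees_of_freedom(self):
        with pytest.raises(InvalidParameterError):
            anova_power(0.2, k=3, n_total=3)


class TestGroupFromCholesterol:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.0, "normal"), (5.19, "normal"), (5.2, "borderline"),
         (6.2, "borderline"), (6.21, "high")],
    )
    def test_thresholds(self, value, expected):
        assert group_from_cholesterol(value) == expected


class TestCovariateRegression:
    def test_known_age_slope_recovered(self, rng):
        hits = 0
        for _ in range(40):
            age = rng.uniform(20, 90, 92)
            sex = rng.choice(["male", "female"], 92)
            fd = 1.3 + 0.002 * age + rng.normal(0, 0.05, 92)
            records = pd.DataFrame(
                {"region": "anterior", "age": age, "sex": sex, "fd": fd}
            )
            out = covariate_regression(records, "anterior")
            est, se = out.loc["age", "estimate"], out.loc["age", "se"]
            if abs(est - 0.002) < 1.96 * se:
                hits += 1
        assert hits >= 36  # ~95% CI coverage

    def test_sex_coding_flip_changes_sign_not_p(self, rng):
        age = rng.uniform(20, 90, 50)
        sex = rng.choice(["male", "female"], 50)
        fd = 1.4 + rng.normal(0, 0.05, 50)
        rec = pd.DataFrame({"region": "anterior", "age": age, "sex": sex, "fd": fd})
        flipped = rec.assign(
            sex=rec["sex"].map({"male": "female", "female": "male"})
        )
        a = covariate_regression(rec, "anterior")
        b = covariate_regression(flipped, "anterior")
        assert a.loc["sex[male]", "estimate"] == pytest.approx(
            -b.loc["sex[male]", "estimate"], abs=1e-9
        )
        assert a.loc["sex[male]", "p"] == pytest.approx(
            b.loc["sex[male]", "p"], abs=1e-9
        )

    def test_too_few_records_rejected(self):
        rec = pd.DataFrame(
            {"region": "anterior", "age": [50] * 5, "sex": ["male"] * 5,
             "fd": [1.4] * 5}
        )
        with pytest.raises(InsufficientDataError):
            covariate_regression(rec, "anterior")


class TestCompareAll:
    def test_study_layout_yields_ten_comparisons(self):
        cohort = make_cohort(CohortParams(seed=0))
        comparisons = compare_all(cohort)
        assert len(comparisons) == 10
        frame = comparisons_to_frame(comparisons)
        assert {"variable", "H", "p", "eta2", "power"} <= set(frame.columns)
        for c in comparisons:
            assert 0 <= c.eta2 < 1
            assert c.cohens_f >= 0
            assert c.alpha <= c.power <= 1
            assert len(c.pairwise) == 3

    def test_group_sizes_and_medians_are_per_group(self):
        cohort = make_cohort(CohortParams(seed=1))
        anterior_fd = next(
            c for c in compare_all(cohort)
            if c.variable == "fd" and c.region_or_side == "anterior"
        )
        assert anterior_fd.group_sizes == (35, 33, 24)
        sub = cohort[cohort.region == "anterior"]
        expected = tuple(
            float(sub.loc[sub.group == g, "fd"].median())
            for g in ("normal", "borderline", "high")
        )
        assert anterior_fd.medians == pytest.approx(expected)
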