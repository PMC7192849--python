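from datetime import date

import numpy as np
import pandas as pd
import pytest

from stressmark.validation import (
    anova_p,
    assign_validation_groups,
    bonferroni_threshold,
    delog_zscore,
    stepwise_flag,
    validate,
    validation_points,
)
from stressmark.io_core import ExpressionSet

from conftest import make_visit


class TestDelogZscore:
    def test_hand_computed_example(self):
        """log2 [1,2,3] -> de-log [2,4,8] -> z with sample sd 3.055."""
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"],
                              columns=["a", "b", "c"])
        strata = {s: ("M", "BP") for s in values.columns}
        z = delog_zscore(values, strata)
        expected = np.array([-0.8729, -0.2182, 1.0911])
        np.testing.assert_allclose(z.loc["p"].to_numpy(), expected,
                                   atol=1e-4)

    def test_constant_stratum_gives_zero(self):
        values = pd.DataFrame([[5.0, 5.0, 5.0]], index=["p"],
                              columns=list("abc"))
        z = delog_zscore(values, {s: ("M", "BP") for s in "abc"})
        assert (z.loc["p"] == 0).all()

    def test_strata_standardized_independently(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(6, 1, size=(4, 10)),
            index=[f"p{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(10)],
        )
        strata = {
            f"s{i}": ("M", "BP") if i < 5 else ("F", "MDD")
            for i in range(10)
        }
        z = delog_zscore(values, strata)
        for cell_samples in (z.columns[:5], z.columns[5:]):
            block = z[cell_samples]
            np.testing.assert_allclose(block.mean(axis=1), 0, atol=1e-9)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1,
                                       atol=1e-9)


class TestStepwise:
    @pytest.mark.parametrize(
        "low,high,severe,direction,expected",
        [
            (-0.3, 0.1, 0.6, "increased", True),
            (-0.3, 0.6, 0.1, "increased", False),
            (0.5, 0.0, -0.4, "decreased", True),
            (0.0, 0.0, 0.5, "increased", False),  # tie counts as failure
            (-0.3, 0.1, 0.6, "decreased", False),
        ],
    )
    def test_strict_monotone_in_direction(self, low, high, severe,
                                          direction, expected):
        assert stepwise_flag(low, high, severe, direction) is expected

    def test_invariant_under_constant_shift(self):
        assert stepwise_flag(-0.3, 0.1, 0.6, "increased") == stepwise_flag(
            9.7, 10.1, 10.6, "increased"
        )

    def test_flips_with_direction_and_negation(self):
        assert stepwise_flag(-0.3, 0.1, 0.6, "increased")
        assert stepwise_flag(0.3, -0.1, -0.6, "decreased")


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        f, p = anova_p([np.array([1, 2, 3])] * 3)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_huge_separation_tiny_p(self):
        _, p = anova_p([
            np.random.default_rng(0).normal(0, 0.1, 20),
            np.random.default_rng(1).normal(50, 0.1, 20),
        ])
        assert p < 1e-6

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            anova_p([np.array([1.0, 2.0]), np.array([])])

    def test_matches_permutation_oracle(self):
        """F-test p agrees with a permutation p on a small sample."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 6), rng.normal(0.8, 1, 6),
                  rng.normal(1.6, 1, 6)]
        f_obs, p_param = anova_p(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            f_perm, _ = anova_p(parts)
            if f_perm >= f_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - p_param) < 0.03


class TestPointsAndThresholds:
    def test_bonferroni_printed_value(self):
        assert bonferroni_threshold(0.05, 3590) == pytest.approx(
            1.39e-5, rel=5e-3
        )
        assert f"{bonferroni_threshold(0.05, 3590):.6f}" == "0.000014"

    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 1, 0.05), (0.05, 285, 1.754e-4)],
    )
    def test_bonferroni_division(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(
            expected, rel=1e-3
        )

    def test_zero_tests_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    @pytest.mark.parametrize(
        "stepwise,p,expected",
        [
            (True, 0.0122, 4),     # nominal
            (True, 0.115, 2),      # stepwise only
            (False, 0.001, 0),     # not stepwise
            (True, 1e-6, 6),       # past Bonferroni
            (True, 0.049999, 4),
        ],
    )
    def test_validation_points(self, stepwise, p, expected):
        assert validation_points(stepwise, p, 1.39e-5) == expected


class TestGroupAssignment:
    def test_three_group_rules(self):
        visits = [
            make_visit(life=20, health=10, pcl_c=30, sample_id="low"),
            make_visit(life=80, health=90, pcl_c=30, sample_id="high"),
            make_visit(life=80, health=90, pcl_c=60, sample_id="severe"),
            make_visit(life=50, health=50, pcl_c=30, sample_id="mid"),
            make_visit(life=20, health=10, pcl_c=30, sample_id=None),
        ]
        groups = assign_validation_groups(visits)
        assert groups == {"low": "LOW", "high": "HIGH", "severe": "SEVERE"}

    def test_validate_detects_planted_stepwise_marker(self):
        rng = np.random.default_rng(8)
        visits, samples = [], []
        for j, (life, pcl, n) in enumerate(
            [(20, 30, 12), (80, 30, 12), (80, 70, 12)]
        ):
            for i in range(n):
                sid = f"g{j}_{i}"
                visits.append(
                    make_visit(subject_id=sid, life=life, health=life,
                               pcl_c=pcl, sample_id=sid,
                               visit_date=date(2016, 1, 1))
                )
                samples.append(sid)
        shift = np.repeat([0.0, 0.6, 1.2], 12)
        values = pd.DataFrame(
            {
                "up": 6.0 + shift + rng.normal(0, 0.1, 36),
                "flat": 6.0 + rng.normal(0, 0.1, 36),
            },
            index=samples,
        ).T
        eset = ExpressionSet(values, None,
                             {s: ("M", "BP") for s in samples})
        directions = pd.Series({"up": "increased", "flat": "increased"})
        result = validate(eset, visits, directions)
        assert bool(result.loc["up", "stepwise"])
        assert result.loc["up", "validation_points"] in (4, 6)
        # a flat marker may be accidentally monotone but never significant
        assert result.loc["flat", "validation_points"] <= 2
        assert not result.loc["flat", "bonferroni_significant"]
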