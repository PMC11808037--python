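"""Association statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from lektimap import (
    PhenotypeStatus,
    StatsError,
    chi_square_2x2,
    fatal_contingency,
    fit_logistic,
    identify_fatal_variants,
    odds_ratio_ci,
)

from conftest import grid_logistic_mle
from test_cohort import make_record


def model_table(outcome, covariate, age):
    return pd.DataFrame({"outcome": outcome, "covariate": covariate, "age": age})


# eight-row fixture with a constant age (so the fit reduces to intercept +
# covariate, matching the two-parameter grid oracle)
_FIX_Y = [0, 1, 0, 0, 1, 1, 1, 1]
_FIX_X = [0, 0, 0, 1, 1, 1, 2, 2]


class TestFitLogistic:
    def test_matches_grid_search_oracle(self):
        table = model_table(_FIX_Y, _FIX_X, [5.0] * 8)
        res = fit_logistic(table)
        _, beta_grid = grid_logistic_mle(_FIX_Y, _FIX_X)
        assert res.converged
        assert not res.age_in_model  # constant age dropped as collinear
        assert abs(res.beta - beta_grid) < 1e-3

    def test_balanced_arms_give_null_effect(self):
        table = model_table([0, 1, 0, 1], [0, 0, 1, 1], [2.0] * 4)
        res = fit_logistic(table)
        assert abs(res.beta) < 1e-6
        assert abs(res.odds_ratio - 1.0) < 1e-6

    def test_recode_symmetry_inverts_odds_ratio(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 80)
        age = rng.uniform(0, 18, 80)
        p = 1 / (1 + np.exp(-(-0.3 + 0.9 * x)))
        y = (rng.random(80) < p).astype(int)
        res = fit_logistic(model_table(y, x, age))
        res_flip = fit_logistic(model_table(y, 1 - x, age))
        assert res.odds_ratio == pytest.approx(1 / res_flip.odds_ratio, rel=1e-6)

    def test_constant_outcome_is_an_error(self):
        with pytest.raises(StatsError, match="constant"):
            fit_logistic(model_table([1, 1, 1], [0, 1, 2], [1, 2, 3]))

    def test_constant_covariate_is_an_error(self):
        with pytest.raises(StatsError, match="covariate"):
            fit_logistic(model_table([0, 1, 0], [2, 2, 2], [1, 2, 3]))

    def test_perfect_separation_is_flagged_not_silent(self):
        y = [0] * 10 + [1] * 10
        x = [0] * 10 + [1] * 10
        res = fit_logistic(model_table(y, x, [3.0] * 20))
        assert not res.converged

    def test_ci_brackets_or_when_converged(self):
        rng = np.random.default_rng(9)
        x = rng.integers(1, 5, 120)
        y = (rng.random(120) < 1 / (1 + np.exp(-(0.5 - 0.4 * x)))).astype(int)
        res = fit_logistic(model_table(y, x, rng.uniform(0, 18, 120)))
        assert res.converged and res.se > 0
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.odds_ratio > 0


class TestOddsRatioCi:
    def test_null_beta_symmetric_about_one(self):
        or_, lo, hi = odds_ratio_ci(0.0, 0.5)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_zero_se_degenerate(self):
        or_, lo, hi = odds_ratio_ci(1.3, 0.0)
        assert lo == or_ == hi == pytest.approx(math.exp(1.3))

    def test_closed_form(self):
        or_, lo, hi = odds_ratio_ci(math.log(2), 0.1)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(math.exp(math.log(2) - 0.196))
        assert hi == pytest.approx(math.exp(math.log(2) + 0.196))

    def test_negative_se_rejected(self):
        with pytest.raises(StatsError):
            odds_ratio_ci(0.0, -1.0)


class TestChiSquare2x2:
    def test_hand_computed_statistic(self):
        # oracle: sum (O-E)^2/E with E = (8.4, 9.6, 5.6, 6.4)
        res = chi_square_2x2([[14, 4], [0, 12]], yates=False)
        assert res.chi2 == pytest.approx(17.5, abs=5e-3)
        assert res.df == 1
        assert res.p_value < 0.001

    def test_significant_with_and_without_correction(self):
        for yates in (False, True):
            res = chi_square_2x2([[14, 4], [0, 12]], yates=yates)
            assert res.p_value < 0.001
            assert res.yates is yates

    def test_independence_gives_zero(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_invariant_under_row_and_column_swap(self):
        t = [[14, 4], [0, 12]]
        swapped = [[12, 0], [4, 14]]
        assert chi_square_2x2(t).chi2 == pytest.approx(chi_square_2x2(swapped).chi2)

    def test_zero_margin_recommends_exact_test(self):
        with pytest.raises(StatsError, match="exact"):
            chi_square_2x2([[0, 5], [0, 7]])

    def test_shape_and_integrality_validated(self):
        with pytest.raises(StatsError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(StatsError):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestFatalVariants:
    def test_demo_cohort_identifies_exactly_five(self, demo_cohort):
        fs = identify_fatal_variants(demo_cohort)
        assert sorted(fs.variants) == [
            "c.1111C>T", "c.1431-12G>A", "c.153delT", "c.1887+1G>A", "c.995delT",
        ]
        st = fs.variants["c.153delT"]
        assert st.homozygous_carriers == 11 and st.homozygous_deaths == 8
        assert st.heterozygous_carriers == 5 and st.heterozygous_deaths == 0

    def test_no_deaths_means_empty_set(self):
        recs = [make_record("P1", "c.153delT", "c.153delT")]
        assert len(identify_fatal_variants(recs)) == 0

    def test_compound_het_death_does_not_flag(self):
        recs = [
            make_record("P1", "c.153delT", "c.995delT",
                        died=PhenotypeStatus.PRESENT, age=0.4),
        ]
        assert len(identify_fatal_variants(recs)) == 0

    def test_demo_contingency_table(self, demo_cohort):
        fs = identify_fatal_variants(demo_cohort)
        res = fatal_contingency(demo_cohort, fs)
        assert res.table.tolist() == [[14, 4], [0, 12]]
        assert res.table.sum(axis=1).tolist() == [18, 12]
        assert res.p_value < 0.001

    def test_all_homozygous_cohort_has_zero_margin(self):
        recs = [
            make_record("P1", "c.153delT", "c.153delT",
                        died=PhenotypeStatus.PRESENT, age=0.5),
            make_record("P2", "c.153delT", "c.153delT"),
        ]
        fs = identify_fatal_variants(recs)
        with pytest.raises(StatsError):
            fatal_contingency(recs, fs)

    def test_empty_fatal_set_rejected(self, demo_cohort):
        from lektimap import FatalVariantSet

        with pytest.raises(StatsError):
            fatal_contingency(demo_cohort, FatalVariantSet())
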