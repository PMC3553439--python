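"""Validation regression, legacy exposure metric, misclassification demo."""
import numpy as np
import pandas as pd
import pytest

from poptk import (
    CompoundParams,
    legacy_metric,
    misclassification_demo,
    misclassification_fixture,
    sample_cohort,
    validate_cohort,
)
from poptk.validation import InsufficientDataError, LegacyExposureMetric


@pytest.fixture(scope="module")
def small_cohort():
    return sample_cohort("slovak", 40, seed=7, sigma_meas=0.0)


@pytest.fixture(scope="module")
def pcb():
    return CompoundParams("PCB-153", 14.4)


class TestValidateCohort:
    def test_noise_free_cohort_gives_perfect_fit(self, small_cohort, pcb):
        reports = validate_cohort(
            small_cohort.records, small_cohort.child_levels, pcb
        )
        assert len(reports) == 3
        for rep in reports:
            assert rep.r_squared == pytest.approx(1.0, abs=1e-4)
            assert rep.slope == pytest.approx(1.0, abs=1e-2)
            assert rep.intercept == pytest.approx(0.0, abs=5e-2)

    def test_r_squared_matches_analytic_attenuation(self, pcb):
        sigma = 0.5
        cohort = sample_cohort("slovak", 250, seed=9, sigma_meas=sigma)
        reports = validate_cohort(cohort.records, cohort.child_levels, pcb)
        six = next(r for r in reports if r.age_group_months == 6)
        # measured = simulated * lognormal noise; R^2 attenuates to
        # var(ln sim) / (var(ln sim) + sigma^2)
        mask = cohort.truth["nominal_age_months"] == 6
        var_sim = np.var(np.log(cohort.truth.loc[mask, "true_ng_g"]))
        expected = var_sim / (var_sim + sigma**2)
        assert six.r_squared == pytest.approx(expected, abs=0.08)

    def test_invariant_to_rescaling_measured_levels(self, small_cohort, pcb):
        noisy = small_cohort.child_levels.copy()
        rng = np.random.default_rng(0)
        noisy["measured_ng_g"] *= np.exp(rng.normal(0, 0.3, len(noisy)))
        base = validate_cohort(small_cohort.records, noisy, pcb)
        scaled = noisy.copy()
        scaled["measured_ng_g"] *= 37.5
        again = validate_cohort(small_cohort.records, scaled, pcb)
        for a, b in zip(base, again):
            assert a.r_squared == pytest.approx(b.r_squared, rel=1e-9)
            assert a.n == b.n

    def test_row_order_invariance(self, small_cohort, pcb):
        noisy = small_cohort.child_levels.copy()
        rng = np.random.default_rng(1)
        noisy["measured_ng_g"] *= np.exp(rng.normal(0, 0.3, len(noisy)))
        base = validate_cohort(small_cohort.records, noisy, pcb)
        permuted = validate_cohort(
            list(np.random.default_rng(2).permutation(small_cohort.records)),
            noisy.sample(frac=1.0, random_state=3),
            pcb,
        )
        for a, b in zip(base, permuted):
            assert a.r_squared == pytest.approx(b.r_squared, rel=1e-9)

    def test_nondetects_excluded_and_small_groups_rejected(self, small_cohort, pcb):
        levels = small_cohort.child_levels.copy()
        six_month = levels[levels["age_yr"] < 1.0]
        two_rows = six_month.iloc[:2]
        with pytest.raises(InsufficientDataError):
            validate_cohort(small_cohort.records, two_rows, pcb)
        # zeros (non-detects) are dropped, not substituted
        dropped = six_month.copy()
        dropped.loc[dropped.index[:5], "measured_ng_g"] = 0.0
        reports = validate_cohort(small_cohort.records, dropped, pcb)
        assert reports[0].n == len(six_month) - 5


class TestLegacyMetric:
    @pytest.mark.parametrize(
        "level,weeks,expected", [(235.0, 20.0, 4700.0), (639.0, 0.0, 0.0)]
    )
    def test_product(self, level, weeks, expected):
        assert legacy_metric(level, weeks) == expected

    def test_degeneracy_under_rescaling(self):
        assert legacy_metric(2 * 235.0, 20.0 / 2) == legacy_metric(235.0, 20.0)
        m = LegacyExposureMetric(weeks_breastfed=20.0, milk_level=235.0)
        assert m.product == 4700.0


class TestMisclassification:
    def test_fixture_products_match_within_five_percent(self):
        a, b = misclassification_fixture()
        assert abs(a.legacy.product - b.legacy.product) <= 0.05 * a.legacy.product

    def test_identical_dyads_give_unit_ratio(self):
        a, _ = misclassification_fixture()
        _, _, ratio = misclassification_demo((a, a))
        assert ratio == pytest.approx(1.0, rel=1e-12)

    def test_swapping_dyads_inverts_the_ratio(self):
        a, b = misclassification_fixture()
        _, _, r_ab = misclassification_demo((a, b))
        _, _, r_ba = misclassification_demo((b, a))
        assert r_ab == pytest.approx(1.0 / r_ba, rel=1e-9)

    def test_mismatched_products_rejected(self):
        a, b = misclassification_fixture()
        bad = type(b)(
            name=b.name,
            profile=b.profile,
            measurement=b.measurement,
            milk_level=b.milk_level * 2,
            weeks_exclusive=b.weeks_exclusive,
        )
        with pytest.raises(ValueError):
            misclassification_demo((a, bad))
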