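"""Physiologic sub-models: equations, clamps, lookups, continuity."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poptk import (
    ChildPhysiology,
    MaternalPhysiology,
    child_lipid_volume,
    elimination_rate,
    exclusive_milk_intake_rate,
    fetal_lipid_mass,
    interpolate_weight,
    maternal_lipid_volume,
    milk_lipid_fraction,
    partial_milk_intake_rate,
    pregnancy_fat_lipid_gain,
)
from poptk.physiology import (
    CompoundParams,
    fetal_growth_table,
    fetal_weight,
    lipid_fraction_table,
    partial_milk_curve,
)


class TestEliminationRate:
    @pytest.mark.parametrize(
        "half_life,expected",
        [(1.0, math.log(2)), (14.4, 0.0481352), (6.0, 0.1155245)],
    )
    def test_values(self, half_life, expected):
        assert elimination_rate(half_life) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_half_life_rejected(self, bad):
        with pytest.raises(ValueError):
            elimination_rate(bad)
        with pytest.raises(ValueError):
            CompoundParams("x", bad)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(derandomize=True)
    def test_rate_times_half_life_is_ln2(self, h):
        assert elimination_rate(h) * h == pytest.approx(math.log(2), rel=1e-12)


class TestMilkIntake:
    @pytest.mark.parametrize(
        "age,weight,expected",
        [(0.0, 1.0, 0.0063), (0.0, 4.0, 0.0252), (2.625, 5.0, 0.0), (3.0, 5.0, 0.0)],
    )
    def test_exclusive_rate(self, age, weight, expected):
        assert exclusive_milk_intake_rate(age, weight) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            exclusive_milk_intake_rate(-0.1, 4.0)
        with pytest.raises(ValueError):
            partial_milk_intake_rate(-0.1, 0.5, 4.0)

    @pytest.mark.parametrize(
        "age,expected",
        [(1.0, 0.0102), (0.0, 0.0188), (0.0188 / 0.0086, 0.0), (3.0, 0.0)],
    )
    def test_partial_curve(self, age, expected):
        assert partial_milk_curve(age) == pytest.approx(expected, abs=1e-12)

    def test_partial_below_one_year_is_fraction_of_exclusive(self):
        rate = partial_milk_intake_rate(0.5, 0.5, child_weight=8.0)
        assert rate == pytest.approx(0.5 * exclusive_milk_intake_rate(0.5, 8.0))
        with pytest.raises(ValueError):
            partial_milk_intake_rate(0.5, 0.5)  # weight required below 1 y

    @given(st.floats(min_value=0.0, max_value=4.0))
    @settings(derandomize=True)
    def test_rates_never_negative(self, age):
        assert exclusive_milk_intake_rate(age, 10.0) >= 0.0
        assert partial_milk_intake_rate(age, 0.5, child_weight=10.0) >= 0.0
        assert milk_lipid_fraction(age) > 0.0


class TestMilkLipid:
    def test_one_year_value(self):
        assert milk_lipid_fraction(1.0) == pytest.approx(0.0414)

    def test_one_month_value(self):
        assert milk_lipid_fraction(1.0 / 12.0) == pytest.approx(
            0.0034 * math.log(1.0 / 12.0) + 0.0414
        )

    def test_birth_clamped_to_week_one(self):
        assert milk_lipid_fraction(0.0) == pytest.approx(
            milk_lipid_fraction(7.0 / 365.25)
        )
        assert milk_lipid_fraction(0.0) > 0


class TestPregnancyFat:
    @pytest.mark.parametrize(
        "gain,frac,expected",
        [(14.5, 1.0, 6.525), (5.8, 1.0, 0.0), (32.0, 1.0, 19.65), (14.5, 0.0, 0.0)],
    )
    def test_values(self, gain, frac, expected):
        assert pregnancy_fat_lipid_gain(gain, frac) == pytest.approx(expected)

    @given(
        st.floats(min_value=0.0, max_value=40.0),
        st.floats(min_value=0.0, max_value=40.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(derandomize=True)
    def test_monotone_in_gain_and_never_negative(self, g1, g2, f):
        lo, hi = sorted((g1, g2))
        assert pregnancy_fat_lipid_gain(lo, f) <= pregnancy_fat_lipid_gain(hi, f)
        assert pregnancy_fat_lipid_gain(lo, f) >= 0.0


class TestFetalAndChildLipids:
    @pytest.mark.parametrize(
        "weight,sex,expected",
        [(3.5, "male", 0.525), (3.4, "female", 0.476), (0.0, "male", 0.0)],
    )
    def test_fetal_lipid_mass(self, weight, sex, expected):
        assert fetal_lipid_mass(weight, sex) == pytest.approx(expected)

    @pytest.mark.parametrize("sex,bw", [("male", 3.5), ("female", 3.4)])
    def test_newborn_matches_fetal_fraction(self, sex, bw):
        assert child_lipid_volume(0.0, bw, sex) == pytest.approx(
            fetal_lipid_mass(bw, sex)
        )

    def test_child_lipid_is_weight_times_lookup(self):
        tab = lipid_fraction_table("female")
        assert child_lipid_volume(0.5, 7.9, "female") == pytest.approx(7.9 * tab(0.5))

    def test_fetal_growth_scaled_to_birth_weight(self):
        assert fetal_weight(40.0, 40.0, 3.5) == pytest.approx(3.5)
        assert fetal_weight(36.0, 36.0, 2.6) == pytest.approx(2.6)
        assert fetal_weight(0.0, 40.0, 3.5) == 0.0
        weeks = np.linspace(0, 42, 200)
        vals = [fetal_weight(w, 40.0, 3.5) for w in weeks]
        assert np.all(np.diff(vals) >= 0)


class TestWeightInterpolation:
    def test_midpoint_nodes_and_extrapolation(self):
        records = [(0.0, 3.4), (0.5, 7.9)]
        assert interpolate_weight(records, 0.25) == pytest.approx(5.65)
        assert interpolate_weight(records, 0.0) == pytest.approx(3.4)
        assert interpolate_weight(records, 2.0) == pytest.approx(7.9)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            interpolate_weight([], 0.5)


class TestMaternalLipidVolume:
    def test_baseline_far_before_conception(self, maternal):
        v = maternal_lipid_volume(maternal, -10.0)
        assert v == pytest.approx(maternal.baseline_lipid(15.0))

    def test_delivery_adds_pregnancy_fat(self, maternal):
        base = maternal.baseline_lipid(25.0)
        v = maternal_lipid_volume(maternal, -1e-9)
        assert v == pytest.approx(base + 6.525, rel=1e-5)

    def test_default_postpartum_offset_at_half_year(self, maternal):
        base = maternal.baseline_lipid(25.5)
        v = maternal_lipid_volume(maternal, 0.5)
        assert v == pytest.approx(base + 0.75 * 2.0, rel=1e-6)

    def test_continuous_across_delivery(self, maternal):
        eps = 1e-7
        before = maternal_lipid_volume(maternal, -eps)
        after = maternal_lipid_volume(maternal, eps)
        assert after == pytest.approx(before, rel=1e-4)

    @given(st.floats(min_value=-0.7, max_value=3.75))
    @settings(derandomize=True)
    def test_strictly_positive(self, t):
        m = MaternalPhysiology(
            age_at_delivery=25.0,
            prepregnancy_weight=51.0,
            postpartum_weight_offsets=((1.0, -12.0),),
        )
        assert maternal_lipid_volume(m, t) > 0.0


class TestChildPhysiologyType:
    def test_birth_record_inserted(self):
        c = ChildPhysiology(sex="male", birth_weight=3.5, weight_records=((0.5, 8.0),))
        assert c.weight_records[0] == (0.0, 3.5)
        assert c.weight(0.0) == pytest.approx(3.5)

    def test_lipid_volume_continuous_across_record_nodes(self, child):
        for node in (0.5, 1.0):
            lo = child.lipid_volume(node - 1e-7)
            hi = child.lipid_volume(node + 1e-7)
            assert hi == pytest.approx(lo, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ChildPhysiology(sex="other", birth_weight=3.4)
        with pytest.raises(ValueError):
            ChildPhysiology(sex="male", birth_weight=-1.0)
        with pytest.raises(ValueError):
            ChildPhysiology(sex="male", birth_weight=3.4, weight_records=((-0.5, 5.0),))
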