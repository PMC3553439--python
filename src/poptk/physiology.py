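"""Deterministic physiologic sub-models.

Everything here is algebra on ages, weights and lipid masses: first-order
elimination rates, breast-milk intake and lipid content as functions of child
age, pregnancy/postpartum fat dynamics, fetal growth, and the age/sex body
lipid-fraction lookups that convert body weight into the lipid "volume" of the
toxicokinetic compartments.

Units throughout: time in years, weight and lipid mass in kg, milk intake in
L/hour, milk lipid content in kg lipid per L of milk.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "DAYS_PER_YEAR",
    "FETAL_LIPID_FRACTION",
    "CompoundParams",
    "MaternalPhysiology",
    "ChildPhysiology",
    "BreastfeedingSchedule",
    "LookupTable",
    "lipid_fraction_table",
    "fetal_growth_table",
    "elimination_rate",
    "exclusive_milk_intake_rate",
    "partial_milk_curve",
    "partial_milk_intake_rate",
    "milk_lipid_fraction",
    "pregnancy_fat_lipid_gain",
    "fetal_lipid_mass",
    "fetal_weight",
    "maternal_lipid_volume",
    "child_lipid_volume",
    "interpolate_weight",
]

MALE = "male"
FEMALE = "female"
DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0

#: Lipid mass fraction of fetal tissue, held constant across gestation at the
#: value at birth: 15% for males, 14% for females.
FETAL_LIPID_FRACTION = {MALE: 0.15, FEMALE: 0.14}

#: Milk lipid content below this age is clamped to its value at 7 days,
#: avoiding the log singularity at birth (colostrum period).
MILK_LIPID_FLOOR_AGE = 7.0 / DAYS_PER_YEAR

#: Default additional adipose tissue is 75% lipid by mass.
ADIPOSE_LIPID_FRACTION = 0.75

#: Lean (non-adipose) tissue gained by term: fetus, uterus, placenta, amniotic
#: fluid, blood, breasts, extracellular/extravascular fluid.
LEAN_GAIN_AT_TERM = 5.8

DEFAULT_PREGNANCY_GAIN = 14.5
DEFAULT_POSTPARTUM_OFFSETS = ((0.5, 2.0), (1.0, 0.0))


def _validate_sex(sex: str) -> str:
    if sex not in (MALE, FEMALE):
        raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}, got {sex!r}")
    return sex


class LookupTable:
    """Piecewise-linear lookup over a 1-D grid with constant extrapolation."""

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.size < 1:
            raise ValueError("lookup table needs matching 1-D x and y arrays")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("lookup table x values must be strictly increasing")

    def __call__(self, x):
        return np.interp(x, self.x, self.y)

    @classmethod
    def from_csv(cls, path_or_text) -> "LookupTable":
        """Read a two-column CSV (comment lines start with '#', one header row)."""
        if hasattr(path_or_text, "read"):
            lines = path_or_text.read().splitlines()
        else:
            with open(path_or_text) as fh:
                lines = fh.read().splitlines()
        rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        data = np.array([[float(v) for v in ln.split(",")] for ln in rows[1:]])
        return cls(data[:, 0], data[:, 1])


@lru_cache(maxsize=None)
def _packaged_table(filename: str) -> LookupTable:
    text = resources.files("poptk.data").joinpath(filename).read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    data = np.array([[float(v) for v in ln.split(",")] for ln in rows[1:]])
    return LookupTable(data[:, 0], data[:, 1])


def lipid_fraction_table(sex: str) -> LookupTable:
    """Body lipid fraction vs age for the given sex (packaged reference curve)."""
    _validate_sex(sex)
    return _packaged_table(f"lipid_fraction_{sex}.csv")


def fetal_growth_table() -> LookupTable:
    """Normalized fetal weight (fraction of term weight) vs gestational week."""
    return _packaged_table("fetal_growth.csv")


@dataclass(frozen=True)
class CompoundParams:
    """A persistent organic pollutant: identity plus elimination kinetics.

    The single kinetic constant is the first-order elimination rate
    k_el = ln(2) / half_life, with half_life in years.
    """

    name: str
    half_life: float
    approximate: bool = False

    def __post_init__(self):
        if not self.half_life > 0:
            raise ValueError(f"half_life must be positive, got {self.half_life}")

    @property
    def k_el(self) -> float:
        """First-order elimination rate constant (1/year)."""
        return math.log(2.0) / self.half_life


def elimination_rate(half_life: float) -> float:
    """First-order elimination rate ln(2)/half_life (1/year).

    Parameters
    ----------
    half_life : float
        Biological half-life in years; must be positive.
    """
    if not half_life > 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    return math.log(2.0) / half_life


def exclusive_milk_intake_rate(age: float, child_weight: float) -> float:
    """Breast-milk intake (L/hour) of an exclusively breastfed child.

    The per-kg hourly intake declines linearly with age,
    ``-0.0024 * age + 0.0063`` L/kg/hour, clamped at zero (the line crosses
    zero at ~2.6 years); multiplied by the child's body weight.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if not child_weight > 0:
        raise ValueError(f"child_weight must be positive, got {child_weight}")
    return max(0.0, -0.0024 * age + 0.0063) * child_weight


def partial_milk_curve(age: float) -> float:
    """Absolute milk intake (L/hour) during partial breastfeeding, ages 1-2 y.

    ``-0.0086 * age + 0.0188`` L/hour, clamped at zero (zero crossing at
    ~2.19 years, after which intake is held at 0).
    """
    return max(0.0, -0.0086 * age + 0.0188)


def partial_milk_intake_rate(
    age: float,
    partial_milk_fraction: float = 0.5,
    child_weight: float | None = None,
) -> float:
    """Milk intake (L/hour) of a partially breastfed child.

    Below 1 year of age partial feeding is modeled as a fraction (default
    50%) of the exclusive-feeding volume at the same age and weight, so
    ``child_weight`` is required there. From 1 year on, the absolute
    partial-feeding intake line is used directly (it already describes mixed
    feeding), extended to its natural zero crossing at ~2.19 years.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if not 0.0 <= partial_milk_fraction <= 1.0:
        raise ValueError("partial_milk_fraction must be in [0, 1]")
    if age < 1.0:
        if child_weight is None:
            raise ValueError("child_weight is required for partial feeding below age 1")
        return partial_milk_fraction * exclusive_milk_intake_rate(age, child_weight)
    return partial_milk_curve(age)


def milk_lipid_fraction(age: float) -> float:
    """Lipid content of breast milk (kg lipid / L milk) at a given child age.

    ``0.0034 * ln(age) + 0.0414``; ages younger than 7 days are clamped to the
    7-day value so the logarithm stays finite over the colostrum period.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    a = max(age, MILK_LIPID_FLOOR_AGE)
    return 0.0034 * math.log(a) + 0.0414


def pregnancy_fat_lipid_gain(
    weight_gain: float,
    gestational_fraction: float,
    lean_gain_at_term: float = LEAN_GAIN_AT_TERM,
    adipose_lipid_fraction: float = ADIPOSE_LIPID_FRACTION,
) -> float:
    """Lipid mass (kg) gained by the mother at a point in gestation.

    Fat gain is the excess of total pregnancy weight gain over the lean-tissue
    increase (both ramp linearly from conception to their term values), and
    the added adipose tissue is 75% lipid by mass. Never negative.

    Parameters
    ----------
    weight_gain : float
        Total weight gain at term (kg).
    gestational_fraction : float
        Progress through gestation, 0 at conception, 1 at term.
    """
    if not 0.0 <= gestational_fraction <= 1.0:
        raise ValueError("gestational_fraction must be in [0, 1]")
    return adipose_lipid_fraction * gestational_fraction * max(
        0.0, weight_gain - lean_gain_at_term
    )


def fetal_lipid_mass(weight: float, sex: str) -> float:
    """Lipid mass (kg) of fetal tissue: 15% of weight for males, 14% for females."""
    if weight < 0:
        raise ValueError(f"weight must be non-negative, got {weight}")
    return FETAL_LIPID_FRACTION[_validate_sex(sex)] * weight


def fetal_weight(
    gestational_week: float,
    gestational_age_at_birth: float,
    birth_weight: float,
    growth_table: LookupTable | None = None,
) -> float:
    """Fetal weight (kg) at a gestational week.

    The normalized reference growth curve is scaled so its value at the
    individual's gestational age at birth equals the observed birth weight.
    """
    table = growth_table or fetal_growth_table()
    ref_at_birth = table(gestational_age_at_birth)
    if ref_at_birth <= 0:
        raise ValueError("gestational age at birth outside the growth curve support")
    return float(birth_weight * table(gestational_week) / ref_at_birth)


def interpolate_weight(records, age):
    """Piecewise-linear interpolation of timed weight records.

    ``records`` is a sequence of (age_years, weight_kg) pairs sorted by age;
    interpolation is exact at the record ages and constant beyond the first
    and last records.
    """
    if len(records) < 1:
        raise ValueError("at least one weight record is required")
    ages = np.array([r[0] for r in records], dtype=float)
    weights = np.array([r[1] for r in records], dtype=float)
    return np.interp(age, ages, weights)


@dataclass
class MaternalPhysiology:
    """Maternal inputs: age, weights, and pregnancy/postpartum weight dynamics.

    ``postpartum_weight_offsets`` are (time since delivery in years,
    weight minus prepregnancy weight in kg) anchors; the trajectory is linear
    between anchors and constant after the last one. The anchor at delivery is
    implicit: the fat mass gained during pregnancy (lean gain is assumed lost
    at delivery).
    """

    age_at_delivery: float
    prepregnancy_weight: float
    pregnancy_weight_gain: float = DEFAULT_PREGNANCY_GAIN
    postpartum_weight_offsets: tuple = DEFAULT_POSTPARTUM_OFFSETS
    lean_gain_at_term: float = LEAN_GAIN_AT_TERM
    adipose_lipid_fraction: float = ADIPOSE_LIPID_FRACTION
    lipid_table: LookupTable | None = None

    #: Weight at birth and the age by which the generic growth ramp reaches
    #: the prepregnancy weight; only the shape of lifetime accumulation
    #: depends on these, and calibration is invariant to that shape.
    weight_at_birth: float = 3.4
    adult_age: float = 18.0

    def __post_init__(self):
        if not self.prepregnancy_weight > 0:
            raise ValueError("prepregnancy_weight must be positive")
        if not 0 < self.adipose_lipid_fraction <= 1:
            raise ValueError("adipose_lipid_fraction must be in (0, 1]")
        if not self.age_at_delivery > 0:
            raise ValueError("age_at_delivery must be positive")
        offs = sorted((float(t), float(w)) for t, w in self.postpartum_weight_offsets)
        if offs and offs[0][0] <= 0:
            raise ValueError("postpartum offsets must be at times > 0 after delivery")
        self.postpartum_weight_offsets = tuple(offs)

    def _table(self) -> LookupTable:
        return self.lipid_table or lipid_fraction_table(FEMALE)

    def baseline_weight(self, age):
        """Body weight (kg) at a maternal age, excluding pregnancy changes."""
        age = np.asarray(age, dtype=float)
        frac = np.clip(age / self.adult_age, 0.0, 1.0)
        w = self.weight_at_birth + frac * (self.prepregnancy_weight - self.weight_at_birth)
        return w if w.ndim else float(w)

    def baseline_lipid(self, age):
        """Baseline body lipid mass (kg): weight times the age-specific fraction."""
        return self.baseline_weight(age) * self._table()(age)

    def fat_gain_at_delivery(self) -> float:
        """Weight excess over prepregnancy weight attributable to fat at delivery."""
        return max(0.0, self.pregnancy_weight_gain - self.lean_gain_at_term)

    def lean_gain(self, gestational_fraction: float) -> float:
        """Lean-tissue mass increment (kg) at a point in gestation (5.8 kg at term)."""
        if not 0.0 <= gestational_fraction <= 1.0:
            raise ValueError("gestational_fraction must be in [0, 1]")
        return self.lean_gain_at_term * gestational_fraction

    def postpartum_offset(self, t):
        """Weight minus prepregnancy weight (kg) at time t >= 0 after delivery."""
        anchors_t = [0.0] + [a[0] for a in self.postpartum_weight_offsets]
        anchors_w = [self.fat_gain_at_delivery()] + [
            a[1] for a in self.postpartum_weight_offsets
        ]
        return np.interp(t, anchors_t, anchors_w)


def maternal_lipid_volume(
    maternal: MaternalPhysiology, t, gestation_years: float = 40.0 / WEEKS_PER_YEAR
):
    """Maternal body lipid mass (kg) at time ``t`` relative to delivery.

    Before conception this is the baseline age/weight lookup; during gestation
    the linearly ramping pregnancy fat (as lipid) is added; after delivery the
    weight excess over prepregnancy weight is treated as adipose tissue (75%
    lipid), interpolated between the postpartum anchors. Fetal lipids are NOT
    included here; the kinetics layer adds them to the shared gestational pool.
    """
    t_arr = np.asarray(t, dtype=float)
    age = np.maximum(maternal.age_at_delivery + t_arr, 0.0)
    base = maternal.baseline_weight(age) * maternal._table()(age)

    out = np.array(base, dtype=float, copy=True)
    gest = (t_arr >= -gestation_years) & (t_arr < 0.0)
    if np.any(gest):
        frac = (t_arr[gest] + gestation_years) / gestation_years
        gain = (
            maternal.adipose_lipid_fraction
            * frac
            * maternal.fat_gain_at_delivery()
        )
        out[gest] = out[gest] + gain
    post = t_arr >= 0.0
    if np.any(post):
        out[post] = out[post] + maternal.adipose_lipid_fraction * maternal.postpartum_offset(
            t_arr[post]
        )
    # Lipid mass must stay strictly positive even under extreme postpartum loss.
    out = np.maximum(out, 0.5)
    return out if out.ndim else float(out)


@dataclass
class ChildPhysiology:
    """Child inputs: sex, gestational age, birth weight and timed weights."""

    sex: str
    birth_weight: float
    weight_records: tuple = ()
    gestational_age: float = 40.0
    lipid_table: LookupTable | None = None

    def __post_init__(self):
        _validate_sex(self.sex)
        if not self.birth_weight > 0:
            raise ValueError("birth_weight must be positive")
        if not 0 < self.gestational_age <= 44:
            raise ValueError("gestational_age (weeks) must be in (0, 44]")
        recs = sorted((float(a), float(w)) for a, w in self.weight_records)
        if any(a < 0 for a, _ in recs):
            raise ValueError("weight record ages must be non-negative")
        if not recs or recs[0][0] > 0:
            recs.insert(0, (0.0, float(self.birth_weight)))
        self.weight_records = tuple(recs)

    @property
    def fetal_lipid_fraction(self) -> float:
        return FETAL_LIPID_FRACTION[self.sex]

    def _table(self) -> LookupTable:
        return self.lipid_table or lipid_fraction_table(self.sex)

    def weight(self, age):
        """Interpolated body weight (kg) at a postnatal age."""
        return interpolate_weight(self.weight_records, age)

    def lipid_volume(self, age):
        """Body lipid mass (kg) at a postnatal age."""
        return child_lipid_volume(age, self.weight(age), self.sex, self.lipid_table)


def child_lipid_volume(age, weight, sex: str, table: LookupTable | None = None):
    """Child body lipid mass (kg): weight times the age/sex lipid fraction.

    The packaged lookup starts at the fetal lipid fraction (15%/14%) at age 0,
    so the newborn value is continuous with the prenatal compartment.
    """
    _validate_sex(sex)
    if np.any(np.asarray(age) < 0):
        raise ValueError("age must be non-negative")
    tab = table or lipid_fraction_table(sex)
    return weight * tab(age)


@dataclass
class BreastfeedingSchedule:
    """Exclusive then partial breastfeeding durations (years) and the milk
    fraction of the diet during partial feeding."""

    exclusive_duration: float
    partial_duration: float = 0.0
    partial_milk_fraction: float = 0.5

    def __post_init__(self):
        if self.exclusive_duration < 0 or self.partial_duration < 0:
            raise ValueError("breastfeeding durations must be non-negative")
        if not 0.0 <= self.partial_milk_fraction <= 1.0:
            raise ValueError("partial_milk_fraction must be in [0, 1]")

    @property
    def total_duration(self) -> float:
        return self.exclusive_duration + self.partial_duration

    def milk_intake_rate(self, age: float, child_weight: float) -> float:
        """Milk intake (L/hour) at a child age under this schedule."""
        if age < self.exclusive_duration:
            return exclusive_milk_intake_rate(age, child_weight)
        if age < self.total_duration:
            return partial_milk_intake_rate(
                age, self.partial_milk_fraction, child_weight
            )
        return 0.0
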