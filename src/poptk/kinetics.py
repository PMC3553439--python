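"""Coupled mother-child lipid-compartment kinetics.

The mother and child are each a single well-mixed lipid pool. The mother
ingests the pollutant at a constant daily rate over her whole life, eliminates
it by first-order kinetics, and — once the child is born — exports it through
breast-milk lipids. During gestation the fetus shares the maternal pool
(equal lipid-normalized concentrations); at delivery the pool splits in
proportion to lipid mass, which makes the newborn's concentration equal to
the mother's. The state variables are chemical amounts (ng), so changes in
lipid volume produce dilution/concentration automatically.

Because the system is linear in dose, a single unit-intake simulation
calibrates the maternal lifetime daily intake from one biomarker measurement
(maternal blood at delivery, cord blood, or breast milk) by simple scaling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .physiology import (
    DAYS_PER_YEAR,
    WEEKS_PER_YEAR,
    BreastfeedingSchedule,
    ChildPhysiology,
    CompoundParams,
    MaternalPhysiology,
    fetal_lipid_mass,
    maternal_lipid_volume,
    milk_lipid_fraction,
    MILK_LIPID_FLOOR_AGE,
)

__all__ = [
    "MATERNAL_BLOOD",
    "CORD_BLOOD",
    "BREAST_MILK",
    "MILK_NEUTRAL_LIPID_FACTOR",
    "DEFAULT_HORIZON",
    "DyadProfile",
    "BiomarkerMeasurement",
    "ConcentrationSeries",
    "IntakeEstimate",
    "CalibrationError",
    "simulate_dyad",
    "simulate_mother",
    "simulate_adult",
    "recover_half_life",
    "calibrate_intake",
    "simulate_from_biomarker",
    "window_average",
]

MATERNAL_BLOOD = "maternal_blood"
CORD_BLOOD = "cord_blood"
BREAST_MILK = "breast_milk"
_MATRICES = (MATERNAL_BLOOD, CORD_BLOOD, BREAST_MILK)

#: Average factor by which lipid-normalized breast-milk readings overread the
#: blood-lipid basis: milk lipids are nearly all neutral triacylglycerols in
#: which POPs partition, while the usual blood lipid adjustment also counts
#: phospholipids with lower binding affinity.
MILK_NEUTRAL_LIPID_FACTOR = 1.6

#: Default simulation horizon: 45 months of child age.
DEFAULT_HORIZON = 45.0 / 12.0

_HOURS_PER_YEAR = 24.0 * DAYS_PER_YEAR
_G_PER_KG = 1000.0


class CalibrationError(ValueError):
    """The model predicts a zero biomarker level; the intake is undetermined."""


@dataclass
class DyadProfile:
    """All inputs for one mother-child pair."""

    maternal: MaternalPhysiology
    child: ChildPhysiology
    feeding: BreastfeedingSchedule

    @property
    def gestation_years(self) -> float:
        return self.child.gestational_age / WEEKS_PER_YEAR


@dataclass(frozen=True)
class BiomarkerMeasurement:
    """One lipid-normalized POP measurement tied to the dyad's timeline.

    ``time`` is in years relative to delivery. Maternal and cord blood are
    delivery samples (time 0); breast milk may be sampled any time at or
    after delivery. ``milk_basis_factor`` is the ratio by which a breast-milk
    reading overreads the blood-lipid-basis concentration; calibration
    divides the measurement by it (1.0 = no correction; 1.6 reflects the
    average neutral-lipid artifact).
    """

    matrix: str
    concentration: float
    time: float = 0.0
    milk_basis_factor: float = 1.0

    def __post_init__(self):
        if self.matrix not in _MATRICES:
            raise ValueError(f"matrix must be one of {_MATRICES}, got {self.matrix!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.matrix in (MATERNAL_BLOOD, CORD_BLOOD) and abs(self.time) > 1e-9:
            raise ValueError(f"{self.matrix} is a delivery sample; time must be 0")
        if self.matrix == BREAST_MILK and self.time < 0:
            raise ValueError("breast milk sampling time must be >= 0")
        if not self.milk_basis_factor > 0:
            raise ValueError("milk_basis_factor must be positive")


@dataclass(frozen=True)
class IntakeEstimate:
    """Constant maternal lifetime oral intake (ng/day) back-calculated from a
    biomarker measurement."""

    daily_intake: float
    source_measurement: BiomarkerMeasurement

    def __post_init__(self):
        if self.daily_intake < 0:
            raise ValueError("daily_intake must be non-negative")


@dataclass
class ConcentrationSeries:
    """Mother and child lipid-normalized concentration profiles on a time grid.

    ``times`` is child age in years. Concentrations are ng/g lipid; lipid
    volumes kg; the cumulative fields audit the mass balance in ng:
    cum_intake = stored (mother + child) + cum_eliminated at every point.
    """

    times: np.ndarray
    child_conc: np.ndarray
    mother_conc: np.ndarray
    child_lipid_kg: np.ndarray
    mother_lipid_kg: np.ndarray
    cum_intake_ng: np.ndarray
    cum_eliminated_ng: np.ndarray
    cum_transferred_ng: np.ndarray
    daily_intake: float = 0.0

    def child_at(self, age):
        return np.interp(age, self.times, self.child_conc)

    def mother_at(self, age):
        return np.interp(age, self.times, self.mother_conc)

    @property
    def mother_amount_ng(self) -> np.ndarray:
        return self.mother_conc * _G_PER_KG * self.mother_lipid_kg

    @property
    def child_amount_ng(self) -> np.ndarray:
        return self.child_conc * _G_PER_KG * self.child_lipid_kg

    def mass_balance_error(self) -> float:
        """Largest relative violation of intake = stored + eliminated."""
        lhs = self.cum_intake_ng
        rhs = self.mother_amount_ng + self.child_amount_ng + self.cum_eliminated_ng
        scale = np.maximum(np.abs(lhs), 1e-300)
        return float(np.max(np.abs(lhs - rhs) / scale))

    def scaled(self, factor: float) -> "ConcentrationSeries":
        """The series under intake scaled by ``factor`` (kinetics are linear)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return ConcentrationSeries(
            times=self.times,
            child_conc=self.child_conc * factor,
            mother_conc=self.mother_conc * factor,
            child_lipid_kg=self.child_lipid_kg,
            mother_lipid_kg=self.mother_lipid_kg,
            cum_intake_ng=self.cum_intake_ng * factor,
            cum_eliminated_ng=self.cum_eliminated_ng * factor,
            cum_transferred_ng=self.cum_transferred_ng * factor,
            daily_intake=self.daily_intake * factor,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_yr": self.times,
                "child_ng_g": self.child_conc,
                "mother_ng_g": self.mother_conc,
                "child_lipid_kg": self.child_lipid_kg,
                "mother_lipid_kg": self.mother_lipid_kg,
                "cum_intake_ng": self.cum_intake_ng,
                "cum_eliminated_ng": self.cum_eliminated_ng,
                "cum_transferred_ng": self.cum_transferred_ng,
            }
        )


def _milk_volume_rate(profile: DyadProfile, ages: np.ndarray) -> np.ndarray:
    """Vectorized milk intake (L/hour) over an age grid under the schedule."""
    f = profile.feeding
    w = profile.child.weight(ages)
    per_kg = np.maximum(0.0, -0.0024 * ages + 0.0063)
    absolute = np.maximum(0.0, -0.0086 * ages + 0.0188)
    exclusive = per_kg * w
    partial = np.where(ages < 1.0, f.partial_milk_fraction * per_kg * w, absolute)
    rate = np.where(ages < f.exclusive_duration, exclusive, 0.0)
    in_partial = (ages >= f.exclusive_duration) & (ages < f.total_duration)
    rate = np.where(in_partial, partial, rate)
    return rate


def _milk_lipid(ages: np.ndarray) -> np.ndarray:
    return 0.0034 * np.log(np.maximum(ages, MILK_LIPID_FLOOR_AGE)) + 0.0414


def _postnatal_grid(profile: DyadProfile, horizon: float, step_days: float) -> np.ndarray:
    """Uniform daily grid augmented with every model breakpoint.

    The right-hand side is only piecewise smooth (feeding-phase boundaries,
    the formula switch at 1 year, the intake zero crossings, the milk-lipid
    floor, weight-record and postpartum-offset kinks); snapping those points
    onto the grid keeps the Runge-Kutta scheme at full order in every step.
    """
    n = max(1, int(round(horizon * DAYS_PER_YEAR / step_days)))
    nodes = np.arange(n + 1) * (horizon / n)
    f = profile.feeding
    breaks = [
        f.exclusive_duration,
        f.total_duration,
        1.0,
        0.0063 / 0.0024,
        0.0188 / 0.0086,
        MILK_LIPID_FLOOR_AGE,
    ]
    breaks += [a for a, _ in profile.child.weight_records]
    breaks += [t for t, _ in profile.maternal.postpartum_weight_offsets]
    breaks = [b for b in breaks if 0.0 < b < horizon]
    nodes = np.unique(np.concatenate([nodes, np.asarray(breaks, dtype=float)]))
    # drop near-duplicate nodes that would create zero-length steps
    keep = np.concatenate([[True], np.diff(nodes) > 1e-12])
    return nodes[keep]


def simulate_dyad(
    profile: DyadProfile,
    compound: CompoundParams,
    daily_intake: float,
    horizon: float = DEFAULT_HORIZON,
    step_days: float = 1.0,
) -> ConcentrationSeries:
    """Simulate mother and child from birth to ``horizon`` years of child age.

    The maternal burden at delivery comes from the exact solution of constant
    intake with first-order elimination over her lifetime (the pre-delivery
    system has constant coefficients); the coupled postnatal phase is
    integrated with a fixed-step classical Runge-Kutta scheme on amounts,
    with the milk-transfer coefficient precomputed on the half-step grid.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if daily_intake < 0:
        raise ValueError("daily_intake must be non-negative")
    k = compound.k_el
    intake_per_year = daily_intake * DAYS_PER_YEAR
    m, c = profile.maternal, profile.child
    gest = profile.gestation_years

    # Maternal + fetal pool at delivery (exact accumulation over her life).
    t_life = m.age_at_delivery
    pool = intake_per_year / k * -math.expm1(-k * t_life)
    v_fetus = fetal_lipid_mass(c.birth_weight, c.sex)
    v_mother_del = maternal_lipid_volume(m, 0.0, gest)
    conc_delivery = pool / (_G_PER_KG * (v_mother_del + v_fetus))
    a_child = _G_PER_KG * v_fetus * conc_delivery
    a_mother = pool - a_child
    eliminated = intake_per_year * t_life - pool
    transferred = 0.0

    times = _postnatal_grid(profile, horizon, step_days)
    n = times.size - 1
    # node/midpoint interleaved evaluation grid for the RK4 stages
    full = np.empty(2 * n + 1)
    full[0::2] = times
    full[1::2] = 0.5 * (times[:-1] + times[1:])

    v_m = np.asarray(maternal_lipid_volume(m, full, gest), dtype=float)
    rate_l_hr = _milk_volume_rate(profile, full)
    # ng/year transferred per ng/g of maternal concentration, divided by the
    # maternal amount: transfer = coef * A_mother with coef in 1/year.
    coef = rate_l_hr * _HOURS_PER_YEAR * _milk_lipid(full) / v_m

    A_m = np.empty(n + 1)
    A_c = np.empty(n + 1)
    E = np.empty(n + 1)
    T = np.empty(n + 1)
    A_m[0], A_c[0], E[0], T[0] = a_mother, a_child, eliminated, transferred

    I = intake_per_year
    for j in range(n):
        h = times[j + 1] - times[j]
        c0 = coef[2 * j]
        c1 = coef[2 * j + 1]
        c2 = coef[2 * j + 2]
        am, ac, e, tr = A_m[j], A_c[j], E[j], T[j]

        def f(am_, ac_, cc):
            trans = cc * am_
            return (
                I - k * am_ - trans,
                trans - k * ac_,
                k * (am_ + ac_),
                trans,
            )

        k1 = f(am, ac, c0)
        k2 = f(am + 0.5 * h * k1[0], ac + 0.5 * h * k1[1], c1)
        k3 = f(am + 0.5 * h * k2[0], ac + 0.5 * h * k2[1], c1)
        k4 = f(am + h * k3[0], ac + h * k3[1], c2)
        A_m[j + 1] = am + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        A_c[j + 1] = ac + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        E[j + 1] = e + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        T[j + 1] = tr + h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])

    v_m_nodes = v_m[::2]
    v_c_nodes = np.asarray(c.lipid_volume(times), dtype=float)
    return ConcentrationSeries(
        times=times,
        child_conc=A_c / (_G_PER_KG * v_c_nodes),
        mother_conc=A_m / (_G_PER_KG * v_m_nodes),
        child_lipid_kg=v_c_nodes,
        mother_lipid_kg=v_m_nodes,
        cum_intake_ng=intake_per_year * (t_life + times),
        cum_eliminated_ng=E,
        cum_transferred_ng=T,
        daily_intake=daily_intake,
    )


def simulate_mother(
    profile: DyadProfile,
    compound: CompoundParams,
    daily_intake: float,
    horizon: float | None = None,
    step_days: float = 1.0,
) -> ConcentrationSeries:
    """Maternal concentration profile on the maternal-age timeline.

    Covers maternal age 0 to ``horizon`` (default: delivery plus 45 months).
    Before delivery the burden follows the exact constant-intake solution
    (the fetus shares the pool during gestation); after delivery the full
    dyad model drives the lactational output. Child fields of the returned
    series hold the postnatal child profile aligned on the same grid (zero
    before birth).
    """
    if daily_intake < 0:
        raise ValueError("daily_intake must be non-negative")
    m = profile.maternal
    t_del = m.age_at_delivery
    if horizon is None:
        horizon = t_del + DEFAULT_HORIZON
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    k = compound.k_el
    I = daily_intake * DAYS_PER_YEAR
    gest = profile.gestation_years
    h = step_days / DAYS_PER_YEAR
    pre_end = min(horizon, t_del)
    n_pre = max(1, int(round(pre_end / h)))
    t_pre = np.linspace(0.0, pre_end, n_pre + 1)
    A_pre = I / k * -np.expm1(-k * t_pre)
    v_pre = np.asarray(maternal_lipid_volume(m, t_pre - t_del, gest), dtype=float)
    # During gestation the fetus shares the pool.
    in_gest = t_pre - t_del >= -gest
    v_fetus = np.zeros_like(t_pre)
    if np.any(in_gest):
        gw = (t_pre[in_gest] - t_del + gest) / gest * profile.child.gestational_age
        from .physiology import fetal_weight, FETAL_LIPID_FRACTION

        fw = np.array(
            [
                fetal_weight(w, profile.child.gestational_age, profile.child.birth_weight)
                for w in np.atleast_1d(gw)
            ]
        )
        v_fetus[in_gest] = FETAL_LIPID_FRACTION[profile.child.sex] * fw
    conc_pre = A_pre / (_G_PER_KG * (v_pre + v_fetus))

    blocks = {
        "times": [t_pre],
        "mother_conc": [conc_pre],
        "mother_lipid": [v_pre + v_fetus],
        "child_conc": [np.zeros_like(t_pre)],
        "child_lipid": [np.zeros_like(t_pre)],
        "cum_intake": [I * t_pre],
        "cum_elim": [I * t_pre - A_pre],
        "cum_trans": [np.zeros_like(t_pre)],
    }
    if horizon > t_del:
        dyad = simulate_dyad(
            profile, compound, daily_intake, horizon - t_del, step_days
        )
        blocks["times"].append(t_del + dyad.times[1:])
        blocks["mother_conc"].append(dyad.mother_conc[1:])
        blocks["mother_lipid"].append(dyad.mother_lipid_kg[1:])
        blocks["child_conc"].append(dyad.child_conc[1:])
        blocks["child_lipid"].append(dyad.child_lipid_kg[1:])
        blocks["cum_intake"].append(dyad.cum_intake_ng[1:])
        blocks["cum_elim"].append(dyad.cum_eliminated_ng[1:])
        blocks["cum_trans"].append(dyad.cum_transferred_ng[1:])
    return ConcentrationSeries(
        times=np.concatenate(blocks["times"]),
        child_conc=np.concatenate(blocks["child_conc"]),
        mother_conc=np.concatenate(blocks["mother_conc"]),
        child_lipid_kg=np.concatenate(blocks["child_lipid"]),
        mother_lipid_kg=np.concatenate(blocks["mother_lipid"]),
        cum_intake_ng=np.concatenate(blocks["cum_intake"]),
        cum_eliminated_ng=np.concatenate(blocks["cum_elim"]),
        cum_transferred_ng=np.concatenate(blocks["cum_trans"]),
        daily_intake=daily_intake,
    )


def simulate_adult(
    compound: CompoundParams,
    daily_intake: float,
    duration: float,
    lipid_kg: float = 20.0,
    intake_until: float | None = None,
    step_days: float = 1.0,
):
    """One-compartment adult simulation at constant lipid mass (RK4).

    Intake (ng/day) applies for t < ``intake_until`` (default: the whole
    duration), elimination is first order throughout. Returns (times, conc)
    with concentration in ng/g lipid. Used for decay-fit experiments such as
    half-life recovery.
    """
    if daily_intake < 0:
        raise ValueError("daily_intake must be non-negative")
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not lipid_kg > 0:
        raise ValueError("lipid_kg must be positive")
    k = compound.k_el
    I = daily_intake * DAYS_PER_YEAR
    t_stop = duration if intake_until is None else intake_until
    n = max(1, int(round(duration * DAYS_PER_YEAR / step_days)))
    h = duration / n
    times = np.arange(n + 1) * h
    A = np.empty(n + 1)
    A[0] = 0.0

    def rate(t, a):
        return (I if t < t_stop else 0.0) - k * a

    for j in range(n):
        t, a = times[j], A[j]
        k1 = rate(t, a)
        k2 = rate(t + 0.5 * h, a + 0.5 * h * k1)
        k3 = rate(t + 0.5 * h, a + 0.5 * h * k2)
        k4 = rate(t + h, a + h * k3)
        A[j + 1] = a + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return times, A / (_G_PER_KG * lipid_kg)


def recover_half_life(
    compound: CompoundParams,
    accumulation_years: float = 20.0,
    decay_years: float = 30.0,
    daily_intake: float = 100.0,
    lipid_kg: float = 20.0,
    step_days: float = 1.0,
) -> float:
    """Recover the elimination half-life (years) by a decay-fit experiment.

    Simulate constant intake to ``accumulation_years``, stop intake,
    integrate ``decay_years`` further, and regress log concentration on time
    over the decay window; returns ln(2)/|slope|.
    """
    duration = accumulation_years + decay_years
    times, conc = simulate_adult(
        compound,
        daily_intake,
        duration,
        lipid_kg=lipid_kg,
        intake_until=accumulation_years,
        step_days=step_days,
    )
    mask = times >= accumulation_years + 2.0 * step_days / DAYS_PER_YEAR
    slope = np.polyfit(times[mask], np.log(conc[mask]), 1)[0]
    return math.log(2.0) / abs(slope)


def _unit_series(
    profile: DyadProfile,
    compound: CompoundParams,
    measurement: BiomarkerMeasurement,
    horizon: float,
    step_days: float,
) -> tuple[ConcentrationSeries, float]:
    """Unit-intake (1 ng/day) simulation and the predicted biomarker reading."""
    sim_horizon = max(horizon, measurement.time + 1.0 / DAYS_PER_YEAR)
    series = simulate_dyad(profile, compound, 1.0, sim_horizon, step_days)
    if measurement.matrix in (MATERNAL_BLOOD, CORD_BLOOD):
        # Cord blood equals maternal blood at delivery on a lipid basis.
        predicted = float(series.mother_conc[0])
    else:
        predicted = float(series.mother_at(measurement.time)) * measurement.milk_basis_factor
    return series, predicted


def calibrate_intake(
    profile: DyadProfile,
    compound: CompoundParams,
    measurement: BiomarkerMeasurement,
    horizon: float = DEFAULT_HORIZON,
    step_days: float = 1.0,
) -> IntakeEstimate:
    """Back-calculate the constant maternal daily intake (ng/day) that makes
    the simulated biomarker match the measurement.

    The kinetics are linear in dose, so one unit-intake simulation suffices:
    intake = measured / predicted-at-unit-intake. Breast-milk readings are
    first divided by ``measurement.milk_basis_factor``.
    """
    _, predicted = _unit_series(profile, compound, measurement, horizon, step_days)
    if predicted <= 0:
        raise CalibrationError(
            "unit-intake simulation predicts a zero biomarker level for this profile"
        )
    return IntakeEstimate(measurement.concentration / predicted, measurement)


def simulate_from_biomarker(
    profile: DyadProfile,
    compound: CompoundParams,
    measurement: BiomarkerMeasurement,
    horizon: float = DEFAULT_HORIZON,
    step_days: float = 1.0,
) -> ConcentrationSeries:
    """Calibrate the intake from the measurement, then return the full dyad
    profile under that intake (one simulation, rescaled by linearity)."""
    series, predicted = _unit_series(profile, compound, measurement, horizon, step_days)
    if predicted <= 0:
        raise CalibrationError(
            "unit-intake simulation predicts a zero biomarker level for this profile"
        )
    return series.scaled(measurement.concentration / predicted)


def window_average(series: ConcentrationSeries, t0: float, t1: float) -> float:
    """Time-weighted mean child concentration (ng/g lipid) over [t0, t1]."""
    tmax = float(series.times[-1])
    if not (0.0 <= t0 < t1 <= tmax + 1e-9):
        raise ValueError(f"window [{t0}, {t1}] must lie within [0, {tmax}]")
    t1 = min(t1, tmax)
    inner = series.times[(series.times > t0) & (series.times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, series.times, series.child_conc)
    return float(np.trapezoid(vals, grid) / (t1 - t0))
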