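"""CSV readers/writers, the compound preset registry, and run configuration."""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .kinetics import BiomarkerMeasurement, DyadProfile
from .physiology import (
    BreastfeedingSchedule,
    ChildPhysiology,
    CompoundParams,
    DAYS_PER_YEAR,
    DEFAULT_POSTPARTUM_OFFSETS,
    DEFAULT_PREGNANCY_GAIN,
    FEMALE,
    MALE,
    MaternalPhysiology,
)

__all__ = [
    "COMPOUND_REGISTRY",
    "resolve_compound",
    "CohortRecord",
    "read_cohort",
    "write_cohort",
    "cohort_from_frame",
    "cohort_to_frame",
    "read_child_levels",
    "RunConfig",
]

log = logging.getLogger("poptk")

#: Elimination half-lives (years) from cross-sectional and longitudinal
#: population data. The p,p'-DDT value is reported as approximate.
COMPOUND_REGISTRY = {
    "PCB-118": CompoundParams("PCB-118", 9.3),
    "PCB-138": CompoundParams("PCB-138", 10.8),
    "PCB-153": CompoundParams("PCB-153", 14.4),
    "PCB-170": CompoundParams("PCB-170", 15.5),
    "PCB-180": CompoundParams("PCB-180", 11.5),
    "p,p'-DDT": CompoundParams("p,p'-DDT", 5.0, approximate=True),
    "p,p'-DDE": CompoundParams("p,p'-DDE", 13.0),
    "HCB": CompoundParams("HCB", 6.0),
}


def _normalize_name(name: str) -> str:
    return name.strip().lower().replace("´", "'").replace("’", "'")


_REGISTRY_BY_NORM = {_normalize_name(k): v for k, v in COMPOUND_REGISTRY.items()}


def resolve_compound(name: str | None = None, half_life: float | None = None) -> CompoundParams:
    """Look up a compound preset, optionally overridden by an explicit half-life.

    A ``half_life`` alone defines a custom compound; a known ``name`` alone
    resolves from the registry; both together override the preset half-life.
    """
    if half_life is not None:
        return CompoundParams(name or "custom", float(half_life))
    if name is None:
        raise ValueError("either a compound name or a half-life is required")
    try:
        return _REGISTRY_BY_NORM[_normalize_name(name)]
    except KeyError:
        raise ValueError(
            f"unknown compound {name!r}; provide an explicit half-life "
            f"(known: {', '.join(COMPOUND_REGISTRY)})"
        ) from None


@dataclass
class CohortRecord:
    """One cohort row: dyad identity, inputs and the biomarker measurement."""

    dyad_id: str
    profile: DyadProfile
    measurement: BiomarkerMeasurement


_WEIGHT_AGE_RE = re.compile(r"^weight_age(\d+)_yr$")

_BASE_COLUMNS = [
    "dyad_id",
    "maternal_age",
    "prepreg_weight_kg",
    "preg_gain_kg",
    "gest_age_wk",
    "sex",
    "birth_weight_kg",
    "excl_bf_days",
    "total_bf_days",
    "partial_fraction",
    "biomarker_matrix",
    "biomarker_time_yr",
    "biomarker_ng_g",
]

#: Columns whose missing values are replaced by the column mean (falling back
#: to the documented default when the whole column is missing).
_IMPUTABLE = {
    "maternal_age": None,
    "prepreg_weight_kg": None,
    "preg_gain_kg": DEFAULT_PREGNANCY_GAIN,
    "gest_age_wk": 40.0,
    "birth_weight_kg": None,
    "partial_fraction": 0.5,
}


def cohort_from_frame(
    df: pd.DataFrame,
    strict: bool = False,
    impute: bool = True,
    milk_basis_factor: float = 1.0,
) -> list[CohortRecord]:
    """Build validated dyad records from a cohort table.

    Rows missing essential fields (sex, breastfeeding durations, biomarker)
    are skipped with a warning, or fatal under ``strict``; missing
    non-essential values are mean-imputed (default when the column is empty).
    """
    df = df.copy()
    missing_cols = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table is missing columns: {missing_cols}")
    if impute:
        for col, default in _IMPUTABLE.items():
            vals = pd.to_numeric(df[col], errors="coerce")
            fill = vals.mean() if vals.notna().any() else default
            if fill is None and vals.isna().any():
                _report(strict, f"column {col!r} is entirely missing and has no default")
                continue
            df[col] = vals.fillna(fill)

    weight_pairs = []
    for col in df.columns:
        match = _WEIGHT_AGE_RE.match(col)
        if match and f"weight{match.group(1)}_kg" in df.columns:
            weight_pairs.append((col, f"weight{match.group(1)}_kg"))

    records, errors = [], []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        r = row._asdict()
        try:
            records.append(_record_from_row(r, weight_pairs, milk_basis_factor))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {line} (dyad {r.get('dyad_id', '?')}): {exc}")
    if errors:
        _report(strict, "; ".join(errors))
    return records


def _report(strict: bool, message: str):
    if strict:
        raise ValueError(message)
    warnings.warn(message, stacklevel=3)


def _record_from_row(r: dict, weight_pairs, milk_basis_factor: float) -> CohortRecord:
    sex = str(r["sex"]).strip().lower()
    sex = {"m": MALE, "f": FEMALE, MALE: MALE, FEMALE: FEMALE}.get(sex)
    if sex is None:
        raise ValueError(f"unrecognized sex {r['sex']!r}")
    excl_days = float(r["excl_bf_days"])
    total_days = float(r["total_bf_days"])
    if np.isnan(excl_days) or np.isnan(total_days):
        raise ValueError("breastfeeding durations are required")
    if excl_days > total_days:
        raise ValueError(
            f"excl_bf_days ({excl_days}) exceeds total_bf_days ({total_days})"
        )
    conc = float(r["biomarker_ng_g"])
    if np.isnan(conc):
        raise ValueError("biomarker measurement is required")
    weights = []
    for age_col, w_col in weight_pairs:
        age, w = r.get(age_col), r.get(w_col)
        if age is not None and w is not None and np.isfinite(age) and np.isfinite(w):
            weights.append((float(age), float(w)))
    maternal = MaternalPhysiology(
        age_at_delivery=float(r["maternal_age"]),
        prepregnancy_weight=float(r["prepreg_weight_kg"]),
        pregnancy_weight_gain=float(r["preg_gain_kg"]),
        postpartum_weight_offsets=DEFAULT_POSTPARTUM_OFFSETS,
    )
    child = ChildPhysiology(
        sex=sex,
        birth_weight=float(r["birth_weight_kg"]),
        gestational_age=float(r["gest_age_wk"]),
        weight_records=tuple(weights),
    )
    feeding = BreastfeedingSchedule(
        exclusive_duration=excl_days / DAYS_PER_YEAR,
        partial_duration=(total_days - excl_days) / DAYS_PER_YEAR,
        partial_milk_fraction=float(r["partial_fraction"]),
    )
    time = float(r["biomarker_time_yr"])
    measurement = BiomarkerMeasurement(
        matrix=str(r["biomarker_matrix"]).strip(),
        concentration=conc,
        time=0.0 if np.isnan(time) else time,
        milk_basis_factor=milk_basis_factor,
    )
    return CohortRecord(str(r["dyad_id"]), DyadProfile(maternal, child, feeding), measurement)


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Inverse of :func:`cohort_from_frame` (lossless for all schema fields)."""
    n_weights = max((len(r.profile.child.weight_records) for r in records), default=0)
    rows = []
    for rec in records:
        p = rec.profile
        row = {
            "dyad_id": rec.dyad_id,
            "maternal_age": p.maternal.age_at_delivery,
            "prepreg_weight_kg": p.maternal.prepregnancy_weight,
            "preg_gain_kg": p.maternal.pregnancy_weight_gain,
            "gest_age_wk": p.child.gestational_age,
            "sex": p.child.sex,
            "birth_weight_kg": p.child.birth_weight,
            "excl_bf_days": p.feeding.exclusive_duration * DAYS_PER_YEAR,
            "total_bf_days": p.feeding.total_duration * DAYS_PER_YEAR,
            "partial_fraction": p.feeding.partial_milk_fraction,
            "biomarker_matrix": rec.measurement.matrix,
            "biomarker_time_yr": rec.measurement.time,
            "biomarker_ng_g": rec.measurement.concentration,
        }
        for i, (age, w) in enumerate(p.child.weight_records, start=1):
            row[f"weight_age{i}_yr"] = age
            row[f"weight{i}_kg"] = w
        for i in range(len(p.child.weight_records) + 1, n_weights + 1):
            row[f"weight_age{i}_yr"] = np.nan
            row[f"weight{i}_kg"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def read_cohort(path, strict: bool = False, impute: bool = True,
                milk_basis_factor: float = 1.0) -> list[CohortRecord]:
    """Read a cohort CSV (UTF-8, comma-separated, dot-decimal, header row)."""
    return cohort_from_frame(
        pd.read_csv(path), strict=strict, impute=impute,
        milk_basis_factor=milk_basis_factor,
    )


def write_cohort(records: list[CohortRecord], path):
    cohort_to_frame(records).to_csv(path, index=False)


def read_child_levels(path) -> pd.DataFrame:
    """Read measured child levels: dyad_id, age_yr, measured_ng_g."""
    df = pd.read_csv(path)
    required = {"dyad_id", "age_yr", "measured_ng_g"}
    if not required.issubset(df.columns):
        raise ValueError(f"child-levels table needs columns {sorted(required)}")
    df["dyad_id"] = df["dyad_id"].astype(str)
    return df


@dataclass
class RunConfig:
    """Validated run defaults, parseable from a flat YAML key-value file."""

    pregnancy_weight_gain: float = DEFAULT_PREGNANCY_GAIN
    postpartum_offsets: tuple = DEFAULT_POSTPARTUM_OFFSETS
    partial_milk_fraction: float = 0.5
    milk_basis_factor: float = 1.0
    step_days: float = 1.0
    horizon: float = 45.0 / 12.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.step_days > 0:
            raise ValueError("step_days must be positive")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        if not 0.0 <= self.partial_milk_fraction <= 1.0:
            raise ValueError("partial_milk_fraction must be in [0, 1]")
        if not self.milk_basis_factor > 0:
            raise ValueError("milk_basis_factor must be positive")
        self.postpartum_offsets = tuple(
            (float(t), float(w)) for t, w in self.postpartum_offsets
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        data = asdict(self)
        data["postpartum_offsets"] = [list(x) for x in self.postpartum_offsets]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def log_resolved(self):
        """Record every resolved default so a run is reproducible from its log."""
        for key, value in asdict(self).items():
            log.info("config %s = %r", key, value)
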