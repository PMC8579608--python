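"""Cohort ingestion, inclusion/exclusion screens and attrition accounting.

A screened cohort shrinks to the analysis set through an ordered rule
chain — missing data, age under 18, dialysis, creatinine-interfering
drugs, edema/cardiac insufficiency, and finally a statistical outlier
screen on the (eGFR, mGFR) pairs. Flags are append-only and each carries
the rule that set it; a record excluded by several rules is counted once
in the attrition table, attributed to the first matching rule.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .clearance import PlasmaStudy
from .equations import _normalize_sex

__all__ = [
    "EXCLUSION_ORDER",
    "CohortSchemaError",
    "ExclusionFlag",
    "CohortRecord",
    "AttritionReport",
    "apply_exclusions",
    "outlier_screen",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Rule order fixed to the study's listing; attribution is first-match.
EXCLUSION_ORDER = (
    "missing_data",
    "under_18",
    "dialysis",
    "interfering_drug",
    "edema_cardiac",
    "outlier",
)

RAW_PLASMA_COLUMNS = (
    "dose_cpm_ml",
    "t1_min",
    "t2_min",
    "p1_cpm_ml",
    "p2_cpm_ml",
)

REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "height_cm",
    "weight_kg",
    "scr_mg_dl",
)


class CohortSchemaError(ValueError):
    """The cohort CSV does not match the expected schema."""


@dataclass(frozen=True)
class ExclusionFlag:
    flag: str
    rule: str


@dataclass
class CohortRecord:
    """One screened patient; missing values are ``None``.

    ``true_mgfr`` is only populated by the synthetic generator (the
    noise-free ground truth behind the simulated plasma samples).
    """

    patient_id: str
    sex: str | None = None
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    scr: float | None = None
    plasma: PlasmaStudy | None = None
    mgfr_precomputed: float | None = None
    on_dialysis: bool = False
    interfering_drug: bool = False
    edema_cardiac: bool = False
    etiology: str | None = None
    true_mgfr: float | None = None
    #: set by the synthetic generator's exclusion scenario (ground truth
    #: for which engineered rule a record should trip), never by real data
    scenario_role: str | None = None
    exclusion_flags: list[ExclusionFlag] = field(default_factory=list)

    @property
    def flag_names(self) -> tuple[str, ...]:
        return tuple(f.flag for f in self.exclusion_flags)

    def add_flag(self, flag: str, rule: str) -> None:
        if flag not in self.flag_names:  # append-only, no duplicates
            self.exclusion_flags.append(ExclusionFlag(flag, rule))

    @property
    def in_analysis_set(self) -> bool:
        return not self.exclusion_flags

    def has_mgfr_source(self) -> bool:
        return self.plasma is not None or _present(self.mgfr_precomputed)


def _present(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return True


@dataclass(frozen=True)
class AttritionReport:
    """Screened-to-enrolled accounting under first-match attribution."""

    n_screened: int
    counts: dict[str, int]
    n_enrolled: int

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "excluded": dict(self.counts),
            "n_enrolled": self.n_enrolled,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"screened: {self.n_screened}"]
        for flag in EXCLUSION_ORDER:
            n = self.counts.get(flag, 0)
            if n:
                lines.append(f"  - excluded ({flag.replace('_', ' ')}): {n}")
        lines.append(f"enrolled: {self.n_enrolled}")
        return "\n".join(lines)


def _applicable_rules(
    record: CohortRecord,
    required_fields: tuple[str, ...],
    age_floor: float,
    outlier_ids: frozenset,
) -> list[tuple[str, str]]:
    rules: list[tuple[str, str]] = []
    missing = [f for f in required_fields if not _present(getattr(record, f))]
    if not record.has_mgfr_source():
        missing.append("mgfr_source")
    if missing:
        rules.append(("missing_data", f"missing required fields: {', '.join(missing)}"))
    if _present(record.age) and record.age < age_floor:
        rules.append(("under_18", f"age {record.age:g} < {age_floor:g}"))
    if record.on_dialysis:
        rules.append(("dialysis", "replacement therapy"))
    if record.interfering_drug:
        rules.append(("interfering_drug", "creatinine-interfering drug"))
    if record.edema_cardiac:
        rules.append(("edema_cardiac", "edema or cardiac insufficiency"))
    if record.patient_id in outlier_ids:
        rules.append(("outlier", "flagged by outlier screen"))
    return rules


def apply_exclusions(
    cohort: list[CohortRecord],
    *,
    required_fields: tuple[str, ...] = ("scr", "age", "weight_kg", "height_cm"),
    age_floor: float = 18.0,
    outlier_ids: frozenset | set = frozenset(),
) -> tuple[list[CohortRecord], AttritionReport]:
    """Apply the ordered exclusion rules; returns (analysis set, attrition).

    Deterministic and idempotent: flags are appended without duplication,
    and a record carrying several flags contributes one exclusion, under
    the first flag in :data:`EXCLUSION_ORDER`.
    """
    outlier_ids = frozenset(outlier_ids)
    counts = {flag: 0 for flag in EXCLUSION_ORDER}
    analysis: list[CohortRecord] = []
    for record in cohort:
        for flag, rule in _applicable_rules(
            record, required_fields, age_floor, outlier_ids
        ):
            record.add_flag(flag, rule)
        if record.in_analysis_set:
            analysis.append(record)
        else:
            first = min(record.flag_names, key=EXCLUSION_ORDER.index)
            counts[first] += 1
    report = AttritionReport(
        n_screened=len(cohort),
        counts={k: v for k, v in counts.items() if v},
        n_enrolled=len(analysis),
    )
    return analysis, report


def outlier_screen(
    pairs,
    threshold: float = 3.0,
    min_n: int = 10,
) -> set:
    """Flag pairs with |externally studentized residual| > ``threshold``
    in the OLS fit of eGFR on mGFR.

    With fewer than ``min_n`` pairs the screen is skipped (empty set, with
    a warning); a perfectly collinear cloud has no outliers by definition.
    """
    pairs = list(pairs)
    if len(pairs) < min_n:
        warnings.warn(
            f"outlier screen skipped: only {len(pairs)} pairs (< {min_n})",
            stacklevel=2,
        )
        return set()
    if not math.isfinite(threshold):
        return set()
    y = np.array([p.egfr for p in pairs], dtype=float)
    x = sm.add_constant(np.array([p.mgfr for p in pairs], dtype=float))
    fit = sm.OLS(y, x).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        return set()  # (near-)perfect fit: zero residuals everywhere
    student = OLSInfluence(fit).resid_studentized_external
    return {pairs[i].patient_id for i in np.flatnonzero(np.abs(student) > threshold)}


def _opt_float(row, col):
    if col in row.index and _present(row[col]) and not pd.isna(row[col]):
        return float(row[col])
    return None


def _row_plasma(row) -> PlasmaStudy | None:
    vals = {c: _opt_float(row, c) for c in RAW_PLASMA_COLUMNS}
    if any(v is None for v in vals.values()):
        return None
    try:
        return PlasmaStudy(
            dose_cpm_ml=vals["dose_cpm_ml"],
            t1_min=vals["t1_min"],
            t2_min=vals["t2_min"],
            p1_cpm_ml=vals["p1_cpm_ml"],
            p2_cpm_ml=vals["p2_cpm_ml"],
            delay1_h=_opt_float(row, "delay1_h") or 0.0,
            delay2_h=_opt_float(row, "delay2_h") or 0.0,
        )
    except ValueError:
        return None  # structurally bad plasma rows become missing-data exclusions


def read_cohort_csv(path) -> list[CohortRecord]:
    """Parse a cohort CSV into records.

    Either the raw plasma columns or ``mgfr_ml_min_173`` must be present
    in the header; per-row gaps become missing-data exclusions later
    rather than read errors. An unparseable sex code is a hard error.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortSchemaError(f"cannot read cohort CSV {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort CSV missing required columns: {missing}")
    has_raw = all(c in df.columns for c in RAW_PLASMA_COLUMNS)
    if not has_raw and "mgfr_ml_min_173" not in df.columns:
        raise CohortSchemaError(
            "cohort CSV needs either the raw plasma columns "
            f"{list(RAW_PLASMA_COLUMNS)} or 'mgfr_ml_min_173'"
        )
    records = []
    for _, row in df.iterrows():
        sex = row["sex"]
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                sex=_normalize_sex(sex) if _present(sex) and not pd.isna(sex) else None,
                age=_opt_float(row, "age_years"),
                height_cm=_opt_float(row, "height_cm"),
                weight_kg=_opt_float(row, "weight_kg"),
                scr=_opt_float(row, "scr_mg_dl"),
                plasma=_row_plasma(row) if has_raw else None,
                mgfr_precomputed=_opt_float(row, "mgfr_ml_min_173"),
                on_dialysis=bool(row.get("on_dialysis", 0) or 0),
                interfering_drug=bool(row.get("interfering_drug", 0) or 0),
                edema_cardiac=bool(row.get("edema_cardiac", 0) or 0),
                etiology=str(row["etiology"])
                if "etiology" in df.columns and not pd.isna(row["etiology"])
                else None,
                true_mgfr=_opt_float(row, "true_mgfr"),
            )
        )
    return records


def write_cohort_csv(records: list[CohortRecord], path) -> pd.DataFrame:
    """Write records back to the cohort CSV schema (plus a flags column)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age_years": r.age,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "scr_mg_dl": r.scr,
        }
        if r.plasma is not None:
            row.update(
                dose_cpm_ml=r.plasma.dose_cpm_ml,
                t1_min=r.plasma.t1_min,
                t2_min=r.plasma.t2_min,
                p1_cpm_ml=r.plasma.p1_cpm_ml,
                p2_cpm_ml=r.plasma.p2_cpm_ml,
                delay1_h=r.plasma.delay1_h,
                delay2_h=r.plasma.delay2_h,
            )
        if r.mgfr_precomputed is not None:
            row["mgfr_ml_min_173"] = r.mgfr_precomputed
        if r.true_mgfr is not None:
            row["true_mgfr"] = r.true_mgfr
        row.update(
            on_dialysis=int(r.on_dialysis),
            interfering_drug=int(r.interfering_drug),
            edema_cardiac=int(r.edema_cardiac),
            etiology=r.etiology,
            flags=";".join(r.flag_names),
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
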