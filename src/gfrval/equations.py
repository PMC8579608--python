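"""Creatinine-based eGFR equations as declarative piecewise power laws.

Every equation in this family has the form

    eGFR = coefficient · (Scr / denominator)^exponent · age_base^age

with sex-specific branches split at a creatinine knot (the "≤" branch
inclusive). Two equations ship pre-registered:

``ckd_epi_asian``
    The Asian modified CKD-EPI equation. The published form uses the male
    creatinine knot 0.9 mg/dL as the male denominator; some transcriptions
    print 0.7 there, which makes the male curve discontinuous at its own
    knot. The ``male_denominator`` option selects between the published
    0.9 (default) and the as-printed 0.7.

``liu_regression``
    The piecewise regression component of the Liu ensemble model. As
    published, its branches do NOT meet at the knots (female 92 vs 79
    mg/dL-normalized coefficients at 1.2; male 98 vs 105 at 1.0); the
    discontinuity is reproduced faithfully, not repaired.

New equations are data, not code: build an :class:`EquationSpec` (or load
one from JSON) and evaluate it with :func:`evaluate_equation`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

__all__ = [
    "EquationBranch",
    "EquationSpec",
    "PatientInput",
    "EnsembleOutputs",
    "evaluate_equation",
    "invert_equation",
    "ensemble_gfr",
    "get_equation",
    "register_equation",
    "available_equations",
]


def _normalize_sex(sex: str) -> str:
    s = str(sex).strip().upper()
    if s not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M' (case-insensitive), got {sex!r}")
    return s


@dataclass(frozen=True)
class EquationBranch:
    """One branch of a piecewise eGFR power law.

    ``side`` is ``'le'`` (Scr ≤ threshold, inclusive) or ``'gt'``.
    """

    sex: str
    threshold: float
    side: str
    coefficient: float
    denominator: float
    exponent: float
    age_base: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _normalize_sex(self.sex))
        if self.side not in ("le", "gt"):
            raise ValueError(f"side must be 'le' or 'gt', got {self.side!r}")
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if self.denominator <= 0:
            raise ValueError("creatinine denominator must be positive")
        if not self.exponent < 0:
            raise ValueError("creatinine exponent must be negative")
        if not 0 < self.age_base < 1:
            raise ValueError("age base must lie in (0, 1)")

    def value(self, scr: float, age: float) -> float:
        return (
            self.coefficient
            * (scr / self.denominator) ** self.exponent
            * self.age_base**age
        )


@dataclass(frozen=True)
class EquationSpec:
    """A named, sex-stratified two-branch eGFR equation."""

    name: str
    branches: tuple[EquationBranch, ...]

    def __post_init__(self) -> None:
        branches = tuple(self.branches)
        object.__setattr__(self, "branches", branches)
        for sex in ("F", "M"):
            sided = {b.side: b for b in branches if b.sex == sex}
            if set(sided) != {"le", "gt"}:
                raise ValueError(
                    f"equation {self.name!r} needs exactly one 'le' and one "
                    f"'gt' branch for sex {sex}"
                )
            if sided["le"].threshold != sided["gt"].threshold:
                raise ValueError(
                    f"equation {self.name!r}: branches for sex {sex} must "
                    "share one creatinine threshold"
                )

    def branch_for(self, sex: str, scr: float) -> EquationBranch:
        sex = _normalize_sex(sex)
        le, gt = None, None
        for b in self.branches:
            if b.sex == sex:
                if b.side == "le":
                    le = b
                else:
                    gt = b
        assert le is not None and gt is not None
        return le if scr <= le.threshold else gt

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "branches": [
                {
                    "sex": b.sex,
                    "threshold": b.threshold,
                    "side": b.side,
                    "coefficient": b.coefficient,
                    "denominator": b.denominator,
                    "exponent": b.exponent,
                    "age_base": b.age_base,
                }
                for b in self.branches
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> EquationSpec:
        return cls(
            name=d["name"],
            branches=tuple(EquationBranch(**b) for b in d["branches"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> EquationSpec:
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PatientInput:
    """Covariates of the creatinine equations: Scr (mg/dL), age (y), sex."""

    scr: float
    age: float
    sex: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _normalize_sex(self.sex))
        if not (self.scr > 0 and math.isfinite(self.scr)):
            raise ValueError(f"serum creatinine must be positive, got {self.scr}")
        if not math.isfinite(self.age) or self.age < 0:
            raise ValueError(f"age must be a non-negative number, got {self.age}")
        if self.age < 18:
            warnings.warn(
                f"age {self.age} is below the adult inclusion floor of 18 y",
                stacklevel=3,
            )


@dataclass(frozen=True)
class EnsembleOutputs:
    """The three ensemble component outputs and their mean."""

    o_ann: float
    o_svm: float
    o_regression: float
    gfr_ensemble: float


def evaluate_equation(spec: EquationSpec, patient: PatientInput) -> float:
    """Evaluate a piecewise eGFR equation at full precision (mL/min/1.73 m²)."""
    return spec.branch_for(patient.sex, patient.scr).value(patient.scr, patient.age)


def invert_equation(spec: EquationSpec, gfr: float, age: float, sex: str) -> float:
    """Serum creatinine at which the equation returns ``gfr`` for age/sex.

    Each branch is strictly decreasing in Scr, so the inversion picks the
    branch whose solution lies in that branch's own creatinine range (the
    'le' branch wins where both qualify, mirroring inclusive-≤
    evaluation). Equations whose branches do not meet at the knot leave a
    gap of unattained values; asking for a value inside the gap raises.
    """
    if gfr <= 0:
        raise ValueError(f"GFR must be positive, got {gfr}")
    sex = _normalize_sex(sex)
    le = next(b for b in spec.branches if b.sex == sex and b.side == "le")
    gt = next(b for b in spec.branches if b.sex == sex and b.side == "gt")
    if gfr >= le.value(le.threshold, age):
        branch = le  # solution is <= threshold by monotonicity
    else:
        branch = gt
        base = gt.coefficient * gt.age_base**age
        candidate = gt.denominator * (gfr / base) ** (1.0 / gt.exponent)
        if candidate <= gt.threshold:
            raise ValueError(
                f"GFR {gfr:g} is not attained by {spec.name!r} for sex {sex} "
                f"at age {age:g}: it falls in the knot discontinuity gap"
            )
    base = branch.coefficient * branch.age_base**age
    return branch.denominator * (gfr / base) ** (1.0 / branch.exponent)


def ensemble_gfr(o_ann: float, o_svm: float, o_regression: float) -> EnsembleOutputs:
    """Ensemble eGFR: the mean of the ANN, SVM and regression outputs.

    All three components are mandatory; a missing one is an error (never a
    silent two-model mean).
    """
    comps = {"o_ann": o_ann, "o_svm": o_svm, "o_regression": o_regression}
    for name, v in comps.items():
        if v is None or not math.isfinite(v):
            raise ValueError(f"ensemble component {name} is missing or non-finite")
    mean = (o_ann + o_svm + o_regression) / 3.0
    return EnsembleOutputs(
        o_ann=o_ann, o_svm=o_svm, o_regression=o_regression, gfr_ensemble=mean
    )


def _build_ckd_epi_asian(male_denominator: float = 0.9) -> EquationSpec:
    if male_denominator not in (0.9, 0.7):
        raise ValueError("male_denominator must be 0.9 (published) or 0.7 (as printed)")
    suffix = "" if male_denominator == 0.9 else "_printed_male_denominator"
    return EquationSpec(
        name=f"ckd_epi_asian{suffix}",
        branches=(
            EquationBranch("F", 0.7, "le", 151.0, 0.7, -0.328, 0.993),
            EquationBranch("F", 0.7, "gt", 151.0, 0.7, -1.210, 0.993),
            EquationBranch("M", 0.9, "le", 149.0, male_denominator, -0.415, 0.993),
            EquationBranch("M", 0.9, "gt", 149.0, male_denominator, -1.210, 0.993),
        ),
    )


#: Piecewise regression component of the Liu ensemble, as published.
LIU_REGRESSION = EquationSpec(
    name="liu_regression",
    branches=(
        EquationBranch("F", 1.2, "le", 92.0, 1.2, -0.534, 0.994),
        EquationBranch("F", 1.2, "gt", 79.0, 1.2, -0.516, 0.994),
        EquationBranch("M", 1.0, "le", 98.0, 1.0, -0.450, 0.996),
        EquationBranch("M", 1.0, "gt", 105.0, 1.0, -0.640, 0.993),
    ),
)

_REGISTRY: dict[str, object] = {
    "ckd_epi_asian": _build_ckd_epi_asian,
    "liu_regression": LIU_REGRESSION,
}


def register_equation(spec: EquationSpec, name: str | None = None) -> None:
    """Add an equation to the registry under ``name`` (default its own)."""
    _REGISTRY[name or spec.name] = spec


def available_equations() -> list[str]:
    return sorted(_REGISTRY)


def get_equation(name: str, **options) -> EquationSpec:
    """Fetch a registered equation; ``ckd_epi_asian`` accepts
    ``male_denominator`` (0.9 or 0.7)."""
    try:
        entry = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown equation {name!r}; available: {available_equations()}"
        ) from None
    if callable(entry):
        return entry(**options)
    if options:
        raise TypeError(f"equation {name!r} accepts no options")
    return entry
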