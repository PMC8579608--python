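"""Method-comparison statistics for paired (eGFR, mGFR) data.

The validation triad is bias (median of eGFR − mGFR), precision (IQR of
that difference) and P30 (percent of patients whose eGFR lies within ±30%
of mGFR, boundary inclusive), each with percentile-bootstrap 95% CIs from
patient-level resampling. Agreement is summarized by Bland–Altman limits
(mean difference ± 1.96 sample SD), association by Spearman correlation
and the OLS regression of eGFR on mGFR. Two estimators on one cohort are
compared with a Wilcoxon signed-rank test on per-patient error
differences (bias), a paired percentile bootstrap (precision) and a
McNemar test on the within-30% indicators (P30). All p-values are
two-sided; no multiplicity adjustment is applied.

Quantiles use linear interpolation throughout (recorded in report
metadata); sign conventions: bias is eGFR − mGFR, Bland–Altman defaults
to mGFR − eGFR (the orientation agreement plots conventionally use), and
every width/CI statistic is invariant to that choice.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "GFRPair",
    "BlandAltman",
    "ModelPerformance",
    "ComparisonReport",
    "bias",
    "precision",
    "p30",
    "within_30pct",
    "bland_altman",
    "correlation_and_regression",
    "bootstrap_ci",
    "compare_bias_wilcoxon",
    "compare_precision_bootstrap",
    "compare_p30_mcnemar",
    "compare_models",
]

# Relative slack making the ±30% boundary numerically inclusive.
_P30_REL_EPS = 1e-12


@dataclass(frozen=True)
class GFRPair:
    """One patient's (estimated, measured) GFR, both mL/min/1.73 m²."""

    patient_id: str
    egfr: float
    mgfr: float

    def __post_init__(self) -> None:
        for label, v in (("egfr", self.egfr), ("mgfr", self.mgfr)):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{label} must be finite and >= 0, got {v}")

    @property
    def diff(self) -> float:
        """eGFR − mGFR; always recomputed, never stored."""
        return self.egfr - self.mgfr


def _arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    e = np.array([p.egfr for p in pairs], dtype=float)
    m = np.array([p.mgfr for p in pairs], dtype=float)
    return e, m


def _diffs(pairs) -> np.ndarray:
    e, m = _arrays(pairs)
    return e - m


def _iqr(values: np.ndarray, axis=None) -> np.ndarray:
    hi, lo = np.percentile(values, [75.0, 25.0], axis=axis)
    return hi - lo


def bias(pairs) -> float:
    """Median of eGFR − mGFR; positive means overestimation."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("bias requires at least one pair")
    return float(np.median(_diffs(pairs)))


def precision(pairs) -> float:
    """Interquartile range of eGFR − mGFR (linear-interpolation quantiles)."""
    pairs = list(pairs)
    if len(pairs) < 4:
        raise ValueError(f"precision requires n >= 4, got {len(pairs)}")
    return float(_iqr(_diffs(pairs)))


def within_30pct(pairs) -> np.ndarray:
    """Boolean indicator |eGFR − mGFR| ≤ 0.30 · mGFR per pair (inclusive)."""
    e, m = _arrays(pairs)
    if (m <= 0).any():
        raise ValueError("P30 requires mgfr > 0 for every pair")
    return np.abs(e - m) <= (0.30 + _P30_REL_EPS) * m


def p30(pairs) -> float:
    """Percentage of pairs with eGFR within ±30% of mGFR."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("p30 requires at least one pair")
    return float(100.0 * within_30pct(pairs).mean())


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    width: float
    sd: float


def bland_altman(pairs, sign: str = "mgfr_minus_egfr") -> BlandAltman:
    """Bland–Altman limits of agreement: mean difference ± 1.96 sample SD.

    ``sign`` selects the difference orientation; the limits' width
    (3.92·SD) is invariant to it.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"Bland-Altman requires n >= 3, got {len(pairs)}")
    d = _diffs(pairs)
    if sign == "mgfr_minus_egfr":
        d = -d
    elif sign != "egfr_minus_mgfr":
        raise ValueError(f"unknown sign convention {sign!r}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        width=2 * 1.96 * sd,
        sd=sd,
    )


def correlation_and_regression(pairs) -> tuple[float, float, float]:
    """(Spearman r, OLS slope, OLS intercept) of eGFR regressed on mGFR."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"correlation/regression requires n >= 3, got {len(pairs)}")
    e, m = _arrays(pairs)
    rho = float(sps.spearmanr(e, m).statistic)
    fit = sps.linregress(m, e)
    return rho, float(fit.slope), float(fit.intercept)


_ROW_STATS: dict[str, tuple[Callable, Callable]] = {
    # name -> (per-patient value vector, row-wise statistic over axis=1)
    "bias": (lambda pairs: _diffs(pairs), lambda v: np.median(v, axis=1)),
    "precision": (lambda pairs: _diffs(pairs), lambda v: _iqr(v, axis=1)),
    "p30": (
        lambda pairs: 100.0 * within_30pct(pairs).astype(float),
        lambda v: v.mean(axis=1),
    ),
}


def bootstrap_ci(
    statistic,
    pairs,
    B: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap CI, resampling patients (pairs) with
    replacement.

    ``statistic`` is one of ``'bias'``/``'precision'``/``'p30'`` (fast
    vectorized path) or any callable mapping a pair list to a float.
    """
    pairs = list(pairs)
    if B < 200:
        raise ValueError(f"bootstrap needs B >= 200, got {B}")
    if not pairs:
        raise ValueError("bootstrap_ci requires at least one pair")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(pairs)
    idx = rng.integers(0, n, size=(B, n))
    if isinstance(statistic, str):
        values_of, row_stat = _ROW_STATS[statistic]
        values = values_of(pairs)
        boot = np.asarray(row_stat(values[idx]), dtype=float)
    else:
        boot = np.array(
            [statistic([pairs[j] for j in row]) for row in idx], dtype=float
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(lo), float(hi)


def _matched_diffs(pairs_a, pairs_b) -> tuple[np.ndarray, np.ndarray]:
    a_by_id = {p.patient_id: p for p in pairs_a}
    b_by_id = {p.patient_id: p for p in pairs_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("between-model tests need the same patients in both sets")
    ids = [p.patient_id for p in pairs_a]
    d_a = np.array([a_by_id[i].diff for i in ids])
    d_b = np.array([b_by_id[i].diff for i in ids])
    return d_a, d_b


def compare_bias_wilcoxon(pairs_a, pairs_b) -> float:
    """Two-sided Wilcoxon signed-rank test on per-patient error differences.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for ≤25 untied non-zero differences, the
    tie-corrected normal approximation otherwise. Identical error vectors
    degenerate to p = 1 with a warning.
    """
    d_a, d_b = _matched_diffs(pairs_a, pairs_b)
    if len(d_a) < 6:
        raise ValueError(f"Wilcoxon comparison needs n >= 6, got {len(d_a)}")
    d = d_a - d_b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn(
            "all per-patient error differences are zero; Wilcoxon test is "
            "degenerate (p = 1)",
            stacklevel=2,
        )
        return 1.0
    untied = np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if (nonzero.size <= 25 and untied) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method="wilcox", method=method)
    return float(res.pvalue)


def compare_precision_bootstrap(
    pairs_a,
    pairs_b,
    B: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "label_swap",
) -> float:
    """Paired patient-level resampling test of IQR_A − IQR_B.

    ``method='label_swap'`` (default) draws the null distribution of the
    IQR difference by randomly exchanging the two models' errors within
    each patient — valid whenever the models are exchangeable under the
    null — and reports p = (1 + #{|Δ*| ≥ |Δ̂|}) / (B + 1). It holds the
    nominal level closely. ``method='percentile'`` instead resamples
    patients jointly and doubles the smaller tail of Δ* = IQR_A* − IQR_B*
    around zero (clipped to [1/B, 1]); it mirrors the percentile CI
    machinery but runs conservative for IQR statistics at cohort-scale n.
    """
    d_a, d_b = _matched_diffs(pairs_a, pairs_b)
    if len(d_a) < 4:
        raise ValueError(f"precision comparison needs n >= 4, got {len(d_a)}")
    if B < 200:
        raise ValueError(f"resampling test needs B >= 200, got {B}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(d_a)
    if method == "label_swap":
        delta_hat = _iqr(d_a) - _iqr(d_b)
        swap = rng.random(size=(B, n)) < 0.5
        null_a = np.where(swap, d_b, d_a)
        null_b = np.where(swap, d_a, d_b)
        delta = _iqr(null_a, axis=1) - _iqr(null_b, axis=1)
        return float((1 + np.sum(np.abs(delta) >= abs(delta_hat))) / (B + 1))
    if method == "percentile":
        idx = rng.integers(0, n, size=(B, n))
        delta = _iqr(d_a[idx], axis=1) - _iqr(d_b[idx], axis=1)
        p = 2.0 * min(float(np.mean(delta <= 0)), float(np.mean(delta >= 0)))
        return float(np.clip(p, 1.0 / B, 1.0))
    raise ValueError(f"unknown method {method!r}")


def compare_p30_mcnemar(pairs_a, pairs_b) -> float:
    """McNemar test on the paired within-30% indicators.

    Exact binomial on the discordant margin when it is < 25, chi-square
    with continuity correction otherwise; a table with no discordant
    pairs degenerates to p = 1 with a warning.
    """
    a_by_id = {p.patient_id: p for p in pairs_a}
    b_by_id = {p.patient_id: p for p in pairs_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("between-model tests need the same patients in both sets")
    ids = list(a_by_id)
    in_a = within_30pct([a_by_id[i] for i in ids])
    in_b = within_30pct([b_by_id[i] for i in ids])
    b_count = int(np.sum(in_a & ~in_b))
    c_count = int(np.sum(~in_a & in_b))
    if b_count + c_count == 0:
        warnings.warn(
            "no discordant within-30% pairs; McNemar test is degenerate (p = 1)",
            stacklevel=2,
        )
        return 1.0
    table = [
        [int(np.sum(in_a & in_b)), b_count],
        [c_count, int(np.sum(~in_a & ~in_b))],
    ]
    exact = (b_count + c_count) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class ModelPerformance:
    """One estimator's full performance panel; unattainable cells are None."""

    name: str
    n: int
    bias: float | None = None
    bias_ci: tuple[float, float] | None = None
    precision: float | None = None
    precision_ci: tuple[float, float] | None = None
    p30: float | None = None
    p30_ci: tuple[float, float] | None = None
    ba_mean_diff: float | None = None
    ba_loa_low: float | None = None
    ba_loa_high: float | None = None
    ba_loa_width: float | None = None
    spearman_r: float | None = None
    ols_slope: float | None = None
    ols_intercept: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("bias_ci", "precision_ci", "p30_ci"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPerformance":
        d = dict(d)
        for key in ("bias_ci", "precision_ci", "p30_ci"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ComparisonReport:
    """Two estimators' panels plus the three between-model p-values."""

    model_a: ModelPerformance
    model_b: ModelPerformance
    p_bias_wilcoxon: float | None = None
    p_precision_bootstrap: float | None = None
    p_p30_mcnemar: float | None = None
    metadata: dict = field(default_factory=dict)
    null_reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a.to_dict(),
            "model_b": self.model_b.to_dict(),
            "p_bias_wilcoxon": self.p_bias_wilcoxon,
            "p_precision_bootstrap": self.p_precision_bootstrap,
            "p_p30_mcnemar": self.p_p30_mcnemar,
            "metadata": dict(self.metadata),
            "null_reasons": dict(self.null_reasons),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            model_a=ModelPerformance.from_dict(d["model_a"]),
            model_b=ModelPerformance.from_dict(d["model_b"]),
            p_bias_wilcoxon=d.get("p_bias_wilcoxon"),
            p_precision_bootstrap=d.get("p_precision_bootstrap"),
            p_p30_mcnemar=d.get("p_p30_mcnemar"),
            metadata=d.get("metadata", {}),
            null_reasons=d.get("null_reasons", {}),
        )

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def to_text(self) -> str:
        """Formatted table: bias / precision / P30 per model, p-values below."""

        def cell(value, ci, pct=False):
            if value is None:
                return "n/a"
            unit = "%" if pct else ""
            out = f"{value:.1f}{unit}"
            if ci is not None:
                out += f" [{ci[0]:.1f}{unit} to {ci[1]:.1f}{unit}]"
            return out

        def pv(p):
            if p is None:
                return "n/a"
            return "<0.001" if p < 0.001 else f"{p:.3f}"

        a, b = self.model_a, self.model_b
        width = max(len(a.name), len(b.name)) + 2
        lines = [
            f"Method comparison (n = {a.n}, units mL/min/1.73 m^2)",
            "-" * 72,
        ]
        for label, attr, ci_attr, pct, p in (
            ("Bias (median difference)", "bias", "bias_ci", False, None),
            ("Precision (IQR of difference)", "precision", "precision_ci", False, None),
            ("Accuracy P30", "p30", "p30_ci", True, None),
        ):
            lines.append(label)
            for m in (a, b):
                lines.append(
                    f"  {m.name:<{width}}"
                    + cell(getattr(m, attr), getattr(m, ci_attr), pct)
                )
        lines.append("Limits of agreement (width)")
        for m in (a, b):
            if m.ba_loa_low is None:
                lines.append(f"  {m.name:<{width}}n/a")
            else:
                lines.append(
                    f"  {m.name:<{width}}{m.ba_loa_low:.1f} to {m.ba_loa_high:.1f} "
                    f"({m.ba_loa_width:.1f})"
                )
        lines.append("Regression of eGFR on mGFR (Spearman r)")
        for m in (a, b):
            if m.ols_slope is None:
                lines.append(f"  {m.name:<{width}}n/a")
            else:
                lines.append(
                    f"  {m.name:<{width}}eGFR = {m.ols_slope:.2f}*mGFR "
                    f"+ {m.ols_intercept:.2f} (r = {m.spearman_r:.2f})"
                )
        lines += [
            "-" * 72,
            f"bias:      Wilcoxon signed-rank p = {pv(self.p_bias_wilcoxon)}",
            f"precision: paired resampling   p = {pv(self.p_precision_bootstrap)}",
            f"P30:       McNemar             p = {pv(self.p_p30_mcnemar)}",
        ]
        return "\n".join(lines)


def _performance(
    name: str, pairs, B: int, rng: np.random.Generator, ba_sign: str, reasons: dict
) -> ModelPerformance:
    pairs = list(pairs)
    n = len(pairs)
    fields: dict = {"name": name, "n": n}

    def attempt(keys, fn):
        try:
            fn()
        except ValueError as exc:
            for k in keys:
                reasons[f"{name}.{k}"] = str(exc)

    def _triad():
        for stat in ("bias", "precision", "p30"):

            def one(stat=stat):
                value = {"bias": bias, "precision": precision, "p30": p30}[stat](pairs)
                fields[stat] = value
                fields[f"{stat}_ci"] = bootstrap_ci(stat, pairs, B=B, rng=rng)

            attempt([stat, f"{stat}_ci"], one)

    _triad()

    def _ba():
        ba = bland_altman(pairs, sign=ba_sign)
        fields.update(
            ba_mean_diff=ba.mean_diff,
            ba_loa_low=ba.loa_low,
            ba_loa_high=ba.loa_high,
            ba_loa_width=ba.width,
        )

    attempt(["bland_altman"], _ba)

    def _corr():
        rho, slope, intercept = correlation_and_regression(pairs)
        fields.update(spearman_r=rho, ols_slope=slope, ols_intercept=intercept)

    attempt(["correlation_regression"], _corr)
    return ModelPerformance(**fields)


def compare_models(
    pairs_a,
    pairs_b,
    *,
    name_a: str = "model_a",
    name_b: str = "model_b",
    bootstrap_reps: int = 2000,
    seed: int = 0,
    ba_sign: str = "mgfr_minus_egfr",
    precision_method: str = "label_swap",
    metadata: dict | None = None,
) -> ComparisonReport:
    """Assemble the full comparison report for two matched pair sets.

    Any statistic whose precondition fails is reported as a null cell with
    its reason under ``null_reasons``; nothing raises mid-report.
    """
    reasons: dict = {}
    rng = np.random.default_rng(seed)
    perf_a = _performance(name_a, pairs_a, bootstrap_reps, rng, ba_sign, reasons)
    perf_b = _performance(name_b, pairs_b, bootstrap_reps, rng, ba_sign, reasons)

    def between(key, fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn()
        except ValueError as exc:
            reasons[key] = str(exc)
            return None

    p_wilcoxon = between(
        "p_bias_wilcoxon", lambda: compare_bias_wilcoxon(pairs_a, pairs_b)
    )
    p_precision = between(
        "p_precision_bootstrap",
        lambda: compare_precision_bootstrap(
            pairs_a, pairs_b, B=bootstrap_reps, rng=rng, method=precision_method
        ),
    )
    p_mcnemar = between(
        "p_p30_mcnemar", lambda: compare_p30_mcnemar(pairs_a, pairs_b)
    )

    meta = {
        "n": len(list(pairs_a)),
        "bootstrap_B": bootstrap_reps,
        "seed": seed,
        "quantile_rule": "linear_interpolation",
        "bias_sign": "egfr_minus_mgfr",
        "bland_altman_sign": ba_sign,
        "precision_test": precision_method,
    }
    meta.update(metadata or {})
    return ComparisonReport(
        model_a=perf_a,
        model_b=perf_b,
        p_bias_wilcoxon=p_wilcoxon,
        p_precision_bootstrap=p_precision,
        p_p30_mcnemar=p_mcnemar,
        metadata=meta,
        null_reasons=reasons,
    )
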