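"""Model/Results front end for the GFR method-comparison pipeline.

:class:`GFRMethodComparison` is constructed from a cohort (records, a
DataFrame, a CSV, or a simulation config) together with the two estimators
to compare; :meth:`~GFRMethodComparison.fit` runs the full study pipeline —
exclusion screens, measured-GFR computation, both estimators, the outlier
screen, and the complete comparison battery — and returns a
:class:`GFRMethodComparisonResults` carrying the per-patient table, the
attrition accounting and the comparison report, with ``summary()``,
plotting and artifact export hanging off it.

>>> model = GFRMethodComparison.from_simulation(CohortSimConfig(seed=7))
>>> res = model.fit(bootstrap_reps=500, seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clearance import Anthropometry, measure_gfr
from .cohort import (
    AttritionReport,
    CohortRecord,
    apply_exclusions,
    outlier_screen,
    read_cohort_csv,
    write_cohort_csv,
)
from .components import EnsembleModel, EquationComponent, train_standin_components
from .equations import LIU_REGRESSION, EquationSpec, PatientInput, get_equation
from .simulate import CohortSimConfig, generate_cohort
from .stats import ComparisonReport, GFRPair, compare_models

__all__ = ["GFRMethodComparison", "GFRMethodComparisonResults"]


class GFRMethodComparison:
    """Compare two eGFR estimators against measured GFR on one cohort.

    Parameters
    ----------
    cohort
        List of :class:`~gfrval.cohort.CohortRecord`.
    model_a, model_b
        ``'liu_ensemble'`` (stand-in ANN + stand-in SVM + published
        regression), ``'ckd_epi_asian'``, ``'liu_regression'``, an
        :class:`~gfrval.equations.EquationSpec`, or any object with a
        ``predict(PatientInput) -> float`` method.
    male_denominator
        Creatinine denominator of the male CKD-EPI branches: 0.9
        (published) or 0.7 (as sometimes printed).
    decay_direction
        ``'as_printed'`` or ``'back_correct'`` decay correction.
    outlier_threshold, outlier_on
        |studentized residual| cutoff of the outlier screen and which
        model's pairs it runs on (``'a'``, ``'b'`` or ``'both'`` = union).
    standin_seed, standin_train_n
        Seed and training-cohort size for the synthetic-trained stand-in
        ensemble components.
    """

    def __init__(
        self,
        cohort: list[CohortRecord],
        model_a: str | EquationSpec | object = "liu_ensemble",
        model_b: str | EquationSpec | object = "ckd_epi_asian",
        *,
        male_denominator: float = 0.9,
        decay_direction: str = "as_printed",
        outlier_threshold: float = 3.0,
        outlier_on: str = "both",
        age_floor: float = 18.0,
        standin_seed: int = 0,
        standin_train_n: int = 2000,
    ):
        if outlier_on not in ("a", "b", "both"):
            raise ValueError("outlier_on must be 'a', 'b' or 'both'")
        self.cohort = list(cohort)
        self.model_a_spec = model_a
        self.model_b_spec = model_b
        self.male_denominator = male_denominator
        self.decay_direction = decay_direction
        self.outlier_threshold = outlier_threshold
        self.outlier_on = outlier_on
        self.age_floor = age_floor
        self.standin_seed = standin_seed
        self.standin_train_n = standin_train_n
        self._resolved: dict[str, object] = {}

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def from_csv(cls, path, **kwargs) -> "GFRMethodComparison":
        return cls(read_cohort_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GFRMethodComparison":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_cohort_csv(buf), **kwargs)

    @classmethod
    def from_simulation(
        cls, config: CohortSimConfig | None = None, **kwargs
    ) -> "GFRMethodComparison":
        config = config or CohortSimConfig()
        model = cls(generate_cohort(config), **kwargs)
        model.sim_config = config
        return model

    # ------------------------------------------------------------------
    def _resolve(self, spec, which: str):
        if which in self._resolved:
            return self._resolved[which]
        if isinstance(spec, str):
            if spec == "liu_ensemble":
                ann, svm = train_standin_components(
                    self.standin_seed, self.standin_train_n
                )
                resolved = EnsembleModel(ann, svm, EquationComponent(LIU_REGRESSION))
            elif spec == "ckd_epi_asian":
                resolved = EquationComponent(
                    get_equation(spec, male_denominator=self.male_denominator)
                )
            else:
                resolved = EquationComponent(get_equation(spec))
        elif isinstance(spec, EquationSpec):
            resolved = EquationComponent(spec)
        elif hasattr(spec, "predict"):
            resolved = spec
        else:
            raise TypeError(f"cannot interpret model specification {spec!r}")
        self._resolved[which] = resolved
        return resolved

    @staticmethod
    def _model_name(resolved) -> str:
        if isinstance(resolved, EnsembleModel):
            return "liu_ensemble"
        return getattr(resolved, "name", type(resolved).__name__)

    def _measured_gfr(self, record: CohortRecord) -> tuple[float | None, list[str]]:
        if record.plasma is not None and record.height_cm and record.weight_kg:
            result = measure_gfr(
                record.plasma,
                Anthropometry(record.height_cm, record.weight_kg),
                self.decay_direction,
            )
            return result.mgfr, list(result.flags)
        if record.mgfr_precomputed is not None:
            return record.mgfr_precomputed, []
        return None, ["no_mgfr_source"]

    def fit(
        self, bootstrap_reps: int = 2000, seed: int = 0
    ) -> "GFRMethodComparisonResults":
        """Run the full pipeline and assemble the results object."""
        model_a = self._resolve(self.model_a_spec, "a")
        model_b = self._resolve(self.model_b_spec, "b")

        analysis, _ = apply_exclusions(self.cohort, age_floor=self.age_floor)

        mgfr: dict[str, float] = {}
        meas_flags: dict[str, list[str]] = {}
        egfr_a: dict[str, float] = {}
        egfr_b: dict[str, float] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in analysis:
                value, flags = self._measured_gfr(r)
                meas_flags[r.patient_id] = flags
                if value is None:
                    continue
                mgfr[r.patient_id] = value
                patient = PatientInput(r.scr, r.age, r.sex)
                egfr_a[r.patient_id] = float(model_a.predict(patient))
                egfr_b[r.patient_id] = float(model_b.predict(patient))

        def pairs_of(egfr: dict) -> list[GFRPair]:
            return [
                GFRPair(pid, egfr[pid], max(mgfr[pid], 0.0))
                for pid in egfr
            ]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            outlier_ids: set = set()
            if self.outlier_on in ("a", "both"):
                outlier_ids |= outlier_screen(
                    pairs_of(egfr_a), threshold=self.outlier_threshold
                )
            if self.outlier_on in ("b", "both"):
                outlier_ids |= outlier_screen(
                    pairs_of(egfr_b), threshold=self.outlier_threshold
                )

        analysis, attrition = apply_exclusions(
            self.cohort, age_floor=self.age_floor, outlier_ids=outlier_ids
        )
        kept = {r.patient_id for r in analysis}
        pairs_a = [p for p in pairs_of(egfr_a) if p.patient_id in kept]
        pairs_b = [p for p in pairs_of(egfr_b) if p.patient_id in kept]

        name_a = self._model_name(model_a)
        name_b = self._model_name(model_b)
        report = compare_models(
            pairs_a,
            pairs_b,
            name_a=name_a,
            name_b=name_b,
            bootstrap_reps=bootstrap_reps,
            seed=seed,
            metadata={
                "male_denominator": self.male_denominator,
                "decay_direction": self.decay_direction,
                "outlier_rule": (
                    f"|studentized residual| > {self.outlier_threshold:g} "
                    f"on eGFR~mGFR OLS ({self.outlier_on})"
                ),
                "standin_seed": self.standin_seed,
                "gfrval_version": __version__,
            },
        )

        rows = []
        for r in self.cohort:
            pid = r.patient_id
            rows.append(
                {
                    "patient_id": pid,
                    "sex": r.sex,
                    "age_years": r.age,
                    "scr_mg_dl": r.scr,
                    "mgfr": mgfr.get(pid),
                    f"egfr_{name_a}": egfr_a.get(pid),
                    f"egfr_{name_b}": egfr_b.get(pid),
                    "flags": ";".join(r.flag_names),
                    "measurement_flags": ";".join(meas_flags.get(pid, [])),
                    "in_analysis_set": pid in kept,
                }
            )
        per_patient = pd.DataFrame(rows)

        return GFRMethodComparisonResults(
            model=self,
            report=report,
            attrition=attrition,
            per_patient=per_patient,
            pairs_a=pairs_a,
            pairs_b=pairs_b,
            seed=seed,
            bootstrap_reps=bootstrap_reps,
        )


class GFRMethodComparisonResults:
    """Fitted results: comparison report, attrition and per-patient table."""

    def __init__(
        self,
        model: GFRMethodComparison,
        report: ComparisonReport,
        attrition: AttritionReport,
        per_patient: pd.DataFrame,
        pairs_a: list[GFRPair],
        pairs_b: list[GFRPair],
        seed: int,
        bootstrap_reps: int,
    ):
        self.model = model
        self.report = report
        self.attrition = attrition
        self.per_patient = per_patient
        self.pairs_a = pairs_a
        self.pairs_b = pairs_b
        self.seed = seed
        self.bootstrap_reps = bootstrap_reps

    def summary(self) -> str:
        lines = [
            "GFR method-comparison results",
            "=" * 72,
            self.attrition.to_text(),
            "",
            self.report.to_text(),
            "",
            f"bootstrap reps: {self.bootstrap_reps}   seed: {self.seed}   "
            f"quantile rule: {self.report.metadata.get('quantile_rule')}",
            f"male CKD-EPI denominator: {self.model.male_denominator}   "
            f"decay: {self.model.decay_direction}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def _pairs(self, which: str) -> tuple[list[GFRPair], str]:
        if which == "a":
            return self.pairs_a, self.report.model_a.name
        if which == "b":
            return self.pairs_b, self.report.model_b.name
        raise ValueError("model must be 'a' or 'b'")

    def bland_altman_frame(self, which: str = "a") -> pd.DataFrame:
        pairs, name = self._pairs(which)
        sign = self.report.metadata.get("bland_altman_sign", "mgfr_minus_egfr")
        flip = -1.0 if sign == "mgfr_minus_egfr" else 1.0
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in pairs],
                "mgfr": [p.mgfr for p in pairs],
                "egfr": [p.egfr for p in pairs],
                "difference": [flip * p.diff for p in pairs],
            }
        )

    def plot_scatter(self, which: str = "a", ax=None):
        """eGFR vs mGFR scatter with identity, regression and 60-unit
        reference lines."""
        import matplotlib.pyplot as plt

        pairs, name = self._pairs(which)
        perf = self.report.model_a if which == "a" else self.report.model_b
        if ax is None:
            _, ax = plt.subplots()
        m = np.array([p.mgfr for p in pairs])
        e = np.array([p.egfr for p in pairs])
        ax.scatter(m, e, s=12, alpha=0.7)
        lim = max(m.max(), e.max()) * 1.05
        grid = np.linspace(0, lim, 50)
        ax.plot(grid, grid, color="green", lw=1, label="identity")
        if perf.ols_slope is not None:
            ax.plot(
                grid,
                perf.ols_slope * grid + perf.ols_intercept,
                color="tab:blue",
                lw=1.5,
                label=f"eGFR = {perf.ols_slope:.2f}·mGFR + {perf.ols_intercept:.2f}",
            )
        for v in (60.0,):
            ax.axvline(v, ls="--", color="lightblue", lw=0.8)
            ax.axhline(v, ls="--", color="lightblue", lw=0.8)
        ax.set_xlabel("mGFR (mL/min/1.73 m$^2$)")
        ax.set_ylabel(f"{name} eGFR (mL/min/1.73 m$^2$)")
        ax.legend(fontsize=8)
        return ax

    def plot_bland_altman(self, which: str = "a", ax=None):
        """Difference vs mGFR with mean and 95% limits of agreement."""
        import matplotlib.pyplot as plt

        frame = self.bland_altman_frame(which)
        perf = self.report.model_a if which == "a" else self.report.model_b
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(frame["mgfr"], frame["difference"], s=12, alpha=0.7)
        if perf.ba_mean_diff is not None:
            ax.axhline(perf.ba_mean_diff, color="tab:blue", lw=1.2, label="mean")
            ax.axhline(perf.ba_loa_low, color="gray", ls="--", lw=1)
            ax.axhline(perf.ba_loa_high, color="gray", ls="--", lw=1, label="95% LoA")
        ax.set_xlabel("mGFR (mL/min/1.73 m$^2$)")
        sign = self.report.metadata.get("bland_altman_sign", "mgfr_minus_egfr")
        label = "mGFR − eGFR" if sign == "mgfr_minus_egfr" else "eGFR − mGFR"
        ax.set_ylabel(f"{label} (mL/min/1.73 m$^2$)")
        ax.legend(fontsize=8)
        return ax

    # ------------------------------------------------------------------
    def manifest(self) -> dict:
        cfg = {
            "model_a": str(self.model.model_a_spec),
            "model_b": str(self.model.model_b_spec),
            "male_denominator": self.model.male_denominator,
            "decay_direction": self.model.decay_direction,
            "outlier_threshold": self.model.outlier_threshold,
            "outlier_on": self.model.outlier_on,
            "age_floor": self.model.age_floor,
            "standin_seed": self.model.standin_seed,
            "standin_train_n": self.model.standin_train_n,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
        }
        sim = getattr(self.model, "sim_config", None)
        if sim is not None:
            cfg["sim_config"] = asdict(sim)
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "gfrval_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
        }

    def save_artifacts(self, out_dir) -> list[Path]:
        """Write the full artifact set; returns the paths written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _write(name, text):
            path = out / name
            with open(path, "w") as fh:
                fh.write(text if text.endswith("\n") else text + "\n")
            written.append(path)

        _write("attrition.json", self.attrition.to_json())
        _write("attrition.txt", self.attrition.to_text())
        _write("report.json", self.report.to_json())
        _write("report.txt", self.report.to_text())
        _write("manifest.json", json.dumps(self.manifest(), indent=2))
        self.per_patient.to_csv(out / "per_patient.csv", index=False)
        written.append(out / "per_patient.csv")
        for which in ("a", "b"):
            name = self._pairs(which)[1]
            path = out / f"bland_altman_{name}.csv"
            self.bland_altman_frame(which).to_csv(path, index=False)
            written.append(path)
        cohort_path = out / "cohort_flagged.csv"
        write_cohort_csv(self.model.cohort, cohort_path)
        written.append(cohort_path)
        return written
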