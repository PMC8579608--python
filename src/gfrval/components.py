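"""Pluggable component models for the ensemble eGFR.

The ensemble averages three component predictions — an artificial neural
network, a support vector machine, and a piecewise regression — all on
(Scr, age, sex). Only the regression component's coefficients are public;
the original ANN and SVM weights are not redistributable here, so this
module provides:

* :class:`EquationComponent` — wraps any :class:`~gfrval.equations.EquationSpec`
  (the regression component uses the published table);
* :class:`FittedComponent` — wraps a scikit-learn regressor on features
  (log Scr, age, male indicator), predicting on the log-GFR scale so
  outputs are always positive;
* :func:`train_standin_components` — synthetic-trained stand-in ANN/SVM
  components (clearly labelled stand-ins), deterministic under a seed;
* :func:`save_component` / :func:`load_component` — serialization, so
  externally obtained coefficient files can be dropped in.

A component that has not been loaded or fitted raises
:class:`ComponentUnavailableError` on prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .equations import (
    EnsembleOutputs,
    EquationSpec,
    PatientInput,
    ensemble_gfr,
    evaluate_equation,
)

__all__ = [
    "ComponentUnavailableError",
    "EquationComponent",
    "FittedComponent",
    "EnsembleModel",
    "train_standin_components",
    "save_component",
    "load_component",
]


class ComponentUnavailableError(RuntimeError):
    """Raised when a component model is asked to predict before being loaded."""


def _features(patients: list[PatientInput]) -> np.ndarray:
    return np.array(
        [[math.log(p.scr), p.age, 1.0 if p.sex == "M" else 0.0] for p in patients]
    )


@dataclass(frozen=True)
class EquationComponent:
    """A component backed by a declarative piecewise equation."""

    spec: EquationSpec

    @property
    def name(self) -> str:
        return self.spec.name

    def predict(self, patient: PatientInput) -> float:
        return evaluate_equation(self.spec, patient)

    def predict_many(self, patients: list[PatientInput]) -> np.ndarray:
        return np.array([self.predict(p) for p in patients])


class FittedComponent:
    """A component backed by a fitted scikit-learn regressor.

    The estimator maps (log Scr, age, male) to log GFR; predictions are
    exponentiated, so they are finite and positive by construction.
    """

    def __init__(self, name: str, estimator=None):
        self.name = name
        self.estimator = estimator
        self._fitted = estimator is not None and hasattr(estimator, "predict")

    def fit(self, patients: list[PatientInput], gfr: np.ndarray) -> "FittedComponent":
        gfr = np.asarray(gfr, dtype=float)
        if (gfr <= 0).any():
            raise ValueError("training GFR values must be positive")
        self.estimator.fit(_features(patients), np.log(gfr))
        self._fitted = True
        return self

    def predict(self, patient: PatientInput) -> float:
        return float(self.predict_many([patient])[0])

    def predict_many(self, patients: list[PatientInput]) -> np.ndarray:
        if not self._fitted or self.estimator is None:
            raise ComponentUnavailableError(
                f"component {self.name!r} unavailable: not fitted or loaded"
            )
        return np.exp(self.estimator.predict(_features(patients)))


@dataclass(frozen=True)
class EnsembleModel:
    """The three-component ensemble; predicts the component mean."""

    ann: object
    svm: object
    regression: object

    def predict_outputs(self, patient: PatientInput) -> EnsembleOutputs:
        return ensemble_gfr(
            self.ann.predict(patient),
            self.svm.predict(patient),
            self.regression.predict(patient),
        )

    def predict(self, patient: PatientInput) -> float:
        return self.predict_outputs(patient).gfr_ensemble

    def predict_many(self, patients: list[PatientInput]) -> np.ndarray:
        return (
            self.ann.predict_many(patients)
            + self.svm.predict_many(patients)
            + self.regression.predict_many(patients)
        ) / 3.0


def train_standin_components(
    seed: int = 0, n_train: int = 2000
) -> tuple[FittedComponent, FittedComponent]:
    """Synthetic-trained stand-ins for the unavailable ANN/SVM components.

    Both are trained on one seeded synthetic cohort (true measured GFR as
    the target) and are fully deterministic given ``seed``. They are
    calibrated surrogates — faithful to the ensemble's *architecture*
    (two nonlinear learners plus a regression, averaged), not to the
    original fitted weights.
    """
    from .simulate import CohortSimConfig, generate_cohort  # deferred: avoid cycle

    cfg = CohortSimConfig(n_patients=n_train, seed=int(seed) % (2**31 - 1))
    records = generate_cohort(cfg)
    patients = [PatientInput(r.scr, r.age, r.sex) for r in records]
    gfr = np.array([r.true_mgfr for r in records])

    ann = FittedComponent(
        "standin_ann",
        MLPRegressor(
            hidden_layer_sizes=(16, 8),
            solver="lbfgs",
            max_iter=2000,
            random_state=int(seed) % (2**31 - 1),
        ),
    ).fit(patients, gfr)
    svm = FittedComponent(
        "standin_svm",
        Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=10.0, epsilon=0.05)),
            ]
        ),
    ).fit(patients, gfr)
    return ann, svm


def save_component(component, path) -> None:
    """Serialize a component (JSON for equations, joblib otherwise)."""
    path = Path(path)
    if isinstance(component, EquationComponent):
        component.spec.to_json(path)
    elif isinstance(component, FittedComponent):
        joblib.dump({"name": component.name, "estimator": component.estimator}, path)
    else:
        raise TypeError(f"cannot serialize component of type {type(component)!r}")


def load_component(path):
    """Load a component saved by :func:`save_component`.

    ``.json`` files are piecewise-equation specs; anything else is treated
    as a joblib payload with a fitted estimator.
    """
    path = Path(path)
    if path.suffix == ".json":
        return EquationComponent(EquationSpec.from_json(path))
    payload = joblib.load(path)
    return FittedComponent(payload["name"], payload["estimator"])
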