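"""Rule-based cholestasis metamodels combining transporter-level outputs.

Two classifiers, both scikit-learn style estimators:

* :class:`PkRuleMetamodel` — with toxicokinetics. A compound is called
  cholestatic when its therapeutic dose TD exceeds ``n`` times the IEOD50
  of any transporter (logical OR, i.e. TD > n * min_t IEOD50_t). The
  safety factor ``n`` is tuned on training data to balance sensitivity
  and specificity. The continuous score is the signed log-dose margin
  ``log10(TD) - log10(n * min_t IEOD50_t)``.
* :class:`NoPkRuleMetamodel` — without toxicokinetics. Positive when any
  transporter IC50 is at or below a fixed concentration threshold
  (default 300 μM); it has no fitted parameters.

An alternative reading of the dose rule compares TD against the highest
IEOD50 across transporters; it is available via ``mode="highest"``. The
OR/minimum form is the default, being the conservative one.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import matthews_corrcoef

from .qivive import DoseMatrix
from .qsar import ActivityMatrix

__all__ = [
    "PkRuleMetamodel",
    "NoPkRuleMetamodel",
    "dose_rule_features",
    "activity_to_ic50_um",
    "default_n_grid",
]


def default_n_grid() -> np.ndarray:
    """25 log-spaced candidates for the safety factor n in [0.1, 100]."""
    return np.logspace(-1, 2, 25)


def dose_rule_features(dose_matrix: DoseMatrix,
                       td: Sequence[float]) -> np.ndarray:
    """Stack [TD | IEOD50 matrix] into the X the PK metamodel consumes."""
    td = np.asarray(td, dtype=float)
    if len(td) != len(dose_matrix.compound_ids):
        raise ValueError("TD length does not match dose matrix")
    if np.any(~np.isfinite(td)) or np.any(td <= 0):
        bad = [cid for cid, t in zip(dose_matrix.compound_ids, td)
               if not np.isfinite(t) or t <= 0]
        raise ValueError(f"missing/invalid therapeutic dose for: {bad[:5]}")
    return np.column_stack([td, dose_matrix.ieod50])


def activity_to_ic50_um(activity: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Convert a pIC50 matrix to IC50 in μM (10**(6 - pIC50}))."""
    values = activity.values if isinstance(activity, ActivityMatrix) \
        else np.asarray(activity, dtype=float)
    return 10.0 ** (6.0 - values)


def _balanced_accuracy(y, yhat):
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=int)
    pos, neg = y == 1, y == 0
    s = yhat[pos].mean() if pos.any() else np.nan
    sp = 1.0 - yhat[neg].mean() if neg.any() else np.nan
    return np.nanmean([s, sp]), s, sp


class PkRuleMetamodel(BaseEstimator, ClassifierMixin):
    """Dose-comparison rule with a tunable safety factor.

    ``fit(X, y)`` expects ``X = [TD | IEOD50_1..T]`` (first column the
    therapeutic dose in mg/kg/day, remaining columns per-transporter
    IEOD50 in the same unit) and tunes ``n`` over ``n_grid`` to maximize
    the balance objective on the training labels; ties take the smallest
    ``n``. ``objective`` is "balanced_accuracy" (default, the arithmetic
    mean of sensitivity and specificity), "youden" or "mcc".
    """

    def __init__(self, n_grid=None, objective: str = "balanced_accuracy",
                 mode: str = "or"):
        self.n_grid = n_grid
        self.objective = objective
        self.mode = mode

    def _aggregate(self, ieod: np.ndarray) -> np.ndarray:
        if self.mode == "or":
            return np.nanmin(ieod, axis=1)
        if self.mode == "highest":
            return np.nanmax(ieod, axis=1)
        raise ValueError(f"unknown mode {self.mode!r}")

    def _split(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be [TD | IEOD50 columns]")
        return X[:, 0], X[:, 1:]

    def _objective(self, y, yhat) -> float:
        ba, s, sp = _balanced_accuracy(y, yhat)
        if self.objective == "balanced_accuracy":
            return float(ba)
        if self.objective == "youden":
            return float(np.nan_to_num(s) + np.nan_to_num(sp) - 1.0)
        if self.objective == "mcc":
            return float(matthews_corrcoef(y, yhat))
        raise ValueError(f"unknown objective {self.objective!r}")

    def fit(self, X, y):
        td, ieod = self._split(X)
        y = np.asarray(y, dtype=int)
        agg = self._aggregate(ieod)
        grid = np.asarray(self.n_grid if self.n_grid is not None
                          else default_n_grid(), dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("n_grid must be nonempty and positive")
        best_n, best_obj = None, -np.inf
        for n in np.sort(grid):
            obj = self._objective(y, (td > n * agg).astype(int))
            if obj > best_obj:  # strict: ties keep the smallest n
                best_n, best_obj = float(n), float(obj)
        self.n_factor_ = best_n
        self.train_objective_ = best_obj
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        """Signed log-dose margin; positive means predicted cholestatic."""
        if not hasattr(self, "n_factor_"):
            raise ValueError("model is not fitted")
        td, ieod = self._split(X)
        return np.log10(td) - np.log10(self.n_factor_ * self._aggregate(ieod))

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def to_json(self) -> str:
        return json.dumps({"kind": "pk_rule", "n_factor": self.n_factor_,
                           "objective": self.objective, "mode": self.mode})

    @classmethod
    def from_json(cls, text: str) -> "PkRuleMetamodel":
        d = json.loads(text)
        m = cls(objective=d["objective"], mode=d["mode"])
        m.n_factor_ = d["n_factor"]
        m.classes_ = np.array([0, 1])
        return m


class NoPkRuleMetamodel(BaseEstimator, ClassifierMixin):
    """Concentration-threshold rule: positive if any IC50 <= threshold μM.

    ``X`` is the compounds x transporters IC50 matrix in μM. The bound is
    inclusive. There are no fitted parameters; ``fit`` only validates
    input so the estimator drops into any CV harness. The score is
    ``log10(threshold / min_t IC50_t)``, positive on predicted positives.
    """

    def __init__(self, ic50_threshold_um: float = 300.0):
        self.ic50_threshold_um = ic50_threshold_um

    def fit(self, X=None, y=None):
        if self.ic50_threshold_um <= 0:
            raise ValueError("ic50_threshold_um must be > 0")
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        min_ic50 = np.nanmin(X, axis=1)
        return np.log10(self.ic50_threshold_um / min_ic50)

    def predict(self, X):
        # inclusive bound: IC50 exactly at the threshold is positive
        X = np.asarray(X, dtype=float)
        return (np.nanmin(X, axis=1) <= self.ic50_threshold_um).astype(int)

    def to_json(self) -> str:
        return json.dumps({"kind": "no_pk_rule",
                           "ic50_threshold_um": self.ic50_threshold_um})

    @classmethod
    def from_json(cls, text: str) -> "NoPkRuleMetamodel":
        d = json.loads(text)
        return cls(ic50_threshold_um=d["ic50_threshold_um"]).fit()
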