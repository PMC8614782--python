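"""The multi-model evaluation protocol.

Seven regression families — XGBoost, LightGBM, CatBoost, random forest,
AdaBoost, LASSO and a small multilayer perceptron — are each trained on
the descriptor table and the fingerprint table separately, under a fixed
random train/test split (66/8 for the canonical 74-compound setting,
random states 0, 10 and 100), and compared by test-set R², test-set RMSE
and the leave-one-out cross-validation score RMSE_LOO.

Notes on the metrics:

* R² uses the test-set mean as baseline and may be negative; negative
  values are preserved, since the consensus-importance stage filters on
  ``r2 >= 0``.
* Each LOOCV fold holds out a single sample, so the per-fold RMSE is the
  absolute error on that sample; RMSE_LOO — the mean of per-fold RMSEs —
  is therefore the mean absolute leave-one-out error.  LOOCV runs on the
  training partition only; the test samples are never touched.

Algorithms whose library is not installed (CatBoost in minimal
installations) raise a :class:`~soacml.errors.CapabilityError`; the grid
records the failure and continues with the remaining algorithms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .errors import CapabilityError
from .table import FeatureTable

ALGORITHMS = ("xgboost", "lightgbm", "catboost", "random_forest",
              "adaboost", "lasso", "dnn")
#: algorithms whose fitted models expose a feature-importance vector
IMPORTANCE_CAPABLE = ("xgboost", "lightgbm", "catboost", "random_forest",
                      "adaboost", "lasso")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "xgboost": {"n_estimators": 300, "learning_rate": 0.1, "max_depth": 3,
                "n_jobs": 1},
    "lightgbm": {"n_estimators": 300, "learning_rate": 0.1, "num_leaves": 15,
                 "min_child_samples": 5, "n_jobs": 1, "verbosity": -1},
    "catboost": {"iterations": 300, "learning_rate": 0.1, "depth": 4,
                 "verbose": False},
    "random_forest": {"n_estimators": 300, "n_jobs": 1},
    "adaboost": {"n_estimators": 100, "max_depth": 3},
    "lasso": {"alpha": 0.01, "max_iter": 50_000},
    "dnn": {"hidden_layer_sizes": (64, 32), "max_iter": 2000, "alpha": 1e-3},
}


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: ``n_test`` held out of ``n_total``."""

    n_total: int
    n_test: int
    random_state: int = 0

    def __post_init__(self):
        if not (0 < self.n_test < self.n_total):
            raise ValueError(
                f"need 0 < n_test < n_total, got n_test={self.n_test}, "
                f"n_total={self.n_total}")


def default_n_test(n_total: int) -> int:
    """8 test samples when n = 74; otherwise the same held-out fraction."""
    if n_total == 74:
        return 8
    return max(1, min(n_total - 1, round(n_total * 8 / 74)))


def split_dataset(table: FeatureTable, targets: pd.Series,
                  spec: SplitSpec) -> tuple[tuple[FeatureTable, pd.Series],
                                            tuple[FeatureTable, pd.Series]]:
    """Disjoint, exhaustive train/test partition, deterministic per state."""
    if table.n_samples != spec.n_total:
        raise ValueError(f"table has {table.n_samples} rows, spec expects {spec.n_total}")
    ids = table.sample_ids
    train_ids, test_ids = train_test_split(
        ids, test_size=spec.n_test, random_state=spec.random_state, shuffle=True)
    assert len(set(train_ids) & set(test_ids)) == 0
    assert len(train_ids) + len(test_ids) == spec.n_total
    return ((table.take_rows(train_ids), targets.loc[train_ids]),
            (table.take_rows(test_ids), targets.loc[test_ids]))


# ---------------------------------------------------------------------------
# algorithm adapters
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted regressor behind one predict/importance contract."""

    algorithm: str
    estimator: object
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(X[self.feature_names]))

    def importance(self) -> pd.Series:
        """Nonnegative importance per feature (LASSO: |coefficient| on the
        standardized scale; tree ensembles: library-native importance)."""
        if self.algorithm == "lasso":
            values = np.abs(self.estimator.named_steps["lasso"].coef_)
        elif self.algorithm == "dnn":
            raise CapabilityError("dnn-importance",
                                  "the MLP exposes no importance vector")
        else:
            values = np.asarray(self.estimator.feature_importances_, dtype=float)
        return pd.Series(values, index=self.feature_names, name="importance")


def make_estimator(algorithm: str, hyperparameters: Optional[dict] = None,
                   random_state: int = 0):
    """Instantiate the library regressor for ``algorithm``.

    Raises :class:`CapabilityError` when the backing library is not
    installed, and ``ValueError`` for unknown algorithm names.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")
    hp = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    hp.update(hyperparameters or {})

    if algorithm == "xgboost":
        try:
            from xgboost import XGBRegressor
        except ImportError as exc:  # pragma: no cover
            raise CapabilityError("xgboost", str(exc)) from exc
        return XGBRegressor(random_state=random_state, **hp)
    if algorithm == "lightgbm":
        try:
            from lightgbm import LGBMRegressor
        except ImportError as exc:  # pragma: no cover
            raise CapabilityError("lightgbm", str(exc)) from exc
        return LGBMRegressor(random_state=random_state, **hp)
    if algorithm == "catboost":
        try:
            from catboost import CatBoostRegressor
        except ImportError as exc:
            raise CapabilityError("catboost", f"library not installed ({exc})") from exc
        return CatBoostRegressor(random_state=random_state, **hp)
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=random_state, **hp)
    if algorithm == "adaboost":
        max_depth = hp.pop("max_depth", 3)
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=max_depth),
            random_state=random_state, **hp)
    if algorithm == "lasso":
        return Pipeline([("scale", StandardScaler()),
                         ("lasso", Lasso(random_state=random_state, **hp))])
    # dnn
    return Pipeline([("scale", StandardScaler()),
                     ("mlp", MLPRegressor(random_state=random_state, **hp))])


def fit_model(algorithm: str, hyperparameters: Optional[dict],
              X_train: pd.DataFrame, y_train: pd.Series,
              random_state: int = 0) -> FittedModel:
    if len(X_train) == 0:
        raise ValueError("training set is empty")
    est = make_estimator(algorithm, hyperparameters, random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny n
        est.fit(X_train, np.asarray(y_train, dtype=float))
    return FittedModel(algorithm, est, list(X_train.columns))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(fitted: FittedModel, X_test: pd.DataFrame,
             y_test: pd.Series) -> tuple[float, float]:
    """Test-set (R², RMSE).  R² is NaN (with a warning) for constant
    test targets, where the variance baseline is undefined."""
    if len(X_test) == 0:
        raise ValueError("test set is empty")
    y_true = np.asarray(y_test, dtype=float)
    y_pred = fitted.predict(X_test)
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    if np.ptp(y_true) == 0:
        warnings.warn("test targets are constant; R² is undefined", stacklevel=2)
        return math.nan, rmse
    return float(r2_score(y_true, y_pred)), rmse


def loocv(algorithm, hyperparameters: Optional[dict],
          X_train: pd.DataFrame, y_train: pd.Series,
          random_state: int = 0) -> float:
    """Leave-one-out score: mean over folds of the single-sample RMSE.

    With one held-out sample per fold the fold RMSE is |y_i - yhat_i|,
    so the returned score equals the mean absolute leave-one-out error.

    ``algorithm`` is an algorithm name, or — for custom predictors —
    a callable ``(X_train, y_train) -> fitted`` where ``fitted`` exposes
    ``predict``.
    """
    n = len(X_train)
    if n < 3:
        raise ValueError(f"LOOCV needs n >= 3, got {n}")
    errors = np.empty(n)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        assert i not in train_idx
        try:
            if callable(algorithm):
                fitted = algorithm(X_train.iloc[train_idx], y_train.iloc[train_idx])
            else:
                fitted = fit_model(algorithm, hyperparameters,
                                   X_train.iloc[train_idx], y_train.iloc[train_idx],
                                   random_state=random_state)
        except Exception as exc:
            raise RuntimeError(f"LOOCV fold {i} failed: {exc}") from exc
        pred = np.asarray(fitted.predict(X_train.iloc[[i]])).ravel()[0]
        errors[i] = abs(float(y_train.iloc[i]) - float(pred))
    return float(errors.mean())


# ---------------------------------------------------------------------------
# the experiment grid
# ---------------------------------------------------------------------------

@dataclass
class ModelRun:
    """One (algorithm x feature-set x random-state) evaluation."""

    algorithm: str
    feature_set: str            # "descriptor" | "fingerprint"
    random_state: int
    hyperparameters: dict
    r2: float
    rmse: float
    rmse_loo: float             # NaN when LOOCV was not computed
    importance: Optional[pd.Series]
    predictions: pd.Series      # indexed by test-sample id

    def __post_init__(self):
        assert self.rmse >= 0
        assert math.isnan(self.r2) or self.r2 <= 1.0 + 1e-12
        assert math.isnan(self.rmse_loo) or self.rmse_loo >= 0
        if self.importance is not None:
            assert (self.importance.to_numpy() >= 0).all()

    @property
    def model_id(self) -> tuple[str, str, int]:
        return (self.algorithm, self.feature_set, self.random_state)


@dataclass
class GridResult:
    runs: list[ModelRun] = field(default_factory=list)
    failures: list[tuple[tuple[str, str, int], str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Accuracy grid: one row per run (algorithm, feature set, state)."""
        rows = [{"algorithm": r.algorithm, "feature_set": r.feature_set,
                 "random_state": r.random_state, "r2": r.r2, "rmse": r.rmse,
                 "rmse_loo": r.rmse_loo} for r in self.runs]
        return pd.DataFrame(rows, columns=["algorithm", "feature_set",
                                           "random_state", "r2", "rmse", "rmse_loo"])


def run_experiment(descriptor_table: FeatureTable,
                   fingerprint_table: FeatureTable,
                   targets: pd.Series,
                   algorithms: Sequence[str] = IMPORTANCE_CAPABLE,
                   random_states: Sequence[int] = (0, 10, 100),
                   hyperparameters: Optional[dict[str, dict]] = None,
                   n_test: Optional[int] = None,
                   compute_loocv: bool = True,
                   logger=None) -> GridResult:
    """Run the full algorithm x feature-set x random-state grid.

    Per-cell failures (e.g. an uninstalled library) are recorded in
    ``failures`` and the grid continues.
    """
    for tbl, label in ((descriptor_table, "descriptor"),
                       (fingerprint_table, "fingerprint")):
        if tbl.sample_ids != list(targets.index):
            raise ValueError(f"{label} table rows are not aligned with targets")
    hyperparameters = hyperparameters or {}
    n_total = descriptor_table.n_samples
    n_test = default_n_test(n_total) if n_test is None else n_test

    result = GridResult()
    partitions: dict[int, set] = {}
    for rs in random_states:
        spec = SplitSpec(n_total=n_total, n_test=n_test, random_state=rs)
        for feature_set, table in (("descriptor", descriptor_table),
                                   ("fingerprint", fingerprint_table)):
            (Xtr_t, ytr), (Xte_t, yte) = split_dataset(table, targets, spec)
            if feature_set == "descriptor":
                test_ids = frozenset(Xte_t.sample_ids)
                if test_ids in partitions.values() and logger:
                    logger(f"random_state {rs}: partition collides with an earlier state")
                partitions[rs] = test_ids
            Xtr, Xte = Xtr_t.values, Xte_t.values
            for algorithm in algorithms:
                cell = (algorithm, feature_set, rs)
                hp = hyperparameters.get(algorithm)
                try:
                    fitted = fit_model(algorithm, hp, Xtr, ytr, random_state=rs)
                    r2, rmse = evaluate(fitted, Xte, yte)
                    rmse_loo = (loocv(algorithm, hp, Xtr, ytr, random_state=rs)
                                if compute_loocv else math.nan)
                    imp = (fitted.importance()
                           if algorithm in IMPORTANCE_CAPABLE else None)
                    preds = pd.Series(fitted.predict(Xte), index=Xte_t.sample_ids)
                    full_hp = dict(DEFAULT_HYPERPARAMETERS[algorithm])
                    full_hp.update(hp or {})
                    result.runs.append(ModelRun(
                        algorithm=algorithm, feature_set=feature_set,
                        random_state=rs, hyperparameters=full_hp,
                        r2=r2, rmse=rmse, rmse_loo=rmse_loo,
                        importance=imp, predictions=preds))
                except CapabilityError as exc:
                    result.failures.append((cell, str(exc)))
                    if logger:
                        logger(f"skipping {cell}: {exc}")
    return result
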