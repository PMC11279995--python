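"""LAI estimation from index values.

A single random 70/30 partition of samples is reused across all angles
and model kinds so results are comparable ("uniform partitioning").
Per-angle models are ordinary least-squares lines in one index; the
multi-angle models feed the index at several view zenith angles into
RBF support-vector regression, a gradient-boosted tree ensemble
(depth 5, learning rate 0.01), or a random forest (500 trees, 3
candidate features per split).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from mavi.errors import DataError, UndefinedStatisticError
from mavi.spectral_core import SampleRecord
from mavi.vi_library import vitable_pivot

log = logging.getLogger(__name__)

MODEL_KINDS = ("linear", "svr_rbf", "gbt", "rf")


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic random train/test partition specification."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DataError(f"train_fraction must be in (0, 1); got {self.train_fraction}")


def train_test_split(sample_ids: Sequence[str], spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive partition; train size = round(fraction * N)
    (banker's rounding, so 0.7 * 180 -> exactly 126).  Identical spec and
    ids give an identical partition regardless of input ordering."""
    ids = sorted(set(sample_ids))
    if len(ids) != len(sample_ids):
        raise DataError("sample_ids contains duplicates")
    n = len(ids)
    if n < 2:
        raise DataError(f"need at least 2 samples to split; got {n}")
    n_train = round(spec.train_fraction * n)
    if n_train == 0 or n_train == n:
        raise DataError(
            f"fraction {spec.train_fraction} on {n} samples yields an empty train or test set"
        )
    order = np.random.default_rng(spec.seed).permutation(n)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def rmse(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Root mean square error: sqrt(mean((obs − pred)^2))."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DataError("obs and pred must have equal length >= 2")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination R² = 1 − SSres/SStot."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DataError("obs and pred must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("constant observations: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class FitResult:
    """A fitted LAI model with train/test metrics and predictions."""

    model_kind: str
    index: str
    vzas: tuple[float, ...]
    parameters: dict
    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    predictions: dict[str, float]  # sample_id -> predicted LAI (train + test)
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    model: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "index": self.index,
            "vzas": list(self.vzas),
            "parameters": self.parameters,
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
            "predictions": self.predictions,
        }


def _design_matrix(
    vitable: pd.DataFrame,
    metadata: Mapping[str, SampleRecord],
    index: str,
    vzas: Sequence[float],
) -> tuple[pd.DataFrame, pd.Series]:
    wide = vitable_pivot(vitable, index)
    missing = [v for v in vzas if v not in wide.columns]
    if missing:
        raise DataError(f"requested VZAs absent from the index table: {missing}")
    X = wide[list(vzas)].dropna()
    unknown = [sid for sid in X.index if sid not in metadata]
    if unknown:
        raise DataError(f"samples without metadata: {unknown[:5]}")
    y = pd.Series({sid: metadata[sid].lai for sid in X.index}, name="lai")
    return X, y


def _evaluate(model_kind, index, vzas, parameters, model, X, y, train_ids, test_ids, predict) -> FitResult:
    pred_train = predict(X.loc[train_ids])
    pred_test = predict(X.loc[test_ids])
    predictions = {
        **{sid: float(p) for sid, p in zip(train_ids, pred_train)},
        **{sid: float(p) for sid, p in zip(test_ids, pred_test)},
    }
    return FitResult(
        model_kind=model_kind,
        index=index,
        vzas=tuple(float(v) for v in vzas),
        parameters=parameters,
        r2_train=r_squared(y.loc[train_ids], pred_train),
        r2_test=r_squared(y.loc[test_ids], pred_test),
        rmse_train=rmse(y.loc[train_ids], pred_train),
        rmse_test=rmse(y.loc[test_ids], pred_test),
        predictions=predictions,
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        model=model,
    )


def fit_linear_per_angle(
    vitable: pd.DataFrame,
    metadata: Mapping[str, SampleRecord],
    index: str,
    vza: float,
    split: SplitSpec = SplitSpec(),
) -> FitResult:
    """Ordinary least-squares line LAI = slope * VI + intercept fitted on
    the training partition at one view zenith angle."""
    X, y = _design_matrix(vitable, metadata, index, [vza])
    train_ids, test_ids = train_test_split(list(X.index), split)
    x_train = X.loc[train_ids, vza].to_numpy()
    if len(train_ids) < 3:
        raise DataError(f"need >= 3 training samples; got {len(train_ids)}")
    if np.std(x_train) == 0.0:
        raise DataError(f"index {index!r} has zero variance at VZA {vza}")
    design = np.column_stack([x_train, np.ones_like(x_train)])
    coef, *_ = np.linalg.lstsq(design, y.loc[train_ids].to_numpy(), rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])

    def predict(frame: pd.DataFrame) -> np.ndarray:
        return slope * frame[vza].to_numpy() + intercept

    return _evaluate(
        "linear", index, (vza,), {"slope": slope, "intercept": intercept},
        None, X, y, train_ids, test_ids, predict,
    )


def _make_model(model_kind: str, seed: int, hyperparams: dict, n_features: int):
    hp = dict(hyperparams)
    if model_kind == "svr_rbf":
        params = {"C": hp.pop("C", 1.0), "epsilon": hp.pop("epsilon", 0.1)}
        # RBF kernels need comparable feature scales
        model = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **params))]
        )
        return model, params
    if model_kind == "gbt":
        params = {
            "max_depth": hp.pop("max_depth", 5),
            "learning_rate": hp.pop("learning_rate", 0.01),
            "n_estimators": hp.pop("n_estimators", 500),
            "alpha_l1": hp.pop("alpha", 0.0),
            "lambda_l2": hp.pop("lambda", 1.0),
        }
        if params["alpha_l1"] != 0.0 or params["lambda_l2"] != 1.0:
            warnings.warn(
                "gbt backend does not apply L1/L2 leaf regularization; "
                "alpha/lambda are recorded but inert",
                stacklevel=3,
            )
        model = GradientBoostingRegressor(
            max_depth=params["max_depth"],
            learning_rate=params["learning_rate"],
            n_estimators=params["n_estimators"],
            random_state=seed,
        )
        return model, params
    if model_kind == "rf":
        mtry = hp.pop("mtry", 3)
        if mtry > n_features:
            warnings.warn(
                f"mtry={mtry} exceeds the {n_features} available features; clamped",
                stacklevel=3,
            )
            mtry = n_features
        params = {"n_trees": hp.pop("n_trees", 500), "mtry": mtry}
        model = RandomForestRegressor(
            n_estimators=params["n_trees"], max_features=mtry, random_state=seed
        )
        return model, params
    raise DataError(f"unknown model_kind {model_kind!r}; expected one of {MODEL_KINDS[1:]}")


def fit_multiangle(
    vitable: pd.DataFrame,
    metadata: Mapping[str, SampleRecord],
    index: str,
    vzas: Sequence[float],
    model_kind: str,
    split: SplitSpec = SplitSpec(),
    seed: int = 0,
    **hyperparams,
) -> FitResult:
    """Fit an ensemble/kernel regressor on the index observed at several
    view zenith angles.

    ``model_kind`` is one of ``svr_rbf`` (RBF support-vector regression,
    C=1, eps=0.1 unless overridden), ``gbt`` (boosted trees, depth 5,
    learning rate 0.01, 500 rounds), or ``rf`` (random forest, 500
    trees, mtry=3 clamped to the feature count).  Fully reproducible
    given ``seed`` and the split spec.
    """
    X, y = _design_matrix(vitable, metadata, index, vzas)
    train_ids, test_ids = train_test_split(list(X.index), split)
    model, params = _make_model(model_kind, seed, hyperparams, n_features=len(vzas))
    model.fit(X.loc[train_ids].to_numpy(), y.loc[train_ids].to_numpy())

    def predict(frame: pd.DataFrame) -> np.ndarray:
        return model.predict(frame.to_numpy())

    return _evaluate(model_kind, index, vzas, params, model, X, y, train_ids, test_ids, predict)
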