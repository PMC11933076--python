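"""Per-label epsilon-SVR surrogates: split, train, evaluate, serialize.

One radial-basis-kernel support-vector regressor is trained per label on the
scaled [0, 1] feature cube, restricted to that label's feature set.  The
fitted model is reduced to explicit artifacts (support vectors, dual
coefficients, bias, gamma) so prediction is a deterministic closed form
  f(x) = sum_i alpha_i exp(-gamma ||x - sv_i||^2) + b
independent of the fitting library, and models round-trip through JSON.

Evaluation inverse-transforms predictions to original label units and scores
them with MAE / MSE / RMSE; RMSE = sqrt(MSE) and MAE <= RMSE hold by
construction for every evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from . import published
from .preprocessing import TransformState
from .report import EvaluationMetrics
from .schema import FEATURE_SETS


@dataclass(frozen=True)
class SvrHyperparams:
    """Radial-basis epsilon-SVR hyperparameters."""

    gamma: float
    C: float
    epsilon: float

    def __post_init__(self) -> None:
        if min(self.gamma, self.C, self.epsilon) <= 0:
            raise ValueError("gamma, C and epsilon must be strictly positive")


def default_hyperparams(label: str) -> SvrHyperparams:
    """The original analysis's final per-label hyperparameters."""
    gamma, c, eps = published.SVR_HYPERPARAMS[label]
    return SvrHyperparams(gamma=gamma, C=c, epsilon=eps)


class TooFewRowsError(ValueError):
    pass


def split_dataset(n_rows: int, test_fraction: float = 0.2, seed: int = 42):
    """Uniformly random disjoint/exhaustive train/test index split.

    Test size is round(test_fraction * n); deterministic given ``seed``.
    """
    if n_rows < 5:
        raise TooFewRowsError(f"need at least 5 rows to split, got {n_rows}")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * n_rows))
    n_test = min(max(n_test, 1), n_rows - 1)
    perm = np.random.default_rng(seed).permutation(n_rows)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


@dataclass
class SurrogateModel:
    """A trained per-label surrogate reduced to prediction artifacts."""

    label: str
    hyperparams: SvrHyperparams
    feature_set: tuple[str, ...]
    support_vectors: np.ndarray  # (n_sv, d) scaled features
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float

    def predict(self, X) -> np.ndarray:
        """Closed-form RBF expansion over the support vectors (scaled units)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        k = np.exp(-self.hyperparams.gamma * np.maximum(d2, 0.0))
        return k @ self.dual_coef + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "label": self.label,
            "hyperparams": {
                "gamma": self.hyperparams.gamma,
                "C": self.hyperparams.C,
                "epsilon": self.hyperparams.epsilon,
            },
            "feature_set": list(self.feature_set),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SurrogateModel":
        p = Path(str(text_or_path))
        doc = json.loads(p.read_text() if p.exists() else str(text_or_path))
        return cls(
            label=doc["label"],
            hyperparams=SvrHyperparams(**doc["hyperparams"]),
            feature_set=tuple(doc["feature_set"]),
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            dual_coef=np.asarray(doc["dual_coef"], dtype=float),
            intercept=float(doc["intercept"]),
        )


def train_svr(
    features: pd.DataFrame,
    label_values: np.ndarray | pd.Series,
    label: str,
    hp: SvrHyperparams | None = None,
) -> SurrogateModel:
    """Fit the epsilon-SVR for ``label`` on its scaled feature set.

    ``features`` must already be scaled to [0, 1] and complete; rows where
    the (scaled) label is missing are dropped.
    """
    hp = hp or default_hyperparams(label)
    feature_set = FEATURE_SETS[label]
    X = features[list(feature_set)].to_numpy(dtype=float)
    y = np.asarray(label_values, dtype=float)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    svr = SVR(kernel="rbf", gamma=hp.gamma, C=hp.C, epsilon=hp.epsilon)
    svr.fit(X, y)
    return SurrogateModel(
        label=label,
        hyperparams=hp,
        feature_set=feature_set,
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coef=np.asarray(svr.dual_coef_, dtype=float).ravel(),
        intercept=float(svr.intercept_[0]),
    )


def error_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationMetrics:
    """MAE, MSE and RMSE of a prediction set (any units)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on an empty set")
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    return EvaluationMetrics(mae=mae, mse=mse, rmse=float(np.sqrt(mse)))


def evaluate(
    model: SurrogateModel,
    features: pd.DataFrame,
    labels_scaled: pd.Series | np.ndarray,
    state: TransformState,
) -> EvaluationMetrics:
    """Score the surrogate on held-out rows, in original label units.

    Predictions (made on the scaled cube) and true labels are both mapped
    back through the inverse min-max + inverse Box-Cox before the error
    metrics are computed, so MAE/RMSE carry the label's physical units.
    """
    y_scaled = np.asarray(labels_scaled, dtype=float)
    ok = np.isfinite(y_scaled)
    if not ok.any():
        raise ValueError("test set has no observed labels")
    X = features[list(model.feature_set)].to_numpy(dtype=float)[ok]
    pred_scaled = model.predict(X)
    y_true = state.inverse_column(model.label, y_scaled[ok])
    y_pred = state.inverse_column(model.label, pred_scaled)
    return error_metrics(y_true, y_pred)
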