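"""Data-cleaning chain: per-column Box-Cox, SoftImpute completion, min-max scaling.

The chain mirrors the original analysis: every feature and label column is
power-transformed toward normality (two-parameter Box-Cox with a shift for
non-positive columns), missing feature cells are completed by iterative
soft-thresholded SVD (nuclear-norm regularized matrix completion), and all
columns are scaled to [0, 1].  Every step is invertible and its parameters
are captured in a JSON-serializable :class:`TransformState`, so surrogate
predictions and optimizer outputs can be mapped back to original units.

Labels are transformed and scaled but never imputed: a missing outcome stays
missing and its row is simply dropped when that label's surrogate is fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataset import NanofiberDataset
from .schema import FEATURES, LABELS

#: Shift target for non-positive columns: smallest perturbation keeping the
#: Box-Cox argument strictly positive.
_SHIFT_EPS = 1e-6


class DegenerateColumnError(ValueError):
    """A column is constant (or too short) and cannot be transformed."""


class ImputationError(ValueError):
    """Matrix completion cannot proceed (e.g. a fully-missing column)."""


# ---------------------------------------------------------------------------
# Box-Cox


def fit_box_cox(column: np.ndarray) -> tuple[float, float]:
    """Fit (shift, lambda) for one column's two-parameter Box-Cox transform.

    shift is 0 for strictly positive columns and ``1e-6 - min`` otherwise;
    lambda maximizes the Box-Cox profile log-likelihood on (column + shift).
    """
    vals = np.asarray(column, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 3:
        raise DegenerateColumnError("need at least 3 observed values")
    if np.ptp(vals) == 0:
        raise DegenerateColumnError("column is constant")
    mn = vals.min()
    shift = 0.0 if mn > 0 else _SHIFT_EPS - mn
    lam = float(stats.boxcox_normmax(vals + shift, method="mle"))
    return shift, lam


def box_cox_forward(x, shift: float, lam: float):
    """(y^lam - 1)/lam for lam != 0, ln y at lam = 0, with y = x + shift."""
    return special.boxcox(np.asarray(x, dtype=float) + shift, lam)


def box_cox_inverse(y, shift: float, lam: float):
    """Inverse of :func:`box_cox_forward`; the argument of the power is
    floored at a tiny positive value so slightly out-of-range surrogate
    predictions stay finite."""
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y) - shift
    base = np.maximum(lam * y + 1.0, 1e-12)
    return base ** (1.0 / lam) - shift


# ---------------------------------------------------------------------------
# SoftImpute


@dataclass
class ImputationResult:
    completed: np.ndarray
    lambda_nuclear: float
    n_iter: int
    converged: bool
    final_delta: float
    objective_history: list[float] = field(default_factory=list)


def _objective(X: np.ndarray, obs: np.ndarray, Z: np.ndarray, lam: float) -> float:
    resid = np.where(obs, X - Z, 0.0)
    return 0.5 * float(np.sum(resid**2)) + lam * float(
        np.linalg.svd(Z, compute_uv=False).sum()
    )


def soft_impute(
    matrix: np.ndarray,
    mask: np.ndarray,
    lambda_nuclear: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ImputationResult:
    """Complete ``matrix`` where ``mask`` is True by soft-thresholded SVD.

    Missing cells start at column means; each sweep takes the SVD of the
    current completion, soft-thresholds the singular values by
    ``lambda_nuclear`` (default: 10% of the mean-filled matrix's largest
    singular value) and overwrites only the missing cells with the
    thresholded reconstruction.  Iteration stops when the relative Frobenius
    change over the missing cells drops below ``tol``.  The regularized
    objective  0.5 * ||P_obs(X - Z)||_F^2 + lambda * ||Z||_*  is recorded
    each sweep and is non-increasing.
    """
    X = np.asarray(matrix, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape != mask.shape:
        raise ValueError("matrix and mask shapes differ")
    obs = ~mask
    fully_missing = np.flatnonzero(~obs.any(axis=0))
    if fully_missing.size:
        raise ImputationError(f"columns {fully_missing.tolist()} are fully missing")

    col_means = np.nanmean(np.where(obs, X, np.nan), axis=0)
    filled = np.where(obs, X, col_means[None, :])

    if lambda_nuclear is None:
        lambda_nuclear = 0.1 * float(np.linalg.svd(filled, compute_uv=False)[0])

    if not mask.any():
        return ImputationResult(
            completed=filled,
            lambda_nuclear=lambda_nuclear,
            n_iter=0,
            converged=True,
            final_delta=0.0,
        )

    history: list[float] = []
    delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        s_thr = np.maximum(s - lambda_nuclear, 0.0)
        Z = (U * s_thr) @ Vt
        new_missing = Z[mask]
        old_missing = filled[mask]
        denom = max(float(np.linalg.norm(old_missing)), 1e-12)
        delta = float(np.linalg.norm(new_missing - old_missing)) / denom
        filled = np.where(obs, X, Z)
        history.append(_objective(X, obs, Z, lambda_nuclear))
        if delta < tol:
            break
    return ImputationResult(
        completed=filled,
        lambda_nuclear=lambda_nuclear,
        n_iter=n_iter,
        converged=delta < tol,
        final_delta=delta,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# Transform state (Box-Cox + min-max per column)


@dataclass
class ColumnTransform:
    shift: float
    lam: float
    x_min: float  # min-max anchors on the Box-Cox-transformed scale
    x_max: float

    def forward(self, x):
        y = box_cox_forward(x, self.shift, self.lam)
        return min_max_scale(y, self.x_min, self.x_max)

    def inverse(self, s):
        y = inverse_min_max(s, self.x_min, self.x_max)
        return box_cox_inverse(y, self.shift, self.lam)


def min_max_scale(x, x_min: float, x_max: float):
    """(x - x_min) / (x_max - x_min); anchors map exactly to 0 and 1."""
    if not x_max > x_min:
        raise DegenerateColumnError("x_max must exceed x_min")
    return (np.asarray(x, dtype=float) - x_min) / (x_max - x_min)


def inverse_min_max(s, x_min: float, x_max: float):
    if not x_max > x_min:
        raise DegenerateColumnError("x_max must exceed x_min")
    return np.asarray(s, dtype=float) * (x_max - x_min) + x_min


@dataclass
class TransformState:
    """Fitted per-column transforms for all feature and label columns."""

    columns: dict[str, ColumnTransform] = field(default_factory=dict)

    def forward_column(self, name: str, x):
        return self.columns[name].forward(x)

    def inverse_column(self, name: str, s):
        return self.columns[name].inverse(s)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            name: {"shift": t.shift, "lambda": t.lam, "x_min": t.x_min, "x_max": t.x_max}
            for name, t in self.columns.items()
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TransformState":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            columns={
                name: ColumnTransform(
                    shift=d["shift"], lam=d["lambda"], x_min=d["x_min"], x_max=d["x_max"]
                )
                for name, d in doc.items()
            }
        )


# ---------------------------------------------------------------------------
# Full chain


@dataclass
class PreprocessedData:
    """Scaled feature/label frames plus the state needed to undo them."""

    features: pd.DataFrame  # n x 12, complete, in [0, 1]
    labels: pd.DataFrame  # n x 4, in [0, 1], NaN where the outcome is missing
    state: TransformState
    imputation: ImputationResult


def preprocess_pipeline(
    ds: NanofiberDataset,
    lambda_nuclear: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> PreprocessedData:
    """Box-Cox each column, SoftImpute the feature matrix, min-max scale.

    Box-Cox parameters are fitted on observed cells only; imputation runs on
    the transformed feature matrix (labels are never imputed); scaling
    anchors are the min/max of each transformed column after completion, so
    every output column spans exactly [0, 1].
    """
    state = TransformState()

    bc_feats = np.empty((ds.n_rows, len(FEATURES)))
    for j, name in enumerate(FEATURES):
        col = ds.features[name].to_numpy()
        shift, lam = fit_box_cox(col)
        bc_feats[:, j] = box_cox_forward(col, shift, lam)
        state.columns[name] = ColumnTransform(shift=shift, lam=lam, x_min=0.0, x_max=1.0)

    mask = ds.missing_mask.to_numpy()
    imput = soft_impute(bc_feats, mask, lambda_nuclear=lambda_nuclear, tol=tol, max_iter=max_iter)

    scaled_feats = {}
    for j, name in enumerate(FEATURES):
        col = imput.completed[:, j]
        x_min, x_max = float(col.min()), float(col.max())
        if not x_max > x_min:
            raise DegenerateColumnError(f"column {name} is constant after transform")
        t = state.columns[name]
        t.x_min, t.x_max = x_min, x_max
        scaled_feats[name] = min_max_scale(col, x_min, x_max)

    scaled_labels = {}
    for name in LABELS:
        col = ds.labels[name].to_numpy()
        shift, lam = fit_box_cox(col)
        y = box_cox_forward(col, shift, lam)
        obs = np.isfinite(y)
        x_min, x_max = float(np.min(y[obs])), float(np.max(y[obs]))
        if not x_max > x_min:
            raise DegenerateColumnError(f"label {name} is constant after transform")
        state.columns[name] = ColumnTransform(shift=shift, lam=lam, x_min=x_min, x_max=x_max)
        scaled_labels[name] = min_max_scale(y, x_min, x_max)

    return PreprocessedData(
        features=pd.DataFrame(scaled_feats),
        labels=pd.DataFrame(scaled_labels),
        state=state,
        imputation=imput,
    )
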