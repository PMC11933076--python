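"""Spearman rank feature importance.

For each label, the rank correlation rho between the label and every feature
in its feature set is computed on rows where both are observed; the relative
importance score is 100 * |rho_i| / max_j |rho_j|, so the most correlated
feature always scores 100%.  Because Spearman correlation depends only on
ranks, the scores are invariant to the whole (strictly monotone)
preprocessing chain, and can be computed on raw or transformed data
interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .report import ImportanceEntry, ImportanceReport
from .schema import FEATURE_SETS


class UndefinedCorrelationError(ValueError):
    """Spearman rho is undefined (constant series or too few points)."""


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with average-rank tie handling.

    With no ties this is exactly  1 - 6 * sum(d_i^2) / (n (n^2 - 1))  with
    d_i the rank differences; with ties it falls back to the product-moment
    correlation of the average ranks (the standard generalization, which the
    simple formula equals in the tie-free case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if not has_ties:
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d**2) / (n * (n**2 - 1)))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def importance_report(
    features: pd.DataFrame, labels: pd.DataFrame, label: str
) -> ImportanceReport:
    """Rank-correlation importance of every feature in ``label``'s feature set.

    Features with no computable correlation (empty observed overlap with the
    label, or constant on it) are reported with ``rho=None`` and excluded
    from the normalizing maximum.  Exactly one entry attains 100% (ties
    broken by schema order).
    """
    feature_set = FEATURE_SETS[label]
    y_all = labels[label].to_numpy(dtype=float)
    rhos: list[float | None] = []
    for feat in feature_set:
        x_all = features[feat].to_numpy(dtype=float)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        try:
            rhos.append(spearman_rho(x_all[ok], y_all[ok]))
        except (UndefinedCorrelationError, ValueError):
            rhos.append(None)
    finite = [abs(r) for r in rhos if r is not None]
    if not finite:
        raise UndefinedCorrelationError(f"no computable correlations for {label}")
    max_abs = max(finite)
    entries = []
    assigned_top = False
    for feat, rho in zip(feature_set, rhos):
        if rho is None:
            entries.append(ImportanceEntry(feature=feat, rho=None, relative_pct=None))
            continue
        pct = 100.0 * abs(rho) / max_abs if max_abs > 0 else 0.0
        # exactly one entry scores 100; on an exact tie the first feature in
        # schema order keeps it and later ties are nudged just below
        if abs(rho) == max_abs:
            if not assigned_top:
                pct = 100.0
                assigned_top = True
            else:
                pct = float(np.nextafter(100.0, 0.0))
        entries.append(ImportanceEntry(feature=feat, rho=float(rho), relative_pct=pct))
    return ImportanceReport(label=label, entries=entries, feature_set=feature_set)
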