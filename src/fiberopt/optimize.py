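"""Particle-swarm inverse design over a trained surrogate.

The swarm searches the scaled [0, 1] cube of the surrogate's feature set with
the canonical update rule

    v <- omega * v + c1 * r1 . (pbest - x) + c2 * r2 . (gbest - x)
    x <- clip(x + v, bounds)

using the coefficients the original analysis settled on
(c1 = 0.4862, c2 = 2.5067, omega = -0.2887; the negative inertia lets
particles reverse direction readily, countering premature convergence).
Fiber diameter is minimized; encapsulation efficiency, drug release and
anticancer activity are maximized by negating the objective.  Optima are
reported in original units via the inverse transform chain, and the four
per-label optima aggregate into per-feature optimal ranges by strict
min/max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import published
from .preprocessing import TransformState
from .report import OptimalRangeTable, OptimizationResult
from .schema import DIRECTIONS, FIXED_FEATURES, LABELS, SCHEMA_BY_NAME
from .surrogate import SurrogateModel


class OptimizationError(RuntimeError):
    pass


@dataclass
class ParticleSwarmConfig:
    c1: float = published.PSO_C1
    c2: float = published.PSO_C2
    omega: float = published.PSO_OMEGA
    n_particles: int = 50
    n_iters: int = 200
    seed: int = 0
    bounds: np.ndarray | None = None  # (d, 2); defaults to the unit cube

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_iters < 1:
            raise ValueError("need at least 1 iteration")
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or not (b[:, 0] < b[:, 1]).all():
                raise ValueError("bounds must be (d, 2) with lower < upper")
            self.bounds = b


def pso_minimize(objective, n_dims: int, cfg: ParticleSwarmConfig):
    """Minimize ``objective`` (mapping an (m, d) array to m values) on a box.

    Velocities start at zero and positions uniform over the box; positions
    are clipped to the bounds each step.  Returns (x_best, f_best, history)
    with ``history`` the best-ever objective per iteration (monotone
    non-increasing).  Deterministic given ``cfg.seed``.
    """
    bounds = (
        np.tile([0.0, 1.0], (n_dims, 1)) if cfg.bounds is None else np.asarray(cfg.bounds)
    )
    if bounds.shape[0] != n_dims:
        raise ValueError(f"bounds have {bounds.shape[0]} dims, expected {n_dims}")
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(cfg.seed)

    x = lo + (hi - lo) * rng.random((cfg.n_particles, n_dims))
    v = np.zeros_like(x)
    f = np.asarray(objective(x), dtype=float)
    if not np.isfinite(f).all():
        raise OptimizationError("objective returned non-finite values")
    pbest, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    history = [gbest_f]
    for _ in range(cfg.n_iters):
        r1 = rng.random((cfg.n_particles, n_dims))
        r2 = rng.random((cfg.n_particles, n_dims))
        v = cfg.omega * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        x = np.clip(x + v, lo, hi)
        f = np.asarray(objective(x), dtype=float)
        if not np.isfinite(f).all():
            raise OptimizationError("objective returned non-finite values")
        better = f < pbest_f
        pbest[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)
    return gbest, gbest_f, history


def optimize_label(
    model: SurrogateModel,
    state: TransformState,
    cfg: ParticleSwarmConfig,
    direction: str | None = None,
) -> OptimizationResult:
    """Inverse-design the feature vector optimizing ``model``'s label.

    The swarm runs on the scaled cube restricted to the model's feature set;
    the returned optimum and predicted label value are mapped back to
    original units.  ``swarm_best_history`` carries the best label value per
    iteration (non-increasing when minimizing, non-decreasing otherwise).
    """
    direction = direction or DIRECTIONS[model.label]
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"direction must be minimize|maximize, got {direction!r}")
    sign = 1.0 if direction == "minimize" else -1.0

    def objective(X):
        return sign * model.predict(X)

    d = len(model.feature_set)
    x_best, f_best, history = pso_minimize(objective, d, cfg)

    # imputed cells can stretch the scaled anchors past the observed support,
    # so the inverse map is clipped to the schema's original-unit bounds
    x_opt = {}
    for i, name in enumerate(model.feature_set):
        lo, hi = SCHEMA_BY_NAME[name].bounds
        x_opt[name] = float(np.clip(state.inverse_column(name, x_best[i]), lo, hi))
    # surrogate extrapolation can leave the scaled training range; clip so the
    # reported label value stays inside the physically observed span
    predicted = float(state.inverse_column(model.label, np.clip(sign * f_best, 0.0, 1.0)))
    return OptimizationResult(
        label=model.label,
        direction=direction,
        x_opt=x_opt,
        predicted_value=predicted,
        swarm_best_history=[sign * h for h in history],
    )


def aggregate_optimal_ranges(
    results: dict[str, OptimizationResult],
) -> OptimalRangeTable:
    """Strict per-feature (min, max) across the four per-label optima.

    Study-time features are excluded (they appear in at most one optimum and
    have no cross-label range).  Requires all four labels.
    """
    missing = [lbl for lbl in LABELS if lbl not in results]
    if missing:
        raise ValueError(f"missing optimization results for labels {missing}")
    ranges = {}
    for feat in FIXED_FEATURES:
        vals = [results[lbl].x_opt[feat] for lbl in LABELS]
        ranges[feat] = (float(min(vals)), float(max(vals)))
    return OptimalRangeTable(ranges=ranges)
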