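"""Literature-like synthetic formulation datasets.

The original mined dataset was never deposited; only per-column five-number
summaries survive.  This module draws feature columns independently from
piecewise-linear inverse CDFs through those quantile anchors, so the synthetic
marginals reproduce the published minima, quartiles and maxima.  Labels are
either drawn the same way ("marginal" mode) or computed from planted quadratic
response surfaces with known closed-form optima ("surface" mode), which makes
inverse-design recovery testable: the optimizer must find an optimum the
generator can name.

Missing feature cells are injected completely at random (MCAR) into the 10
fixed-feature columns, defaulting to the 126 missing cells the original
data-cleaning step dealt with.  Because only marginals are published, no
feature-feature dependence is modelled; see docs/methods.md for what that
implies about realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import published
from .dataset import NanofiberDataset
from .schema import FEATURE_SETS, FEATURES, FIXED_FEATURES, LABELS, SCHEMA_BY_NAME

Anchors = tuple[float, float, float, float, float]

_QUANTILES = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


class ConfigError(ValueError):
    """Invalid synthetic-generation configuration."""


def sample_marginal(anchors: Anchors, u) -> np.ndarray | float:
    """Map uniform probabilities through the piecewise-linear inverse CDF
    defined by (min, q1, median, q3, max) anchors.

    u=0 returns the minimum, u=0.5 the median, u=1 the maximum; intermediate
    probabilities interpolate linearly between adjacent anchors.
    """
    lo, q1, q2, q3, hi = anchors
    if not (lo <= q1 <= q2 <= q3 <= hi):
        raise ConfigError(f"anchors must be sorted, got {anchors}")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ConfigError("probabilities must lie in [0, 1]")
    out = np.interp(u_arr, _QUANTILES, np.array(anchors, dtype=float))
    return float(out) if np.isscalar(u) or out.ndim == 0 else out


@dataclass(frozen=True)
class LabelSurface:
    """A planted quadratic response surface for one label.

    The surface is an axis-aligned quadratic around the optimum ``x_opt``:
    for feature i with bounds (lo_i, hi_i) and scaled deviation
    z_i = (x_i - x*_i) / (hi_i - lo_i),

        bowl:  y = base_value + sum_i c_i z_i^2 + sum_i b_i s_i
        peak:  y = base_value - sum_i c_i z_i^2 + sum_i b_i s_i

    with s_i the min-max scaled coordinate.  The three ``active`` features
    carry large curvature c_i; the remaining features of the label's feature
    set carry weak curvature so the global optimum is exactly ``x_opt`` in
    every dimension while the signal is dominated by the active ones.
    """

    kind: str  # "bowl" (minimized at x_opt) or "peak" (maximized)
    active: tuple[str, ...]
    x_opt: dict[str, float]
    curvature: dict[str, float]
    linear: dict[str, float]
    base_value: float
    noise_sd: float
    clip: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("bowl", "peak"):
            raise ConfigError(f"surface kind must be bowl|peak, got {self.kind!r}")
        for name, x in self.x_opt.items():
            lo, hi = SCHEMA_BY_NAME[name].bounds
            if not lo < x < hi:
                raise ConfigError(
                    f"planted optimum {x} for {name} not strictly inside {lo, hi}"
                )
        if any(c <= 0 for c in self.curvature.values()):
            raise ConfigError("curvature coefficients must be positive")

    def evaluate(self, features: pd.DataFrame) -> np.ndarray:
        """Noise-free surface value at each row, before clipping."""
        y = np.full(len(features), self.base_value, dtype=float)
        sign = 1.0 if self.kind == "bowl" else -1.0
        for name, c in self.curvature.items():
            lo, hi = SCHEMA_BY_NAME[name].bounds
            z = (features[name].to_numpy() - self.x_opt[name]) / (hi - lo)
            y += sign * c * z**2
        for name, b in self.linear.items():
            lo, hi = SCHEMA_BY_NAME[name].bounds
            y += b * (features[name].to_numpy() - lo) / (hi - lo)
        return y


#: SyntheticTruth: the planted surface per label.
SyntheticTruth = dict[str, LabelSurface]


def _surface(
    label: str,
    kind: str,
    active: dict[str, tuple[float, float]],
    base_value: float,
    noise_sd: float,
    weak_curvature: float = 12.0,
) -> LabelSurface:
    """Build a surface whose inactive-dimension optima sit at the column
    medians with weak curvature."""
    x_opt: dict[str, float] = {}
    curvature: dict[str, float] = {}
    for name in FEATURE_SETS[label]:
        if name in active:
            x_opt[name], curvature[name] = active[name]
        else:
            x_opt[name] = published.FEATURE_ANCHORS[name][2]
            curvature[name] = weak_curvature
    lo, hi = (
        published.LABEL_ANCHORS[label][0],
        published.LABEL_ANCHORS[label][4],
    )
    return LabelSurface(
        kind=kind,
        active=tuple(active),
        x_opt=x_opt,
        curvature=curvature,
        linear={},
        base_value=base_value,
        noise_sd=noise_sd,
        clip=(lo, hi),
    )


def default_truth() -> SyntheticTruth:
    """Planted surfaces echoing the optima the original analysis reported.

    Fiber diameter is a bowl (minimized) in distance / polymer density /
    polymer concentration near (15 cm, 1.529 g/cm^3, 9 wt%); the three
    outcome labels are peaks in their reported top-three features.
    """
    return {
        "average_diameter_nm": _surface(
            "average_diameter_nm",
            "bowl",
            {
                "distance_cm": (15.0, 600.0),
                "polymer_density_g_cm3": (1.529, 500.0),
                "polymer_concentration_wt_pct": (9.0, 450.0),
            },
            base_value=60.0,
            noise_sd=40.0,
        ),
        "encapsulation_efficiency_pct": _surface(
            "encapsulation_efficiency_pct",
            "peak",
            {
                "polymer_concentration_wt_pct": (7.1982, 300.0),
                "dielectric_constant": (40.0, 160.0),
                "voltage_kV": (22.0, 160.0),
            },
            base_value=97.0,
            noise_sd=4.0,
        ),
        "drug_release_pct": _surface(
            "drug_release_pct",
            "peak",
            {
                "polymer_concentration_wt_pct": (6.618, 300.0),
                "distance_cm": (14.109, 250.0),
                "flow_rate_mL_h": (1.0, 200.0),
            },
            base_value=97.0,
            noise_sd=4.0,
        ),
        "anticancer_activity_pct": _surface(
            "anticancer_activity_pct",
            "peak",
            {
                "polymer_density_g_cm3": (1.2, 350.0),
                "polymer_concentration_wt_pct": (8.0, 300.0),
                "dox_concentration_wt_pct": (3.182, 250.0),
            },
            base_value=88.0,
            noise_sd=4.0,
        ),
    }


@dataclass
class SyntheticConfig:
    """Conditions for one synthetic draw.

    ``mode`` is "marginal" (labels drawn from their own quantile anchors,
    independent of features) or "surface" (labels from the planted surfaces).
    ``n_missing`` fixed-feature cells are masked MCAR; the default of 126
    matches the missing-cell count the original data cleaning handled.
    """

    n_rows: int = 200
    seed: int = 0
    mode: str = "marginal"
    anchors: dict[str, Anchors] = field(
        default_factory=lambda: dict(published.FEATURE_ANCHORS)
    )
    label_anchors: dict[str, Anchors] = field(
        default_factory=lambda: dict(published.LABEL_ANCHORS)
    )
    truth: SyntheticTruth = field(default_factory=default_truth)
    n_missing: int = 126
    noise_scale: float = 1.0  # multiplies every surface's noise_sd

    def __post_init__(self) -> None:
        if self.mode not in ("marginal", "surface"):
            raise ConfigError(f"mode must be marginal|surface, got {self.mode!r}")
        if self.n_rows <= 0:
            raise ConfigError("n_rows must be positive")
        if not 0 <= self.n_missing <= self.n_rows * len(FIXED_FEATURES):
            raise ConfigError(
                f"n_missing={self.n_missing} exceeds the "
                f"{self.n_rows * len(FIXED_FEATURES)} fixed-feature cells"
            )


def generate_dataset(config: SyntheticConfig) -> tuple[NanofiberDataset, SyntheticTruth]:
    """Draw a dataset under ``config``; deterministic given (seed, config).

    One global seed drives three independent substreams (feature draws, label
    noise/draws, missingness) so changing e.g. the missing-cell count never
    perturbs the feature values.
    """
    ss_feat, ss_label, ss_miss = np.random.SeedSequence(config.seed).spawn(3)
    rng_feat = np.random.default_rng(ss_feat)
    rng_label = np.random.default_rng(ss_label)

    features = pd.DataFrame(
        {
            name: sample_marginal(config.anchors[name], rng_feat.random(config.n_rows))
            for name in FEATURES
        }
    )

    labels = {}
    for label in LABELS:
        if config.mode == "marginal":
            labels[label] = sample_marginal(
                config.label_anchors[label], rng_label.random(config.n_rows)
            )
        else:
            surf = config.truth[label]
            y = surf.evaluate(features)
            sd = surf.noise_sd * config.noise_scale
            if sd > 0:
                y = y + rng_label.normal(0.0, sd, config.n_rows)
            labels[label] = np.clip(y, *surf.clip)
    ds = NanofiberDataset(features, pd.DataFrame(labels))

    if config.n_missing > 0:
        miss_seed = int(np.random.default_rng(ss_miss).integers(2**31))
        ds = inject_missingness(ds, config.n_missing, miss_seed)
    return ds, config.truth


def inject_missingness(ds: NanofiberDataset, n_missing: int, seed: int) -> NanofiberDataset:
    """Mask exactly ``n_missing`` distinct fixed-feature cells, MCAR.

    Labels and study-time features are never masked.  Deterministic given
    ``seed``; re-injecting with the same seed reproduces the same mask.
    """
    n_cells = ds.n_rows * len(FIXED_FEATURES)
    if not 0 <= n_missing <= n_cells:
        raise ConfigError(f"n_missing={n_missing} exceeds {n_cells} fixed-feature cells")
    out = ds.copy()
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_missing, replace=False)
    rows, cols = np.divmod(flat, len(FIXED_FEATURES))
    for r, c in zip(rows, cols):
        out.features.iat[int(r), out.features.columns.get_loc(FIXED_FEATURES[int(c)])] = np.nan
    return out


def true_optimum(truth: SyntheticTruth, label: str) -> dict[str, float]:
    """The planted optimum feature vector for ``label``, in original units."""
    if label not in truth:
        raise KeyError(f"no planted surface for label {label!r}")
    return dict(truth[label].x_opt)


def with_noise(truth: SyntheticTruth, noise_sd: float) -> SyntheticTruth:
    """Copy of ``truth`` with every surface's noise sd replaced."""
    return {k: replace(v, noise_sd=noise_sd) for k, v in truth.items()}
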