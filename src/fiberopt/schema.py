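"""Column schema for the nanofiber formulation table.

The table has 12 features — 10 "fixed" ones describing the electrospinning
machine settings and the material formulation, plus 2 study-design durations —
and 4 labels (fiber diameter and the three pharmacological outcomes).  Column
headers are fixed snake_case tokens; the schema is the single source of truth
for names, units, roles and default bounds, so every CSV written by one stage
parses bit-identically in the next.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureSchema:
    """One feature column: header token, physical unit, role and support.

    ``role`` is one of ``machine`` (electrospinning device setting),
    ``material`` (formulation property) or ``study_time`` (duration of the
    release / activity assay).  ``bounds`` is the closed interval of plausible
    values in original units, anchored at the observed min/max of the mined
    literature table.
    """

    name: str
    unit: str
    role: str
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.role not in ("machine", "material", "study_time"):
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"degenerate bounds {self.bounds} for {self.name}")


def _f(name: str, unit: str, role: str, lo: float, hi: float) -> FeatureSchema:
    return FeatureSchema(name=name, unit=unit, role=role, bounds=(lo, hi))


#: The 12 feature columns in canonical order (machine, material, study-time).
FEATURE_SCHEMA: tuple[FeatureSchema, ...] = (
    _f("flow_rate_mL_h", "mL/h", "machine", 0.006, 26.0),
    _f("distance_cm", "cm", "machine", 8.0, 24.0),
    _f("voltage_kV", "kV", "machine", 0.0, 95.4),
    _f("polymer_mw_kDa", "kDa", "material", 1750.36, 1300000.0),
    _f("polymer_density_g_cm3", "g/cm^3", "material", 0.559, 1.53),
    _f("additive_mw_kDa", "kDa", "material", 12.01, 100000.0),
    _f("additive_concentration_wt_pct", "wt%", "material", 0.0, 30.0),
    _f("dox_concentration_wt_pct", "wt%", "material", 0.0, 26.66),
    _f("dielectric_constant", "1", "material", 4.81, 80.1),
    _f("polymer_concentration_wt_pct", "wt%", "material", 0.1, 50.0),
    _f("drug_release_time_d", "day", "study_time", 0.02, 35.0),
    _f("anticancer_study_time_d", "day", "study_time", 0.02, 35.0),
)

FEATURES: tuple[str, ...] = tuple(f.name for f in FEATURE_SCHEMA)

#: The 10 fixed (machine + material) features, excluding study durations.
FIXED_FEATURES: tuple[str, ...] = tuple(
    f.name for f in FEATURE_SCHEMA if f.role != "study_time"
)

#: The 4 labels in canonical order.
LABELS: tuple[str, ...] = (
    "average_diameter_nm",
    "encapsulation_efficiency_pct",
    "drug_release_pct",
    "anticancer_activity_pct",
)

#: Default label bounds (observed min/max of the mined table), original units.
LABEL_BOUNDS: dict[str, tuple[float, float]] = {
    "average_diameter_nm": (37.0, 1500.0),
    "encapsulation_efficiency_pct": (0.031, 99.0),
    "drug_release_pct": (0.1, 99.0),
    "anticancer_activity_pct": (0.07, 90.0),
}

#: Feature set used for each label's surrogate: the 10 fixed features, plus
#: the matching study duration for the two time-dependent outcomes.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "average_diameter_nm": FIXED_FEATURES,
    "encapsulation_efficiency_pct": FIXED_FEATURES,
    "drug_release_pct": FIXED_FEATURES + ("drug_release_time_d",),
    "anticancer_activity_pct": FIXED_FEATURES + ("anticancer_study_time_d",),
}

#: Optimization direction per label: the smallest fiber diameter and the
#: largest encapsulation, release and anticancer activity are sought.
DIRECTIONS: dict[str, str] = {
    "average_diameter_nm": "minimize",
    "encapsulation_efficiency_pct": "maximize",
    "drug_release_pct": "maximize",
    "anticancer_activity_pct": "maximize",
}

SCHEMA_BY_NAME: dict[str, FeatureSchema] = {f.name: f for f in FEATURE_SCHEMA}


def feature_bounds(names: tuple[str, ...] | list[str]) -> list[tuple[float, float]]:
    """Original-unit bounds for the given feature names, in order."""
    return [SCHEMA_BY_NAME[n].bounds for n in names]
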