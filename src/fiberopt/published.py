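"""Reference values reported by the literature-mining study this package re-implements.

The original analysis mined in-vitro/in-vivo reports of doxorubicin-loaded
electrospun nanofibers into a 12-feature / 4-label table, trained one epsilon-SVR
per label, and ran particle-swarm inverse design.  The raw table was never
deposited; what survives are its column summary statistics (five-number
summaries), the final SVR hyperparameters, the PSO coefficients, the per-label
optima, the aggregated optimal ranges, and the test-set error metrics.  Those
printed numbers are collected here verbatim: they calibrate the synthetic-data
generator, seed the pipeline defaults, and serve as internal-consistency
fixtures (RMSE = sqrt(MSE); ranges = min/max over optima).
"""

from __future__ import annotations

import math

from .schema import FIXED_FEATURES, LABELS

#: Five-number summaries (min, q1, median, q3, max) per feature column, in
#: original units.  The published statistics table omits the drug-release-time
#: column; its anchors are borrowed from the anticancer-study-time column
#: (both are study durations on comparable day scales).
FEATURE_ANCHORS: dict[str, tuple[float, float, float, float, float]] = {
    "flow_rate_mL_h": (0.006, 0.5, 0.6, 1.0, 26.0),
    "distance_cm": (8.0, 13.21, 15.0, 15.0, 24.0),
    "voltage_kV": (0.0, 15.0, 20.0, 21.33, 95.4),
    "polymer_mw_kDa": (1750.36, 81000.0, 119250.0, 172000.0, 1300000.0),
    "polymer_density_g_cm3": (0.559, 1.117, 1.19, 1.26, 1.53),
    "additive_mw_kDa": (12.01, 157.24, 234.4, 853.9, 100000.0),
    "additive_concentration_wt_pct": (0.0, 1.0, 4.1151, 5.4762, 30.0),
    "dox_concentration_wt_pct": (0.0, 0.0387, 0.2, 1.8772, 26.66),
    "dielectric_constant": (4.81, 8.55, 16.7, 31.3275, 80.1),
    "polymer_concentration_wt_pct": (0.1, 6.0, 8.0, 10.0, 50.0),
    "drug_release_time_d": (0.02, 1.0, 2.0, 3.0, 35.0),
    "anticancer_study_time_d": (0.02, 1.0, 2.0, 3.0, 35.0),
}

#: Five-number summaries per label column, in original units.
LABEL_ANCHORS: dict[str, tuple[float, float, float, float, float]] = {
    "average_diameter_nm": (37.0, 267.0, 452.34, 750.0, 1500.0),
    "encapsulation_efficiency_pct": (0.031, 0.7327, 2.8, 92.0, 99.0),
    "drug_release_pct": (0.1, 0.7775, 29.0, 60.0, 99.0),
    "anticancer_activity_pct": (0.07, 16.325, 35.25, 54.75, 90.0),
}

#: Final per-label epsilon-SVR hyperparameters (gamma, C, epsilon) of the
#: original analysis; the package's pipeline defaults.
SVR_HYPERPARAMS: dict[str, tuple[float, float, float]] = {
    "average_diameter_nm": (41.50438, 32.19417, 6.44520e-5),
    "encapsulation_efficiency_pct": (1.16007, 30.52169, 1.23861e-3),
    "drug_release_pct": (3.49121, 12.33292, 1.60926e-5),
    "anticancer_activity_pct": (0.85080, 41.04649, 0.08052),
}

#: PSO coefficients of the original analysis (cognitive, social, inertia).
PSO_C1 = 0.4862
PSO_C2 = 2.5067
PSO_OMEGA = -0.2887

#: Reported test-set error metrics per label: (MAE, MSE, RMSE) in original
#: label units.  The anticancer row prints MAE > RMSE, which is impossible for
#: a single evaluation set (power-mean inequality); it is retained verbatim
#: but excluded from consistency checks.
REPORTED_METRICS: dict[str, tuple[float, float, float]] = {
    "average_diameter_nm": (43.74205, 8361.02123, 91.43862),
    "encapsulation_efficiency_pct": (2.35201, 117.63967, 10.84618),
    "drug_release_pct": (3.21023, 47.71458, 6.90757),
    "anticancer_activity_pct": (13.14296, 99.67285, 9.98362),
}

#: Labels whose reported (MSE, RMSE) pair satisfies RMSE = sqrt(MSE).
SELF_CONSISTENT_METRIC_LABELS = (
    "average_diameter_nm",
    "encapsulation_efficiency_pct",
    "drug_release_pct",
)

#: Reported optimal feature vectors, one per label (minimum diameter, maximum
#: for the other three).  Keys follow the schema; study-time features appear
#: only for the label that uses them.
REPORTED_OPTIMA: dict[str, dict[str, float]] = {
    "average_diameter_nm": {
        "polymer_mw_kDa": 80.8597,
        "polymer_density_g_cm3": 1.5299,
        "additive_mw_kDa": 493.0598,
        "additive_concentration_wt_pct": 0.0848,
        "dox_concentration_wt_pct": 1.0044,
        "dielectric_constant": 14.8257,
        "polymer_concentration_wt_pct": 0.2593,
        "flow_rate_mL_h": 0.8129,
        "distance_cm": 15.0380,
        "voltage_kV": 19.9763,
    },
    "encapsulation_efficiency_pct": {
        "polymer_mw_kDa": 474.8010,
        "polymer_density_g_cm3": 1.1960,
        "additive_mw_kDa": 188.3852,
        "additive_concentration_wt_pct": 22.3219,
        "dox_concentration_wt_pct": 9.6091,
        "dielectric_constant": 65.1107,
        "polymer_concentration_wt_pct": 7.1982,
        "flow_rate_mL_h": 15.0100,
        "distance_cm": 13.0735,
        "voltage_kV": 31.2323,
    },
    "drug_release_pct": {
        "polymer_mw_kDa": 318.1338,
        "polymer_density_g_cm3": 1.1983,
        "additive_mw_kDa": 250.7143,
        "additive_concentration_wt_pct": 2.5661,
        "dox_concentration_wt_pct": 2.0584,
        "dielectric_constant": 5.3971,
        "polymer_concentration_wt_pct": 6.6184,
        "flow_rate_mL_h": 19.6483,
        "distance_cm": 14.1093,
        "voltage_kV": 46.1441,
        "drug_release_time_d": 0.2208,
    },
    "anticancer_activity_pct": {
        "polymer_mw_kDa": 262.0249,
        "polymer_density_g_cm3": 1.5207,
        "additive_mw_kDa": 83.3650,
        "additive_concentration_wt_pct": 23.2383,
        "dox_concentration_wt_pct": 3.1828,
        "dielectric_constant": 25.8070,
        "polymer_concentration_wt_pct": 0.1391,
        "flow_rate_mL_h": 6.2994,
        "distance_cm": 19.5443,
        "voltage_kV": 26.7860,
        "anticancer_study_time_d": 15.4382,
    },
}

#: Reported per-feature optimal ranges (printed to two decimals).
REPORTED_RANGES: dict[str, tuple[float, float]] = {
    "polymer_mw_kDa": (80.85, 474.80),
    "polymer_density_g_cm3": (1.19, 1.53),
    "additive_mw_kDa": (83.36, 250.71),
    "additive_concentration_wt_pct": (0.08, 23.23),
    "dox_concentration_wt_pct": (1.01, 9.61),
    "dielectric_constant": (5.39, 65.11),
    "polymer_concentration_wt_pct": (0.14, 7.19),
    "flow_rate_mL_h": (0.81, 19.65),
    "distance_cm": (13.07, 19.54),
    "voltage_kV": (19.97, 46.14),
}


def metric_consistency() -> dict[str, bool]:
    """Check RMSE = sqrt(MSE) per reported label row at printed precision."""
    out = {}
    for label, (_mae, mse, rmse) in REPORTED_METRICS.items():
        out[label] = math.isclose(math.sqrt(mse), rmse, abs_tol=5e-5)
    return out


def check_reported_consistency(tol: float = 0.011) -> dict[str, bool]:
    """Compare strict min/max aggregation of the reported optima with the
    reported optimal ranges, per fixed feature.

    The printed ranges are truncated to two decimals, hence the default
    tolerance of just over 0.01.  One feature (additive molecular weight) is
    known not to satisfy the aggregation rule and is returned as False.
    """
    agreement: dict[str, bool] = {}
    for feat in FIXED_FEATURES:
        vals = [REPORTED_OPTIMA[lbl][feat] for lbl in LABELS]
        lo, hi = min(vals), max(vals)
        ref_lo, ref_hi = REPORTED_RANGES[feat]
        agreement[feat] = abs(lo - ref_lo) <= tol and abs(hi - ref_hi) <= tol
    return agreement
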