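"""Risk-factor-attributable deaths prevented or postponed.

Two attribution methods, following the comparative-risk-assessment convention:

* Continuous factors (total cholesterol mmol/l, systolic blood pressure mmHg,
  BMI kg/m^2): a regression approach. A relative mortality reduction r per
  one-unit fall gives a log-linear coefficient beta = ln(1 - r); a fall of
  Delta units in a stratum with E expected deaths averts
  (1 - exp(beta * Delta)) x E deaths.

* Binary factors (current smoking, physical inactivity, diagnosed diabetes):
  the population attributable risk fraction PARF = P(RR-1) / (1 + P(RR-1));
  DPPs = E x (PARF_base - PARF_final). A rising prevalence yields negative
  DPPs (deaths brought forward).

Joint benefit across factors within a stratum is cumulative, not additive:
the per-factor fractional reductions f_i = DPP_i / E combine as
F = 1 - prod(1 - f_i), and F x E is apportioned back to factors proportionally
to their gross DPPs (signs preserved, sum exact). Finally, for blood pressure
and cholesterol, DPPs already credited to primary-prevention drug treatment
are subtracted so the same averted death is not counted twice.

Risk-factor levels measured in off years can be brought to the index years by
straight-line (least-squares) extrapolation over the survey years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import apportion
from .errors import ConfigurationError, InputValidationError
from .strata import STRATUM_COLS

CONTINUOUS_FACTORS = ("total_cholesterol", "systolic_blood_pressure", "bmi")
BINARY_FACTORS = ("smoking", "physical_inactivity", "diabetes")

CONTINUOUS_COLS = ["factor"] + STRATUM_COLS + ["mean_base", "mean_final", "reduction_per_unit"]
BINARY_COLS = ["factor"] + STRATUM_COLS + ["prev_base", "prev_final", "rr"]

#: Default netting of primary-prevention treatment DPPs out of risk-factor DPPs.
DEFAULT_NET_PAIRS = {
    "systolic_blood_pressure": "hypertension_primary_prevention",
    "total_cholesterol": "hypercholesterolemia_primary_prevention",
}


def log_coefficient(reduction_per_unit):
    """Log-linear coefficient beta = ln(1 - r) for a per-unit reduction r in [0, 1)."""
    r = np.asarray(reduction_per_unit, dtype=float)
    if np.isnan(r).any() or (r < 0).any() or (r >= 1).any():
        raise InputValidationError("reduction_per_unit must lie in [0, 1)")
    out = np.log1p(-r)
    if out.ndim == 0:
        return float(out)
    return out


def continuous_dpp(beta, absolute_fall, expected_deaths):
    """Regression-method DPPs: (1 - exp(beta x fall)) x expected deaths.

    ``absolute_fall`` is mean_base - mean_final: positive when the factor
    improved, so a worsening factor (fall < 0, beta < 0) gives negative DPPs.
    """
    e = np.asarray(expected_deaths, dtype=float)
    if (e < 0).any():
        raise InputValidationError("expected_deaths must be non-negative")
    out = (1.0 - np.exp(np.asarray(beta, float) * np.asarray(absolute_fall, float))) * e
    if out.ndim == 0:
        return float(out)
    return out


def parf(prevalence, rr):
    """Population attributable risk fraction [P(RR-1)] / [1 + P(RR-1)].

    Zero at P = 0 or RR = 1; negative for a protective exposure (RR < 1).
    """
    p = np.asarray(prevalence, dtype=float)
    r = np.asarray(rr, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputValidationError("prevalence must lie in [0, 1]")
    if np.isnan(r).any() or (r <= 0).any():
        raise InputValidationError("relative risk must be positive")
    x = p * (r - 1.0)
    out = x / (1.0 + x)
    if out.ndim == 0:
        return float(out)
    return out


def binary_dpp(parf_base, parf_final, expected_deaths):
    """PARF-method DPPs: expected deaths x (PARF_base - PARF_final)."""
    e = np.asarray(expected_deaths, dtype=float)
    if (e < 0).any():
        raise InputValidationError("expected_deaths must be non-negative")
    out = e * (np.asarray(parf_base, float) - np.asarray(parf_final, float))
    if out.ndim == 0:
        return float(out)
    return out


def interpolate_levels(measurements, target_years, clamp: tuple | None = None):
    """Straight-line (least-squares) fit through survey (year, value) points,
    evaluated at the two index years.

    With exactly two points this is the line through them; more points are fit
    by ordinary least squares. ``clamp=(lo, hi)`` clips extrapolated values to
    a domain (e.g. (0, 1) for prevalences), warning whenever a value is clipped.
    """
    pts = [(float(y), float(v)) for y, v in measurements]
    if len(pts) < 2:
        raise InputValidationError("interpolate_levels: need at least two measurements")
    years = np.array([p[0] for p in pts])
    values = np.array([p[1] for p in pts])
    if len(np.unique(years)) != len(years):
        raise InputValidationError("interpolate_levels: duplicate measurement years")
    slope, intercept = np.polyfit(years, values, 1)
    out = np.array([slope * float(t) + intercept for t in target_years])
    if clamp is not None:
        lo, hi = clamp
        clipped = np.clip(out, lo, hi)
        if (clipped != out).any():
            warnings.warn(
                f"interpolate_levels: extrapolated value clipped to [{lo}, {hi}]",
                stacklevel=2,
            )
        out = clipped
    return tuple(float(v) for v in out)


def joint_adjustment(gross_dpps, expected_deaths: float) -> np.ndarray:
    """Cumulative joint-risk adjustment for one stratum.

    The per-factor fractions f_i = gross_i / expected combine multiplicatively:
    F = 1 - prod(1 - f_i). The joint total F x expected is apportioned back to
    factors proportionally to their gross DPPs, preserving signs; the adjusted
    DPPs sum to F x expected exactly. A single factor passes through unchanged.
    """
    gross = np.asarray(gross_dpps, dtype=float)
    if gross.size == 0:
        return gross
    if expected_deaths < 0:
        raise InputValidationError("joint_adjustment: expected_deaths must be >= 0")
    if expected_deaths == 0:
        if np.any(gross != 0):
            raise InputValidationError(
                "joint_adjustment: nonzero gross DPPs with zero expected deaths"
            )
        return gross
    f = gross / expected_deaths
    if (f >= 1).any():
        raise InputValidationError(
            "joint_adjustment: a single factor cannot avert more than all expected deaths"
        )
    joint_total = (1.0 - np.prod(1.0 - f)) * expected_deaths
    return apportion(joint_total, gross)


def net_of_treatment(gross_rf_dpp, primary_prevention_treatment_dpp):
    """Net risk-factor DPPs after removing the paired treatment's DPPs."""
    out = np.asarray(gross_rf_dpp, float) - np.asarray(primary_prevention_treatment_dpp, float)
    if out.ndim == 0:
        return float(out)
    return out


def validate_risk_factors(
    continuous: pd.DataFrame, binary: pd.DataFrame
) -> list[str]:
    """Schema and domain checks for the two risk-factor tables."""
    problems: list[str] = []
    missing = [c for c in CONTINUOUS_COLS if c not in continuous.columns]
    if missing:
        problems.append(f"risk_continuous: missing columns {missing}")
    else:
        unknown = set(continuous["factor"]) - set(CONTINUOUS_FACTORS)
        if unknown:
            problems.append(f"risk_continuous: unknown factors {sorted(unknown)}")
        if not continuous.empty:
            if (pd.to_numeric(continuous["mean_base"], errors="coerce") <= 0).any() \
                    or (pd.to_numeric(continuous["mean_final"], errors="coerce") <= 0).any():
                problems.append("risk_continuous: means must be positive")
            r = pd.to_numeric(continuous["reduction_per_unit"], errors="coerce")
            if r.isna().any() or (r < 0).any() or (r >= 1).any():
                problems.append("risk_continuous: reduction_per_unit must lie in [0, 1)")
            if continuous.duplicated(subset=["factor"] + STRATUM_COLS).any():
                problems.append("risk_continuous: duplicated (factor, stratum) rows")
    missing = [c for c in BINARY_COLS if c not in binary.columns]
    if missing:
        problems.append(f"risk_binary: missing columns {missing}")
    else:
        unknown = set(binary["factor"]) - set(BINARY_FACTORS)
        if unknown:
            problems.append(f"risk_binary: unknown factors {sorted(unknown)}")
        if not binary.empty:
            for col in ("prev_base", "prev_final"):
                v = pd.to_numeric(binary[col], errors="coerce")
                if v.isna().any() or (v < 0).any() or (v > 1).any():
                    problems.append(f"risk_binary: {col} must lie in [0, 1]")
            rr = pd.to_numeric(binary["rr"], errors="coerce")
            if rr.isna().any() or (rr <= 0).any() or (~np.isfinite(rr)).any():
                problems.append("risk_binary: rr must be finite and positive")
            if binary.duplicated(subset=["factor"] + STRATUM_COLS).any():
                problems.append("risk_binary: duplicated (factor, stratum) rows")
    return problems


def compute_risk_factor_dpps(
    continuous: pd.DataFrame,
    binary: pd.DataFrame,
    expected: pd.DataFrame,
    mode: str = "cumulative",
) -> pd.DataFrame:
    """Per (factor x stratum) gross and joint-adjusted DPPs.

    ``expected`` is the per-stratum expected-deaths frame from
    :func:`impactsec.strata.expected_deaths`. mode='cumulative' applies the
    within-stratum joint adjustment; mode='additive' leaves gross values.
    """
    if mode not in ("cumulative", "additive"):
        raise ConfigurationError(f"unknown joint-risk mode {mode!r}")
    problems = validate_risk_factors(continuous, binary)
    if problems:
        raise InputValidationError("; ".join(problems))

    parts = []
    if not continuous.empty:
        c = continuous.merge(expected, on=STRATUM_COLS, how="left")
        if c["expected"].isna().any():
            raise InputValidationError(
                "risk_continuous: rows reference strata absent from the mortality table"
            )
        beta = log_coefficient(c["reduction_per_unit"])
        fall = c["mean_base"].to_numpy(float) - c["mean_final"].to_numpy(float)
        c["gross"] = continuous_dpp(beta, fall, c["expected"])
        parts.append(c[["factor"] + STRATUM_COLS + ["expected", "gross"]])
    if not binary.empty:
        b = binary.merge(expected, on=STRATUM_COLS, how="left")
        if b["expected"].isna().any():
            raise InputValidationError(
                "risk_binary: rows reference strata absent from the mortality table"
            )
        b["gross"] = binary_dpp(
            parf(b["prev_base"], b["rr"]), parf(b["prev_final"], b["rr"]), b["expected"]
        )
        parts.append(b[["factor"] + STRATUM_COLS + ["expected", "gross"]])
    if not parts:
        return pd.DataFrame(columns=["factor"] + STRATUM_COLS + ["expected", "gross", "dpp"])
    rf = pd.concat(parts, ignore_index=True)

    if mode == "additive":
        rf["dpp"] = rf["gross"]
        return rf

    def _adjust(sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.copy()
        sub["dpp"] = joint_adjustment(sub["gross"].to_numpy(), float(sub["expected"].iloc[0]))
        return sub

    rf = (
        rf.groupby(STRATUM_COLS, sort=False, observed=True, group_keys=False)[rf.columns]
        .apply(_adjust)
        .reset_index(drop=True)
    )
    return rf


def apply_net_of_treatment(
    rf_dpps: pd.DataFrame,
    treatment_dpps: pd.DataFrame,
    pairs: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Add a ``net`` column: DPP minus the paired primary-prevention treatment DPP.

    ``pairs`` maps risk factor -> disease group whose treatment DPPs are
    subtracted, per stratum, before aggregation. Factors without a pairing pass
    through unchanged. Raises :class:`ConfigurationError` if pairs is None
    while paired factors are present (the pairing must be configured).
    """
    out = rf_dpps.copy()
    if out.empty:
        out["net"] = pd.Series(dtype=float)
        return out
    if pairs is None:
        needed = set(out["factor"]) & set(DEFAULT_NET_PAIRS)
        if needed:
            raise ConfigurationError(
                f"net_of_treatment pairing missing from config for factors {sorted(needed)}"
            )
        pairs = {}
    out["net"] = out["dpp"]
    if not pairs:
        return out
    if treatment_dpps is None or treatment_dpps.empty:
        return out
    group_totals = (
        treatment_dpps.groupby(["disease_group"] + STRATUM_COLS, sort=False, observed=True)[
            "dpp"
        ]
        .sum()
        .reset_index()
    )
    for factor, group in pairs.items():
        sub = group_totals[group_totals["disease_group"] == group]
        if sub.empty:
            continue
        merged = out.loc[out["factor"] == factor, STRATUM_COLS].merge(
            sub[STRATUM_COLS + ["dpp"]], on=STRATUM_COLS, how="left"
        )["dpp"].fillna(0.0)
        out.loc[out["factor"] == factor, "net"] = (
            out.loc[out["factor"] == factor, "net"].to_numpy() - merged.to_numpy()
        )
    return out


def risk_factor_table(
    rf_dpps: pd.DataFrame,
    total_dpp: float,
    total_dpp_by_secq: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate risk-factor DPPs per factor and quintile (Table-3 shape).

    Uses the ``net`` column (net of primary-prevention treatment) when present,
    else the joint-adjusted DPPs. Percentages are against the total DPPs.
    """
    value_col = "net" if "net" in rf_dpps.columns else "dpp"
    # canonical row order: smoking, inactivity, SBP, cholesterol, BMI, diabetes
    factors = ["smoking", "physical_inactivity", "systolic_blood_pressure",
               "total_cholesterol", "bmi", "diabetes"]
    if rf_dpps.empty:
        tab = pd.DataFrame(index=pd.Index(factors + ["total_risk_factors"], name="factor"))
        tab["dpp"] = 0.0
        tab["pct_of_total"] = np.nan if total_dpp == 0 else 0.0
        for q in (1, 2, 3, 4, 5):
            tab[f"dpp_secq{q}"] = 0.0
            tab[f"pct_secq{q}"] = np.nan
        return tab
    per_factor = rf_dpps.groupby("factor", sort=False, observed=True)[value_col].sum()
    present = [f for f in factors if f in per_factor.index]
    per_factor = per_factor.reindex(present)
    tab = per_factor.to_frame("dpp")
    tab.loc["total_risk_factors"] = per_factor.sum()
    tab["pct_of_total"] = 100.0 * tab["dpp"] / total_dpp if total_dpp != 0 else np.nan
    by_q = (
        rf_dpps.groupby(["factor", "secq"], sort=False, observed=True)[value_col]
        .sum()
        .unstack("secq")
        .reindex(present)
        .reindex(columns=[1, 2, 3, 4, 5], fill_value=0.0)
        .fillna(0.0)
    )
    by_q.loc["total_risk_factors"] = by_q.sum()
    for q in (1, 2, 3, 4, 5):
        tab[f"dpp_secq{q}"] = by_q[q]
        if total_dpp_by_secq is not None and q in total_dpp_by_secq.index \
                and total_dpp_by_secq[q] != 0:
            tab[f"pct_secq{q}"] = 100.0 * by_q[q] / total_dpp_by_secq[q]
        else:
            tab[f"pct_secq{q}"] = np.nan
    tab.index.name = "factor"
    return tab
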