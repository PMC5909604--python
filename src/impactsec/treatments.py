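"""Treatment-attributable deaths prevented or postponed.

Each of nine mutually exclusive disease groups (patients with more than one
cardiac diagnosis are counted once, in the group with the highest mortality
risk) carries a set of evidence-based treatments. The net effect of one
treatment in one stratum is

    patients x (uptake_final - uptake_base) x compliance x RRR x case_fatality

where RRR is the trial relative risk reduction and case_fatality the one-year
case fatality the RRR acts on. Within a group, benefits of multiple
medications are combined multiplicatively (the Mant-Hicks adjustment,
1 - prod(1 - RRR_i x effective_uptake_i)) so polypharmacy benefit is never
double-counted; the adjusted group DPP is apportioned back to treatments
proportionally to their unadjusted DPPs.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError
from .strata import AGE_BANDS, SECQS, SEXES, STRATUM_COLS

DISEASE_GROUPS = (
    "stemi",
    "nstemi",
    "secondary_prevention_post_mi",
    "secondary_prevention_post_revascularisation",
    "chronic_stable_angina",
    "heart_failure_hospital",
    "heart_failure_community",
    "hypertension_primary_prevention",
    "hypercholesterolemia_primary_prevention",
)

TREATMENT_COLS = ["disease_group", "treatment"] + STRATUM_COLS + [
    "patients",
    "uptake_base",
    "uptake_final",
    "rrr",
    "compliance",
    "case_fatality",
]

_PROPORTION_FIELDS = ("uptake_base", "uptake_final", "compliance", "case_fatality")


def _check_proportion(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise InputValidationError(f"treatment field {name!r} must lie in [0, 1]")
    return arr


def treatment_dpp(patients, uptake_base, uptake_final, compliance, rrr, case_fatality):
    """Net DPPs for one treatment: the uptake-change product formula.

    Negative when uptake fell. Vectorised over aligned array inputs.
    """
    pts = np.asarray(patients, dtype=float)
    if (pts < 0).any():
        raise InputValidationError("treatment field 'patients' must be non-negative")
    ub = _check_proportion("uptake_base", uptake_base)
    uf = _check_proportion("uptake_final", uptake_final)
    c = _check_proportion("compliance", compliance)
    cf = _check_proportion("case_fatality", case_fatality)
    r = np.asarray(rrr, dtype=float)
    if np.isnan(r).any() or (r < 0).any() or (r >= 1).any():
        raise InputValidationError("treatment field 'rrr' must lie in [0, 1)")
    out = pts * (uf - ub) * c * r * cf
    if out.ndim == 0:
        return float(out)
    return out


def mant_hicks_benefit(treatments: Iterable[tuple[float, float]]) -> float:
    """Combined relative benefit of several treatments in one patient group.

    ``treatments`` is an iterable of (rrr, effective_uptake) pairs; the joint
    benefit is 1 - prod(1 - rrr_i x uptake_i), which reduces to rrr x uptake
    for a single treatment and never reaches 1. Empty input gives 0.
    """
    surv = 1.0
    for rrr, uptake in treatments:
        if not (0.0 <= rrr < 1.0):
            raise InputValidationError("mant_hicks_benefit: rrr must lie in [0, 1)")
        if not (0.0 <= uptake <= 1.0):
            raise InputValidationError(
                "mant_hicks_benefit: effective uptake must lie in [0, 1]"
            )
        surv *= 1.0 - rrr * uptake
    return 1.0 - surv


def validate_treatments(df: pd.DataFrame) -> list[str]:
    """Schema and domain checks for a per-stratum treatments table."""
    problems: list[str] = []
    missing = [c for c in TREATMENT_COLS if c not in df.columns]
    if missing:
        return [f"treatments: missing columns {missing}"]
    if df.empty:
        return problems
    unknown = set(df["disease_group"]) - set(DISEASE_GROUPS)
    if unknown:
        problems.append(f"treatments: unknown disease groups {sorted(unknown)}")
    if (set(df["sex"]) - set(SEXES)) or (set(df["age_band"]) - set(AGE_BANDS)) \
            or (set(df["secq"]) - set(SECQS)):
        problems.append("treatments: unknown stratum labels")
    if (df["patients"] < 0).any():
        problems.append("treatments: field 'patients' must be non-negative")
    for col in _PROPORTION_FIELDS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals > 1).any():
            problems.append(f"treatments: field {col!r} must lie in [0, 1]")
    r = pd.to_numeric(df["rrr"], errors="coerce")
    if r.isna().any() or (r < 0).any() or (r >= 1).any():
        problems.append("treatments: field 'rrr' must lie in [0, 1)")
    dup = df.duplicated(subset=["disease_group", "treatment"] + STRATUM_COLS)
    if dup.any():
        problems.append(
            f"treatments: {int(dup.sum())} duplicated (group, treatment, stratum) rows"
        )
    key = ["disease_group"] + STRATUM_COLS
    grp = df.groupby(key, sort=False, observed=True)
    for col in ("patients", "case_fatality"):
        if (grp[col].transform("max") != grp[col].transform("min")).any():
            problems.append(
                f"treatments: {col!r} differs between treatments of the same "
                "disease group and stratum (it is a property of the group)"
            )
    return problems


def compute_treatment_dpps(df: pd.DataFrame, mode: str = "mant_hicks") -> pd.DataFrame:
    """Per-row (treatment x stratum) DPPs for the whole treatments table.

    mode='independent' takes each treatment's uptake-change product on its own;
    mode='mant_hicks' computes the group DPP from the joint benefit at both
    years, patients x [B_final - B_base] x case_fatality, and apportions it to
    treatments proportionally to their independent DPPs.

    Returns the input columns plus ``dpp_independent`` and ``dpp``.
    """
    if mode not in ("independent", "mant_hicks"):
        raise ConfigurationError(f"unknown treatment mode {mode!r}")
    problems = validate_treatments(df)
    if problems:
        raise InputValidationError("; ".join(problems))
    out = df.copy()
    if out.empty:
        out["dpp_independent"] = pd.Series(dtype=float)
        out["dpp"] = pd.Series(dtype=float)
        return out
    indep = treatment_dpp(
        out["patients"], out["uptake_base"], out["uptake_final"],
        out["compliance"], out["rrr"], out["case_fatality"],
    )
    out["dpp_independent"] = indep
    if mode == "independent":
        out["dpp"] = indep
        return out

    key = ["disease_group"] + STRATUM_COLS
    surv_base = 1.0 - out["rrr"] * out["uptake_base"] * out["compliance"]
    surv_final = 1.0 - out["rrr"] * out["uptake_final"] * out["compliance"]
    grp = out.assign(_sb=surv_base, _sf=surv_final, _abs=np.abs(indep)).groupby(
        key, sort=False, observed=True
    )
    prod_base = grp["_sb"].transform("prod")
    prod_final = grp["_sf"].transform("prod")
    group_total = out["patients"] * (prod_base - prod_final) * out["case_fatality"]
    sum_indep = grp["dpp_independent"].transform("sum")
    sum_abs = grp["_abs"].transform("sum")
    n_in_group = grp["dpp_independent"].transform("size")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["dpp"] = np.select(
            [sum_indep != 0.0, sum_abs > 0.0],
            [
                indep / sum_indep * group_total,
                np.abs(indep) / sum_abs * group_total,
            ],
            default=group_total / n_in_group,
        )
    return out


def group_dpp(group_df: pd.DataFrame, mode: str = "mant_hicks"):
    """DPPs for a single disease group: (per-treatment rows, per-stratum totals)."""
    groups = group_df["disease_group"].unique()
    if len(groups) > 1:
        raise InputValidationError(
            f"group_dpp: rows span several disease groups {sorted(groups)}"
        )
    rows = compute_treatment_dpps(group_df, mode=mode)
    totals = (
        rows.groupby(STRATUM_COLS, sort=False, observed=True)["dpp"].sum().reset_index()
    )
    return rows, totals


def treatment_table(
    dpp_rows: pd.DataFrame,
    total_dpp: float,
    total_dpp_by_secq: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate treatment DPPs per disease group and quintile (Table-2 shape).

    Percentages are 100 x group DPP / total DPP (overall, and per quintile
    against that quintile's own total), reported raw; display rounding is a
    rendering concern. With total DPP = 0 percentages are NaN (undefined).
    """
    groups = [g for g in DISEASE_GROUPS]
    if dpp_rows.empty:
        base = pd.DataFrame(index=pd.Index(groups + ["total_treatment"], name="disease_group"))
        base["dpp"] = 0.0
        base["pct_of_total"] = np.nan if total_dpp == 0 else 0.0
        for q in SECQS:
            base[f"dpp_secq{q}"] = 0.0
            base[f"pct_secq{q}"] = np.nan
        return base
    per_group = dpp_rows.groupby("disease_group", sort=False, observed=True)["dpp"].sum()
    per_group = per_group.reindex(groups, fill_value=0.0)
    tab = per_group.to_frame("dpp")
    tab.loc["total_treatment"] = per_group.sum()
    tab["pct_of_total"] = (
        100.0 * tab["dpp"] / total_dpp if total_dpp != 0 else np.nan
    )
    by_q = (
        dpp_rows.groupby(["disease_group", "secq"], sort=False, observed=True)["dpp"]
        .sum()
        .unstack("secq")
        .reindex(groups, fill_value=0.0)
        .reindex(columns=list(SECQS), fill_value=0.0)
        .fillna(0.0)
    )
    by_q.loc["total_treatment"] = by_q.sum()
    for q in SECQS:
        tab[f"dpp_secq{q}"] = by_q[q]
        if total_dpp_by_secq is not None and q in total_dpp_by_secq.index \
                and total_dpp_by_secq[q] != 0:
            tab[f"pct_secq{q}"] = 100.0 * by_q[q] / total_dpp_by_secq[q]
        else:
            tab[f"pct_secq{q}"] = np.nan
    tab.index.name = "disease_group"
    return tab
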