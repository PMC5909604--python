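"""End-to-end orchestration: validate inputs, decompose the mortality decline,
and render Table-1/2/3-style outputs with an explained-share summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_away
from .config import ModelConfig
from .errors import InputValidationError
from .risk_factors import (
    apply_net_of_treatment,
    compute_risk_factor_dpps,
    risk_factor_table,
    validate_risk_factors,
)
from .strata import (
    SECQS,
    STRATUM_COLS,
    dpp_by_stratum,
    expected_deaths,
    mortality_summary,
    validate_mortality,
)
from .treatments import compute_treatment_dpps, treatment_table, validate_treatments


def validate_inputs(inputs: dict) -> list[str]:
    """Consolidated validation report over the whole input bundle."""
    problems = validate_mortality(inputs["mortality"])
    problems += validate_treatments(inputs.get("treatments", pd.DataFrame(
        columns=["disease_group", "treatment"] + STRATUM_COLS
        + ["patients", "uptake_base", "uptake_final", "rrr", "compliance", "case_fatality"])))
    cont = inputs.get("risk_continuous")
    binr = inputs.get("risk_binary")
    if cont is not None or binr is not None:
        from .risk_factors import BINARY_COLS, CONTINUOUS_COLS

        cont = cont if cont is not None else pd.DataFrame(columns=CONTINUOUS_COLS)
        binr = binr if binr is not None else pd.DataFrame(columns=BINARY_COLS)
        problems += validate_risk_factors(cont, binr)
    # cross-table: risk-factor strata must exist in the mortality table
    strata = set(map(tuple, inputs["mortality"][STRATUM_COLS].itertuples(index=False)))
    for key, label in (("risk_continuous", "risk_continuous"), ("risk_binary", "risk_binary")):
        df = inputs.get(key)
        if df is not None and not df.empty and all(c in df.columns for c in STRATUM_COLS):
            extra = set(map(tuple, df[STRATUM_COLS].itertuples(index=False))) - strata
            if extra:
                problems.append(
                    f"{label}: {len(extra)} strata absent from the mortality table"
                )
    return problems


@dataclass
class DecompositionResult:
    """All outputs of one model run."""

    mortality: pd.DataFrame                 # Table-1 shape summary
    dpp_stratum: pd.DataFrame               # per-stratum expected + DPP
    treatment_dpps: pd.DataFrame            # per (treatment x stratum) rows
    treatment_summary: pd.DataFrame         # Table-2 shape
    risk_factor_dpps: pd.DataFrame          # per (factor x stratum) rows
    risk_factor_summary: pd.DataFrame       # Table-3 shape
    totals: dict = field(default_factory=dict)
    config: ModelConfig = field(default_factory=ModelConfig)
    manifest: dict | None = None

    def render_summary(self) -> str:
        t = self.totals
        lines = [
            "IMPACT-style CHD mortality decomposition",
            f"  total DPPs (expected - observed): {round_half_away(t['total_dpp']):.0f}",
            f"  treatment contribution:          {round_half_away(t['treatment_dpp']):.0f}"
            f" ({t['treatment_share_pct']:.1f}%)" if np.isfinite(t["treatment_share_pct"])
            else f"  treatment contribution:          {round_half_away(t['treatment_dpp']):.0f}",
            f"  risk-factor contribution (net):  {round_half_away(t['risk_factor_dpp']):.0f}"
            f" ({t['risk_factor_share_pct']:.1f}%)" if np.isfinite(t["risk_factor_share_pct"])
            else f"  risk-factor contribution (net):  {round_half_away(t['risk_factor_dpp']):.0f}",
        ]
        if np.isfinite(t["explained_share_pct"]):
            lines.append(
                f"  explained share of the decline:  {t['explained_share_pct']:.1f}%"
                f" (unexplained {100 - t['explained_share_pct']:.1f}%)"
            )
        return "\n".join(lines)


def run_pipeline(inputs: dict, config: ModelConfig | None = None) -> DecompositionResult:
    """Run the full decomposition on a validated input bundle.

    Produces per-stratum and aggregate DPPs, the treatment and risk-factor
    contribution tables, and the explained share
    (treatment DPPs + net risk-factor DPPs) / total DPPs.
    """
    config = config or ModelConfig()
    problems = validate_inputs(inputs)
    if problems:
        raise InputValidationError(
            "input validation failed:\n  " + "\n  ".join(problems)
        )
    mortality = inputs["mortality"]
    treatments = inputs.get("treatments")
    if treatments is None:
        treatments = pd.DataFrame(
            columns=["disease_group", "treatment"] + STRATUM_COLS
            + ["patients", "uptake_base", "uptake_final", "rrr", "compliance", "case_fatality"])
    if config.compliance_overrides and not treatments.empty:
        treatments = treatments.copy()
        for group, value in config.compliance_overrides.items():
            treatments.loc[treatments["disease_group"] == group, "compliance"] = value

    summary = mortality_summary(
        mortality,
        reference=inputs.get("reference_weights"),
        method=config.standardisation,
    )
    stratum = dpp_by_stratum(mortality)
    total = float(stratum["dpp"].sum())
    by_secq = stratum.groupby("secq", observed=True)["dpp"].sum()

    treat = compute_treatment_dpps(treatments, mode=config.treatment_mode)
    exp = expected_deaths(mortality)
    rf = compute_risk_factor_dpps(
        inputs.get("risk_continuous", pd.DataFrame(columns=["factor"] + STRATUM_COLS
                   + ["mean_base", "mean_final", "reduction_per_unit"])),
        inputs.get("risk_binary", pd.DataFrame(columns=["factor"] + STRATUM_COLS
                   + ["prev_base", "prev_final", "rr"])),
        exp,
        mode=config.joint_risk,
    )
    rf = apply_net_of_treatment(rf, treat, config.net_of_treatment_pairs)

    treat_tab = treatment_table(treat, total, by_secq)
    rf_tab = risk_factor_table(rf, total, by_secq)

    treatment_total = float(treat["dpp"].sum()) if not treat.empty else 0.0
    rf_total = float(rf["net"].sum()) if not rf.empty else 0.0
    explained = treatment_total + rf_total
    totals = {
        "expected_deaths": float(stratum["expected"].sum()),
        "observed_deaths": float(mortality["deaths_final"].sum()),
        "total_dpp": total,
        "treatment_dpp": treatment_total,
        "risk_factor_dpp": rf_total,
        "explained_dpp": explained,
        "treatment_share_pct": 100.0 * treatment_total / total if total != 0 else np.nan,
        "risk_factor_share_pct": 100.0 * rf_total / total if total != 0 else np.nan,
        "explained_share_pct": 100.0 * explained / total if total != 0 else np.nan,
    }
    return DecompositionResult(
        mortality=summary,
        dpp_stratum=stratum,
        treatment_dpps=treat,
        treatment_summary=treat_tab,
        risk_factor_dpps=rf,
        risk_factor_summary=rf_tab,
        totals=totals,
        config=config,
    )


def decomposition_totals(inputs: dict, config: ModelConfig | None = None) -> dict:
    """The pipeline reduced to its headline scalars (Monte Carlo model hook)."""
    res = run_pipeline(inputs, config)
    return res.totals


def equity_summary(result: DecompositionResult) -> pd.DataFrame:
    """Per-quintile DPPs, contribution shares, and rate reductions.

    Flags (in ``attrs``) whether the treatment and risk-factor shares change
    monotonically from the most affluent (secq 1) to the most deprived (secq 5)
    quintile.
    """
    strat = result.dpp_stratum
    quintiles = sorted(strat["secq"].unique())
    if len(quintiles) < 2:
        raise InputValidationError("equity_summary: needs at least two quintiles")
    dpp_q = strat.groupby("secq", observed=True)["dpp"].sum()
    treat_q = (
        result.treatment_dpps.groupby("secq", observed=True)["dpp"].sum()
        if not result.treatment_dpps.empty else pd.Series(dtype=float)
    ).reindex(quintiles, fill_value=0.0)
    rf_col = "net" if "net" in result.risk_factor_dpps.columns else "dpp"
    rf_q = (
        result.risk_factor_dpps.groupby("secq", observed=True)[rf_col].sum()
        if not result.risk_factor_dpps.empty else pd.Series(dtype=float)
    ).reindex(quintiles, fill_value=0.0)
    rows = []
    for q in quintiles:
        total = dpp_q[q]
        label = f"secq_{q}"
        mort = result.mortality.loc[label] if label in result.mortality.index else None
        rows.append({
            "secq": q,
            "dpp": total,
            "treatment_dpp": treat_q[q],
            "risk_factor_dpp": rf_q[q],
            "treatment_share_pct": 100.0 * treat_q[q] / total if total != 0 else np.nan,
            "risk_factor_share_pct": 100.0 * rf_q[q] / total if total != 0 else np.nan,
            "explained_share_pct": 100.0 * (treat_q[q] + rf_q[q]) / total
            if total != 0 else np.nan,
            "abs_reduction": mort["abs_reduction"] if mort is not None else np.nan,
            "rel_reduction": mort["rel_reduction"] if mort is not None else np.nan,
        })
    out = pd.DataFrame(rows).set_index("secq")

    def _monotone(series: pd.Series) -> str:
        vals = series.to_numpy()
        if np.all(np.diff(vals) < 0):
            return "decreasing"
        if np.all(np.diff(vals) > 0):
            return "increasing"
        return "none"

    out.attrs["treatment_share_gradient"] = _monotone(out["treatment_share_pct"])
    out.attrs["risk_factor_share_gradient"] = _monotone(out["risk_factor_share_pct"])
    return out


def write_outputs(result: DecompositionResult, outdir, manifest: dict | None = None) -> None:
    """Write the machine-readable output bundle (raw values, full precision).

    Display-rounded companions (DPPs to integers, shares to one decimal,
    half-away-from-zero) are written alongside with a ``_display`` suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.mortality.to_csv(outdir / "mortality_summary.csv")
    result.dpp_stratum.to_csv(outdir / "dpp_by_stratum.csv", index=False)
    result.treatment_dpps.to_csv(outdir / "treatment_dpps.csv", index=False)
    result.treatment_summary.to_csv(outdir / "treatment_summary.csv")
    result.risk_factor_dpps.to_csv(outdir / "risk_factor_dpps.csv", index=False)
    result.risk_factor_summary.to_csv(outdir / "risk_factor_summary.csv")

    for name, tab in (("treatment_summary", result.treatment_summary),
                      ("risk_factor_summary", result.risk_factor_summary)):
        disp = tab.copy()
        for col in disp.columns:
            if col.startswith("dpp"):
                disp[col] = round_half_away(disp[col].to_numpy(), 0)
            elif col.startswith("pct"):
                disp[col] = round_half_away(disp[col].to_numpy(), 1)
        disp.to_csv(outdir / f"{name}_display.csv")
    (outdir / "summary.txt").write_text(result.render_summary() + "\n")
    if manifest is not None:
        from .io import write_manifest

        write_manifest(manifest, outdir / "manifest.json")
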