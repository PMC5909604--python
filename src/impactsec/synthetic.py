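"""Synthetic input bundles emulating a registry-based CHD mortality study.

Generates internally consistent model inputs over the full 60-stratum grid
(2 sexes x 6 age bands x 5 income quintiles): population and CHD death counts
for two index years, per-disease-group treatment uptake tables, and continuous
and binary risk-factor tables. The defaults emulate the study conditions:
equal quintile populations, a steep age gradient in mortality, roughly a
two-fold mortality-rate gradient from the most affluent to the most deprived
quintile, an overall mortality decline of about 75% slightly favouring the
affluent, a cholesterol fall of about 1.2 mmol/l, a modest blood-pressure
fall, falling smoking and inactivity, and rising BMI and diabetes. All
treatment uptakes, relative risk reductions, case fatalities and risk-factor
effect sizes are illustrative magnitudes (only one worked value per method is
published for the Danish study), not Danish estimates.

The generator is deterministic under its seed. Optional noise jitters
proportions on the logit scale and positive quantities on the log scale, so
generated values always stay within their domains.

Also provides ``paper_fixture`` (the three published worked-example input
rows) and ``generate_known_truth``, which rewrites the observed final-year
deaths so the share of the mortality decline explained by the model is known
exactly by construction — the basis for closure/recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ModelConfig
from .errors import GenerationError
from .risk_factors import apply_net_of_treatment, compute_risk_factor_dpps
from .strata import AGE_BANDS, SECQS, SEXES, STRATUM_COLS, expected_deaths, full_grid
from .treatments import compute_treatment_dpps

# Illustrative base-year CHD mortality per 100,000 by sex and age band.
_BASE_RATE = {
    "male": {"25-34": 8.0, "35-44": 40.0, "45-54": 160.0, "55-64": 430.0,
             "65-74": 1100.0, "75-84": 2600.0},
    "female": {"25-34": 3.0, "35-44": 12.0, "45-54": 55.0, "55-64": 180.0,
               "65-74": 620.0, "75-84": 2000.0},
}

# Treatment catalogue: disease group -> (treatment, rrr, uptake_base, uptake_final).
_CATALOGUE = {
    "stemi": [
        ("aspirin", 0.23, 0.14, 0.97),
        ("thrombolysis", 0.25, 0.05, 0.35),
        ("ace_inhibitor", 0.20, 0.02, 0.60),
    ],
    "nstemi": [
        ("aspirin", 0.20, 0.12, 0.90),
        ("beta_blocker", 0.13, 0.10, 0.70),
    ],
    "secondary_prevention_post_mi": [
        ("aspirin", 0.25, 0.30, 0.90),
        ("beta_blocker", 0.23, 0.20, 0.70),
        ("statin", 0.22, 0.00, 0.80),
    ],
    "secondary_prevention_post_revascularisation": [
        ("aspirin", 0.25, 0.40, 0.92),
        ("statin", 0.22, 0.02, 0.85),
    ],
    "chronic_stable_angina": [
        ("aspirin", 0.15, 0.25, 0.75),
        ("statin", 0.22, 0.00, 0.70),
        ("revascularisation", 0.20, 0.05, 0.25),
    ],
    "heart_failure_hospital": [
        ("ace_inhibitor", 0.20, 0.25, 0.80),
        ("beta_blocker", 0.30, 0.02, 0.55),
        ("spironolactone", 0.30, 0.00, 0.30),
    ],
    "heart_failure_community": [
        ("ace_inhibitor", 0.20, 0.15, 0.70),
        ("beta_blocker", 0.30, 0.01, 0.45),
    ],
    "hypertension_primary_prevention": [
        ("antihypertensive_therapy", 0.13, 0.20, 0.55),
    ],
    "hypercholesterolemia_primary_prevention": [
        ("statin", 0.22, 0.00, 0.25),
    ],
}

# Per-group one-year case fatality at ages 55-64 and compliance defaults
# (hospital-administered treatment is taken as fully complied with).
_GROUP_PARAMS = {
    "stemi": {"cf": 0.34, "compliance": 1.0, "prev": 0.0020},
    "nstemi": {"cf": 0.25, "compliance": 1.0, "prev": 0.0022},
    "secondary_prevention_post_mi": {"cf": 0.06, "compliance": 0.85, "prev": 0.012},
    "secondary_prevention_post_revascularisation": {"cf": 0.05, "compliance": 0.85, "prev": 0.008},
    "chronic_stable_angina": {"cf": 0.04, "compliance": 0.85, "prev": 0.015},
    "heart_failure_hospital": {"cf": 0.35, "compliance": 1.0, "prev": 0.004},
    "heart_failure_community": {"cf": 0.15, "compliance": 0.85, "prev": 0.012},
    "hypertension_primary_prevention": {"cf": 0.015, "compliance": 0.70, "prev": 0.18},
    "hypercholesterolemia_primary_prevention": {"cf": 0.010, "compliance": 0.70, "prev": 0.25},
}

_CF_AGE_MULT = {"25-34": 0.15, "35-44": 0.30, "45-54": 0.60, "55-64": 1.0,
                "65-74": 1.6, "75-84": 2.6}
_PREV_AGE_MULT = {"25-34": 0.03, "35-44": 0.10, "45-54": 0.35, "55-64": 1.0,
                  "65-74": 1.8, "75-84": 2.6}

# Continuous risk factors: per-age mean levels, per-age relative mortality
# reduction per unit fall, and a deprivation tilt added linearly to q5.
_CONTINUOUS = {
    "total_cholesterol": {
        "means": {"25-34": 5.2, "35-44": 5.7, "45-54": 6.1, "55-64": 6.4,
                  "65-74": 6.5, "75-84": 6.4},
        "reduction": {"25-34": 0.50, "35-44": 0.45, "45-54": 0.40, "55-64": 0.35,
                      "65-74": 0.28, "75-84": 0.20},
        "tilt": 0.25,
    },
    "systolic_blood_pressure": {
        "means": {"25-34": 124.0, "35-44": 128.0, "45-54": 133.0, "55-64": 138.0,
                  "65-74": 144.0, "75-84": 150.0},
        "reduction": {"25-34": 0.035, "35-44": 0.032, "45-54": 0.028, "55-64": 0.024,
                      "65-74": 0.018, "75-84": 0.012},
        "tilt": 4.0,
    },
    "bmi": {
        "means": {"25-34": 24.5, "35-44": 25.2, "45-54": 25.9, "55-64": 26.4,
                  "65-74": 26.6, "75-84": 26.3},
        "reduction": {"25-34": 0.050, "35-44": 0.045, "45-54": 0.040, "55-64": 0.035,
                      "65-74": 0.025, "75-84": 0.015},
        "tilt": 1.0,
    },
}

# Binary risk factors: per-age prevalences and relative risks; deprivation
# tilt added to the prevalence in q5.
_BINARY = {
    "smoking": {
        "prev": {"25-34": 0.42, "35-44": 0.44, "45-54": 0.46, "55-64": 0.45,
                 "65-74": 0.40, "75-84": 0.32},
        "rr": {"25-34": 3.2, "35-44": 2.9, "45-54": 2.5, "55-64": 2.1,
               "65-74": 1.7, "75-84": 1.4},
        "tilt": 0.08,
    },
    "physical_inactivity": {
        "prev": {"25-34": 0.25, "35-44": 0.27, "45-54": 0.30, "55-64": 0.33,
                 "65-74": 0.38, "75-84": 0.45},
        "rr": {"25-34": 1.9, "35-44": 1.8, "45-54": 1.7, "55-64": 1.6,
               "65-74": 1.5, "75-84": 1.4},
        "tilt": 0.10,
    },
    "diabetes": {
        "prev": {"25-34": 0.004, "35-44": 0.008, "45-54": 0.018, "55-64": 0.030,
                 "65-74": 0.043, "75-84": 0.055},
        "rr": {"25-34": 2.6, "35-44": 2.4, "45-54": 2.1, "55-64": 1.95,
               "65-74": 1.86, "75-84": 1.5},
        "tilt": 0.30,  # relative: q5 prevalence = (1 + tilt) x q1 prevalence
    },
}


@dataclass
class ScenarioConfig:
    """Study conditions for the synthetic-data generator.

    The mortality gradient is the rate ratio of the most deprived to the most
    affluent quintile; relative declines give the fraction by which mortality
    rates fall from the base to the final year in quintiles 1 and 5 (linear in
    between). Risk-factor changes are in natural units (mmol/l, mmHg, kg/m^2,
    prevalence points; diabetes grows multiplicatively). ``noise`` is the
    standard deviation of logit/log-scale jitter applied to generated
    quantities (0 = fully structural generation). ``truth_residual`` is the
    unexplained share of DPPs built into known-truth scenarios.
    """

    seed: int = 20070
    base_year: int = 1991
    final_year: int = 2007
    mortality_gradient: float = 2.0
    relative_decline_affluent: float = 0.78
    relative_decline_deprived: float = 0.71
    population_range: tuple = (45_000, 62_000)
    population_growth: float = 1.08
    uptake_secq_gap: float = 0.10
    patient_scale: float = 0.5
    cholesterol_fall: float = 1.2
    sbp_fall: float = 4.0
    bmi_rise: float = 0.8
    smoking_fall: float = 0.12
    inactivity_fall: float = 0.05
    diabetes_growth: float = 1.9
    risk_tilt_scale: float = 1.0  # scales the deprivation tilt on risk-factor levels
    noise: float = 0.0
    truth_residual: float = 0.36

    def __post_init__(self):
        if not (0 <= self.truth_residual < 1):
            raise GenerationError("truth_residual must lie in [0, 1)")
        if self.mortality_gradient <= 0:
            raise GenerationError("mortality_gradient must be positive")
        for d in (self.relative_decline_affluent, self.relative_decline_deprived):
            if not (0 <= d < 1):
                raise GenerationError("relative declines must lie in [0, 1)")


def _q_frac(q: int) -> float:
    return (q - 1) / (len(SECQS) - 1)


def _logit_jitter(values, rng, sd):
    v = np.clip(np.asarray(values, dtype=float), 1e-9, 1 - 1e-9)
    if sd == 0:
        return np.asarray(values, dtype=float)
    z = np.log(v / (1 - v)) + rng.normal(0.0, sd, size=v.shape)
    return 1.0 / (1.0 + np.exp(-z))


def _log_jitter(values, rng, sd):
    v = np.asarray(values, dtype=float)
    if sd == 0:
        return v
    return v * np.exp(rng.normal(0.0, sd, size=v.shape))


def _mortality_table(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    grid = full_grid()
    lo, hi = cfg.population_range
    # one population draw per (sex, age) cell, shared by all quintiles (Table-1
    # structure: quintiles are equal-sized by construction)
    cell_pop = {
        (sex, age): float(rng.integers(lo, hi + 1))
        for sex in SEXES
        for age in AGE_BANDS
    }
    rows = []
    for _, s in grid.iterrows():
        sex, age, q = s["sex"], s["age_band"], int(s["secq"])
        pop_base = cell_pop[(sex, age)]
        pop_final = pop_base * cfg.population_growth
        rate_base = (_BASE_RATE[sex][age] / 1e5) * cfg.mortality_gradient ** _q_frac(q)
        decline = cfg.relative_decline_affluent + (
            cfg.relative_decline_deprived - cfg.relative_decline_affluent
        ) * _q_frac(q)
        rate_final = rate_base * (1.0 - decline)
        if cfg.noise > 0:
            rate_base = float(_log_jitter(rate_base, rng, cfg.noise))
            rate_final = float(_log_jitter(rate_final, rng, cfg.noise))
        deaths_base = float(np.round(rate_base * pop_base))
        deaths_final = float(np.round(rate_final * pop_final))
        if deaths_base > pop_base or deaths_final > pop_final:
            raise GenerationError(
                f"infeasible mortality configuration: deaths exceed population "
                f"in (sex={sex}, age_band={age}, secq={q})"
            )
        rows.append((sex, age, q, pop_base, pop_final, deaths_base, deaths_final))
    return pd.DataFrame(rows, columns=STRATUM_COLS
                        + ["pop_base", "pop_final", "deaths_base", "deaths_final"])


def _treatments_table(cfg: ScenarioConfig, mortality: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pop_final = mortality.set_index(STRATUM_COLS)["pop_final"]
    for group, treatments in _CATALOGUE.items():
        params = _GROUP_PARAMS[group]
        for _, s in full_grid().iterrows():
            sex, age, q = s["sex"], s["age_band"], int(s["secq"])
            prev = params["prev"] * _PREV_AGE_MULT[age]
            if group not in ("hypertension_primary_prevention",
                             "hypercholesterolemia_primary_prevention"):
                prev *= cfg.mortality_gradient ** _q_frac(q)  # more disease when deprived
            patients = pop_final[(sex, age, q)] * prev * cfg.patient_scale
            if cfg.noise > 0:
                patients = float(_log_jitter(patients, rng, cfg.noise))
            patients = float(np.round(patients))
            cf = min(params["cf"] * _CF_AGE_MULT[age] * (0.85 if sex == "female" else 1.0), 0.95)
            for name, rrr, ub, uf in treatments:
                uf_q = np.clip(uf - cfg.uptake_secq_gap * _q_frac(q), 0.0, 0.99)
                ub_q, uf_q = float(ub), float(uf_q)
                if cfg.noise > 0:
                    ub_q = float(_logit_jitter(max(ub_q, 1e-4), rng, cfg.noise))
                    uf_q = float(_logit_jitter(uf_q, rng, cfg.noise))
                rows.append((group, name, sex, age, q, patients, ub_q, uf_q,
                             rrr, params["compliance"], cf))
    return pd.DataFrame(
        rows,
        columns=["disease_group", "treatment"] + STRATUM_COLS
        + ["patients", "uptake_base", "uptake_final", "rrr", "compliance", "case_fatality"],
    )


def _risk_factor_tables(cfg: ScenarioConfig, rng: np.random.Generator):
    falls = {"total_cholesterol": cfg.cholesterol_fall,
             "systolic_blood_pressure": cfg.sbp_fall,
             "bmi": -cfg.bmi_rise}
    cont_rows, bin_rows = [], []
    for _, s in full_grid().iterrows():
        sex, age, q = s["sex"], s["age_band"], int(s["secq"])
        for factor, spec in _CONTINUOUS.items():
            mean_base = spec["means"][age] \
                + spec["tilt"] * cfg.risk_tilt_scale * _q_frac(q)
            mean_final = mean_base - falls[factor]
            if cfg.noise > 0:
                mean_base = float(_log_jitter(mean_base, rng, cfg.noise))
                mean_final = float(_log_jitter(mean_final, rng, cfg.noise))
            cont_rows.append((factor, sex, age, q, mean_base, mean_final,
                              spec["reduction"][age]))
        for factor, spec in _BINARY.items():
            tilt = spec["tilt"] * cfg.risk_tilt_scale
            if factor == "diabetes":
                prev_base = spec["prev"][age] * (1.0 + tilt * _q_frac(q))
                prev_final = min(prev_base * cfg.diabetes_growth, 0.99)
            else:
                prev_base = min(spec["prev"][age] + tilt * _q_frac(q), 0.99)
                fall = cfg.smoking_fall if factor == "smoking" else cfg.inactivity_fall
                prev_final = max(prev_base - fall, 0.0)
            if cfg.noise > 0:
                prev_base = float(_logit_jitter(prev_base, rng, cfg.noise))
                prev_final = float(_logit_jitter(prev_final, rng, cfg.noise))
            bin_rows.append((factor, sex, age, q, prev_base, prev_final, spec["rr"][age]))
    continuous = pd.DataFrame(
        cont_rows, columns=["factor"] + STRATUM_COLS
        + ["mean_base", "mean_final", "reduction_per_unit"])
    binary = pd.DataFrame(
        bin_rows, columns=["factor"] + STRATUM_COLS + ["prev_base", "prev_final", "rr"])
    return continuous, binary


def generate_scenario(config: ScenarioConfig | None = None) -> dict:
    """Generate a complete input bundle; deterministic under ``config.seed``."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    mortality = _mortality_table(cfg, rng)
    treatments = _treatments_table(cfg, mortality, rng)
    continuous, binary = _risk_factor_tables(cfg, rng)
    return {
        "mortality": mortality,
        "treatments": treatments,
        "risk_continuous": continuous,
        "risk_binary": binary,
    }


def paper_fixture() -> dict:
    """The three published worked-example input rows.

    aspirin: STEMI, men 55-64, most deprived quintile — 147 patients, uptake
    14% -> 97%, compliance 1, RRR 23%, one-year case fatality 34% (9.5 DPPs).
    cholesterol: women 55-64, most deprived — mean 7.04 -> 5.76 mmol/l, 35%
    mortality reduction per mmol/l, 176 expected deaths (75 DPPs).
    diabetes: men 65-74, most deprived — prevalence 4.3% -> 8.2%, RR 1.86,
    874 expected deaths (-26 DPPs).
    """
    return {
        "aspirin": {
            "disease_group": "stemi", "treatment": "aspirin",
            "sex": "male", "age_band": "55-64", "secq": 5,
            "patients": 147.0, "uptake_base": 0.14, "uptake_final": 0.97,
            "rrr": 0.23, "compliance": 1.0, "case_fatality": 0.34,
        },
        "cholesterol": {
            "factor": "total_cholesterol",
            "sex": "female", "age_band": "55-64", "secq": 5,
            "mean_base": 7.04, "mean_final": 5.76, "reduction_per_unit": 0.35,
            "expected_deaths": 176.0,
        },
        "diabetes": {
            "factor": "diabetes",
            "sex": "male", "age_band": "65-74", "secq": 5,
            "prev_base": 0.043, "prev_final": 0.082, "rr": 1.86,
            "expected_deaths": 874.0,
        },
    }


def paper_fixture_bundle() -> dict:
    """A minimal three-stratum input bundle embedding the worked-example rows.

    Base-year populations equal final-year populations, and base-year deaths
    equal the published expected deaths, so the expected final-year deaths in
    each stratum are exactly the published figures.
    """
    fx = paper_fixture()
    mortality = pd.DataFrame(
        [
            ("male", "55-64", 5, 100_000.0, 100_000.0, 500.0, 150.0),
            ("female", "55-64", 5, 100_000.0, 100_000.0, 176.0, 53.0),
            ("male", "65-74", 5, 100_000.0, 100_000.0, 874.0, 262.0),
        ],
        columns=STRATUM_COLS + ["pop_base", "pop_final", "deaths_base", "deaths_final"],
    )
    treatments = pd.DataFrame([fx["aspirin"]])[
        ["disease_group", "treatment"] + STRATUM_COLS
        + ["patients", "uptake_base", "uptake_final", "rrr", "compliance", "case_fatality"]
    ]
    continuous = pd.DataFrame([{k: v for k, v in fx["cholesterol"].items()
                                if k != "expected_deaths"}])[
        ["factor"] + STRATUM_COLS + ["mean_base", "mean_final", "reduction_per_unit"]
    ]
    binary = pd.DataFrame([{k: v for k, v in fx["diabetes"].items()
                            if k != "expected_deaths"}])[
        ["factor"] + STRATUM_COLS + ["prev_base", "prev_final", "rr"]
    ]
    return {
        "mortality": mortality,
        "treatments": treatments,
        "risk_continuous": continuous,
        "risk_binary": binary,
    }


def generate_known_truth(
    config: ScenarioConfig | None = None,
    residual: float | None = None,
    model_config: ModelConfig | None = None,
) -> tuple[dict, dict]:
    """Scenario whose explained share of DPPs is known exactly by construction.

    The generated final-year observed deaths are rewritten so that the
    modelled DPPs (treatments plus net risk factors, computed with the same
    accounting the pipeline uses) make up exactly ``1 - residual`` of the
    aggregate total DPPs. The unexplained DPPs, total_modelled x
    residual/(1 - residual), are distributed over strata proportionally to
    each stratum's headroom (expected - modelled deaths), so observed counts
    stay non-negative whenever every stratum's modelled fractional reduction
    is below 1. With residual 0 the model explains the whole decline and
    observed = expected - modelled in every stratum.

    Returns (inputs, truth) where truth records the target explained share (%)
    and the construction's modelled and total DPPs.
    """
    cfg = config or ScenarioConfig()
    if residual is None:
        residual = cfg.truth_residual
    if not (0 <= residual < 1):
        raise GenerationError("residual must lie in [0, 1)")
    mc = model_config or ModelConfig()
    inputs = generate_scenario(cfg)
    mortality = inputs["mortality"]
    exp = expected_deaths(mortality)

    treat = compute_treatment_dpps(inputs["treatments"], mode=mc.treatment_mode)
    rf = compute_risk_factor_dpps(
        inputs["risk_continuous"], inputs["risk_binary"], exp, mode=mc.joint_risk
    )
    rf = apply_net_of_treatment(rf, treat, mc.net_of_treatment_pairs)

    by_stratum = exp.set_index(STRATUM_COLS)["expected"].to_frame()
    by_stratum["modelled"] = (
        treat.groupby(STRATUM_COLS, observed=True)["dpp"].sum()
        .add(rf.groupby(STRATUM_COLS, observed=True)["net"].sum(), fill_value=0.0)
        .reindex(by_stratum.index, fill_value=0.0)
    )
    frac = np.where(by_stratum["expected"] > 0,
                    by_stratum["modelled"] / by_stratum["expected"], 0.0)
    if (frac >= 1.0).any():
        raise GenerationError(
            "modelled fractional reduction reaches 1 in at least one stratum"
        )
    modelled_total = float(by_stratum["modelled"].sum())
    target_total = modelled_total / (1.0 - residual)
    unexplained_total = target_total - modelled_total
    headroom = by_stratum["expected"] - by_stratum["modelled"]
    headroom_total = float(headroom.sum())
    if unexplained_total > headroom_total:
        raise GenerationError(
            "infeasible residual: unexplained DPPs exceed the available headroom"
        )
    unexplained = (headroom / headroom_total * unexplained_total
                   if headroom_total > 0 else headroom * 0.0)
    target_dpp = by_stratum["modelled"] + unexplained
    observed = by_stratum["expected"] - target_dpp
    if (observed < 0).any():
        raise GenerationError(
            "infeasible residual: implied observed deaths negative in at least one stratum"
        )
    mortality = mortality.set_index(STRATUM_COLS)
    if (observed > mortality["pop_final"]).any():
        raise GenerationError("implied observed deaths exceed population")
    mortality["deaths_final"] = observed
    inputs["mortality"] = mortality.reset_index()
    truth = {
        "explained_share_pct": 100.0 * (1.0 - residual),
        "residual": residual,
        "modelled_dpp": float(by_stratum["modelled"].sum()),
        "total_dpp": float(target_dpp.sum()),
    }
    return inputs, truth


def scaled(config: ScenarioConfig, population_factor: float) -> ScenarioConfig:
    """Convenience: the same scenario with populations scaled by a factor."""
    lo, hi = config.population_range
    return replace(config, population_range=(int(lo * population_factor),
                                             int(hi * population_factor)))
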