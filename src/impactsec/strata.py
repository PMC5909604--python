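"""Stratification grid and mortality accounting.

The model's atomic unit is a stratum: one (sex, age band, socioeconomic
quintile) cell. A full grid has 2 sexes x 6 ten-year age bands (25-34 ... 75-84)
x 5 income quintiles = 60 strata. All mortality accounting is cell-based:
quantities are computed per stratum and then summed, never from pre-aggregated
rates.

Core accounting
---------------
Expected deaths in the final year are the base-year stratum-specific mortality
rates applied to final-year population counts. Deaths prevented or postponed
(DPPs) are expected minus observed final-year deaths; a negative DPP denotes
deaths brought forward (a mortality rise). Age-standardised rates support both
direct standardisation (reference weights) and an indirect variant
(standardised mortality ratio x reference crude rate); reference weights are
renormalised over occupied age bands so both variants collapse to the crude
rate when the population is concentrated in a single band.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError

SEXES = ("male", "female")
AGE_BANDS = ("25-34", "35-44", "45-54", "55-64", "65-74", "75-84")
SECQS = (1, 2, 3, 4, 5)  # 1 = most affluent, 5 = most deprived
STRATUM_COLS = ["sex", "age_band", "secq"]
N_STRATA = len(SEXES) * len(AGE_BANDS) * len(SECQS)

MORTALITY_COLS = STRATUM_COLS + ["pop_base", "pop_final", "deaths_base", "deaths_final"]

RATE_SCALE = 100_000.0


def full_grid() -> pd.DataFrame:
    """Return the complete 60-stratum grid as a DataFrame."""
    rows = list(itertools.product(SEXES, AGE_BANDS, SECQS))
    return pd.DataFrame(rows, columns=STRATUM_COLS)


def _stratum_label(row) -> str:
    return f"(sex={row['sex']}, age_band={row['age_band']}, secq={row['secq']})"


def validate_mortality(df: pd.DataFrame, require_full_grid: bool = False) -> list[str]:
    """Check a mortality table against its schema; return a list of problems."""
    problems: list[str] = []
    missing = [c for c in MORTALITY_COLS if c not in df.columns]
    if missing:
        return [f"mortality: missing columns {missing}"]
    if df.empty:
        problems.append("mortality: table is empty")
        return problems
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        problems.append(f"mortality: unknown sex values {sorted(bad_sex)}")
    bad_age = set(df["age_band"]) - set(AGE_BANDS)
    if bad_age:
        problems.append(f"mortality: unknown age bands {sorted(bad_age)}")
    bad_q = set(df["secq"]) - set(SECQS)
    if bad_q:
        problems.append(f"mortality: unknown secq values {sorted(bad_q)}")
    dup = df.duplicated(subset=STRATUM_COLS)
    if dup.any():
        problems.append(f"mortality: {int(dup.sum())} duplicated strata")
    if require_full_grid and len(df.drop_duplicates(subset=STRATUM_COLS)) != N_STRATA:
        problems.append(
            f"mortality: expected a full {N_STRATA}-stratum grid, "
            f"got {len(df.drop_duplicates(subset=STRATUM_COLS))}"
        )
    for col in ("pop_base", "pop_final", "deaths_base", "deaths_final"):
        if (pd.to_numeric(df[col], errors="coerce") < 0).any() or df[col].isna().any():
            problems.append(f"mortality: column {col} has negative or missing values")
    for year, (d, p) in {
        "base": ("deaths_base", "pop_base"),
        "final": ("deaths_final", "pop_final"),
    }.items():
        over = df[df[d] > df[p]]
        for _, row in over.iterrows():
            problems.append(
                f"mortality: deaths exceed population ({year} year) in {_stratum_label(row)}"
            )
        orphan = df[(df[d] > 0) & (df[p] == 0)]
        for _, row in orphan.iterrows():
            problems.append(
                f"mortality: {d} > 0 with zero {p} in {_stratum_label(row)}"
            )
    return problems


def expected_deaths(mortality: pd.DataFrame) -> pd.DataFrame:
    """Expected final-year deaths per stratum under base-year mortality rates.

    expected[s] = (deaths_base[s] / pop_base[s]) * pop_final[s].

    Returns a DataFrame with the stratum columns plus an ``expected`` column.
    Raises :class:`InputValidationError` naming the stratum if a stratum has
    base-year deaths but no base-year population.
    """
    bad = mortality[(mortality["deaths_base"] > 0) & (mortality["pop_base"] <= 0)]
    if not bad.empty:
        labels = ", ".join(_stratum_label(r) for _, r in bad.iterrows())
        raise InputValidationError(
            f"expected_deaths: zero base population with nonzero base deaths in {labels}"
        )
    out = mortality[STRATUM_COLS].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(
            mortality["pop_base"] > 0,
            mortality["deaths_base"] / mortality["pop_base"],
            0.0,
        )
    out["expected"] = rate * mortality["pop_final"].to_numpy(dtype=float)
    return out


def total_dpp(expected_final, observed_final):
    """Deaths prevented or postponed: expected minus observed final-year deaths.

    May be negative (a mortality rise). Works elementwise on arrays/Series.
    """
    e = np.asarray(expected_final, dtype=float)
    o = np.asarray(observed_final, dtype=float)
    if (e < 0).any() or (o < 0).any():
        raise InputValidationError("total_dpp: death counts must be non-negative")
    out = e - o
    if out.ndim == 0:
        return float(out)
    return out


def standardised_rate(deaths, pop, weights, per: float = RATE_SCALE) -> float:
    """Directly standardised rate per ``per`` persons.

    ``deaths``, ``pop`` and ``weights`` are aligned per age band. Weights must
    be non-negative, cover every occupied band (pop > 0), and sum to 1 over all
    bands; they are renormalised over occupied bands so a population
    concentrated in one band yields that band's crude rate.
    """
    d = np.asarray(deaths, dtype=float)
    n = np.asarray(pop, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != n.shape or n.shape != w.shape:
        raise InputValidationError("standardised_rate: inputs must be aligned")
    occ = n > 0
    if not occ.any():
        raise InputValidationError("standardised_rate: no occupied age band")
    if np.isnan(w[occ]).any():
        raise ConfigurationError(
            "standardised_rate: missing reference weight for an occupied age band"
        )
    if (w[~np.isnan(w)] < 0).any():
        raise ConfigurationError("standardised_rate: negative reference weight")
    if abs(np.nansum(w) - 1.0) > 1e-6:
        raise ConfigurationError("standardised_rate: reference weights must sum to 1")
    w_occ = w[occ] / w[occ].sum()
    rates = d[occ] / n[occ]
    return float((w_occ * rates).sum() * per)


def indirect_standardised_rate(deaths, pop, ref_rates, ref_weights, per: float = RATE_SCALE) -> float:
    """Indirectly standardised rate: SMR x reference crude rate, per ``per``.

    SMR = observed deaths / expected deaths under the reference band rates;
    the reference crude rate is the weight-averaged reference rate over the
    occupied bands (weights renormalised, as in direct standardisation).
    """
    d = np.asarray(deaths, dtype=float)
    n = np.asarray(pop, dtype=float)
    r = np.asarray(ref_rates, dtype=float)
    w = np.asarray(ref_weights, dtype=float)
    occ = n > 0
    if not occ.any():
        raise InputValidationError("indirect_standardised_rate: no occupied age band")
    if np.isnan(r[occ]).any() or np.isnan(w[occ]).any():
        raise ConfigurationError(
            "indirect_standardised_rate: missing reference rate or weight for an occupied band"
        )
    expected_ref = (n[occ] * r[occ]).sum()
    if expected_ref <= 0:
        raise ConfigurationError("indirect_standardised_rate: reference rates are all zero")
    smr = d[occ].sum() / expected_ref
    w_occ = w[occ] / w[occ].sum()
    ref_crude = (w_occ * r[occ]).sum()
    return float(smr * ref_crude * per)


def reduction_stats(rate_base: float, rate_final: float) -> dict[str, float]:
    """Absolute (same scale as the rates) and relative (%) rate reduction."""
    if rate_base <= 0:
        raise InputValidationError(
            "reduction_stats: relative reduction undefined for rate_base <= 0"
        )
    absolute = rate_base - rate_final
    return {"absolute": absolute, "relative": 100.0 * absolute / rate_base}


def pooled_reference(mortality: pd.DataFrame) -> pd.DataFrame:
    """Default standardisation reference: the pooled base-year population.

    Returns per (sex, age_band): ``weight`` (base-year population share) and
    ``ref_rate`` (base-year pooled mortality rate), for use by both the direct
    and indirect variants.
    """
    cells = (
        mortality.groupby(["sex", "age_band"], sort=False, observed=True)[
            ["pop_base", "deaths_base"]
        ]
        .sum()
        .reset_index()
    )
    total_pop = cells["pop_base"].sum()
    if total_pop <= 0:
        raise InputValidationError("pooled_reference: zero total base-year population")
    cells["weight"] = cells["pop_base"] / total_pop
    with np.errstate(invalid="ignore", divide="ignore"):
        cells["ref_rate"] = np.where(
            cells["pop_base"] > 0, cells["deaths_base"] / cells["pop_base"], 0.0
        )
    return cells[["sex", "age_band", "weight", "ref_rate"]]


def _subset_rate(sub: pd.DataFrame, reference: pd.DataFrame, year: str, method: str) -> float:
    """Standardised rate for a subset of strata (pooled over quintiles)."""
    pop_col, death_col = (("pop_base", "deaths_base") if year == "base"
                          else ("pop_final", "deaths_final"))
    cells = (
        sub.groupby(["sex", "age_band"], sort=False, observed=True)[[pop_col, death_col]]
        .sum()
        .reset_index()
        .merge(reference, on=["sex", "age_band"], how="left")
    )
    if cells["weight"].isna().any():
        raise ConfigurationError(
            "mortality_summary: reference table is missing a (sex, age_band) cell"
        )
    if method == "direct":
        return standardised_rate(cells[death_col], cells[pop_col],
                                 cells["weight"] / cells["weight"].sum())
    if method == "indirect":
        return indirect_standardised_rate(
            cells[death_col], cells[pop_col], cells["ref_rate"], cells["weight"]
        )
    raise ConfigurationError(f"mortality_summary: unknown standardisation method {method!r}")


def mortality_summary(
    mortality: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    method: str = "direct",
) -> pd.DataFrame:
    """Table-1 style mortality accounting: overall, by sex, and by quintile.

    Columns: populations and observed deaths at both years, expected final-year
    deaths, DPPs (expected - observed, summed over strata), standardised rates
    per 100,000 at both years, and absolute/relative rate reductions.
    """
    problems = validate_mortality(mortality)
    if problems:
        raise InputValidationError("; ".join(problems))
    if reference is None:
        reference = pooled_reference(mortality)
    elif "ref_rate" not in reference.columns:
        reference = reference.merge(
            pooled_reference(mortality)[["sex", "age_band", "ref_rate"]],
            on=["sex", "age_band"],
            how="left",
        )
    exp = expected_deaths(mortality)
    df = mortality.merge(exp, on=STRATUM_COLS)

    def one(label: str, sub: pd.DataFrame) -> dict:
        rate_b = _subset_rate(sub, reference, "base", method)
        rate_f = _subset_rate(sub, reference, "final", method)
        red = reduction_stats(rate_b, rate_f)
        return {
            "group": label,
            "pop_base": sub["pop_base"].sum(),
            "pop_final": sub["pop_final"].sum(),
            "deaths_base": sub["deaths_base"].sum(),
            "deaths_final": sub["deaths_final"].sum(),
            "expected_final": sub["expected"].sum(),
            "dpp": (sub["expected"] - sub["deaths_final"]).sum(),
            "rate_base": rate_b,
            "rate_final": rate_f,
            "abs_reduction": red["absolute"],
            "rel_reduction": red["relative"],
        }

    rows = [one("total", df)]
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        if not sub.empty:
            rows.append(one(sex, sub))
    for q in SECQS:
        sub = df[df["secq"] == q]
        if not sub.empty:
            rows.append(one(f"secq_{q}", sub))
    return pd.DataFrame(rows).set_index("group")


def dpp_by_stratum(mortality: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum DPP = expected - observed final-year deaths."""
    exp = expected_deaths(mortality)
    out = exp.merge(mortality[STRATUM_COLS + ["deaths_final"]], on=STRATUM_COLS)
    out["dpp"] = out["expected"] - out["deaths_final"]
    return out[STRATUM_COLS + ["expected", "dpp"]]
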