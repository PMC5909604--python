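"""Monte Carlo propagation of input-parameter uncertainty.

Fixed input parameters are replaced by probability distributions, the full
decomposition is recalculated per draw, and 95% empirical intervals (2.5th and
97.5th centiles of the stored draws) are reported around every output
quantity. Families respect each parameter's domain: beta for proportions
(uptakes, compliance, case fatality, prevalences), lognormal for relative
risks and for 1-RRR (mean-preserving multiplicative noise), normal for
continuous risk-factor means, and point (degenerate) for fixed values.
Registry-derived patient and population counts are fixed by default, being
near-census quantities.

Each parameter owns its own random substream, derived from (seed, run index,
CRC32 of the parameter path), so adding a parameter to the configuration does
not perturb the draws of the others at the same seed, and identical seeds give
bit-identical results.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MonteCarloError

FAMILIES = ("point", "beta", "normal", "lognormal")


@dataclass(frozen=True)
class ParameterDistribution:
    """Distribution attached to one input-table column (optionally row-filtered).

    The central value is taken from the input table itself; ``spread`` is the
    relative standard error around it (method of moments). ``transform``
    'complement' applies the family to 1 - value (used for RRR, whose
    complement 1-RRR is the multiplicative survival factor). ``bounds`` clips
    draws to the parameter's domain.
    """

    table: str
    column: str
    family: str = "beta"
    spread: float = 0.10
    transform: str | None = None
    bounds: tuple | None = None
    row: Mapping | None = None
    group_by: tuple | None = None  # one draw per unique key, broadcast to rows

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.transform not in (None, "complement"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.spread < 0:
            raise ConfigurationError("spread must be non-negative")

    @property
    def key(self) -> str:
        row = "" if self.row is None else "|" + ",".join(
            f"{k}={v}" for k, v in sorted(self.row.items())
        )
        return f"{self.table}.{self.column}{row}"

    def _draw_raw(self, central: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point" or self.spread == 0.0:
            return central.copy()
        if self.family == "beta":
            if (central < 0).any() or (central > 1).any():
                raise ConfigurationError(
                    f"beta family incompatible with {self.key}: values outside [0, 1]"
                )
            m = central
            out = m.copy()
            interior = (m > 0) & (m < 1)
            mi = m[interior]
            var = np.minimum((self.spread * mi) ** 2, 0.95 * mi * (1 - mi))
            k = mi * (1 - mi) / var - 1.0
            out[interior] = rng.beta(mi * k, (1 - mi) * k)
            return out
        if self.family == "normal":
            return central + rng.normal(0.0, self.spread * np.abs(central))
        # lognormal, mean-preserving multiplicative noise
        if (central <= 0).any():
            raise ConfigurationError(
                f"lognormal family incompatible with {self.key}: non-positive values"
            )
        sigma = np.sqrt(np.log1p(self.spread**2))
        return central * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=central.shape))

    def draw(self, central: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        central = np.asarray(central, dtype=float)
        if self.transform == "complement":
            out = 1.0 - self._draw_raw(1.0 - central, rng)
        else:
            out = self._draw_raw(central, rng)
        if self.bounds is not None:
            lo, hi = self.bounds
            out = np.clip(out, -np.inf if lo is None else lo, np.inf if hi is None else hi)
        return out


def _substream(seed: int, run: int, key: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(run), zlib.crc32(key.encode())])
    )


def sample_inputs(
    inputs: Mapping[str, pd.DataFrame],
    distributions: list[ParameterDistribution],
    seed: int,
    run: int = 0,
) -> dict[str, pd.DataFrame]:
    """One complete perturbed input set; identical (seed, run) gives identical draws."""
    out = {k: (v.copy() if isinstance(v, pd.DataFrame) else v) for k, v in inputs.items()}
    for dist in distributions:
        if dist.table not in out:
            raise ConfigurationError(f"distribution references unknown table {dist.table!r}")
        df = out[dist.table]
        if dist.column not in df.columns:
            raise ConfigurationError(
                f"distribution references unknown column {dist.table}.{dist.column}"
            )
        mask = pd.Series(True, index=df.index)
        if dist.row:
            for col, val in dist.row.items():
                mask &= df[col] == val
        if not mask.any():
            continue
        rng = _substream(seed, run, dist.key)
        if dist.group_by:
            # parameters that are a shared property of a group (e.g. case
            # fatality within a disease group and stratum) get one draw per
            # group, broadcast to every member row
            sub = df.loc[mask]
            codes, _ = pd.factorize(
                pd.MultiIndex.from_frame(sub[list(dist.group_by)]), sort=True
            )
            central_by_group = (
                sub[dist.column].to_numpy(dtype=float)
                [np.unique(codes, return_index=True)[1]]
            )
            drawn = dist.draw(central_by_group, rng)
            df.loc[mask, dist.column] = drawn[codes]
        else:
            central = df.loc[mask, dist.column].to_numpy(dtype=float)
            df.loc[mask, dist.column] = dist.draw(central, rng)
    return out


def default_distributions(
    inputs: Mapping[str, pd.DataFrame], rel_se: float = 0.10
) -> list[ParameterDistribution]:
    """Default family per parameter domain for a standard input bundle."""
    dists: list[ParameterDistribution] = []
    if "treatments" in inputs and not inputs["treatments"].empty:
        for col in ("uptake_base", "uptake_final", "compliance"):
            dists.append(ParameterDistribution("treatments", col, "beta", rel_se))
        dists.append(
            ParameterDistribution(
                "treatments", "case_fatality", "beta", rel_se,
                group_by=("disease_group", "sex", "age_band", "secq"),
            )
        )
        dists.append(
            ParameterDistribution(
                "treatments", "rrr", "lognormal", rel_se,
                transform="complement", bounds=(0.0, 0.999),
            )
        )
    if "risk_binary" in inputs and not inputs["risk_binary"].empty:
        for col in ("prev_base", "prev_final"):
            dists.append(ParameterDistribution("risk_binary", col, "beta", rel_se))
        dists.append(
            ParameterDistribution("risk_binary", "rr", "lognormal", rel_se, bounds=(1e-9, None))
        )
    if "risk_continuous" in inputs and not inputs["risk_continuous"].empty:
        for col in ("mean_base", "mean_final"):
            dists.append(
                ParameterDistribution(
                    "risk_continuous", col, "normal", rel_se / 10.0, bounds=(1e-9, None)
                )
            )
        dists.append(
            ParameterDistribution(
                "risk_continuous", "reduction_per_unit", "lognormal", rel_se,
                transform="complement", bounds=(0.0, 0.999),
            )
        )
    return dists


@dataclass
class UncertaintyResult:
    """Central estimates with 95% empirical intervals per reported quantity."""

    summary: pd.DataFrame  # index: quantity; columns: central, lower, upper
    n_runs: int
    seed: int
    draws: pd.DataFrame = field(repr=False, default=None)

    def interval(self, quantity: str) -> tuple[float, float]:
        row = self.summary.loc[quantity]
        return float(row["lower"]), float(row["upper"])


def run_monte_carlo(
    model: Callable[[Mapping[str, pd.DataFrame]], Mapping[str, float]],
    inputs: Mapping[str, pd.DataFrame],
    distributions: list[ParameterDistribution],
    n_runs: int = 10_000,
    seed: int = 0,
) -> UncertaintyResult:
    """Recalculate ``model`` over ``n_runs`` sampled input sets.

    ``model`` maps an input bundle to a dict of scalar output quantities. The
    interval endpoints are the 2.5th/97.5th empirical centiles of the stored
    draws. A failing run aborts with its draw index.
    """
    if n_runs < 2:
        raise ConfigurationError("run_monte_carlo: n_runs must be >= 2")
    central = dict(model(inputs))
    names = list(central)
    draws = np.empty((n_runs, len(names)), dtype=float)
    for i in range(n_runs):
        try:
            sampled = sample_inputs(inputs, distributions, seed, run=i)
            res = model(sampled)
            draws[i] = [res[name] for name in names]
        except MonteCarloError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise MonteCarloError(f"Monte Carlo run {i} failed: {exc}") from exc
    lower, upper = np.quantile(draws, [0.025, 0.975], axis=0)
    summary = pd.DataFrame(
        {
            "central": [central[n] for n in names],
            "lower": lower,
            "upper": upper,
        },
        index=pd.Index(names, name="quantity"),
    )
    return UncertaintyResult(
        summary=summary,
        n_runs=n_runs,
        seed=seed,
        draws=pd.DataFrame(draws, columns=names),
    )
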