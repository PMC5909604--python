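"""Model configuration (model.yaml) and uncertainty configuration loading."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .risk_factors import DEFAULT_NET_PAIRS
from .uncertainty import ParameterDistribution


@dataclass
class ModelConfig:
    """Tunable model behaviour.

    mant_hicks: combine within-group treatment benefits multiplicatively
        (default) instead of summing them independently.
    joint_risk: 'cumulative' (default) or 'additive' combination of
        risk-factor benefits within a stratum.
    compliance_overrides: disease group -> compliance value applied to all of
        that group's treatment rows.
    net_of_treatment_pairs: risk factor -> disease group whose treatment DPPs
        are subtracted from that factor's DPPs (double-counting guard).
    standardisation: 'direct' or 'indirect' age standardisation.
    """

    mant_hicks: bool = True
    joint_risk: str = "cumulative"
    compliance_overrides: dict = field(default_factory=dict)
    net_of_treatment_pairs: dict = field(default_factory=lambda: dict(DEFAULT_NET_PAIRS))
    standardisation: str = "direct"

    def __post_init__(self):
        if self.joint_risk not in ("cumulative", "additive"):
            raise ConfigurationError(f"joint_risk must be cumulative|additive, got {self.joint_risk!r}")
        if self.standardisation not in ("direct", "indirect"):
            raise ConfigurationError(
                f"standardisation must be direct|indirect, got {self.standardisation!r}"
            )

    @property
    def treatment_mode(self) -> str:
        return "mant_hicks" if self.mant_hicks else "independent"

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown model.yaml keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "mant_hicks": self.mant_hicks,
            "joint_risk": self.joint_risk,
            "compliance_overrides": dict(self.compliance_overrides),
            "net_of_treatment_pairs": dict(self.net_of_treatment_pairs),
            "standardisation": self.standardisation,
        }


def load_uncertainty_config(path) -> list[ParameterDistribution]:
    """Parse uncertainty.yaml: a list of {table, column, family, spread, ...} entries."""
    raw = yaml.safe_load(Path(path).read_text()) or []
    if not isinstance(raw, list):
        raise ConfigurationError("uncertainty.yaml must contain a list of parameter entries")
    dists = []
    for entry in raw:
        if not isinstance(entry, dict) or "table" not in entry or "column" not in entry:
            raise ConfigurationError(f"bad uncertainty entry: {entry!r}")
        bounds = entry.get("bounds")
        dists.append(
            ParameterDistribution(
                table=entry["table"],
                column=entry["column"],
                family=entry.get("family", "beta"),
                spread=float(entry.get("spread", 0.10)),
                transform=entry.get("transform"),
                bounds=tuple(bounds) if bounds is not None else None,
                row=entry.get("row"),
            )
        )
    return dists
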