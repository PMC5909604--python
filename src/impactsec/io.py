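"""Reading and writing the delimited-text input bundle.

Expected files in an input directory:
  mortality.csv                 sex, age_band, secq, pop_base, pop_final,
                                deaths_base, deaths_final
  treatments.csv                disease_group, treatment, [sex, age_band,
                                secq,] patients, uptake_base, uptake_final,
                                rrr, compliance, case_fatality
  risk_factors_continuous.csv   factor, sex, age_band, secq, mean_base,
                                mean_final, reduction_per_unit
  risk_factors_binary.csv       factor, sex, age_band, secq, prev_base,
                                prev_final, rr
  reference_weights.csv         sex, age_band, weight        (optional)
  model.yaml                                                 (optional)

The treatments compact dialect (no stratum columns) broadcasts each row to all
60 strata unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .config import ModelConfig
from .errors import InputValidationError
from .strata import STRATUM_COLS, full_grid

MORTALITY_FILE = "mortality.csv"
TREATMENTS_FILE = "treatments.csv"
RISK_CONT_FILE = "risk_factors_continuous.csv"
RISK_BIN_FILE = "risk_factors_binary.csv"
REF_WEIGHTS_FILE = "reference_weights.csv"
MODEL_CONFIG_FILE = "model.yaml"

_TABLE_FILES = {
    "mortality": MORTALITY_FILE,
    "treatments": TREATMENTS_FILE,
    "risk_continuous": RISK_CONT_FILE,
    "risk_binary": RISK_BIN_FILE,
}


def _expand_compact_treatments(df: pd.DataFrame) -> pd.DataFrame:
    if all(c in df.columns for c in STRATUM_COLS):
        return df
    if any(c in df.columns for c in STRATUM_COLS):
        raise InputValidationError(
            "treatments.csv must carry either all of sex/age_band/secq or none"
        )
    return df.merge(full_grid(), how="cross")


def read_inputs(directory) -> dict:
    """Load an input bundle from a directory of delimited text files."""
    directory = Path(directory)
    path = directory / MORTALITY_FILE
    if not path.exists():
        raise InputValidationError(f"missing required input file {path}")
    inputs: dict = {"mortality": pd.read_csv(path)}
    inputs["mortality"]["secq"] = inputs["mortality"]["secq"].astype(int)

    tpath = directory / TREATMENTS_FILE
    if tpath.exists():
        t = pd.read_csv(tpath)
        t = _expand_compact_treatments(t)
        t["secq"] = t["secq"].astype(int)
        inputs["treatments"] = t
    else:
        inputs["treatments"] = pd.DataFrame(
            columns=["disease_group", "treatment"] + STRATUM_COLS
            + ["patients", "uptake_base", "uptake_final", "rrr", "compliance", "case_fatality"]
        )
    for key, fname, cols in (
        ("risk_continuous", RISK_CONT_FILE,
         ["factor"] + STRATUM_COLS + ["mean_base", "mean_final", "reduction_per_unit"]),
        ("risk_binary", RISK_BIN_FILE,
         ["factor"] + STRATUM_COLS + ["prev_base", "prev_final", "rr"]),
    ):
        p = directory / fname
        if p.exists():
            df = pd.read_csv(p)
            df["secq"] = df["secq"].astype(int)
            inputs[key] = df
        else:
            inputs[key] = pd.DataFrame(columns=cols)
    wpath = directory / REF_WEIGHTS_FILE
    if wpath.exists():
        inputs["reference_weights"] = pd.read_csv(wpath)
    cpath = directory / MODEL_CONFIG_FILE
    if cpath.exists():
        inputs["config"] = ModelConfig.from_yaml(cpath)
    return inputs


def write_inputs(inputs: dict, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, fname in _TABLE_FILES.items():
        if key in inputs and isinstance(inputs[key], pd.DataFrame):
            inputs[key].to_csv(directory / fname, index=False)
    if "reference_weights" in inputs:
        inputs["reference_weights"].to_csv(directory / REF_WEIGHTS_FILE, index=False)


def table_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a table (canonical CSV bytes)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def build_manifest(inputs: dict, config: ModelConfig, seed=None) -> dict:
    from . import __version__

    return {
        "tables": {
            k: table_hash(v) for k, v in inputs.items() if isinstance(v, pd.DataFrame)
        },
        "config": config.to_dict(),
        "seed": seed,
        "version": __version__,
        "timestamp": pd.Timestamp.now().isoformat(),
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
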