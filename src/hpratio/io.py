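"""Readers and writers for the campaign CSV/YAML/JSON schemas.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals.  Every result artifact embeds the seed and log base needed to
regenerate it.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .core import FactorMapping
from .field import TreatmentRecord
from .inference import PREDICTORS, RegressionResult

__all__ = [
    "TREATMENT_COLUMNS",
    "load_treatment_table",
    "save_treatment_table",
    "result_to_dict",
    "write_result_json",
    "format_result_table",
    "write_truth_yaml",
    "load_mapping_yaml",
]

#: Required columns of a treatment table; ``theta`` is optional and filled
#: as cpue + 1 when absent.
TREATMENT_COLUMNS = (
    "pond",
    "treatment",
    "h_ugC_L",
    "p_ugC_L",
    "cp_molar",
    "edible_frac",
    "mu",
    "cpue",
)


def load_treatment_table(path: str | Path) -> list[TreatmentRecord]:
    """Read and validate a treatment-means CSV.

    Raises ``ValueError`` naming the offending row (1-based, excluding the
    header) on invalid values, and listing any missing columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TREATMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = dict(
            pond=str(row.pond),
            treatment=str(row.treatment),
            h_biomass=float(row.h_ugC_L),
            p_biomass=float(row.p_ugC_L),
            a_nut=float(row.cp_molar),
            a_edi=float(row.edible_frac),
            mu=float(row.mu),
            cpue=float(row.cpue),
        )
        if "theta" in df.columns and not pd.isna(getattr(row, "theta", None)):
            kwargs["theta"] = float(row.theta)
        try:
            records.append(TreatmentRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
    return records


def save_treatment_table(records: Sequence[TreatmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "pond": [r.pond for r in records],
            "treatment": [r.treatment for r in records],
            "h_ugC_L": [r.h_biomass for r in records],
            "p_ugC_L": [r.p_biomass for r in records],
            "cp_molar": [r.a_nut for r in records],
            "edible_frac": [r.a_edi for r in records],
            "mu": [r.mu for r in records],
            "cpue": [r.cpue for r in records],
            "theta": [r.theta for r in records],
        }
    ).to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def result_to_dict(result: RegressionResult) -> dict:
    """JSON-ready dictionary mirroring the coefficient-table layout."""
    params = {}
    for name in ("gamma",) + tuple(PREDICTORS):
        est = result.gamma_hat if name == "gamma" else result.eps_hat[name]
        params[name] = {
            "coefficient": est,
            "ci95": list(result.ci[name]),
            "std_coef": None if name == "gamma" else result.std_coef[name],
        }
    return {
        "parameters": params,
        "r2": result.r2,
        "aic": result.aic,
        "vif": dict(result.vif),
        "n": result.n,
        "log_base": "e" if math.isclose(result.log_base, math.e) else result.log_base,
        "n_boot": result.n_boot,
        "seed": result.seed,
    }


def write_result_json(result: RegressionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2) + "\n")


_ROW_LABELS = {
    "gamma": "Intercept (gamma)",
    "a_nut": "Seston C:P (eps1)",
    "a_edi": "Edible fraction (eps2)",
    "mu": "Production rate (eps3)",
    "theta": "Fish abundance (eps4)",
}


def format_result_table(result: RegressionResult) -> str:
    """Aligned plain-text coefficient table (human-readable companion)."""
    lines = [
        f"{'Variable':<24}{'Coefficient':>12}{'95% CI':>22}{'Std coef':>10}",
    ]
    for name in ("gamma",) + tuple(PREDICTORS):
        est = result.gamma_hat if name == "gamma" else result.eps_hat[name]
        lo, hi = result.ci[name]
        std = "-" if name == "gamma" else f"{result.std_coef[name]:.2f}"
        lines.append(
            f"{_ROW_LABELS[name]:<24}{est:>12.2f}"
            f"{f'{lo:.2f} ~ {hi:.2f}':>22}{std:>10}"
        )
    base = "e" if math.isclose(result.log_base, math.e) else f"{result.log_base:g}"
    lines.append(
        f"n = {result.n}, R^2 = {result.r2:.2f}, AIC = {result.aic:.2f}, "
        f"log base {base}, {result.n_boot} bootstrap replicates, "
        f"seed {result.seed}"
    )
    return "\n".join(lines)


def write_truth_yaml(
    mapping: FactorMapping, path: str | Path, seed: Optional[int] = None
) -> None:
    """Ground-truth sidecar for a synthetic dataset."""
    payload = {
        "eps1": mapping.eps1,
        "eps2": mapping.eps2,
        "eps3": mapping.eps3,
        "eps4": mapping.eps4,
        "gamma": mapping.gamma,
        "log_base": "e" if math.isclose(mapping.log_base, math.e) else mapping.log_base,
        "seed": seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_mapping_yaml(path: str | Path) -> FactorMapping:
    raw = yaml.safe_load(Path(path).read_text())
    base = raw.get("log_base", "e")
    return FactorMapping(
        eps1=float(raw["eps1"]),
        eps2=float(raw["eps2"]),
        eps3=float(raw["eps3"]),
        eps4=float(raw["eps4"]),
        gamma=float(raw["gamma"]),
        log_base=math.e if base == "e" else float(base),
    )
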