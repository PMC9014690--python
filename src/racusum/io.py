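"""File I/O: patient-record CSV parsing and config/result serialization.

Patient records travel as comma-separated files with a header; the
columns ``score`` (nonnegative integer) and ``outcome`` (0/1) are
required, ``id`` and ``date`` are carried through when present.
Configs and results are plain JSON.
"""

from __future__ import annotations

import json
from typing import Any

import pandas as pd

from .cusum import ArlResult
from .patient_mix import BetaBinomialMix, BetaMix, DiscretizedBetaMix, PatientMix
from .risk_model import RiskModel


class PatientCsvError(ValueError):
    """Malformed patient-record file; the message cites the data line."""


def read_patient_csv(path) -> pd.DataFrame:
    """Read and validate patient records (columns ``score``, ``outcome``).

    Line numbers in error messages count the header as line 1, matching
    what an editor shows.
    """
    df = pd.read_csv(path)
    for col in ("score", "outcome"):
        if col not in df.columns:
            raise PatientCsvError(f"missing required column '{col}' in {path}")
    for i, (score, outcome) in enumerate(zip(df["score"], df["outcome"])):
        line = i + 2  # header is line 1
        if pd.isna(score) or float(score) != int(score) or int(score) < 0:
            raise PatientCsvError(f"line {line}: score must be a nonnegative integer, got {score!r}")
        if outcome not in (0, 1):
            raise PatientCsvError(f"line {line}: outcome must be 0 or 1, got {outcome!r}")
    df["score"] = df["score"].astype(int)
    df["outcome"] = df["outcome"].astype(int)
    return df


def mix_from_config(cfg: dict[str, Any]) -> PatientMix:
    """Build a mix from ``{family, n, alpha, beta}``.

    Families: ``beta`` (n = smax), ``discrete_beta`` (n+1 categories),
    ``betabinomial``.
    """
    family = cfg["family"]
    n = int(cfg.get("n", 71))
    alpha = float(cfg["alpha"])
    beta = float(cfg["beta"])
    if family == "beta":
        return BetaMix(alpha, beta, smax=n)
    if family == "discrete_beta":
        return DiscretizedBetaMix(alpha, beta, ncat=n + 1)
    if family == "betabinomial":
        return BetaBinomialMix(n, alpha, beta)
    raise ValueError(f"unknown mix family {family!r}")


def mix_to_config(mix: PatientMix) -> dict[str, Any]:
    if isinstance(mix, BetaMix):
        return {"family": "beta", "n": mix.smax, "alpha": mix.alpha, "beta": mix.beta}
    if isinstance(mix, DiscretizedBetaMix):
        return {"family": "discrete_beta", "n": mix.ncat - 1, "alpha": mix.alpha, "beta": mix.beta}
    return {"family": "betabinomial", "n": mix.n, "alpha": mix.alpha, "beta": mix.beta}


def risk_model_from_config(cfg: dict[str, Any]) -> RiskModel:
    return RiskModel(b0=float(cfg["b0"]), b1=float(cfg["b1"]))


def arl_result_to_json(res: ArlResult) -> str:
    payload = {
        "arl": float(f"{res.arl:.10g}"),
        "engine": res.engine,
        "resolution": res.resolution,
    }
    if res.se is not None:
        payload["se"] = float(f"{res.se:.6g}")
    return json.dumps(payload, indent=2, default=float)
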