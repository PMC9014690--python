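"""Synthetic patient streams with a change-point, and online monitoring.

A monitored stream is a sequence of (score, outcome) pairs.  Before the
change-point tau the scores come from a "pre" mix and outcomes follow
the risk model with odds shifted by qstar_pre; from patient tau onward
the "post" mix and qstar_post apply.  Step changes in the mix, in the
surgical performance, or in both can thereby be emulated, including the
classic confounded cases: a pure mix shift that triggers a false
performance signal, and a performance shift masked by a simultaneous
move to lower-risk patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cusum import CusumChart, run_chart
from .patient_mix import DiscreteMix
from .risk_model import RiskModel

__all__ = ["ScenarioSpec", "generate_stream", "monitor_stream", "SignalReport"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Stream definition: mixes, performance levels, change-point, length."""

    pre_mix: DiscreteMix
    post_mix: DiscreteMix
    qstar_pre: float
    qstar_post: float
    tau: int
    total: int
    seed: int

    def __post_init__(self) -> None:
        if not (1 <= self.tau <= self.total):
            raise ValueError("need 1 <= tau <= total")
        if self.qstar_pre <= 0 or self.qstar_post <= 0:
            raise ValueError("qstar must be > 0")


def generate_stream(spec: ScenarioSpec, model: RiskModel) -> pd.DataFrame:
    """Seeded (index, score, outcome) stream with a single step change.

    Patients are 1-indexed; patient i draws from the pre regime when
    i < tau and from the post regime when i >= tau.
    """
    rng = np.random.default_rng(spec.seed)
    n_pre = spec.tau - 1
    n_post = spec.total - n_pre
    scores = np.concatenate(
        [
            spec.pre_mix.sample(n_pre, rng),
            spec.post_mix.sample(n_post, rng),
        ]
    ).astype(int)
    pi = model.prob_death(scores)
    qs = np.where(np.arange(1, spec.total + 1) < spec.tau, spec.qstar_pre, spec.qstar_post)
    pistar = qs * pi / (1.0 - pi + qs * pi)
    outcomes = (rng.random(spec.total) < pistar).astype(int)
    return pd.DataFrame(
        {"index": np.arange(1, spec.total + 1), "score": scores, "outcome": outcomes}
    )


@dataclass(frozen=True)
class SignalReport:
    """First signal per chart and the full statistic paths."""

    upper_signal: Optional[int]
    lower_signal: Optional[int]
    upper_path: np.ndarray
    lower_path: np.ndarray

    def first_signal(self) -> Optional[tuple[int, str]]:
        cands = []
        if self.upper_signal is not None:
            cands.append((self.upper_signal, "up"))
        if self.lower_signal is not None:
            cands.append((self.lower_signal, "down"))
        return min(cands) if cands else None


def monitor_stream(
    stream: pd.DataFrame,
    up_chart: CusumChart,
    down_chart: CusumChart,
    model: RiskModel,
) -> SignalReport:
    """Run both one-sided charts over a stream of (score, outcome)."""
    scores = stream["score"].to_numpy()
    outcomes = stream["outcome"].to_numpy()
    up_path, up_sig = run_chart(scores, outcomes, up_chart, model)
    dn_path, dn_sig = run_chart(scores, outcomes, down_chart, model)
    return SignalReport(up_sig, dn_sig, up_path, dn_path)
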