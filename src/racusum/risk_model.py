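"""Logistic risk model and the odds-ratio performance-shift operator.

The risk model links a patient's integer risk score s to the predicted
probability of death within 30 days of surgery:

    logit pi(s) = b0 + b1 * s

A change in surgical performance is expressed as a multiplicative shift
Q* of the odds of death: odds*(s) = Q* * odds(s).  Q* > 1 models
deterioration, Q* < 1 improvement, Q* = 1 leaves the risk unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class RiskModel:
    """Logistic model coefficients: intercept b0, slope b1 per score unit."""

    b0: float
    b1: float

    def prob_death(self, s):
        """pi(s) = (1 + exp(-b0 - b1*s))^-1, strictly inside (0, 1)."""
        return expit(self.b0 + self.b1 * np.asarray(s, dtype=float))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        return cls(b0=float(d["b0"]), b1=float(d["b1"]))


#: Coefficients of the cardiac-surgery Phase-I logistic fit used for all
#: headline computations when no data is supplied.
DEFAULT_RISK_MODEL = RiskModel(b0=-3.6798, b1=0.0768)


def prob_death(s, model: RiskModel):
    """Probability of death for score s under the logistic risk model."""
    return model.prob_death(s)


def shift_odds(p, qstar: float):
    """Multiply the odds of p by qstar: returns qstar*p / (1 - p + qstar*p).

    Preserves (0, 1); qstar < 1 decreases the probability, qstar > 1
    increases it, qstar = 1 is the identity.
    """
    if qstar <= 0:
        raise ValueError("qstar must be > 0")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    return qstar * p / (1.0 - p + qstar * p)


def fit_risk_model(scores: Sequence[int], outcomes: Sequence[int]) -> RiskModel:
    """Maximum-likelihood logistic fit of outcome on score.

    Raises ``ValueError`` if outcomes are single-class or the lengths
    differ; convergence failures (e.g. complete separation) surface as
    errors from the underlying IRLS fit.
    """
    import statsmodels.api as sm

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present to fit a logistic model")
    X = sm.add_constant(s)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (separation or degenerate data)")
    b0, b1 = res.params
    return RiskModel(b0=float(b0), b1=float(b1))
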