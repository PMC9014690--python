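"""Risk-adjusted Bernoulli CUSUM: LLR scores, chart recursions, W atoms,
and Monte Carlo run-length estimation.

Each patient contributes a log-likelihood-ratio (LLR) increment W that
compares the alternative odds ratio QA against the null Q0 (usually 1),
adjusted for the patient's predicted death probability pi(s):

    y = 1:  W = log[ (1 - pi + Q0*pi) * QA / ((1 - pi + QA*pi) * Q0) ]
    y = 0:  W = log[ (1 - pi + Q0*pi) / (1 - pi + QA*pi) ]

For Q0 = 1 this simplifies to W = -log(1 - pi + QA*pi) + y*log(QA).

The upper chart accumulates C+_i = max(0, C+_{i-1} + W_i) and signals
when C+ > h; the lower chart C-_i = min(0, C-_{i-1} - W_i) signals when
C- < -h.  The lower chart is an exact reflection of the upper chart run
on the same increments (computed with its own QA < 1), which is how it
is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .patient_mix import DiscreteMix
from .risk_model import RiskModel, shift_odds


@dataclass(frozen=True)
class CusumChart:
    """One-sided chart design: direction, odds ratios, control limit."""

    direction: str  # "up" | "down"
    qa: float
    h: float
    q0: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.h <= 0:
            raise ValueError("control limit h must be > 0")
        if self.qa <= 0 or self.q0 <= 0:
            raise ValueError("odds ratios must be > 0")
        if self.direction == "up" and self.qa <= self.q0:
            warnings.warn("an upper chart normally uses qa > q0", stacklevel=2)
        if self.direction == "down" and self.qa >= self.q0:
            warnings.warn("a lower chart normally uses qa < q0", stacklevel=2)


@dataclass(frozen=True)
class WAtomDistribution:
    """Discrete distribution of the LLR increment W: atoms and weights."""

    values: np.ndarray
    probs: np.ndarray
    # log(qa/q0): exact spacing between the y=1 and y=0 atom of a score
    log_odds_gap: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if v.shape != p.shape:
            raise ValueError("values and probs must have equal length")
        if np.any(p < -1e-15):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "probs", p)

    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    def negated(self) -> "WAtomDistribution":
        return WAtomDistribution(-self.values, self.probs, -self.log_odds_gap)


@dataclass(frozen=True)
class ArlResult:
    """ARL value with engine metadata (and a standard error if stochastic)."""

    arl: float
    engine: str
    resolution: dict = field(default_factory=dict)
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.arl < 1:
            raise ValueError("an ARL cannot be below 1")
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be >= 0")


def llr_weight(p, y, qa: float, q0: float = 1.0):
    """LLR increment for death probability p and outcome y in {0, 1}."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if qa <= 0 or q0 <= 0:
        raise ValueError("odds ratios must be > 0")
    y = np.asarray(y)
    if np.any((y != 0) & (y != 1)):
        raise ValueError("outcomes must be 0 or 1")
    w0 = np.log(1.0 - p + q0 * p) - np.log(1.0 - p + qa * p)
    return w0 + y * (np.log(qa) - np.log(q0))


def w_atoms(
    mix: DiscreteMix,
    model: RiskModel,
    qa: float,
    qstar: float = 1.0,
    q0: float = 1.0,
) -> WAtomDistribution:
    """Distribution of W induced by a discrete mix and a risk model.

    Chart weights use the in-control probabilities pi(s); the outcome
    probabilities use pi*(s), the odds-shifted probabilities under the
    true process odds ratio ``qstar``.  For each score s there are two
    atoms: W(s, y=0) with mass P(s)*(1 - pi*(s)) and W(s, y=1) with
    mass P(s)*pi*(s).
    """
    if getattr(mix, "continuous", False):
        raise TypeError("w_atoms requires a discrete mix; use the integral-equation path for a continuous beta mix")
    s = mix.support
    P = mix.probs
    pi = model.prob_death(s)
    pistar = shift_odds(pi, qstar) if qstar != 1.0 else pi
    w0 = llr_weight(pi, 0, qa, q0)
    w1 = llr_weight(pi, 1, qa, q0)
    values = np.concatenate([w0, w1])
    probs = np.concatenate([P * (1.0 - pistar), P * pistar])
    return WAtomDistribution(values, probs, log_odds_gap=float(np.log(qa) - np.log(q0)))


def run_chart(
    scores: Sequence[int],
    outcomes: Sequence[int],
    chart: CusumChart,
    model: RiskModel,
):
    """Run a one-sided chart over a patient sequence.

    Returns ``(path, signal_index)`` where ``path[i]`` is the statistic
    after patient i+1 and ``signal_index`` is the 1-based index of the
    first signaling patient (None if the chart never signals; the path
    continues past the first signal for display purposes).
    """
    s = np.asarray(scores)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    pi = model.prob_death(s)
    w = llr_weight(pi, y, chart.qa, chart.q0)
    path = np.empty(len(w))
    c = 0.0
    signal = None
    if chart.direction == "up":
        for i, wi in enumerate(w):
            c = max(0.0, c + wi)
            path[i] = c
            if signal is None and c > chart.h:
                signal = i + 1
    else:
        # lower chart: C- = min(0, C- - W), signal when C- < -h
        for i, wi in enumerate(w):
            c = min(0.0, c - wi)
            path[i] = c
            if signal is None and c < -chart.h:
                signal = i + 1
    return path, signal


# ---------------------------------------------------------------------------
# Monte Carlo run-length estimation (numba-accelerated)

_MC_KERNELS = {}


def _get_mc_kernel():
    if "atoms" in _MC_KERNELS:
        return _MC_KERNELS["atoms"]
    from numba import njit

    @njit(cache=True)
    def _mc_atoms(values, cdf, h, reps, seed, maxlen):
        np.random.seed(seed)
        n = len(cdf)
        total = 0.0
        total2 = 0.0
        for _ in range(reps):
            c = 0.0
            t = 0
            while t < maxlen:
                t += 1
                u = np.random.random()
                lo, hi = 0, n - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cdf[mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                c += values[lo]
                if c < 0.0:
                    c = 0.0
                if c > h:
                    break
            total += t
            total2 += t * t
        return total, total2

    _MC_KERNELS["atoms"] = _mc_atoms
    return _mc_atoms


def simulate_run_length(
    watoms_or_stream: Union[WAtomDistribution, Iterable[float]],
    chart: CusumChart,
    reps: int,
    seed: int,
    max_run_length: int = 10_000_000,
) -> ArlResult:
    """Monte Carlo ARL: mean run length over ``reps`` independent runs.

    The signaling patient counts toward the run length (1-based).  For a
    :class:`WAtomDistribution` the increments are drawn by inverse-CDF
    sampling inside a compiled loop; alternatively an iterable of
    pre-drawn increments can be supplied (one long stream, consumed
    sequentially, mainly for testing).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(watoms_or_stream, WAtomDistribution):
        watoms = watoms_or_stream
        kern = _get_mc_kernel()
        cdf = np.cumsum(watoms.probs)
        cdf[-1] = 1.0
        total, total2 = kern(
            np.asarray(watoms.values, dtype=np.float64),
            cdf,
            float(chart.h),
            int(reps),
            int(seed) & 0x7FFFFFFF,
            int(max_run_length),
        )
        mean = total / reps
        var = max(total2 / reps - mean**2, 0.0)
        se = float(np.sqrt(var / reps)) if reps > 1 else None
        return ArlResult(mean, "montecarlo", {"reps": reps, "seed": seed}, se)

    # generic stream of increments: run consecutive charts until the
    # stream is exhausted or `reps` runs are complete
    lengths = []
    c, t = 0.0, 0
    for w in watoms_or_stream:
        t += 1
        c = max(0.0, c + w)
        if c > chart.h:
            lengths.append(t)
            c, t = 0.0, 0
            if len(lengths) >= reps:
                break
    if not lengths:
        raise ValueError("stream exhausted before a single signal")
    arr = np.asarray(lengths, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else None
    return ArlResult(float(arr.mean()), "montecarlo", {"reps": len(arr), "seed": None}, se)
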