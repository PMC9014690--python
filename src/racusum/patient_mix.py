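"""Parametric models of the patient risk-score population ("patient mix").

The patient mix is the probability distribution of perioperative risk
scores (e.g. the integer Parsonnet score, 0..71) of the patients entering
a monitored surgical process.  Three parametric families are provided:

* :class:`BetaMix` -- a continuous beta(alpha, beta) distribution on
  [0, 1]; the score scale is recovered by multiplying with ``smax``.
* :class:`DiscretizedBetaMix` -- the beta distribution chopped into
  ``ncat`` equal-width categories of [0, 1], giving a discrete pmf over
  the integer scores 0..ncat-1.
* :class:`BetaBinomialMix` -- the beta-binomial compound distribution,
  a binomial with beta-distributed success probability; discrete and
  bounded by construction, so it fits an integer scoring system without
  any rescaling.

Shape parameters can be fitted from score samples by the method of
moments (:func:`mom_fit_beta`, :func:`mom_fit_betabinomial`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import betaln


class EstimationError(ValueError):
    """Raised when moment estimates are inadmissible (e.g. zero variance)."""


def _check_shapes(alpha: float, beta: float) -> None:
    if not (alpha > 0 and beta > 0):
        raise ValueError(f"shape parameters must be positive, got alpha={alpha}, beta={beta}")


@dataclass(frozen=True)
class BetaMix:
    """Continuous beta(alpha, beta) patient mix on [0, 1].

    ``smax`` is the maximum integer score of the underlying scoring
    system; the continuous variable x maps to the score scale as
    ``s = smax * x``.
    """

    alpha: float
    beta: float
    smax: int = 71

    def __post_init__(self) -> None:
        _check_shapes(self.alpha, self.beta)
        if self.smax < 1:
            raise ValueError("smax must be >= 1")

    @property
    def continuous(self) -> bool:
        return True

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("x must lie in [0, 1]")
        return stats.beta.pdf(x, self.alpha, self.beta)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("x must lie in [0, 1]")
        return stats.beta.cdf(x, self.alpha, self.beta)

    def mean_score(self) -> float:
        return self.smax * self.alpha / (self.alpha + self.beta)

    def sample(self, count: int, rng: np.random.Generator):
        """Draw i.i.d. values on the continuous [0, 1] scale."""
        return rng.beta(self.alpha, self.beta, size=count)


class _DiscreteMixBase:
    """Shared behaviour of discrete mixes with pmf over {0, ..., n}."""

    probs: np.ndarray

    @property
    def continuous(self) -> bool:
        return False

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))

    def pmf(self, s):
        s = np.asarray(s)
        if np.any((s < 0) | (s >= len(self.probs))):
            raise ValueError(f"score outside support 0..{len(self.probs) - 1}")
        return self.probs[s]

    def cdf(self, s):
        c = np.cumsum(self.probs)
        s = np.asarray(s, dtype=int)
        return c[np.clip(s, 0, len(c) - 1)]

    def mean_score(self) -> float:
        return float(np.dot(self.support, self.probs))

    def median_score(self) -> int:
        # tolerance so an exact CDF value of 1/2 is not missed to roundoff
        return int(np.searchsorted(np.cumsum(self.probs), 0.5 - 1e-12))

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        if count == 0:
            return np.array([], dtype=int)
        return rng.choice(len(self.probs), size=count, p=self.probs)


@dataclass(frozen=True)
class BetaBinomialMix(_DiscreteMixBase):
    """Beta-binomial(n, alpha, beta) patient mix over scores {0, ..., n}."""

    n: int
    alpha: float
    beta: float
    probs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_shapes(self.alpha, self.beta)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p = stats.betabinom.pmf(np.arange(self.n + 1), self.n, self.alpha, self.beta)
        object.__setattr__(self, "probs", p)

    def mean_score(self) -> float:
        # exact first moment n*alpha/(alpha+beta)
        return self.n * self.alpha / (self.alpha + self.beta)

    def raw_moment2(self) -> float:
        a, b, n = self.alpha, self.beta, self.n
        return n * a * (n * (1 + a) + b) / ((a + b) * (a + b + 1))


@dataclass(frozen=True)
class DiscretizedBetaMix(_DiscreteMixBase):
    """Beta(alpha, beta) discretized into ncat equal-width categories.

    Category i carries the beta probability mass of [i/ncat, (i+1)/ncat],
    so the pmf over the scores 0..ncat-1 sums to one without any
    renormalization.
    """

    alpha: float
    beta: float
    ncat: int = 72
    probs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_shapes(self.alpha, self.beta)
        if self.ncat < 2:
            raise ValueError("ncat must be >= 2")
        edges = np.linspace(0.0, 1.0, self.ncat + 1)
        p = np.diff(stats.beta.cdf(edges, self.alpha, self.beta))
        object.__setattr__(self, "probs", p)


DiscreteMix = Union[BetaBinomialMix, DiscretizedBetaMix]
PatientMix = Union[BetaMix, BetaBinomialMix, DiscretizedBetaMix]


@dataclass(frozen=True)
class MomentEstimates:
    """First two raw sample moments of a score sample of size K."""

    m1: float
    m2: float
    K: int

    def __post_init__(self) -> None:
        if self.K < 2:
            raise EstimationError("need at least K=2 observations")
        if self.m2 < self.m1**2 - 1e-12:
            raise EstimationError("m2 < m1^2: negative sample variance")


def moments(values: Sequence[float]) -> MomentEstimates:
    v = np.asarray(values, dtype=float)
    return MomentEstimates(float(np.mean(v)), float(np.mean(v**2)), len(v))


def beta_pdf(x, mix: BetaMix):
    """Beta density x^(a-1) (1-x)^(b-1) / B(a, b) on [0, 1]."""
    return mix.pdf(x)


def beta_cdf(x, mix: BetaMix):
    """Regularized incomplete beta function B(x; a, b) / B(a, b)."""
    return mix.cdf(x)


def rescale_scores(scores: Sequence[int], smax: int) -> np.ndarray:
    """Map integer scores to the interval midpoints (s + 1/2) / (smax + 1).

    This transformation carries a bounded integer scoring system into
    (0, 1) so that a continuous beta distribution can be fitted.
    """
    s = np.asarray(scores)
    if s.size and (s.min() < 0 or s.max() > smax):
        raise ValueError(f"scores must lie in 0..{smax}")
    return (s + 0.5) / (smax + 1)


def _beta_mom(m: MomentEstimates) -> tuple[float, float]:
    var = m.m2 - m.m1**2
    if var <= 0:
        raise EstimationError("zero sample variance: beta shapes are not identifiable")
    factor = m.m1 * (1 - m.m1) / var - 1.0
    alpha = m.m1 * factor
    beta = (1 - m.m1) * factor
    if alpha <= 0 or beta <= 0:
        raise EstimationError(
            f"method of moments gave non-positive shapes (alpha={alpha:.4g}, beta={beta:.4g}); "
            "the sample is over-dispersed for a beta model"
        )
    return alpha, beta


def mom_fit_beta(scores: Sequence[int], smax: int = 71) -> BetaMix:
    """Fit beta(alpha, beta) by the method of moments on rescaled scores."""
    m = moments(rescale_scores(scores, smax))
    alpha, beta = _beta_mom(m)
    return BetaMix(alpha, beta, smax=smax)


def mom_fit_beta_from_moments(m: MomentEstimates, smax: int = 71) -> BetaMix:
    """Method-of-moments beta fit from pre-computed rescaled-score moments."""
    alpha, beta = _beta_mom(m)
    return BetaMix(alpha, beta, smax=smax)


def _betabinomial_mom(m: MomentEstimates, n: int) -> tuple[float, float]:
    if m.m1 <= 0:
        raise EstimationError("mean score must be positive")
    denom = n * (m.m2 / m.m1 - m.m1 - 1.0) + m.m1
    if denom == 0:
        raise EstimationError("degenerate moments: beta-binomial shapes undefined")
    alpha = (n * m.m1 - m.m2) / denom
    beta = (n - m.m1) * (n - m.m2 / m.m1) / denom
    if alpha <= 0 or beta <= 0:
        raise EstimationError(
            f"method of moments gave non-positive shapes (alpha={alpha:.4g}, beta={beta:.4g}); "
            "the sample is under-dispersed relative to a binomial"
        )
    return alpha, beta


def mom_fit_betabinomial(scores: Sequence[int], n: int = 71) -> BetaBinomialMix:
    """Fit beta-binomial(n, alpha, beta) by the method of moments.

    The raw moments are taken on the original score scale (no
    rescaling): m1 is the patient mix's average risk score.
    """
    s = np.asarray(scores)
    if s.size and (s.min() < 0 or s.max() > n):
        raise ValueError(f"scores must lie in 0..{n}")
    m = moments(s)
    if m.m2 - m.m1**2 <= 0:
        raise EstimationError("zero sample variance: shapes are not identifiable")
    alpha, beta = _betabinomial_mom(m, n)
    return BetaBinomialMix(n, alpha, beta)


def mom_fit_betabinomial_from_moments(m: MomentEstimates, n: int = 71) -> BetaBinomialMix:
    alpha, beta = _betabinomial_mom(m, n)
    return BetaBinomialMix(n, alpha, beta)


def betabinomial_pmf(x, mix: BetaBinomialMix):
    """P(x | n, a, b) = C(n, x) B(a + x, n + b - x) / B(a, b)."""
    return mix.pmf(x)


def expected_score(mix: PatientMix) -> float:
    """Mean risk score of the mix on the integer score scale."""
    return mix.mean_score()


def median_score(mix: DiscreteMix) -> int:
    """Smallest score s with CDF(s) >= 1/2."""
    if getattr(mix, "continuous", False):
        raise TypeError("median_score is defined for discrete mixes")
    return mix.median_score()


def sample_scores(mix: PatientMix, count: int, seed: int) -> np.ndarray:
    """Draw ``count`` i.i.d. scores from the mix, reproducibly.

    Discrete mixes return integer scores; a continuous BetaMix returns
    values on the [0, 1] scale.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(seed)
    return mix.sample(count, rng)


def log_beta(alpha: float, beta: float) -> float:
    """log B(alpha, beta), stable at extreme shapes."""
    return float(betaln(alpha, beta))
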