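"""Control-limit calibration: find h achieving a target in-control ARL.

The in-control ARL is a nondecreasing (for discrete mixes: fine step)
function of the control limit h.  The calibrated limit is defined as
the smallest h on the four-decimal grid whose ARL reaches the target
from above -- the conservative choice on the false-alarm side.  A cheap
coarse-resolution bisection brackets the limit first; the exact grid
point is then located by stepping the full-resolution engine.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arl_markov import MarkovConfig, arl_markov_discrete
from .arl_integral import CollocationConfig, arl_piecewise_collocation, w_continuous_distribution
from .cusum import w_atoms
from .patient_mix import PatientMix
from .risk_model import RiskModel

__all__ = ["CalibrationSpec", "find_limit"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Target in-control ARL, grid precision of h, and ARL engine."""

    target_arl0: float
    precision: float = 1e-4
    engine: str = "markov"
    gamma: int = 10_000
    rounding: str = "split"
    degree: int = 40
    pieces: int = 16
    h_lo: float = 0.1
    h_hi: float = 12.0

    def __post_init__(self) -> None:
        if self.target_arl0 <= 1:
            raise ValueError("target_arl0 must be > 1")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        if self.engine not in ("markov", "collocation"):
            raise ValueError("engine must be 'markov' or 'collocation'")


def _make_evaluator(mix: PatientMix, model: RiskModel, qa: float, spec: CalibrationSpec):
    if spec.engine == "markov":
        if getattr(mix, "continuous", False):
            raise TypeError("markov calibration requires a discrete mix")
        watoms = w_atoms(mix, model, qa)

        def arl(h: float, gamma: int) -> float:
            cfg = MarkovConfig(gamma=gamma, rounding=spec.rounding)
            return arl_markov_discrete(watoms, h, cfg).arl

    else:
        wdist = w_continuous_distribution(mix, model, qa)
        width = wdist.support[1] - wdist.support[0]

        def arl(h: float, gamma: int) -> float:  # gamma ignored
            # at least one subinterval per increment-support width, or
            # the interpolant cannot track L over a wide [0, h]
            import math

            pieces = max(spec.pieces, math.ceil(h / width))
            cfg = CollocationConfig(degree=spec.degree, pieces=pieces)
            return arl_piecewise_collocation(wdist, h, cfg).arl

    return arl


def find_limit(mix: PatientMix, model: RiskModel, qa: float, spec: CalibrationSpec) -> float:
    """Smallest grid h (step ``spec.precision``) with ARL(h) >= target."""
    arl = _make_evaluator(mix, model, qa, spec)
    target = spec.target_arl0
    step = spec.precision
    gamma = spec.gamma
    coarse_gamma = max(2000, gamma // 5)

    lo, hi = spec.h_lo, spec.h_hi
    if arl(hi, coarse_gamma) < target:
        raise ValueError(f"target ARL {target} not bracketed below h = {hi}")
    if arl(lo, coarse_gamma) >= target:
        raise ValueError(f"target ARL {target} already reached at h = {lo}")
    # coarse bisection to ~5 grid steps
    while hi - lo > 5 * step:
        mid = 0.5 * (lo + hi)
        if arl(mid, coarse_gamma) >= target:
            hi = mid
        else:
            lo = mid

    # full-resolution walk on the precision grid
    k = round(lo / step)
    h = k * step
    a = arl(h, gamma)
    if a >= target:
        while a >= target and h > spec.h_lo:
            k -= 1
            h = k * step
            a = arl(h, gamma)
        return round((k + 1) * step, 10)
    while a < target:
        k += 1
        h = k * step
        if h > spec.h_hi:
            raise ValueError("target ARL not reached inside the search interval")
        a = arl(h, gamma)
    return round(k * step, 10)
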