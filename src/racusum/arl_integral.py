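"""ARL via the Fredholm integral equation for a continuous patient mix.

For a continuous W-increment density f_W the expected run length L(u)
of the reflected CUSUM started at u in [0, h] satisfies the Fredholm
equation of the second kind

    L(u) = 1 + L(0) F_W(-u) + int_0^h L(z) f_W(z - u) dz ,

where the F_W(-u) term carries the atom that the reflection at zero
places on state 0.  The equation is solved by (piece-wise) collocation:
L is represented per subinterval of [0, h] by its values at Chebyshev-
Gauss nodes and the equation is enforced at those nodes.  Subinterval
boundaries default to the kink locations of the ARL function (images of
the W branch-support endpoints), which is what makes the piece-wise
variant stable where single-interval collocation plateaus erratically.

For the beta patient mix the kernel integrals are evaluated after a
change of variables back to the score scale x (where the integrand is
the beta density times a smooth factor), with a t = x^alpha
substitution absorbing the integrable endpoint singularity when
alpha < 1.  This avoids quadrature against the kinked and unbounded
W-density altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import expit, logit

from .cusum import ArlResult
from .patient_mix import BetaMix, log_beta
from .risk_model import RiskModel

__all__ = [
    "CollocationConfig",
    "WContinuousDistribution",
    "w_continuous_distribution",
    "arl_collocation",
    "arl_piecewise_collocation",
]


@dataclass(frozen=True)
class CollocationConfig:
    """Chebyshev degree N per subinterval and subinterval count M."""

    degree: int = 40
    pieces: int = 16

    def __post_init__(self) -> None:
        if self.degree < 2:
            raise ValueError("degree must be >= 2")
        if self.pieces < 1:
            raise ValueError("pieces must be >= 1")

    @property
    def dimension(self) -> int:
        return self.degree * self.pieces


class _BetaScoreForm:
    """W as a monotone function of the continuous score x in [0, 1].

    With Q0 = 1 the survival branch is w0(x) = -log(1 + (qa-1) pi(x))
    and the death branch w1(x) = w0(x) + log(qa); pi(x) is the logistic
    risk at score smax*x.  Outcome probabilities use the odds-shifted
    pi*(x) (true process odds ratio qstar).
    """

    def __init__(self, mix: BetaMix, model: RiskModel, qa: float, qstar: float):
        if model.b1 == 0:
            raise ValueError("b1 = 0: W is not an invertible function of the score")
        if qa <= 0 or qstar <= 0 or qa == 1.0:
            raise ValueError("need qa > 0, qa != 1 and qstar > 0")
        self.mix = mix
        self.model = model
        self.qa = qa
        self.qstar = qstar
        self.lnB = log_beta(mix.alpha, mix.beta)
        self.log_qa = np.log(qa)

    def pi(self, x):
        return expit(self.model.b0 + self.model.b1 * self.mix.smax * np.asarray(x, dtype=float))

    def pistar(self, x):
        p = self.pi(x)
        if self.qstar == 1.0:
            return p
        o = self.qstar * p / (1.0 - p)
        return o / (1.0 + o)

    def w0(self, x):
        return -np.log1p((self.qa - 1.0) * self.pi(x))

    def x_of_w0(self, w: float) -> Optional[float]:
        """Inverse of w0 on (0, 1); None if w is outside the open range."""
        p = np.expm1(-w) / (self.qa - 1.0)
        if p <= 0.0 or p >= 1.0:
            return None
        x = (logit(p) - self.model.b0) / (self.model.b1 * self.mix.smax)
        if x <= 0.0 or x >= 1.0:
            return None
        return float(x)

    def fbeta(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            return np.exp(
                (self.mix.alpha - 1.0) * np.log(x)
                + (self.mix.beta - 1.0) * np.log1p(-x)
                - self.lnB
            )

    def branch_supports(self) -> list[tuple[float, float]]:
        """Closed supports [lo, hi] of the y=0 and y=1 branches."""
        a, b = sorted((float(self.w0(0.0)), float(self.w0(1.0))))
        return [(a, b), (a + self.log_qa, b + self.log_qa)]

    def quad_x(self, a: float, b: float, ngl: int, glx, glw):
        """Gauss nodes and beta-density weights on the x-segment [a, b].

        When the segment touches x = 0 and alpha < 1 the substitution
        t = x^alpha removes the endpoint singularity exactly.
        """
        al, be = self.mix.alpha, self.mix.beta
        if al < 1.0:
            # valid for any 0 <= a < b; exact removal of the x=0 singularity
            ta, tb = a**al, b**al
            tq = 0.5 * (ta + tb) + 0.5 * (tb - ta) * glx
            xq = tq ** (1.0 / al)
            wq = glw * 0.5 * (tb - ta) * np.exp(-self.lnB) * (1.0 - xq) ** (be - 1.0) / al
        else:
            xq = 0.5 * (a + b) + 0.5 * (b - a) * glx
            wq = glw * 0.5 * (b - a) * self.fbeta(xq)
        return xq, wq


def _masses(form: _BetaScoreForm, a: float, b: float, ngl: int = 80):
    """(P(y=0, x in [a,b]), P(y=1, x in [a,b])) under the shifted outcome law."""
    if b <= a:
        return 0.0, 0.0
    glx, glw = leggauss(ngl)
    xq, wq = form.quad_x(a, b, ngl, glx, glw)
    ps = form.pistar(xq)
    return float(np.dot(wq, 1.0 - ps)), float(np.dot(wq, ps))


@dataclass
class WContinuousDistribution:
    """CDF/density of the continuous LLR increment W.

    ``branch_points`` lists the kink locations of the density (branch
    support endpoints); an empty tuple means a smooth density (e.g. a
    synthetic test kernel).  ``score_form`` is set when the
    distribution was derived from a beta mix and enables the exact
    change-of-variables kernel integrals in the collocation solver.
    """

    cdf: Callable[[np.ndarray], np.ndarray]
    density: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    branch_points: tuple[float, ...] = ()
    score_form: Optional[_BetaScoreForm] = field(default=None, repr=False)


def w_continuous_distribution(
    mix: BetaMix, model: RiskModel, qa: float, qstar: float = 1.0
) -> WContinuousDistribution:
    """Distribution of W for a continuous beta mix.

    F_W(w) = int [ (1-pi*(x)) 1{w0(x) <= w} + pi*(x) 1{w1(x) <= w} ] f(x) dx,
    computed by monotone inversion of the branches plus quadrature; the
    density follows from the change of variables on each branch.
    """
    form = _BetaScoreForm(mix, model, qa, qstar)
    sup0, sup1 = form.branch_supports()
    lo = min(sup0[0], sup1[0])
    hi = max(sup0[1], sup1[1])
    decreasing = qa > 1.0  # w0 decreasing in x for qa > 1

    def _branch_cdf(w: float, off: float, y: int) -> float:
        """P(y, w_y <= w) for branch offset off (0 or log qa)."""
        lo_b, hi_b = (sup0 if y == 0 else sup1)
        if w < lo_b:
            return 0.0
        if w >= hi_b:
            return _masses(form, 0.0, 1.0)[y]
        x = form.x_of_w0(w - off)
        if x is None:
            return _masses(form, 0.0, 1.0)[y] if w >= hi_b else 0.0
        if decreasing:  # w_y <= w  <=>  x >= x(w)
            return _masses(form, x, 1.0)[y]
        return _masses(form, 0.0, x)[y]

    def cdf(w):
        w = np.atleast_1d(np.asarray(w, dtype=float))
        out = np.array(
            [_branch_cdf(wi, 0.0, 0) + _branch_cdf(wi, form.log_qa, 1) for wi in w]
        )
        return out if out.size > 1 else float(out[0])

    def _branch_pdf(w: float, off: float, y: int) -> float:
        lo_b, hi_b = (sup0 if y == 0 else sup1)
        if not (lo_b < w < hi_b):
            return 0.0
        x = form.x_of_w0(w - off)
        if x is None:
            return 0.0
        p = form.pi(x)
        # |dx/dw| from w0 = -log(1 + (qa-1) pi(x))
        dwdx = abs(qa - 1.0) * model.b1 * mix.smax * p * (1.0 - p) / (1.0 + (qa - 1.0) * p)
        ps = form.pistar(x)
        weight = ps if y == 1 else 1.0 - ps
        return float(weight * form.fbeta(x) / dwdx)

    def density(w):
        w = np.atleast_1d(np.asarray(w, dtype=float))
        out = np.array(
            [_branch_pdf(wi, 0.0, 0) + _branch_pdf(wi, form.log_qa, 1) for wi in w]
        )
        return out if out.size > 1 else float(out[0])

    bps = tuple(sorted({sup0[0], sup0[1], sup1[0], sup1[1]}))
    return WContinuousDistribution(cdf, density, (lo, hi), bps, form)


# ---------------------------------------------------------------------------
# collocation machinery


def _cheb_nodes(a: float, b: float, n: int) -> np.ndarray:
    k = np.arange(n)
    t = np.cos((2 * k + 1) * np.pi / (2 * n))[::-1]
    return 0.5 * (a + b) + 0.5 * (b - a) * t


def _bary_weights(nodes: np.ndarray) -> np.ndarray:
    w = np.empty(len(nodes))
    for j in range(len(nodes)):
        w[j] = 1.0 / np.prod(nodes[j] - np.delete(nodes, j))
    return w


def _bary_eval(nodes: np.ndarray, bw: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Matrix E[p, l] = l-th Lagrange basis evaluated at pts[p]."""
    E = np.zeros((len(pts), len(nodes)))
    for p, x in enumerate(pts):
        d = x - nodes
        hit = np.flatnonzero(np.abs(d) < 1e-14)
        if hit.size:
            E[p, hit[0]] = 1.0
        else:
            t = bw / d
            E[p] = t / t.sum()
    return E


def _partition(h: float, wdist: WContinuousDistribution, pieces: int) -> list[float]:
    """Subinterval boundaries: ARL kink candidates padded to `pieces`."""
    tol = 1e-3 * h  # merge near-coincident kinks: tiny pieces only hurt
    cand: list[float] = []
    for e in wdist.branch_points:
        for c in (-e, h - e):
            if tol < c < h - tol:
                cand.append(c)
    bks = [0.0]
    for c in sorted(cand):
        if c - bks[-1] > tol:
            bks.append(c)
    if h - bks[-1] <= tol:
        bks.pop()
    bks.append(h)
    while len(bks) - 1 > pieces:
        # too many natural kinks for the requested piece count: drop the
        # boundary bounding the smallest piece
        widths = np.diff(bks)
        i = int(np.argmin(widths)) + 1
        if i == len(bks) - 1:
            i -= 1
        bks.pop(i)
    while len(bks) - 1 < pieces:
        widths = np.diff(bks)
        i = int(np.argmax(widths))
        bks.insert(i + 1, 0.5 * (bks[i] + bks[i + 1]))
    return bks


def _solve_collocation_beta(
    form: _BetaScoreForm, h: float, bks: list[float], N: int, ngl: int
) -> tuple[float, int, float]:
    """Assemble and solve the collocation system via x-space integrals."""
    M = len(bks) - 1
    nodes = [_cheb_nodes(bks[j], bks[j + 1], N) for j in range(M)]
    bw = [_bary_weights(nd) for nd in nodes]
    allu = np.concatenate(nodes)
    dim = N * M
    A = np.eye(dim)
    glx, glw = leggauss(ngl)
    E0 = _bary_eval(nodes[0], bw[0], np.array([0.0]))[0]

    def piece_of(v: float) -> int:
        j = int(np.searchsorted(bks, v, side="right")) - 1
        return min(max(j, 0), M - 1)

    for i, u in enumerate(allu):
        for y, off in ((0, 0.0), (1, form.log_qa)):
            # x-breakpoints where v(x) = u + w0(x) + off crosses a boundary
            xs = [0.0, 1.0]
            for tv in [0.0, *bks, h]:
                xx = form.x_of_w0(tv - u - off)
                if xx is not None:
                    xs.append(xx)
            xs = sorted(set(xs))
            for a, b in zip(xs[:-1], xs[1:]):
                if b - a < 1e-14:
                    continue
                xm = 0.5 * (a + b)
                v_mid = u + float(form.w0(xm)) + off
                if v_mid > h:
                    continue  # absorbed: contributes nothing
                xq, wq = form.quad_x(a, b, ngl, glx, glw)
                ps = form.pistar(xq)
                fac = wq * (ps if y == 1 else 1.0 - ps)
                if v_mid < 0:
                    # reflected to 0: weight on the piece-0 interpolant at u=0
                    A[i, :N] -= fac.sum() * E0
                else:
                    j = piece_of(v_mid)
                    vq = u + form.w0(xq) + off
                    A[i, j * N : (j + 1) * N] -= fac @ _bary_eval(nodes[j], bw[j], vq)
    cond = float(np.linalg.cond(A))
    if cond > 1e13:
        raise RuntimeError(f"ill-conditioned collocation system (cond ~ {cond:.2e})")
    L = np.linalg.solve(A, np.ones(dim))
    return float(E0 @ L[:N]), dim, cond


def _solve_collocation_generic(
    wdist: WContinuousDistribution, h: float, bks: list[float], N: int, ngl: int
) -> tuple[float, int, float]:
    """Collocation for an arbitrary (smooth-density) W distribution."""
    M = len(bks) - 1
    nodes = [_cheb_nodes(bks[j], bks[j + 1], N) for j in range(M)]
    bw = [_bary_weights(nd) for nd in nodes]
    allu = np.concatenate(nodes)
    dim = N * M
    A = np.eye(dim)
    glx, glw = leggauss(ngl)
    E0 = _bary_eval(nodes[0], bw[0], np.array([0.0]))[0]
    kinks = np.asarray(wdist.branch_points, dtype=float)
    for i, u in enumerate(allu):
        A[i, :N] -= float(np.atleast_1d(wdist.cdf(-u))[0]) * E0
        for j in range(M):
            a, b = bks[j], bks[j + 1]
            # split [a, b] at z where z - u hits a density kink
            cuts = [a, b] + [u + k for k in kinks if a < u + k < b]
            for za, zb in zip(sorted(cuts)[:-1], sorted(cuts)[1:]):
                if zb - za < 1e-14:
                    continue
                zq = 0.5 * (za + zb) + 0.5 * (zb - za) * glx
                fq = np.atleast_1d(wdist.density(zq - u))
                fac = glw * 0.5 * (zb - za) * fq
                A[i, j * N : (j + 1) * N] -= fac @ _bary_eval(nodes[j], bw[j], zq)
    cond = float(np.linalg.cond(A))
    if cond > 1e13:
        raise RuntimeError(f"ill-conditioned collocation system (cond ~ {cond:.2e})")
    L = np.linalg.solve(A, np.ones(dim))
    return float(E0 @ L[:N]), dim, cond


def _solve(wdist: WContinuousDistribution, h: float, cfg: CollocationConfig, ngl: int):
    if h <= 0:
        raise ValueError("h must be > 0")
    bks = _partition(h, wdist, cfg.pieces)
    if wdist.score_form is not None:
        return _solve_collocation_beta(wdist.score_form, h, bks, cfg.degree, ngl)
    return _solve_collocation_generic(wdist, h, bks, cfg.degree, ngl)


def arl_collocation(
    wdist: WContinuousDistribution, h: float, cfg: CollocationConfig | None = None, ngl: int = 80
) -> ArlResult:
    """Single-interval (M = 1) Chebyshev collocation on [0, h].

    Can plateau erratically when the ARL function has interior kinks;
    prefer :func:`arl_piecewise_collocation` for production numbers.
    """
    cfg = cfg or CollocationConfig(degree=64, pieces=1)
    cfg = CollocationConfig(degree=cfg.degree, pieces=1)
    arl, dim, cond = _solve(wdist, h, cfg, ngl)
    return ArlResult(arl, "collocation", {"degree": cfg.degree, "pieces": 1, "dimension": dim, "cond": cond})


def arl_piecewise_collocation(
    wdist: WContinuousDistribution, h: float, cfg: CollocationConfig | None = None, ngl: int = 80
) -> ArlResult:
    """Piece-wise Chebyshev collocation with kink-aligned subintervals."""
    cfg = cfg or CollocationConfig()
    arl, dim, cond = _solve(wdist, h, cfg, ngl)
    return ArlResult(
        arl,
        "collocation",
        {"degree": cfg.degree, "pieces": cfg.pieces, "dimension": dim, "cond": cond},
    )
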