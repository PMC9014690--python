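"""Structured linear solve for absorbing CUSUM chains.

Both Markov-chain ARL engines lead to a transient submatrix Q whose rows
are shifted copies of one increment distribution, modified only in
column 0 (reflection of the chart at zero) and truncated at the top
(absorption beyond the control limit).  Hence

    I - Q = T - u e0^T

with T a (finite section of a) Toeplitz matrix and u the per-state
probability mass reflected to zero in excess of the Toeplitz value.
The fundamental-matrix system (I - Q) L = 1 is solved with a Levinson
Toeplitz solve plus a Sherman-Morrison rank-1 update, costing O(n^2)
time and O(n) memory instead of the O(n^3)/O(n^2) of a generic solve.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz


class AbsorptionError(RuntimeError):
    """The chain cannot reach the signal region (ARL is infinite)."""


def arl_from_toeplitz(col: np.ndarray, row: np.ndarray, u: np.ndarray) -> float:
    """Solve (T - u e0^T) L = 1 and return L[0].

    ``col``/``row`` are the first column and row of T = I - Toeplitz
    part of Q; ``u`` is the column-0 correction (reflected mass below
    zero).  Raises :class:`AbsorptionError` if the system is singular
    or produces a non-finite/negative expected run length.
    """
    ones = np.ones_like(col)
    try:
        y = solve_toeplitz((col, row), ones)
        z = solve_toeplitz((col, row), u)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise AbsorptionError("singular CUSUM chain system") from exc
    denom = 1.0 - z[0]
    if denom <= 0 or not np.isfinite(denom):
        raise AbsorptionError("no path to absorption: chain never signals")
    L0 = y[0] + z[0] * (y[0] / denom)
    if not np.isfinite(L0) or L0 < 1.0 - 1e-9:
        raise AbsorptionError(f"invalid expected run length {L0}")
    return float(L0)


def toeplitz_pieces_from_lattice(
    offsets: np.ndarray, probs: np.ndarray, nstates: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble col/row of T = I - Toeplitz(Q) and the reflection column u.

    ``offsets`` are integer lattice jumps with probabilities ``probs``;
    the transient states are 0..nstates-1 (jumps beyond the top are
    absorbed, jumps below 0 are clipped to 0).
    """
    n = nstates
    col = np.zeros(n)
    row = np.zeros(n)
    u = np.zeros(n)
    for v, p in zip(offsets, probs):
        v = int(v)
        if v <= 0 and -v < n:
            col[-v] -= p
        if v >= 0 and v < n:
            row[v] -= p
        if v < 0:
            u[: min(n, -v)] += p
    col[0] += 1.0
    row[0] = col[0]
    return col, row, u
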