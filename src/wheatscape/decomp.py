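"""Hodrick-Prescott decomposition of annual area/yield series.

The HP filter splits an annual series x into a smooth trend tau and a
high-frequency residual (here interpreted as the climate-driven component)
by minimizing

    sum_t (x_t - tau_t)^2 + lam * sum_t (tau_{t+1} - 2 tau_t + tau_{t-1})^2.

The first-order conditions are the linear system (I + lam D'D) tau = x with
D the second-difference operator; the system is pentadiagonal and is solved
exactly with a sparse direct solve.  lam controls smoothness: lam -> 0
returns the series itself, lam -> inf the least-squares line.  The default
lam = 100 is the classic choice for annual data (6.25 is the common
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = ["DecompResult", "hp_filter", "annual_difference"]


@dataclass
class DecompResult:
    series: np.ndarray
    trend: np.ndarray       # low-frequency component, same units as series
    climatic: np.ndarray    # series - trend (high-frequency residual)
    annual_diff: np.ndarray  # first differences, indexed by the later year
    lam: float


def hp_filter(series, lam: float = 100.0) -> DecompResult:
    """Exact HP decomposition of an annual series.

    Raises ValueError for n < 4 or lam <= 0.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("HP filter needs a 1-D series with n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if lam <= 0:
        raise ValueError("lam must be positive")
    n = x.size
    eye = sparse.eye(n, format="csc")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    trend = spsolve((eye + lam * (D.T @ D)).tocsc(), x)
    climatic = x - trend
    return DecompResult(
        series=x,
        trend=trend,
        climatic=climatic,
        annual_diff=annual_difference(x),
        lam=float(lam),
    )


def annual_difference(series) -> np.ndarray:
    """First differences x_t - x_{t-1}, aligned to the later year."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("annual difference needs at least two observations")
    return np.diff(x)
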