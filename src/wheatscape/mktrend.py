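"""Mann-Kendall trend test and sequential UF/UB abrupt-change detection.

The Mann-Kendall (MK) test is a nonparametric test for monotone trend in a
time series, built on the pairwise sign statistic

    S = sum_{1 <= j < i <= n} sign(x_i - x_j)

standardized (with a continuity correction) to

    Z = (S - 1)/sqrt(Var S)   if S > 0
        0                     if S = 0
        (S + 1)/sqrt(Var S)   if S < 0

where Var S = [n(n-1)(2n+5) - sum_p t_p(t_p-1)(2t_p+5)] / 18 and the t_p are
the sizes of tied groups.  |Z| > z_crit (1.96 at the conventional two-sided
alpha = 0.05) indicates a significant trend.

The *sequential* MK test (Sneyers) produces a progressive curve UF and a
retrograde curve UB.  UF_i standardizes the cumulative count of pairs
x_i > x_j (j < i, ties counted 1/2) with mean i(i-1)/4 and variance
i(i-1)(2i+5)/72; UB is the progressive statistic of the reversed series,
sign-flipped and re-reversed.  A crossing of UF and UB inside the
[-z_crit, +z_crit] band marks an abrupt change ("mutation") year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


__all__ = [
    "SeriesMK",
    "mk_statistic",
    "mk_variance",
    "critical_value",
    "sequential_uf_ub",
    "detect_mutations",
    "mk_series",
]


@dataclass
class SeriesMK:
    """Full MK analysis of one annual series."""

    years: np.ndarray
    values: np.ndarray
    S: int
    Z: float
    UF: np.ndarray
    UB: np.ndarray
    alpha: float
    z_crit: float
    mutation_years: list[int] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return abs(self.Z) > self.z_crit

    def to_dict(self) -> dict:
        return {
            "years": np.asarray(self.years).tolist(),
            "values": np.asarray(self.values, dtype=float).tolist(),
            "S": int(self.S),
            "Z": float(self.Z),
            "UF": self.UF.tolist(),
            "UB": self.UB.tolist(),
            "alpha": self.alpha,
            "z_crit": self.z_crit,
            "significant": bool(self.significant),
            "mutation_years": [int(y) for y in self.mutation_years],
        }


def _validate(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 3:
        raise ValueError(f"MK test needs n >= 3 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def mk_variance(values) -> float:
    """Tie-corrected variance of S: [n(n-1)(2n+5) - sum t(t-1)(2t+5)]/18."""
    x = np.asarray(values, dtype=float)
    n = x.size
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    if ties.size:
        var -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    return float(var)


def mk_statistic(values) -> tuple[int, float]:
    """Return (S, Z) for the Mann-Kendall test.

    S sums sign(x_i - x_j) over all ordered pairs j < i; Z applies the
    continuity correction (S-1 for S>0, S+1 for S<0) and is 0 when S = 0.
    """
    x = _validate(values)
    diff_signs = np.sign(x[:, None] - x[None, :])  # [i, j] = sign(x_i - x_j)
    S = int(np.sum(np.tril(diff_signs, k=-1)))
    var = mk_variance(x)
    if S == 0 or var == 0.0:
        return S, 0.0
    if S > 0:
        return S, (S - 1) / np.sqrt(var)
    return S, (S + 1) / np.sqrt(var)


def critical_value(alpha: float = 0.05) -> float:
    """Two-sided standard-normal critical value (1.96 at alpha = 0.05)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.norm.ppf(1 - alpha / 2))


def _progressive(x: np.ndarray) -> np.ndarray:
    """Sneyers progressive statistic; ties counted with weight 1/2."""
    n = x.size
    uf = np.zeros(n)
    cum = 0.0
    for i in range(1, n):
        cum += np.sum(x[i] > x[:i]) + 0.5 * np.sum(x[i] == x[:i])
        k = i + 1
        mean = k * (k - 1) / 4.0
        var = k * (k - 1) * (2 * k + 5) / 72.0
        uf[i] = (cum - mean) / np.sqrt(var)
    return uf


def sequential_uf_ub(values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Progressive (UF) and retrograde (UB) sequential MK curves.

    UB is the progressive statistic of the reversed series, negated and
    reversed back so it aligns index-for-index with UF.  Both endpoints
    (UF[0], UB[-1]) are 0 by construction.
    """
    x = _validate(values)
    uf = _progressive(x)
    ub = -_progressive(x[::-1])[::-1]
    return uf, ub


def detect_mutations(
    UF, UB, years=None, z_crit: float = 1.96
) -> list[int]:
    """Years where UF and UB cross inside the +/- z_crit significance band.

    A crossing requires a strict sign change of d = UF - UB between
    consecutive indices; the crossing year is located by linear
    interpolation and rounded to the nearest year.  A run of exact
    equality (d = 0) flanked by opposite signs reports the run's first
    year; equality flanked by the same sign is not a crossing.
    """
    UF = np.asarray(UF, dtype=float)
    UB = np.asarray(UB, dtype=float)
    if UF.shape != UB.shape:
        raise ValueError("UF and UB must have the same length")
    n = UF.size
    if years is None:
        years = np.arange(n)
    years = np.asarray(years, dtype=float)
    d = UF - UB
    out: list[int] = []
    i = 0
    while i < n - 1:
        if d[i] == 0:
            i += 1
            continue
        j = i + 1
        while j < n and d[j] == 0:
            j += 1
        if j < n and np.sign(d[j]) != np.sign(d[i]):
            if j == i + 1:
                t = d[i] / (d[i] - d[j])
                cross_val = UF[i] + t * (UF[j] - UF[i])
                cross_year = years[i] + t * (years[j] - years[i])
            else:  # zero run between opposite signs: take the run's first year
                cross_val = UF[i + 1]
                cross_year = years[i + 1]
            if abs(cross_val) <= z_crit:
                out.append(int(np.floor(cross_year + 0.5)))  # round half up
        i = j if j > i + 1 else i + 1
    return out


def mk_series(years, values, alpha: float = 0.05) -> SeriesMK:
    """Run the full MK analysis (S, Z, UF/UB, mutation years) on one series."""
    x = _validate(values)
    years = np.asarray(years)
    if years.size != x.size:
        raise ValueError("years and values must align")
    S, Z = mk_statistic(x)
    zc = critical_value(alpha)
    uf, ub = sequential_uf_ub(x, alpha=alpha)
    muts = detect_mutations(uf, ub, years=years, z_crit=zc)
    return SeriesMK(
        years=years, values=x, S=S, Z=Z, UF=uf, UB=ub,
        alpha=alpha, z_crit=zc, mutation_years=muts,
    )
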