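"""Pearson correlation of meteorological drivers against area/yield targets.

Builds the 3 x 4 driver table: rows are the growing-season meteorological
factors (accumulated temperature T, precipitation P, sunshine hours h),
columns are planting area, its annual difference, yield, and its annual
difference.  Each cell carries the product-moment r, the two-sided p-value
from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, and the usual
star convention (* p < 0.05, ** p < 0.01).  Drivers are ranked per target
by |r|.  Annual-difference targets are paired with the *level* of the met
factor in the same (later) season; set diff_met=True to pair with the
factor's own annual difference instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrTable", "pearson_with_p", "stars_for", "build_corr_table"]

FACTORS = ["T", "P", "h"]
TARGETS = ["area", "d_area", "yield", "d_yield"]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value (Student-t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def stars_for(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrTable:
    """3 x 4 grid of (r, p, stars) plus a per-target |r| ranking."""

    table: pd.DataFrame                      # index: factor, columns: (target, r/p/stars)
    ranking: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def to_dict(self) -> dict:
        out: dict = {"cells": {}, "ranking": self.ranking}
        for f in self.table.index:
            out["cells"][f] = {
                t: {
                    "r": float(self.table.loc[f, (t, "r")]),
                    "p": float(self.table.loc[f, (t, "p")]),
                    "stars": str(self.table.loc[f, (t, "stars")]),
                }
                for t in TARGETS
            }
        return out


def build_corr_table(
    met: pd.DataFrame,
    area: pd.Series,
    yield_: pd.Series,
    diff_met: bool = False,
) -> CorrTable:
    """Correlate T/P/h against area, yield, and their annual differences.

    `met` is the season table (columns season, T, P, h); `area` and
    `yield_` are indexed by season.  Differences drop the first season and
    pair with the later year's met level (or met difference if diff_met).
    """
    met = met.set_index("season") if "season" in met.columns else met
    seasons = met.index.to_numpy()
    for name, s in (("area", area), ("yield", yield_)):
        if not np.array_equal(np.asarray(s.index), seasons):
            raise ValueError(f"{name} series seasons do not align with met seasons")

    targets = {
        "area": (np.asarray(area, dtype=float), seasons),
        "yield": (np.asarray(yield_, dtype=float), seasons),
        "d_area": (np.diff(np.asarray(area, dtype=float)), seasons[1:]),
        "d_yield": (np.diff(np.asarray(yield_, dtype=float)), seasons[1:]),
    }

    cols = pd.MultiIndex.from_product([TARGETS, ["r", "p", "stars"]])
    table = pd.DataFrame(index=pd.Index(FACTORS, name="factor"), columns=cols)
    ranking: dict[str, list[str]] = {}
    for tname, (tvals, tseasons) in targets.items():
        rs = {}
        for f in FACTORS:
            fvals = met[f].to_numpy(dtype=float)
            if tname.startswith("d_"):
                fv = np.diff(fvals) if diff_met else fvals[1:]
            else:
                fv = fvals
            r, p = pearson_with_p(fv, tvals)
            table.loc[f, (tname, "r")] = r
            table.loc[f, (tname, "p")] = p
            table.loc[f, (tname, "stars")] = stars_for(p)
            rs[f] = abs(r)
        ranking[tname] = sorted(FACTORS, key=lambda f: -rs[f])
    return CorrTable(table=table, ranking=ranking)
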