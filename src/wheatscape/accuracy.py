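"""Area-extraction accuracy against reference (statistical-yearbook) areas.

The relative error of an extracted planting area A_e against the reference
area A_r is

    delta = |A_e - A_r| / A_r * 100   [%]

and extraction accuracy is its complement, 100 - delta.  The metric is
scale-invariant but deliberately asymmetric: the reference area is the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AccuracyReport", "relative_error", "accuracy_series"]


@dataclass
class AccuracyReport:
    A_e: float       # extracted area, k ha
    A_r: float       # reference area, k ha
    delta: float     # relative error, %
    accuracy: float  # 100 - delta, %


def relative_error(A_e: float, A_r: float) -> float:
    """Relative error |A_e - A_r| / A_r * 100, in percent."""
    if A_r <= 0:
        raise ValueError(f"reference area must be positive, got {A_r}")
    if A_e < 0:
        raise ValueError(f"extracted area must be non-negative, got {A_e}")
    return abs(A_e - A_r) / A_r * 100.0


def accuracy_series(extracted: pd.Series, reference: pd.Series) -> tuple[pd.DataFrame, float]:
    """Per-year accuracy reports plus the mean accuracy.

    Both inputs are indexed by year (k ha).  Years must match exactly;
    a mismatch raises naming the offending years.
    """
    ext = pd.Series(extracted, dtype=float)
    ref = pd.Series(reference, dtype=float)
    missing = ref.index.difference(ext.index)
    extra = ext.index.difference(ref.index)
    if len(missing) or len(extra):
        raise ValueError(
            f"year mismatch: missing from extracted {list(missing)}, "
            f"absent from reference {list(extra)}"
        )
    ext = ext.loc[ref.index]
    deltas = np.array([relative_error(e, r) for e, r in zip(ext, ref)])
    table = pd.DataFrame(
        {
            "year": ref.index,
            "extracted_kha": ext.to_numpy(),
            "reference_kha": ref.to_numpy(),
            "delta_pct": deltas,
            "accuracy_pct": 100.0 - deltas,
        }
    ).reset_index(drop=True)
    return table, float(np.mean(100.0 - deltas))
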