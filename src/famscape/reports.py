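"""Summary data behind the survey figures: 3-D projection pies and period
histograms with skewness.

Rendering is deliberately thin and optional; everything here returns plain
data structures that the tests (and any plotting frontend) consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gridspace import VARIED_PARAMS

__all__ = ["ProjectionPoint", "projection_pies", "period_histograms"]


@dataclass(frozen=True)
class ProjectionPoint:
    coordinates: tuple[float, ...]
    count: int
    composition: dict[float, int]
    radius: float  # natural log of count


def _column(db: pd.DataFrame, param: str) -> str:
    if param == "e_leak":
        return "e_leak_mV"
    if param not in VARIED_PARAMS:
        raise KeyError(f"unknown varied parameter: {param!r}")
    return param


def projection_pies(db: pd.DataFrame, axes: tuple[str, str, str],
                    pie_param: str) -> list[ProjectionPoint]:
    """Project instances onto three parameter axes with a composition pie.

    Each distinct coordinate triple becomes one point whose radius is the
    natural log of the number of instances projected there, and whose
    composition tallies the fourth parameter's values.
    """
    if len(set(axes) | {pie_param}) != 4:
        raise ValueError("axes and pie parameter must be four distinct parameters")
    cols = [_column(db, a) for a in axes]
    pie_col = _column(db, pie_param)
    points = []
    for coords, sub in db.groupby(cols, sort=True):
        comp = sub[pie_col].value_counts().to_dict()
        count = int(len(sub))
        points.append(
            ProjectionPoint(
                coordinates=tuple(float(c) for c in np.atleast_1d(coords)),
                count=count,
                composition={float(k): int(v) for k, v in comp.items()},
                radius=math.log(count),
            )
        )
    return points


def period_histograms(db: pd.DataFrame, by_param: str,
                      period_col: str = "period_s") -> dict[float, dict[str, object]]:
    """Per-parameter-value period histogram (1 s integer bins) + skewness.

    Bins are ``[n, n+1)`` on integer edges; skewness is the adjusted
    Fisher–Pearson standardized third moment (the common small-sample
    corrected estimator).
    """
    col = _column(db, by_param)
    out: dict[float, dict[str, object]] = {}
    for value, sub in db.groupby(col, sort=True):
        periods = sub[period_col].dropna().to_numpy(dtype=float)
        if len(periods) == 0:
            out[float(value)] = {"edges": np.empty(0), "counts": np.empty(0, dtype=int),
                                 "skewness": float("nan"), "n": 0}
            continue
        lo = math.floor(periods.min())
        hi = math.floor(periods.max()) + 1  # max value falls in [n, n+1)
        edges = np.arange(lo, hi + 1)
        counts, _ = np.histogram(periods, bins=edges)
        skew = float(stats.skew(periods, bias=False)) if len(periods) >= 3 else float("nan")
        out[float(value)] = {"edges": edges, "counts": counts,
                             "skewness": skew, "n": int(len(periods))}
    return out
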