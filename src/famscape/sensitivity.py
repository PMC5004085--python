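"""Monotonicity and slope-based sensitivity classification of family curves.

A family curve plots one burst characteristic (period in s or spike
frequency in Hz) against the defining-parameter fraction of each member.
Sensitivity is judged by the most negative tangent slope of a smooth
polynomial fit (degree 5, reduced for short curves): steeper than −2.5
(descent angle ≳ 68°) is *high*, shallower than −0.4 (≲ 22°) is *low*, the
rest is *medium*.  The x axis is in canonical-fraction units (0.00–1.75) so
those thresholds correspond to the stated angles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .family_analysis import Family

__all__ = [
    "FamilyCurve",
    "SensitivityClass",
    "is_monotonic",
    "classify_sensitivity",
    "average_change",
    "group_summary",
]

HIGH_SLOPE_THRESHOLD = -2.5
LOW_SLOPE_THRESHOLD = -0.4
_DERIV_GRID = 1000


@dataclass(frozen=True)
class FamilyCurve:
    x: tuple[float, ...]
    y: tuple[float, ...]
    family: Family | None = None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ValueError("curve needs matching x/y with at least 2 points")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("curve x values must be strictly increasing")


@dataclass(frozen=True)
class SensitivityClass:
    label: str  # high | medium | low
    max_descent_slope: float


def is_monotonic(curve: FamilyCurve) -> str:
    """``increasing`` / ``decreasing`` / ``non_monotonic`` by sign test.

    Zero differences are compatible with either direction (non-strict); an
    entirely flat curve reports ``increasing`` by convention.
    """
    diffs = np.diff(curve.y)
    if np.all(diffs >= 0):
        return "increasing"
    if np.all(diffs <= 0):
        return "decreasing"
    return "non_monotonic"


def classify_sensitivity(curve: FamilyCurve) -> SensitivityClass:
    """Three-way class from the most negative fitted tangent slope.

    Fits a polynomial of degree ``min(5, npoints - 1)`` and minimizes its
    derivative over the member span, sampling a dense grid plus the
    derivative's analytic critical points (deterministic).
    """
    if len(curve.x) < 3:
        raise ValueError("curve too short to fit (need >= 3 points)")
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    deg = min(5, len(x) - 1)
    poly = Polynomial.fit(x, y, deg)
    deriv = poly.deriv()
    grid = np.linspace(x[0], x[-1], _DERIV_GRID)
    candidates = [grid]
    crit = deriv.deriv().roots()
    crit = crit[np.isreal(crit)].real
    crit = crit[(crit >= x[0]) & (crit <= x[-1])]
    if len(crit):
        candidates.append(crit)
    pts = np.concatenate(candidates)
    slope = float(np.min(deriv(pts)))
    # 1e-9 tie-break so exact-threshold slopes are not misfiled by fit noise
    if slope <= HIGH_SLOPE_THRESHOLD + 1e-9:
        label = "high"
    elif slope >= LOW_SLOPE_THRESHOLD - 1e-9:
        label = "low"
    else:
        label = "medium"
    return SensitivityClass(label=label, max_descent_slope=slope)


def average_change(curves: list[FamilyCurve]) -> float:
    """Mean over curves of (last − first) characteristic value."""
    if not curves:
        raise ValueError("curve set must be nonempty")
    return float(np.mean([c.y[-1] - c.y[0] for c in curves]))


def group_summary(classified: list[tuple[FamilyCurve, SensitivityClass]]
                  ) -> dict[str, dict[str, dict[float, int]]]:
    """Per sensitivity class and context parameter: value counts + medians.

    Returns ``summary[class][param]`` mapping each grid value to the number
    of distinct families holding it; the median value is stored under key
    ``summary[class][param + "_median"]`` as a scalar.
    """
    values: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for curve, cls in classified:
        if curve.family is None:
            raise ValueError("group_summary needs curves with family references")
        for name, val in curve.family.context:
            values[cls.label][name].append(val)
    out: dict[str, dict[str, object]] = {}
    for label, params in values.items():
        out[label] = {}
        for name, vals in params.items():
            counts: dict[float, int] = defaultdict(int)
            for v in vals:
                counts[v] += 1
            out[label][name] = dict(sorted(counts.items()))
            out[label][name + "_median"] = float(np.median(vals))
    return out
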