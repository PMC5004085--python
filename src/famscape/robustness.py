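"""Family-structure robustness measures and the weighted score.

For a parameter *t* and a size threshold *n*:

* ``X`` — number of families with more than *n* members,
* ``Y`` — number of noninterrupted families with more than *n* members,
* ``Z`` — number of interruptions whose missing member keeps functional
  bursting (label fHCO); ``z_scope="all_missing"`` additionally counts
  missing members outside the permissible range.

The score is the weighted cumulative sum ``R = wX*X + wY*Y + wZ*Z`` with
nonnegative weights summing to one, optionally normalized to a
user-supplied denominator (e.g. X itself).
"""

from __future__ import annotations

from dataclasses import dataclass

from .family_analysis import FamilySizeTable, MissingAttribution

__all__ = ["RobustnessReport", "measures", "score", "normalize"]

DEFAULT_WEIGHTS = (0.5, 0.5, 0.0)


@dataclass(frozen=True)
class RobustnessReport:
    parameter: str
    n: int
    X: int
    Y: int
    Z: int
    weights: tuple[float, float, float]
    R: float
    normalized: float | None = None


def measures(size_table: FamilySizeTable,
             attribution: MissingAttribution | None = None,
             n: int = 4,
             z_scope: str = "inside") -> tuple[int, int, int]:
    """(X, Y, Z) for threshold ``n`` (families with more than ``n`` members)."""
    max_size = max(size_table.total, default=8)
    if not 0 <= n <= max(7, max_size - 1):
        raise ValueError(f"threshold n={n} out of range")
    if z_scope not in {"inside", "all_missing"}:
        raise ValueError(f"unknown z_scope: {z_scope!r}")
    X = sum(c for s, c in size_table.total.items() if s > n)
    Y = sum(c for s, c in size_table.noninterrupted.items() if s > n)
    Z = 0
    if attribution is not None:
        Z = sum(
            1
            for m in attribution.members
            if m.family.size > n
            and m.label == "fHCO"
            and (m.inside or z_scope == "all_missing")
        )
    return X, Y, Z


def score(X: float, Y: float, Z: float,
          weights: tuple[float, float, float] = DEFAULT_WEIGHTS) -> float:
    """Weighted cumulative sum ``wX*X + wY*Y + wZ*Z``."""
    wX, wY, wZ = weights
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    if abs(wX + wY + wZ - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return wX * X + wY * Y + wZ * Z


def normalize(R: float, denominator: float) -> float:
    """``R / denominator``, reported to three decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(R / denominator, 3)


def report(parameter: str, size_table: FamilySizeTable,
           attribution: MissingAttribution | None = None, n: int = 4,
           weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
           z_scope: str = "inside",
           normalize_to: str | float | None = None) -> RobustnessReport:
    """Convenience wrapper producing a full :class:`RobustnessReport`."""
    X, Y, Z = measures(size_table, attribution, n=n, z_scope=z_scope)
    R = score(X, Y, Z, weights)
    norm = None
    if normalize_to == "X":
        norm = normalize(R, X)
    elif isinstance(normalize_to, (int, float)):
        norm = normalize(R, float(normalize_to))
    return RobustnessReport(parameter=parameter, n=n, X=X, Y=Y, Z=Z,
                            weights=tuple(weights), R=R, normalized=norm)
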