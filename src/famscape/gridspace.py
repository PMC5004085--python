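"""Parameter-space definitions, grid enumeration and the instance-table format.

The model space is spanned by seven maximal conductances, each varied as a
fraction of its canonical value, plus the leak reversal potential ``E_leak``.
A *grid point* fixes all eight; a *grid* is the Cartesian product of the
per-parameter level lists.  Instance databases are stored as TSV with a
versioned header line so that a table written by one version of the package
is readable (or rejected loudly) by another.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "VARIED_FRACTIONS",
    "VARIED_PARAMS",
    "CanonicalSet",
    "GridSpec",
    "ParameterPoint",
    "InstanceRecord",
    "LABELS",
    "enumerate_grid",
    "grid_size",
    "to_absolute",
    "context_key",
    "read_db",
    "write_db",
    "records_to_frame",
    "frame_to_records",
]

#: Conductance scale fractions, in the fixed mixed-radix enumeration order
#: (slowest-varying first).  ``e_leak`` varies fastest.
VARIED_FRACTIONS = ("x_P", "x_K2", "x_Leak", "x_CaS", "x_h", "x_SynS", "x_SynG")
#: All eight varied parameters (fractions + leak reversal potential).
VARIED_PARAMS = VARIED_FRACTIONS + ("e_leak",)

#: Activity labels an instance can carry.
LABELS = (
    "silent",
    "spiking",
    "plateau",
    "asymmetric",
    "burster",
    "realistic_burster",
    "fHCO",
    "rHCO",
    "other",
)

_CHAR_COLS = ("period_s", "spike_freq_hz", "duty_pct", "phase", "cv_period", "cv_amp")

DB_COLUMNS = VARIED_FRACTIONS + ("e_leak_mV", "label") + _CHAR_COLS + ("fail_flags",)
DB_HEADER = "# famscape-db v1"


@dataclass(frozen=True)
class CanonicalSet:
    """Canonical maximal conductances (nS) and leak reversal potential (mV).

    The first seven conductances are the varied ones; ``g_Na``, ``g_CaF``,
    ``g_K1`` and ``g_KA`` are held fixed in every instance.
    """

    g_CaS: float = 3.2
    g_h: float = 4.0
    g_P: float = 7.0
    g_K2: float = 80.0
    g_Leak: float = 8.0
    g_SynS: float = 60.0
    g_SynG: float = 30.0
    g_Na: float = 200.0
    g_CaF: float = 5.0
    g_K1: float = 100.0
    g_KA: float = 80.0
    E_leak_canonical: float = -60.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name.startswith("g_") and getattr(self, f.name) < 0:
                raise ValueError(f"conductance {f.name} must be >= 0")


_DEFAULT_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75)
_DEFAULT_ELEAK = (-70.0, -65.0, -60.0, -55.0, -50.0)


def _round2(values: Iterable[float]) -> tuple[float, ...]:
    # fractions are exact two-decimal values; rounding on entry keeps
    # grouping by equality safe.
    return tuple(round(float(v), 2) for v in values)


@dataclass(frozen=True)
class GridSpec:
    """Level lists for the seven fractions and for ``E_leak``."""

    x_P: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_K2: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_Leak: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_CaS: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_h: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_SynS: tuple[float, ...] = _DEFAULT_FRACTIONS
    x_SynG: tuple[float, ...] = _DEFAULT_FRACTIONS
    e_leak_levels: tuple[float, ...] = _DEFAULT_ELEAK

    def __post_init__(self) -> None:
        for name in VARIED_FRACTIONS:
            levels = _round2(getattr(self, name))
            if not levels:
                raise ValueError(f"empty level list for {name}")
            if any(v < 0 for v in levels):
                raise ValueError(f"negative fraction in {name}")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"levels for {name} must be strictly increasing")
            object.__setattr__(self, name, levels)
        e = tuple(float(v) for v in self.e_leak_levels)
        if not e:
            raise ValueError("empty level list for e_leak")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("e_leak levels must be strictly increasing")
        object.__setattr__(self, "e_leak_levels", e)

    def levels(self, param: str) -> tuple[float, ...]:
        """Level list for any of the eight varied parameters."""
        if param == "e_leak":
            return self.e_leak_levels
        if param in VARIED_FRACTIONS:
            return getattr(self, param)
        raise KeyError(f"unknown varied parameter: {param!r}")


@dataclass(frozen=True)
class ParameterPoint:
    """One grid point: seven scale fractions plus ``E_leak`` in mV."""

    x_P: float
    x_K2: float
    x_Leak: float
    x_CaS: float
    x_h: float
    x_SynS: float
    x_SynG: float
    e_leak: float

    def __post_init__(self) -> None:
        for name in VARIED_FRACTIONS:
            object.__setattr__(self, name, round(float(getattr(self, name)), 2))
        object.__setattr__(self, "e_leak", float(self.e_leak))

    def get(self, param: str) -> float:
        if param not in VARIED_PARAMS:
            raise KeyError(f"unknown varied parameter: {param!r}")
        return getattr(self, param)

    def replace(self, **kwargs: float) -> "ParameterPoint":
        d = {p: self.get(p) for p in VARIED_PARAMS}
        d.update(kwargs)
        return ParameterPoint(**d)


@dataclass
class InstanceRecord:
    """A grid point with its activity label and burst characteristics.

    Characteristics are ``None`` for labels that have no bursting (silent,
    spiking, plateau, ...).  ``fail_flags`` is a three-character mask over
    the realistic criteria (period / spike frequency / duty cycle), e.g.
    ``"P-D"`` for an instance failing period and duty cycle; ``"---"`` means
    all criteria met and ``""`` means not applicable.
    """

    point: ParameterPoint
    label: str
    period_s: float | None = None
    spike_freq_hz: float | None = None
    duty_pct: float | None = None
    phase: float | None = None
    cv_period: float | None = None
    cv_amp: float | None = None
    fail_flags: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown activity label: {self.label!r}")


def grid_size(spec: GridSpec) -> int:
    """Number of points in the grid (analytic, no enumeration)."""
    return math.prod(len(spec.levels(p)) for p in VARIED_PARAMS)


def enumerate_grid(spec: GridSpec) -> Iterator[ParameterPoint]:
    """Yield every grid point exactly once.

    Order is mixed-radix with ``x_P`` varying slowest and ``e_leak``
    fastest, i.e. lexicographic in
    ``(x_P, x_K2, x_Leak, x_CaS, x_h, x_SynS, x_SynG, e_leak)``.
    """
    level_lists = [spec.levels(p) for p in VARIED_PARAMS]
    for combo in itertools.product(*level_lists):
        yield ParameterPoint(*combo)


def to_absolute(point: ParameterPoint, canon: CanonicalSet | None = None) -> dict[str, float]:
    """Absolute conductances (nS) and ``E_leak`` (mV) for a grid point.

    Varied conductances are ``fraction x canonical``; the four fixed
    conductances pass through unchanged.
    """
    canon = canon or CanonicalSet()
    out = {
        "g_P": point.x_P * canon.g_P,
        "g_K2": point.x_K2 * canon.g_K2,
        "g_Leak": point.x_Leak * canon.g_Leak,
        "g_CaS": point.x_CaS * canon.g_CaS,
        "g_h": point.x_h * canon.g_h,
        "g_SynS": point.x_SynS * canon.g_SynS,
        "g_SynG": point.x_SynG * canon.g_SynG,
        "g_Na": canon.g_Na,
        "g_CaF": canon.g_CaF,
        "g_K1": canon.g_K1,
        "g_KA": canon.g_KA,
        "E_leak": point.e_leak,
    }
    return out


def context_key(point: ParameterPoint, defining: str) -> tuple[tuple[str, float], ...]:
    """Opaque-but-introspectable key identifying a family context.

    Two points share a key iff they agree on all varied parameters except
    ``defining``.  The key is a tuple of ``(name, value)`` pairs in the
    canonical parameter order, with the defining parameter omitted.
    """
    if defining not in VARIED_PARAMS:
        raise KeyError(f"unknown varied parameter: {defining!r}")
    return tuple((p, point.get(p)) for p in VARIED_PARAMS if p != defining)


# ---------------------------------------------------------------------------
# instance-table I/O (TSV, versioned header)
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[InstanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {p: r.point.get(p) for p in VARIED_FRACTIONS}
        row["e_leak_mV"] = r.point.e_leak
        row["label"] = r.label
        for c in _CHAR_COLS:
            row[c] = getattr(r, c)
        row["fail_flags"] = r.fail_flags
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DB_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[InstanceRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            point = ParameterPoint(
                *[d[p] for p in VARIED_FRACTIONS], e_leak=d["e_leak_mV"]
            )
            chars = {
                c: (None if pd.isna(d[c]) else float(d[c])) for c in _CHAR_COLS
            }
            flags = d["fail_flags"]
            rec = InstanceRecord(
                point=point,
                label=str(d["label"]),
                fail_flags="" if pd.isna(flags) else str(flags),
                **chars,
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed instance table row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_db(path, records: Iterable[InstanceRecord] | pd.DataFrame) -> None:
    """Write an instance table as TSV with the versioned header line."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    with open(path, "w") as fh:
        fh.write(DB_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_db(path, as_frame: bool = False) -> list[InstanceRecord] | pd.DataFrame:
    """Read an instance table written by :func:`write_db`.

    Malformed rows raise :class:`ValueError` naming the (0-based) row.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if header != DB_HEADER:
            raise ValueError(
                f"not a famscape instance table (header {header!r}, expected {DB_HEADER!r})"
            )
        df = pd.read_csv(fh, sep="\t", dtype={"fail_flags": "string", "label": "string"})
    missing = set(DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"instance table missing columns: {sorted(missing)}")
    records = frame_to_records(df)  # validates every row
    if as_frame:
        return records_to_frame(records)
    return records
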