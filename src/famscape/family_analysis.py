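"""One-parameter families: construction, size tables, missing-member
attribution and ensemble selection.

A *family* is a maximal set of instances from one activity group that agree
on every varied parameter except the defining one.  Its *sequence* is the
sorted list of defining-parameter values; the *permissible range* runs from
the first to the last member.  Grid levels absent from the sequence inside
that range are interruptions (``missing_inside``); levels outside the range
are ``missing_outside``.  One-member families count as noninterrupted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .gridspace import (
    GridSpec,
    InstanceRecord,
    ParameterPoint,
    context_key,
)

__all__ = [
    "Family",
    "FamilySizeTable",
    "MissingMember",
    "MissingAttribution",
    "build_families",
    "tabulate_sizes",
    "attribute_missing",
    "select_ensembles",
]

ContextKey = tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class Family:
    defining: str
    context: ContextKey
    members: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate family members")
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        for m in self.members:
            if m not in self.levels:
                raise ValueError(f"member {m} not on the grid for {self.defining}")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def begin(self) -> float:
        return self.members[0]

    @property
    def end(self) -> float:
        return self.members[-1]

    @property
    def missing_inside(self) -> tuple[float, ...]:
        return tuple(
            v for v in self.levels if self.begin < v < self.end and v not in self.members
        )

    @property
    def missing_outside(self) -> tuple[float, ...]:
        return tuple(v for v in self.levels if v < self.begin or v > self.end)

    @property
    def interrupted(self) -> bool:
        return len(self.missing_inside) > 0

    def member_point(self, value: float) -> ParameterPoint:
        """The grid point of the (possibly missing) member at ``value``."""
        d = dict(self.context)
        d[self.defining] = value
        return ParameterPoint(**d)


@dataclass
class FamilySizeTable:
    """Counts of (total, noninterrupted) families per size."""

    total: dict[int, int] = field(default_factory=dict)
    noninterrupted: dict[int, int] = field(default_factory=dict)

    def sizes(self) -> list[int]:
        return sorted(self.total)

    def group_size(self) -> int:
        return sum(s * c for s, c in self.total.items())


@dataclass(frozen=True)
class MissingMember:
    family: Family
    value: float
    inside: bool
    label: str
    category: str | None  # failed-criteria category for fHCO labels


@dataclass
class MissingAttribution:
    members: list[MissingMember] = field(default_factory=list)

    def by_label(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for m in self.members:
            out[m.label] += 1
        return dict(out)

    def fhco_share(self, size: int, inside_only: bool = False) -> float:
        """Fraction of missing members of size-``size`` families labelled fHCO."""
        pool = [
            m for m in self.members
            if m.family.size == size and (m.inside or not inside_only)
        ]
        if not pool:
            return float("nan")
        return sum(m.label == "fHCO" for m in pool) / len(pool)

    def category_table(self) -> dict[int, dict[str, int]]:
        """fHCO missing members binned by family size and failed criteria."""
        out: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        for m in self.members:
            if m.label == "fHCO" and m.category is not None:
                out[m.family.size][m.category] += 1
        return {s: dict(d) for s, d in out.items()}


def build_families(group: list[InstanceRecord], defining: str,
                   spec: GridSpec) -> list[Family]:
    """Partition a label-homogeneous instance group into families.

    Instances are grouped by their context key (all varied parameters but
    the defining one); each context becomes one family, singletons
    included.  Off-grid instances raise.
    """
    levels = spec.levels(defining)
    buckets: dict[ContextKey, list[float]] = defaultdict(list)
    for rec in group:
        value = rec.point.get(defining)
        if value not in levels:
            raise ValueError(
                f"instance value {value} for {defining} is not a grid level"
            )
        buckets[context_key(rec.point, defining)].append(value)
    return [
        Family(defining=defining, context=ctx, members=tuple(vals), levels=levels)
        for ctx, vals in buckets.items()
    ]


def tabulate_sizes(families: list[Family]) -> FamilySizeTable:
    table = FamilySizeTable()
    for fam in families:
        table.total[fam.size] = table.total.get(fam.size, 0) + 1
        if not fam.interrupted:
            table.noninterrupted[fam.size] = table.noninterrupted.get(fam.size, 0) + 1
        else:
            table.noninterrupted.setdefault(fam.size, 0)
    return table


def attribute_missing(families: list[Family],
                      full_db: dict[ParameterPoint, InstanceRecord] | list[InstanceRecord],
                      include_outside: bool = True) -> MissingAttribution:
    """Look up the activity label of every missing family member.

    ``full_db`` must contain a record for every grid point referenced; a
    missing grid point raises.  fHCO-labelled members are binned by the
    realistic criteria they fail (taken from the record's ``fail_flags``).
    """
    if not isinstance(full_db, dict):
        full_db = {rec.point: rec for rec in full_db}
    attribution = MissingAttribution()
    for fam in families:
        targets = [(v, True) for v in fam.missing_inside]
        if include_outside:
            targets += [(v, False) for v in fam.missing_outside]
        for value, inside in targets:
            point = fam.member_point(value)
            rec = full_db.get(point)
            if rec is None:
                raise KeyError(f"grid point {point} absent from full database")
            category = None
            if rec.label == "fHCO":
                category = _category_from_mask(rec.fail_flags)
            attribution.members.append(
                MissingMember(family=fam, value=value, inside=inside,
                              label=rec.label, category=category)
            )
    return attribution


def _category_from_mask(mask: str) -> str | None:
    from .activity_classifier import CATEGORY_NAMES

    failed = set()
    if len(mask) == 3:
        if mask[0] == "P":
            failed.add("period")
        if mask[1] == "F":
            failed.add("freq")
        if mask[2] == "D":
            failed.add("duty")
    if not failed:
        return None
    return CATEGORY_NAMES[frozenset(failed)]


def select_ensembles(families: list[Family],
                     full_db: dict[ParameterPoint, InstanceRecord] | list[InstanceRecord] | None,
                     min_members: int = 4,
                     isolated_filter: str | None = None) -> list[Family]:
    """Noninterrupted large families suitable as model ensembles.

    Keeps noninterrupted families with more than ``min_members`` members
    whose context has every conductance fraction nonzero.  With
    ``isolated_filter`` set (e.g. ``"spiking"`` or ``"realistic_burster"``),
    each member's synapse-free counterpart in ``full_db`` must carry that
    label.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    from .gridspace import LABELS

    if isolated_filter is not None and isolated_filter not in LABELS:
        raise ValueError(f"unknown filter label: {isolated_filter!r}")
    if isolated_filter is not None and full_db is None:
        raise ValueError("isolated_filter requires the full database")
    if full_db is not None and not isinstance(full_db, dict):
        full_db = {rec.point: rec for rec in full_db}
    selected = []
    for fam in families:
        if fam.interrupted or fam.size <= min_members:
            continue
        ctx = dict(fam.context)
        if any(v == 0 for name, v in ctx.items() if name != "e_leak"):
            continue
        if isolated_filter is not None:
            ok = True
            for value in fam.members:
                iso_point = fam.member_point(value).replace(x_SynS=0.0, x_SynG=0.0)
                rec = full_db.get(iso_point)
                if rec is None:
                    raise KeyError(f"isolated counterpart {iso_point} absent from full database")
                if rec.label != isolated_filter:
                    ok = False
                    break
            if not ok:
                continue
        selected.append(fam)
    return selected
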