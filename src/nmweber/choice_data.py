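"""Ingestion and reduction of 2AFC feeder-visit data.

A discrimination session offers an animal two feeders: a *standard* at a
fixed sugar concentration and a *test* feeder whose concentration varies
between conditions.  Each session starts with a forced alternation phase
(equal sampling of both feeders) followed by a free choice phase.  The unit
of analysis is the per-condition *discrimination performance*: the
proportion of choice-phase visits (capped at a fixed number per
presentation, 100 by default, so every animal contributes after an equal
amount of sampling) that went to the higher-concentration feeder, pooled
over the repeated presentations of the condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    ClassificationError,
    DomainError,
    EmptyDataError,
    FormatError,
    PoolingError,
)

__all__ = [
    "ConditionSpec",
    "VisitRecord",
    "PerformanceRecord",
    "discrimination_performance",
    "split_high_low",
    "pool_performance",
    "read_performance_csv",
    "write_performance_csv",
    "read_visit_csv",
    "write_visit_csv",
    "visits_to_performance",
]

PHASES = ("alternation", "choice")
ROLES = ("test", "standard")
SIDES = ("left", "right")

PERFORMANCE_COLUMNS = ["x_conc", "a_conc", "n_high", "n_total"]
VISIT_COLUMNS = [
    "timestamp",
    "individual_id",
    "session_id",
    "phase",
    "feeder_role",
    "feeder_side",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One concentration pairing of a 2AFC experiment.

    ``positions`` lists, per presentation, which side held the test feeder;
    consecutive presentations of a condition swap sides as a positional-bias
    control.
    """

    sequence_index: int
    test_conc: float
    standard_conc: float = 20.0
    n_presentations: int = 2
    positions: tuple[str, ...] = ("left", "right")

    def __post_init__(self) -> None:
        if self.test_conc <= 0 or self.standard_conc <= 0:
            raise DomainError("concentrations must be positive")
        if self.n_presentations < 1:
            raise DomainError("n_presentations must be >= 1")
        if len(self.positions) != self.n_presentations:
            raise DomainError(
                f"positions length {len(self.positions)} != "
                f"n_presentations {self.n_presentations}"
            )
        for p in self.positions:
            if p not in SIDES:
                raise DomainError(f"unknown side {p!r}")

    @property
    def higher_role(self) -> str:
        """Which feeder role holds the higher concentration.

        On equal concentrations the test feeder is 'higher' by convention;
        performance then measures side/position bias only.
        """
        return "test" if self.test_conc >= self.standard_conc else "standard"

    @property
    def x(self) -> float:
        return max(self.test_conc, self.standard_conc)

    @property
    def a(self) -> float:
        return min(self.test_conc, self.standard_conc)


@dataclass(frozen=True)
class VisitRecord:
    """A single feeder visit."""

    timestamp: float
    individual_id: str
    session_id: str
    phase: str
    feeder_role: str
    feeder_side: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise FormatError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.feeder_role not in ROLES:
            raise FormatError(f"unknown feeder role {self.feeder_role!r}")
        if self.feeder_side not in SIDES:
            raise FormatError(f"unknown feeder side {self.feeder_side!r}")


@dataclass(frozen=True)
class PerformanceRecord:
    """Per-condition discrimination performance.

    ``x`` is the higher and ``a`` the lower of the two concentrations;
    ``n_high`` of ``n_total`` counted visits went to the higher option.
    ``meta`` carries bookkeeping such as visit shortfalls and never affects
    equality or pooling.
    """

    x: float
    a: float
    n_high: int
    n_total: int
    meta: Mapping[str, object] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.x < self.a or self.a <= 0:
            raise DomainError(f"need x >= a > 0, got x={self.x}, a={self.a}")
        if self.n_total <= 0:
            raise DomainError("n_total must be positive")
        if not 0 <= self.n_high <= self.n_total:
            raise DomainError(
                f"n_high={self.n_high} outside [0, n_total={self.n_total}]"
            )

    @property
    def performance(self) -> float:
        return self.n_high / self.n_total

    @property
    def condition_key(self) -> tuple[float, float]:
        return (self.x, self.a)


def discrimination_performance(
    visits: Sequence[VisitRecord],
    condition: ConditionSpec,
    max_choice_visits: int = 100,
) -> PerformanceRecord:
    """Reduce one individual's visits for one condition to a performance record.

    Only choice-phase visits count, and at most ``max_choice_visits`` per
    presentation (session), pooled over all presentations.  ``n_high`` counts
    visits to the feeder role holding the higher concentration.  If a session
    has fewer than ``max_choice_visits`` choice visits, all available visits
    are used and the shortfall is recorded in ``meta['shortfall']``.
    """
    if max_choice_visits < 1:
        raise DomainError("max_choice_visits must be >= 1")
    individuals = {v.individual_id for v in visits}
    if len(individuals) > 1:
        raise DomainError(
            f"visits must belong to one individual, got {sorted(individuals)}"
        )
    higher_role = condition.higher_role
    n_high = 0
    n_total = 0
    shortfall = 0
    sessions_seen = []
    # group by session preserving first-appearance order
    by_session: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_session.setdefault(v.session_id, []).append(v)
    for session_id, session_visits in by_session.items():
        session_visits.sort(key=lambda v: v.timestamp)
        choice_visits = [v for v in session_visits if v.phase == "choice"]
        counted = choice_visits[:max_choice_visits]
        if not counted:
            continue
        sessions_seen.append(session_id)
        shortfall += max(0, max_choice_visits - len(counted))
        n_total += len(counted)
        n_high += sum(1 for v in counted if v.feeder_role == higher_role)
    if n_total == 0:
        raise EmptyDataError(
            f"no choice-phase visits for condition {condition.sequence_index} "
            f"(test {condition.test_conc}% vs standard {condition.standard_conc}%)"
        )
    return PerformanceRecord(
        x=condition.x,
        a=condition.a,
        n_high=n_high,
        n_total=n_total,
        meta={
            "sequence_index": condition.sequence_index,
            "n_sessions": len(sessions_seen),
            "shortfall": shortfall,
        },
    )


def split_high_low(
    records: Iterable[PerformanceRecord],
    standard: float,
) -> tuple[list[PerformanceRecord], list[PerformanceRecord]]:
    """Split records into (LOW, HIGH) sets around the standard concentration.

    LOW holds conditions whose test concentration is <= the standard, HIGH
    those >= the standard; the equal-concentration condition belongs to both
    sets.  Every record must involve the standard as one of its two
    concentrations.
    """
    low: list[PerformanceRecord] = []
    high: list[PerformanceRecord] = []
    for rec in records:
        involves = math.isclose(rec.x, standard) or math.isclose(rec.a, standard)
        if not involves:
            raise ClassificationError(
                f"record ({rec.x}, {rec.a}) does not involve the standard {standard}"
            )
        if math.isclose(rec.x, rec.a):
            low.append(rec)
            high.append(rec)
        elif math.isclose(rec.a, standard):  # test above the standard
            high.append(rec)
        else:  # test below the standard
            low.append(rec)
    return low, high


def pool_performance(
    record_sets: Mapping[str, Iterable[PerformanceRecord]],
) -> list[PerformanceRecord]:
    """Pool per-individual records over individuals, condition by condition.

    Counts are summed across individuals for identical (x, a) pairs and the
    performance recomputed — a visit-weighted mean.  Pooling heterogeneous
    individuals attenuates the fitted slope but leaves threshold and lapse
    essentially unbiased, which is why cross-study comparisons pool even
    when individual data exist.
    """
    keys_by_individual = {
        ind: {r.condition_key for r in recs}
        for ind, recs in {k: list(v) for k, v in record_sets.items()}.items()
    }
    all_keys = set().union(*keys_by_individual.values()) if keys_by_individual else set()
    for ind, keys in keys_by_individual.items():
        missing = all_keys - keys
        if missing:
            raise PoolingError(
                f"individual {ind!r} lacks conditions {sorted(missing)}"
            )
    totals: dict[tuple[float, float], list[int]] = {}
    for recs in record_sets.values():
        for rec in recs:
            agg = totals.setdefault(rec.condition_key, [0, 0])
            agg[0] += rec.n_high
            agg[1] += rec.n_total
    return [
        PerformanceRecord(x=x, a=a, n_high=nh, n_total=nt, meta={"pooled_over": len(record_sets)})
        for (x, a), (nh, nt) in sorted(totals.items())
    ]


def read_performance_csv(path: str | Path) -> list[PerformanceRecord]:
    """Read performance records from CSV with columns x_conc,a_conc,n_high,n_total."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in PERFORMANCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            x = float(row["x_conc"])
            a = float(row["a_conc"])
            n_high = int(row["n_high"])
            n_total = int(row["n_total"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {line}: non-numeric cell ({exc})") from exc
        try:
            records.append(PerformanceRecord(x=x, a=a, n_high=n_high, n_total=n_total))
        except DomainError as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
    return records


def write_performance_csv(records: Iterable[PerformanceRecord], path: str | Path) -> None:
    """Write performance records to CSV; round-trips with the reader."""
    df = pd.DataFrame(
        [(r.x, r.a, r.n_high, r.n_total) for r in records],
        columns=PERFORMANCE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_visit_csv(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
) -> list[VisitRecord]:
    """Read a visit log.

    The native schema is ``timestamp,individual_id,session_id,phase,
    feeder_role,feeder_side``.  ``column_mapping`` translates foreign column
    names (``{native_name: foreign_name}``) so logs from other acquisition
    systems can be adapted without rewriting files.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if column_mapping:
        rename = {foreign: native for native, foreign in column_mapping.items()}
        df = df.rename(columns=rename)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    visits = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            visits.append(
                VisitRecord(
                    timestamp=float(row["timestamp"]),
                    individual_id=str(row["individual_id"]),
                    session_id=str(row["session_id"]),
                    phase=str(row["phase"]),
                    feeder_role=str(row["feeder_role"]),
                    feeder_side=str(row["feeder_side"]),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
    return visits


def write_visit_csv(visits: Iterable[VisitRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (v.timestamp, v.individual_id, v.session_id, v.phase, v.feeder_role, v.feeder_side)
            for v in visits
        ],
        columns=VISIT_COLUMNS,
    )
    df.to_csv(path, index=False)


def visits_to_performance(
    visits: Sequence[VisitRecord],
    conditions: Mapping[str, ConditionSpec],
    max_choice_visits: int = 100,
) -> dict[str, list[PerformanceRecord]]:
    """Reduce a multi-individual visit log to per-individual performance tables.

    ``conditions`` maps session_id -> ConditionSpec.  Sessions belonging to
    the same condition (repeated presentations) share a ConditionSpec object
    and are pooled inside :func:`discrimination_performance`.
    """
    by_individual: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_individual.setdefault(v.individual_id, []).append(v)
    out: dict[str, list[PerformanceRecord]] = {}
    for ind, ind_visits in by_individual.items():
        by_condition: dict[int, tuple[ConditionSpec, list[VisitRecord]]] = {}
        for v in ind_visits:
            if v.session_id not in conditions:
                raise FormatError(f"session {v.session_id!r} has no condition spec")
            cond = conditions[v.session_id]
            entry = by_condition.setdefault(cond.sequence_index, (cond, []))
            entry[1].append(v)
        out[ind] = [
            discrimination_performance(vs, cond, max_choice_visits)
            for cond, vs in (by_condition[k] for k in sorted(by_condition))
        ]
    return out
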