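"""Combination-schedule regimen grid and its a-priori partial toxicity order.

The trial studies two agents given together: a backbone agent N (two dose
levels, 100 and 200 mg) and a novel agent M (five dose levels, 30-180 mg)
administered under one of two schedules -- S1, continuous once-daily dosing,
or S2, an intermittent schedule roughly half as intensive over the 28-day
DLT window.  The 20 resulting combination-schedule regimens are laid out on
a grid; toxicity is known a priori to increase with either agent's dose and
with schedule intensification, but "anti-diagonal" pairs (for example a
higher single dose of M under the less intensive schedule versus a lower
single dose given continuously) have an unknown order.  This module encodes
the grid, derived quantities (average weekly dose of M) and the partial
order that every candidate toxicity ordering must respect.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Schedule",
    "Regimen",
    "RegimenGrid",
    "PartialOrder",
    "MoveDescriptor",
    "avg_weekly_dose",
    "build_default_grid",
    "known_partial_order",
    "classify_move",
]

N_DOSES = (100, 200)
M_DOSES = (30, 60, 90, 130, 180)


class Schedule(str, enum.Enum):
    """Administration schedule of agent M, ordered by intensity."""

    S2 = "S2"  # intermittent, ~half as intensive over the DLT window
    S1 = "S1"  # continuous once daily

    @property
    def intensity(self) -> int:
        return 1 if self is Schedule.S2 else 2

    @property
    def days_per_week(self) -> float:
        """Effective dosing days per week (S2 is half as intensive as S1)."""
        return 7.0 if self is Schedule.S1 else 3.5


def avg_weekly_dose(m_dose: float, schedule: Schedule | str) -> float:
    """Average weekly dose of agent M in mg/week.

    7 x single dose under the continuous schedule S1, 3.5 x under the
    intermittent schedule S2 (half intensity).
    """
    if m_dose <= 0:
        raise ValueError(f"m_dose must be positive, got {m_dose}")
    schedule = Schedule(schedule)
    return schedule.days_per_week * m_dose


@dataclass(frozen=True)
class Regimen:
    """One combination-schedule regimen (a cell of the grid)."""

    index: int
    n_dose: float  # mg of the backbone agent N
    m_dose: float  # single dose of agent M, mg
    schedule: Schedule

    @property
    def avg_weekly_dose(self) -> float:
        return avg_weekly_dose(self.m_dose, self.schedule)

    @property
    def coords(self) -> tuple[float, float, int]:
        """(n_dose, m_dose, schedule intensity) triple."""
        return (self.n_dose, self.m_dose, self.schedule.intensity)

    def __repr__(self) -> str:  # compact, matches the trial's labels
        return (
            f"Regimen({self.index}: N={self.n_dose:g}, M={self.m_dose:g}, "
            f"{self.schedule.value}, {self.avg_weekly_dose:g} mg/wk)"
        )


@dataclass(frozen=True)
class RegimenGrid:
    """Ordered collection of regimens with 1-based contiguous indices."""

    regimens: tuple[Regimen, ...]

    def __post_init__(self) -> None:
        indices = [r.index for r in self.regimens]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("regimen indices must be 1..K with no gaps")
        coords = {r.coords for r in self.regimens}
        if len(coords) != len(self.regimens):
            raise ValueError("(n_dose, m_dose, schedule) triples must be distinct")

    def __len__(self) -> int:
        return len(self.regimens)

    def __iter__(self):
        return iter(self.regimens)

    def __getitem__(self, index: int) -> Regimen:
        """Look up a regimen by its 1-based index."""
        if not 1 <= index <= len(self.regimens):
            raise KeyError(f"regimen index {index} outside 1..{len(self.regimens)}")
        return self.regimens[index - 1]

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(r.index for r in self.regimens)

    @property
    def dose_levels_n(self) -> tuple[float, ...]:
        return tuple(sorted({r.n_dose for r in self.regimens}))

    @property
    def dose_levels_m(self) -> tuple[float, ...]:
        return tuple(sorted({r.m_dose for r in self.regimens}))

    @property
    def schedules(self) -> tuple[Schedule, ...]:
        present = {r.schedule for r in self.regimens}
        return tuple(s for s in (Schedule.S2, Schedule.S1) if s in present)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.regimens],
                "n_dose_mg": [r.n_dose for r in self.regimens],
                "m_dose_mg": [r.m_dose for r in self.regimens],
                "schedule": [r.schedule.value for r in self.regimens],
                "avg_weekly_dose_mg": [r.avg_weekly_dose for r in self.regimens],
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegimenGrid":
        regimens = tuple(
            Regimen(
                index=int(row["index"]),
                n_dose=float(row["n_dose_mg"]),
                m_dose=float(row["m_dose_mg"]),
                schedule=Schedule(row["schedule"]),
            )
            for _, row in df.sort_values("index").iterrows()
        )
        grid = cls(regimens)
        if "avg_weekly_dose_mg" in df.columns:
            declared = df.sort_values("index")["avg_weekly_dose_mg"].to_numpy()
            for r, d in zip(grid.regimens, declared):
                if abs(r.avg_weekly_dose - float(d)) > 1e-9:
                    raise ValueError(
                        f"regimen {r.index}: declared average weekly dose {d} "
                        f"inconsistent with schedule ({r.avg_weekly_dose})"
                    )
        return grid

    @classmethod
    def from_csv(cls, path_or_buf) -> "RegimenGrid":
        return cls.from_frame(pd.read_csv(path_or_buf))


def build_default_grid() -> RegimenGrid:
    """The trial's 20-regimen grid.

    Indices 1-5: N=100, schedule S2, M in (30, 60, 90, 130, 180);
    6-10: N=100, S1, same M doses; 11-20 repeat the pattern at N=200.
    """
    regimens = []
    idx = 1
    for n in N_DOSES:
        for sched in (Schedule.S2, Schedule.S1):
            for m in M_DOSES:
                regimens.append(Regimen(index=idx, n_dose=n, m_dose=m, schedule=sched))
                idx += 1
    return RegimenGrid(tuple(regimens))


@dataclass(frozen=True)
class PartialOrder:
    """A-priori known toxicity relations between regimens.

    ``known_less_toxic`` holds ordered index pairs (a, b): regimen a is known
    to be no more toxic than regimen b.  It is irreflexive, acyclic and
    transitively closed.  ``unknown_pairs`` holds the remaining (unordered)
    pairs, stored with a < b.
    """

    known_less_toxic: frozenset[tuple[int, int]]
    unknown_pairs: frozenset[tuple[int, int]] = field(default=frozenset())

    def __post_init__(self) -> None:
        for a, b in self.known_less_toxic:
            if a == b:
                raise ValueError("known_less_toxic must be irreflexive")
            if (b, a) in self.known_less_toxic:
                raise ValueError(f"cyclic relation between {a} and {b}")
        overlap = {tuple(sorted(p)) for p in self.known_less_toxic} & set(
            self.unknown_pairs
        )
        if overlap:
            raise ValueError(f"pairs both known and unknown: {sorted(overlap)}")

    def is_known(self, a: int, b: int) -> bool:
        """True iff a is known a-priori to be no more toxic than b."""
        return (a, b) in self.known_less_toxic


def _base_relations(
    grid: RegimenGrid, diagonal_dominance: bool = True
) -> set[tuple[int, int]]:
    rel: set[tuple[int, int]] = set()
    for a in grid:
        for b in grid:
            if a.index == b.index:
                continue
            # monotonicity in one coordinate with the other two fixed
            if (
                a.n_dose == b.n_dose
                and a.schedule == b.schedule
                and a.m_dose < b.m_dose
            ):
                rel.add((a.index, b.index))
            elif (
                a.n_dose == b.n_dose
                and a.m_dose == b.m_dose
                and a.schedule.intensity < b.schedule.intensity
            ):
                rel.add((a.index, b.index))
            elif (
                a.m_dose == b.m_dose
                and a.schedule == b.schedule
                and a.n_dose < b.n_dose
            ):
                rel.add((a.index, b.index))
            # clinician-asserted diagonal dominance: intensifying the
            # schedule while strictly raising the average weekly dose of M
            # outweighs any decrease in the single dose (e.g. (14) < (18)).
            elif (
                diagonal_dominance
                and a.n_dose == b.n_dose
                and a.schedule.intensity < b.schedule.intensity
                and a.avg_weekly_dose < b.avg_weekly_dose
            ):
                rel.add((a.index, b.index))
    return rel


def _transitive_closure(rel: set[tuple[int, int]], nodes) -> set[tuple[int, int]]:
    succ = {n: set() for n in nodes}
    for a, b in rel:
        succ[a].add(b)
    closed = set(rel)
    changed = True
    while changed:
        changed = False
        for a in nodes:
            new = set()
            for b in succ[a]:
                new |= succ[b]
            if not new <= succ[a]:
                succ[a] |= new
                changed = True
    return {(a, b) for a in nodes for b in succ[a]}


def known_partial_order(
    grid: RegimenGrid, diagonal_dominance: bool = True
) -> PartialOrder:
    """Derive the a-priori partial order from the grid coordinates.

    Known relations: monotonicity within each single coordinate (dose of
    either agent, or schedule intensity, the others fixed) plus -- by
    default -- the clinician-asserted diagonal rule: schedule
    intensification combined with a strict increase in the average weekly
    dose of M dominates a decrease in the single dose.  Everything else
    (the anti-diagonal moves, and cross-N moves not implied transitively)
    is left unknown.

    ``diagonal_dominance=False`` drops the clinical diagonal assertions and
    leaves pure within-agent monotonicity -- the weaker notion under which
    ordering *feasibility* is defined (the classic robustness traversals
    such as "by columns" are feasible in that sense but violate the
    diagonal assertions).
    """
    base = _base_relations(grid, diagonal_dominance)
    closed = _transitive_closure(base, list(grid.indices))
    for a, b in closed:
        if (b, a) in closed:
            raise AssertionError("derived partial order is cyclic")
    unknown = frozenset(
        (a, b)
        for a in grid.indices
        for b in grid.indices
        if a < b and (a, b) not in closed and (b, a) not in closed
    )
    return PartialOrder(known_less_toxic=frozenset(closed), unknown_pairs=unknown)


@dataclass(frozen=True)
class MoveDescriptor:
    """Per-dimension changes between two regimens (escalation bookkeeping)."""

    n_dose: int  # -1 decrease, 0 unchanged, +1 increase
    m_dose: int
    schedule: int  # +1 intensify (S2 -> S1), -1 de-intensify

    @property
    def increases(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, v in (
                ("n_dose", self.n_dose),
                ("m_dose", self.m_dose),
                ("schedule", self.schedule),
            )
            if v > 0
        )

    @property
    def decreases(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, v in (
                ("n_dose", self.n_dose),
                ("m_dose", self.m_dose),
                ("schedule", self.schedule),
            )
            if v < 0
        )

    @property
    def changed(self) -> tuple[str, ...]:
        return self.increases + self.decreases


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_move(from_regimen: Regimen, to_regimen: Regimen) -> MoveDescriptor:
    """Describe which of the three dimensions change, and in which direction."""
    return MoveDescriptor(
        n_dose=_sign(to_regimen.n_dose - from_regimen.n_dose),
        m_dose=_sign(to_regimen.m_dose - from_regimen.m_dose),
        schedule=_sign(
            to_regimen.schedule.intensity - from_regimen.schedule.intensity
        ),
    )
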