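"""Escalation restrictions, admissible set, allocation and stopping rules.

Four restrictions gate which regimens the next cohort may receive:

1. *Overdose control*: regimen i is safe only if the posterior probability
   that its DLT risk exceeds the upper target bound stays below the
   threshold c_overdose.
2. *One dimension at a time*: an escalating move may increase at most one
   of {backbone dose, single dose of M, schedule intensity}.  A move may
   combine that single increase with de-escalations in other dimensions
   (the anti-diagonal moves of the grid), and pure de-escalations or
   lateral moves are not constrained by this rule.
3. *No more than doubling*: neither the average weekly dose nor the single
   dose of M may more than double relative to the current regimen when any
   dimension is escalated.
4. *No increase after a DLT*: if the current cohort experienced at least
   one DLT, neither the average weekly dose of M nor the backbone dose may
   increase.

The recommended regimen is the admissible delta-minimiser; the engine also
exposes the full admissible set so that a safety committee (or the
randomised "within admissible set" allocation) can overrule the point
recommendation.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np

from .grid import classify_move

if TYPE_CHECKING:  # pragma: no cover
    from .model import POCRMResults, TrialData

__all__ = [
    "admissible_set",
    "recommend_next",
    "randomize_within_admissible",
    "check_stopping",
    "final_selection",
]


def admissible_set(
    results: "POCRMResults", current: int, dlts_in_current_cohort: int
) -> set[int]:
    """Regimens the next cohort may receive, given the current regimen and
    the number of DLTs observed in the cohort just completed."""
    grid = results.model.grid
    design = results.model.design
    if not 1 <= current <= len(grid):
        raise ValueError(f"current regimen {current} not in the grid")
    cur = grid[current]
    overdose = results.overdose_prob
    admissible: set[int] = set()
    for reg in grid:
        if overdose[reg.index - 1] >= design.c_overdose:
            continue  # restriction 1
        move = classify_move(cur, reg)
        if move.increases:
            if len(move.increases) > 1:
                continue  # restriction 2
            if (
                reg.avg_weekly_dose > 2.0 * cur.avg_weekly_dose
                or reg.m_dose > 2.0 * cur.m_dose
            ):
                continue  # restriction 3
        if dlts_in_current_cohort >= 1:
            if reg.avg_weekly_dose > cur.avg_weekly_dose or reg.n_dose > cur.n_dose:
                continue  # restriction 4
        admissible.add(reg.index)
    return admissible


def recommend_next(
    admissible: Iterable[int],
    deltas: np.ndarray,
    results: "POCRMResults | None" = None,
) -> int | None:
    """The delta-minimising admissible regimen; None signals a stop.

    Ties in delta are broken toward the regimen with the smaller estimated
    DLT risk (the less toxic one under the selected ordering), then toward
    the lower index for full determinism.
    """
    admissible = sorted(admissible)
    if not admissible:
        return None
    deltas = np.asarray(deltas, dtype=float)
    best = min(d for i, d in zip(range(1, len(deltas) + 1), deltas) if i in set(admissible))
    tied = [i for i in admissible if deltas[i - 1] <= best + 1e-12]
    if len(tied) > 1 and results is not None:
        p_hat = results.p_hat
        tied.sort(key=lambda i: (p_hat[i - 1], i))
    return tied[0]


def randomize_within_admissible(
    admissible: Iterable[int],
    deltas: np.ndarray,
    rng: np.random.Generator,
) -> int | None:
    """Sample the next regimen within the admissible set with probabilities
    proportional to 1/delta.  A numerically zero delta is replaced by the
    smallest positive delta in the set divided by 10, keeping weights finite
    while still strongly favouring the on-target regimen."""
    admissible = sorted(admissible)
    if not admissible:
        return None
    deltas = np.asarray(deltas, dtype=float)
    d = deltas[[i - 1 for i in admissible]].copy()
    positive = d[d > 0]
    if positive.size == 0:
        weights = np.ones_like(d)
    else:
        d[d <= 0] = positive.min() / 10.0
        weights = 1.0 / d
    probs = weights / weights.sum()
    return int(rng.choice(admissible, p=probs))


def check_stopping(
    data: "TrialData", any_regimen_safe: bool, max_n: int
) -> str:
    """Trial status: 'stop_safety', 'stop_maxn' or 'continue'."""
    if not any_regimen_safe:
        return "stop_safety"
    if data.total_n >= max_n:
        return "stop_maxn"
    return "continue"


def final_selection(
    results: "POCRMResults", apply_move_restrictions: bool = False
) -> int | None:
    """Terminal regimen selection at the end of the trial.

    Default rule: among all regimens passing overdose control under the
    final fit, return the delta-minimiser with no relative-move
    restrictions.  Optionally the full restriction set relative to the last
    treated regimen can be applied instead.  Returns None when nothing is
    safe (a safety stop).
    """
    if apply_move_restrictions:
        candidates = results.admissible_set()
    else:
        candidates = results.safe_set()
    return recommend_next(candidates, results.delta, results)
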