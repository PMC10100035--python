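"""Dose-transition pathways and safety-committee reports.

A dose-transition pathway (DTP) is the decision tree obtained by running
the full update/admissibility/recommendation cycle on every hypothetical
DLT outcome (0..c per cohort) of the next few cohorts.  Within each branch
the criterion-recommended regimen (the starred one) drives the trajectory;
alongside it the admissible set is reported so the safety committee can see
the choice it would have at each step.

Because the full admissible set can be large (with no DLTs everything is
eventually admissible), the displayed set is condensed for communication:
if several admissible regimens carry the high backbone dose, only those are
shown; if exactly one does, it is shown together with the low-backbone
regimens whose average weekly dose of M is no less than half the current
one; otherwise all admissible regimens are shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .grid import RegimenGrid
from .model import PartialOrderCRM, POCRMResults, TrialData

__all__ = ["PathwayNode", "build_dtp", "display_filter", "src_report", "dtp_table", "to_dot"]


@dataclass(frozen=True)
class PathwayNode:
    """State of the pathway after observing one hypothetical cohort outcome.

    The node's cohort was treated at ``regimen``; ``dlts`` of the
    ``cohort_size`` patients experienced a DLT.  The decision fields hold
    the model's reaction to that outcome; ``children`` maps each possible
    DLT count of the *next* cohort (treated at ``recommended``) to the
    corresponding node, and is empty at the requested depth or after a
    stop.
    """

    cohort: int  # 1-based cohort number of the observed outcome
    regimen: int  # regimen the cohort received
    dlts: int  # hypothetical DLT count in that cohort
    admissible: frozenset[int]
    displayed: tuple[int, ...]
    recommended: int | None  # starred regimen; None = safety stop
    stopped: bool
    children: dict[int, "PathwayNode"] = field(default_factory=dict)


def display_filter(
    admissible: set[int] | frozenset[int], grid: RegimenGrid, current: int
) -> tuple[int, ...]:
    """Condense the admissible set for display (three-case rule)."""
    n_high = max(grid.dose_levels_n)
    high = sorted(i for i in admissible if grid[i].n_dose == n_high)
    if len(high) >= 2:
        return tuple(high)
    if len(high) == 1:
        half = grid[current].avg_weekly_dose / 2.0
        low = sorted(
            i
            for i in admissible
            if grid[i].n_dose < n_high and grid[i].avg_weekly_dose >= half - 1e-9
        )
        return tuple(sorted(high + low))
    return tuple(sorted(admissible))


def build_dtp(
    model: PartialOrderCRM,
    start: int | None = None,
    depth: int = 3,
    model_averaging: bool = False,
    initial_data: TrialData | None = None,
) -> dict[int, PathwayNode]:
    """Decision tree over all hypothetical DLT outcomes of ``depth`` cohorts.

    Returns the first-cohort branches: a mapping from the DLT count of the
    first cohort (treated at ``start``) to its :class:`PathwayNode`.  Every
    node's decisions are produced by exactly the same fit/admissibility/
    recommendation code the trial engine uses, so pathway branches are
    bit-identical to running the escalation sequentially on the same
    hypothetical data.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    start = start if start is not None else model.design.start_regimen
    c = model.design.cohort_size
    data0 = initial_data if initial_data is not None else model.empty_data()

    def expand(cohort: int, regimen: int, dlts: int, data: TrialData) -> PathwayNode:
        data = data.add_cohort(regimen, c, dlts)
        results = model.fit(data, model_averaging=model_averaging)
        safe = results.safe_set()
        admissible = results.admissible_set(regimen, dlts) if safe else set()
        recommended = (
            results.recommend(regimen, dlts) if admissible else None
        )
        node = PathwayNode(
            cohort=cohort,
            regimen=regimen,
            dlts=dlts,
            admissible=frozenset(admissible),
            displayed=display_filter(admissible, model.grid, regimen)
            if admissible
            else (),
            recommended=recommended,
            stopped=recommended is None,
        )
        if cohort < depth and recommended is not None:
            for k in range(c + 1):
                node.children[k] = expand(cohort + 1, recommended, k, data)
        return node

    return {k: expand(1, start, k, data0) for k in range(c + 1)}


def dtp_table(branches: dict[int, PathwayNode]) -> pd.DataFrame:
    """Flatten a pathway tree into one row per node (canonical text form)."""
    rows = []

    def walk(node: PathwayNode, path: tuple[int, ...]):
        rows.append(
            {
                "cohort": node.cohort,
                "dlt_path": "/".join(map(str, path)),
                "regimen": node.regimen,
                "dlts": node.dlts,
                "admissible": " ".join(map(str, sorted(node.admissible))),
                "displayed": " ".join(map(str, node.displayed)),
                "recommended": node.recommended if node.recommended else "stop",
            }
        )
        for k in sorted(node.children):
            walk(node.children[k], path + (k,))

    for k in sorted(branches):
        walk(branches[k], (k,))
    return pd.DataFrame(rows)


def to_dot(branches: dict[int, PathwayNode]) -> str:
    """Graphviz rendering of the pathway tree (presentation only)."""
    lines = ["digraph dtp {", "  node [shape=box, fontsize=10];"]
    counter = [0]

    def label(node: PathwayNode) -> str:
        shown = ", ".join(
            f"({i})*" if i == node.recommended else f"({i})"
            for i in (node.displayed or sorted(node.admissible))
        )
        if node.stopped:
            shown = "stop: no admissible regimen"
        return f"cohort {node.cohort}: ({node.regimen}) with {node.dlts} DLT\\n{shown}"

    def walk(node: PathwayNode, parent: str | None):
        counter[0] += 1
        name = f"n{counter[0]}"
        lines.append(f'  {name} [label="{label(node)}"];')
        if parent is not None:
            lines.append(f"  {parent} -> {name};")
        for k in sorted(node.children):
            walk(node.children[k], name)

    root = "root"
    lines.append(f'  {root} [label="start", shape=ellipse];')
    for k in sorted(branches):
        walk(branches[k], root)
    lines.append("}")
    return "\n".join(lines)


def src_report(results: POCRMResults) -> pd.DataFrame:
    """Per-regimen report for the safety review committee.

    Counts, posterior mean DLT risk, underdose/target/overdose interval
    probabilities, criterion values, admissibility flags and the starred
    recommendation -- the numerical companion to the pathway tree.
    """
    return results.summary()


def plot_interval_probabilities(results: POCRMResults, ax=None):
    """Stacked-bar display of P(underdose)/P(target)/P(overdose) per regimen."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    table = results.summary()
    idx = table.index
    ax.bar(idx, table["prob_underdose"], label="P(risk < lower bound)")
    ax.bar(
        idx,
        table["prob_target"],
        bottom=table["prob_underdose"],
        label="P(risk in target range)",
    )
    ax.bar(
        idx,
        table["prob_overdose"],
        bottom=table["prob_underdose"] + table["prob_target"],
        label="P(risk > upper bound)",
    )
    ax.set_xlabel("regimen")
    ax.set_ylabel("posterior probability")
    ax.set_xticks(list(idx))
    ax.legend(fontsize=8)
    return ax
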