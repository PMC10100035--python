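"""Trial simulation, operating characteristics and design calibration.

Scenarios assign a true DLT probability to every regimen.  The bundled set
of twenty scenarios moves the anti-diagonal carrying the target regimens
across the grid, from the most optimistic case (only the highest regimen is
at the target) to the most toxic one (only the lowest regimen is
tolerable).  For each scenario the *optimal* regimens are those whose true
toxicity is closest to the middle of the target range (27.5%) and the
*correct* ones those with true toxicity inside the 20-35% band; both sets
are derived from the probabilities rather than stored.

A simulated trial runs cohorts of 3 from the starting regimen, samples DLT
counts from the true probabilities, refits the model after every cohort and
allocates the next cohort either to the criterion minimiser ("next best")
or by randomisation within the admissible set with weights proportional to
1/delta ("within admissible set"); each rule is also available under
ordering-averaged (model averaging) inference.  Operating characteristics
are Monte-Carlo estimates over independent replicate trials; the summary
row reports per-metric means over scenarios (M) and the fraction of
scenarios clearing the reporting thresholds (optimal selections above 40%,
correct above 60%, overly toxic below 25%; strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import escalation
from .design import DesignParams
from .model import PartialOrderCRM, TrialData

__all__ = [
    "Scenario",
    "TrialRecord",
    "default_scenarios",
    "load_scenarios",
    "scenarios_to_csv",
    "simulate_trial",
    "operating_characteristics",
    "oc_table",
    "summary_metrics",
    "first_cohort_constraints_hold",
    "calibrate",
    "ALLOCATION_RULES",
]

ALLOCATION_RULES = (
    "next_best",
    "within_admissible",
    "model_averaging_next_best",
    "model_averaging_within_admissible",
)


@dataclass(frozen=True)
class Scenario:
    """True per-regimen DLT probabilities plus derived target sets."""

    name: str
    true_tox: tuple[float, ...]
    gamma: float = 0.275
    correct_band: tuple[float, float] = (0.20, 0.35)

    def __post_init__(self) -> None:
        arr = np.asarray(self.true_tox)
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError("true toxicities must lie strictly in (0, 1)")

    @property
    def optimal_set(self) -> frozenset[int]:
        """Regimens with true toxicity closest to the target gamma."""
        arr = np.asarray(self.true_tox)
        dist = np.abs(arr - self.gamma)
        best = dist.min()
        return frozenset(int(i) + 1 for i in np.flatnonzero(dist <= best + 1e-12))

    @property
    def correct_set(self) -> frozenset[int]:
        lo, hi = self.correct_band
        arr = np.asarray(self.true_tox)
        return frozenset(
            int(i) + 1 for i in np.flatnonzero((arr >= lo - 1e-12) & (arr <= hi + 1e-12))
        )

    @property
    def overtoxic_set(self) -> frozenset[int]:
        hi = self.correct_band[1]
        arr = np.asarray(self.true_tox)
        return frozenset(int(i) + 1 for i in np.flatnonzero(arr > hi + 1e-12))

    def prob(self, regimen: int) -> float:
        return self.true_tox[regimen - 1]


# The bundled regimen-toxicity scenarios.  Each entry lists the true DLT
# probabilities for regimens 1..20 (index order: N=100/S2, N=100/S1,
# N=200/S2, N=200/S1, each block by increasing single dose of M).
_SCENARIO_TABLE: dict[str, tuple[float, ...]] = {
    "1": (
        0.01, 0.02, 0.03, 0.05, 0.10,
        0.02, 0.05, 0.10, 0.15, 0.20,
        0.02, 0.03, 0.05, 0.10, 0.15,
        0.05, 0.10, 0.15, 0.20, 0.30,
    ),
    "2.1": (
        0.02, 0.03, 0.05, 0.10, 0.15,
        0.03, 0.10, 0.15, 0.20, 0.30,
        0.03, 0.05, 0.10, 0.15, 0.20,
        0.10, 0.15, 0.20, 0.30, 0.50,
    ),
    "2.2": (
        0.01, 0.02, 0.03, 0.05, 0.10,
        0.03, 0.05, 0.10, 0.15, 0.45,
        0.03, 0.05, 0.10, 0.15, 0.20,
        0.10, 0.15, 0.20, 0.30, 0.50,
    ),
    "2.3": (
        0.01, 0.03, 0.05, 0.10, 0.15,
        0.03, 0.10, 0.13, 0.20, 0.30,
        0.03, 0.05, 0.10, 0.13, 0.20,
        0.10, 0.13, 0.15, 0.45, 0.50,
    ),
    "3.1": (
        0.03, 0.05, 0.10, 0.15, 0.20,
        0.05, 0.15, 0.20, 0.30, 0.45,
        0.05, 0.10, 0.15, 0.20, 0.30,
        0.15, 0.20, 0.30, 0.45, 0.55,
    ),
    "3.2": (
        0.03, 0.05, 0.08, 0.10, 0.15,
        0.05, 0.10, 0.15, 0.20, 0.45,
        0.05, 0.10, 0.15, 0.20, 0.30,
        0.15, 0.20, 0.30, 0.45, 0.55,
    ),
    "3.3": (
        0.03, 0.05, 0.08, 0.10, 0.15,
        0.05, 0.10, 0.15, 0.20, 0.45,
        0.05, 0.08, 0.10, 0.15, 0.20,
        0.15, 0.20, 0.30, 0.45, 0.55,
    ),
    "4.1": (
        0.10, 0.13, 0.15, 0.20, 0.30,
        0.13, 0.20, 0.30, 0.45, 0.50,
        0.13, 0.15, 0.20, 0.30, 0.45,
        0.15, 0.30, 0.45, 0.50, 0.55,
    ),
    "4.2": (
        0.08, 0.10, 0.13, 0.15, 0.20,
        0.10, 0.15, 0.20, 0.45, 0.50,
        0.10, 0.15, 0.20, 0.30, 0.45,
        0.20, 0.30, 0.45, 0.50, 0.55,
    ),
    "4.3": (
        0.08, 0.10, 0.13, 0.15, 0.20,
        0.10, 0.15, 0.20, 0.45, 0.50,
        0.10, 0.13, 0.15, 0.20, 0.45,
        0.20, 0.30, 0.45, 0.50, 0.55,
    ),
    "4.4": (
        0.08, 0.10, 0.13, 0.15, 0.20,
        0.10, 0.15, 0.20, 0.45, 0.50,
        0.10, 0.15, 0.20, 0.30, 0.45,
        0.15, 0.20, 0.45, 0.50, 0.55,
    ),
    "4.5": (
        0.08, 0.10, 0.13, 0.13, 0.15,
        0.10, 0.15, 0.20, 0.45, 0.55,
        0.10, 0.13, 0.15, 0.30, 0.45,
        0.20, 0.45, 0.50, 0.55, 0.60,
    ),
    "5.1": (
        0.13, 0.15, 0.20, 0.30, 0.45,
        0.15, 0.30, 0.45, 0.50, 0.55,
        0.15, 0.20, 0.30, 0.45, 0.50,
        0.30, 0.45, 0.50, 0.55, 0.60,
    ),
    "5.2": (
        0.08, 0.10, 0.15, 0.20, 0.45,
        0.10, 0.20, 0.45, 0.50, 0.55,
        0.15, 0.20, 0.30, 0.45, 0.50,
        0.30, 0.45, 0.50, 0.55, 0.60,
    ),
    "5.3": (
        0.08, 0.10, 0.15, 0.16, 0.18,
        0.10, 0.16, 0.18, 0.20, 0.22,
        0.10, 0.15, 0.20, 0.30, 0.45,
        0.30, 0.45, 0.50, 0.55, 0.60,
    ),
    "5.4": (
        0.08, 0.10, 0.15, 0.16, 0.17,
        0.10, 0.13, 0.20, 0.30, 0.45,
        0.15, 0.20, 0.30, 0.45, 0.50,
        0.20, 0.45, 0.50, 0.55, 0.60,
    ),
    "6.1": (
        0.10, 0.13, 0.15, 0.20, 0.45,
        0.15, 0.20, 0.45, 0.55, 0.60,
        0.20, 0.30, 0.43, 0.45, 0.55,
        0.30, 0.45, 0.50, 0.60, 0.65,
    ),
    "6.2": (
        0.10, 0.13, 0.15, 0.20, 0.45,
        0.13, 0.20, 0.45, 0.55, 0.60,
        0.13, 0.15, 0.20, 0.45, 0.55,
        0.30, 0.45, 0.50, 0.60, 0.65,
    ),
    "7": (
        0.20, 0.30, 0.45, 0.50, 0.55,
        0.30, 0.48, 0.55, 0.60, 0.65,
        0.30, 0.45, 0.50, 0.55, 0.60,
        0.45, 0.55, 0.60, 0.65, 0.70,
    ),
    "8": (
        0.30, 0.45, 0.50, 0.55, 0.60,
        0.45, 0.55, 0.60, 0.65, 0.70,
        0.45, 0.50, 0.55, 0.60, 0.65,
        0.50, 0.60, 0.65, 0.70, 0.75,
    ),
}


def default_scenarios() -> list[Scenario]:
    """The twenty bundled regimen-toxicity scenarios."""
    return [Scenario(name=k, true_tox=v) for k, v in _SCENARIO_TABLE.items()]


def load_scenarios(path_or_buf) -> list[Scenario]:
    """Load scenarios from CSV with columns scenario, regimen_index, true_tox."""
    df = pd.read_csv(path_or_buf, dtype={"scenario": str})
    scenarios = []
    for name, group in df.groupby("scenario", sort=False):
        group = group.sort_values("regimen_index")
        idx = group["regimen_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(f"scenario {name}: regimen indices must be 1..K")
        scenarios.append(Scenario(name=str(name), true_tox=tuple(group["true_tox"])))
    return scenarios


def scenarios_to_csv(scenarios: Sequence[Scenario], path_or_buf) -> None:
    rows = [
        {"scenario": s.name, "regimen_index": i + 1, "true_tox": p}
        for s in scenarios
        for i, p in enumerate(s.true_tox)
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# Single-trial simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """Complete record of one simulated trial."""

    scenario: str
    allocation_rule: str
    cohorts: tuple[tuple[int, int, int], ...]  # (regimen, size, DLTs)
    selection: int | None
    stop_reason: str  # 'max_n' or 'safety'
    fallback_used: bool = False

    @property
    def total_n(self) -> int:
        return sum(c[1] for c in self.cohorts)

    @property
    def total_dlts(self) -> int:
        return sum(c[2] for c in self.cohorts)


def simulate_trial(
    model: PartialOrderCRM,
    scenario: Scenario,
    allocation_rule: str,
    rng: np.random.Generator,
) -> TrialRecord:
    """Run one complete trial under the given true-toxicity scenario."""
    if allocation_rule not in ALLOCATION_RULES:
        raise ValueError(f"unknown allocation rule {allocation_rule!r}")
    averaging = allocation_rule.startswith("model_averaging")
    randomised = allocation_rule.endswith("within_admissible")
    design = model.design
    c = design.cohort_size
    data = model.empty_data()
    current = design.start_regimen
    fallback = False
    while True:
        dlts = int(rng.binomial(c, scenario.prob(current)))
        data = data.add_cohort(current, c, dlts)
        results = model.fit(data, model_averaging=averaging)
        safe = results.safe_set()
        status = escalation.check_stopping(data, bool(safe), design.max_n)
        if status == "stop_safety":
            return TrialRecord(
                scenario.name, allocation_rule, data.cohort_log, None, "safety", fallback
            )
        if status == "stop_maxn":
            selection = results.final_selection()
            return TrialRecord(
                scenario.name,
                allocation_rule,
                data.cohort_log,
                selection,
                "max_n",
                fallback,
            )
        admissible = results.admissible_set(current, dlts)
        if admissible:
            if randomised:
                nxt = escalation.randomize_within_admissible(
                    admissible, results.delta, rng
                )
            else:
                nxt = escalation.recommend_next(admissible, results.delta, results)
        else:
            # No admissible move although some regimen is safe (a rare corner
            # when every safe regimen would raise the dose after a DLT):
            # de-escalate to the safe regimen with the smallest criterion.
            fallback = True
            nxt = escalation.recommend_next(safe, results.delta, results)
        current = nxt


# ---------------------------------------------------------------------------
# Operating characteristics
# ---------------------------------------------------------------------------


def operating_characteristics(
    model: PartialOrderCRM,
    scenario: Scenario,
    allocation_rule: str,
    n_sim: int,
    seed: int | np.random.SeedSequence,
) -> dict:
    """Monte-Carlo operating characteristics for one scenario."""
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(seq)
    optimal, correct, overtoxic = scenario.optimal_set, scenario.correct_set, scenario.overtoxic_set
    counts = {"optimal": 0, "correct": 0, "overtoxic": 0, "stop": 0}
    dlt_props = []
    sample_sizes = []
    for _ in range(n_sim):
        rec = simulate_trial(model, scenario, allocation_rule, rng)
        dlt_props.append(rec.total_dlts / rec.total_n)
        sample_sizes.append(rec.total_n)
        if rec.selection is None:
            counts["stop"] += 1
            continue
        if rec.selection in optimal:
            counts["optimal"] += 1
        if rec.selection in correct:
            counts["correct"] += 1
        if rec.selection in overtoxic:
            counts["overtoxic"] += 1
    return {
        "scenario": scenario.name,
        "allocation_rule": allocation_rule,
        "n_sim": n_sim,
        "optimal_pct": 100.0 * counts["optimal"] / n_sim,
        "correct_pct": 100.0 * counts["correct"] / n_sim,
        "overtoxic_pct": 100.0 * counts["overtoxic"] / n_sim,
        "dlt_pct": 100.0 * float(np.mean(dlt_props)),
        "early_stop_pct": 100.0 * counts["stop"] / n_sim,
        "mean_sample_size": float(np.mean(sample_sizes)),
    }


def oc_table(
    model: PartialOrderCRM,
    scenarios: Sequence[Scenario],
    allocation_rule: str,
    n_sim: int,
    seed: int,
) -> pd.DataFrame:
    """Operating characteristics for every scenario, one independent RNG
    stream per scenario spawned from the master seed."""
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    rows = [
        operating_characteristics(model, sc, allocation_rule, n_sim, stream)
        for sc, stream in zip(scenarios, streams)
    ]
    return pd.DataFrame(rows)


def summary_metrics(rows: pd.DataFrame) -> dict:
    """Mean metrics over scenarios (M) plus the threshold fractions.

    The threshold comparisons are strict: a scenario counts only if its
    optimal-selection percentage is strictly above 40, correct strictly
    above 60, overly toxic strictly below 25.
    """
    if len(rows) == 0:
        raise ValueError("need at least one scenario row")
    n = len(rows)
    return {
        "mean_optimal_pct": float(rows["optimal_pct"].mean()),
        "mean_correct_pct": float(rows["correct_pct"].mean()),
        "mean_overtoxic_pct": float(rows["overtoxic_pct"].mean()),
        "mean_dlt_pct": float(rows["dlt_pct"].mean()),
        "pct_scenarios_optimal_above_40": 100.0 * float((rows["optimal_pct"] > 40).sum()) / n,
        "pct_scenarios_correct_above_60": 100.0 * float((rows["correct_pct"] > 60).sum()) / n,
        "pct_scenarios_overtoxic_below_25": 100.0 * float((rows["overtoxic_pct"] < 25).sum()) / n,
    }


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def first_cohort_constraints_hold(model: PartialOrderCRM) -> bool:
    """The deterministic first-cohort requirements used to prune the
    calibration grid: after 0/3 DLTs at the start regimen, regimen 19 must
    be the recommended next regimen with 20 inadmissible; after 1/3,
    regimens 14 and 17 must be admissible with the start regimen 18 not."""
    start = model.design.start_regimen
    c = model.design.cohort_size
    res0 = model.fit(TrialData.from_cohorts([(start, c, 0)], model.K))
    adm0 = res0.admissible_set(start, 0)
    if 20 in adm0 or escalation.recommend_next(adm0, res0.delta, res0) != 19:
        return False
    res1 = model.fit(TrialData.from_cohorts([(start, c, 1)], model.K))
    adm1 = res1.admissible_set(start, 1)
    return 14 in adm1 and 17 in adm1 and start not in adm1


def calibrate(
    param_sets: Sequence[DesignParams],
    scenarios: Sequence[Scenario],
    n_sim: int,
    seed: int,
    grid=None,
    orderings=None,
    allocation_rule: str = "next_best",
) -> pd.DataFrame:
    """Rank candidate design-parameter sets.

    Candidates failing the deterministic first-cohort constraints are
    excluded before any simulation; survivors are ranked by the geometric
    mean over scenarios of the correct-selection proportion.
    """
    records = []
    for k, params in enumerate(param_sets):
        model = PartialOrderCRM(grid=grid, orderings=orderings, design=params)
        passed = first_cohort_constraints_hold(model)
        rec = {
            "option": k + 1,
            "mu": params.mu,
            "sigma2": params.sigma2,
            "c_overdose": params.c_overdose,
            "passes_first_cohort": passed,
            "geometric_mean_correct_pct": np.nan,
        }
        if passed:
            rows = oc_table(model, scenarios, allocation_rule, n_sim, seed)
            correct = np.maximum(rows["correct_pct"].to_numpy(), 1e-9)
            rec["geometric_mean_correct_pct"] = float(
                np.exp(np.mean(np.log(correct)))
            )
        records.append(rec)
    df = pd.DataFrame(records)
    return df.sort_values(
        "geometric_mean_correct_pct", ascending=False, na_position="last"
    ).reset_index(drop=True)
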