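"""Exact operating characteristics of the rule-based 3+3 design.

The comparator applies the classic 3+3 escalation with de-escalation to a
subset of regimens assumed to be monotonically ordered (by default the
high-backbone regimens 11..20 in index order, starting from the trial's
actual starting regimen 18).  Because every trial path is a short sequence
of cohort outcomes with binomial probabilities, the full distribution of
trial trajectories -- and hence every operating characteristic -- is
computed exactly by enumerating all paths, with no simulation error.

Rule set (each switch configurable):

* cohorts of 3; dose levels carry at most 6 patients;
* 0/3 DLTs: escalate to the next untried dose; at the top dose the current
  dose is selected outright (``select_top_on_three``, default) or expanded
  to 6 first;
* 1/3: treat 3 more at the same dose;
* at most 1 of 6: escalate; if there is no dose to escalate to (top dose,
  or the next dose was already declared too toxic) the current dose is
  selected;
* 2+ of 3 or 2+ of 6: the dose is declared too toxic and the trial
  de-escalates to the next lower dose -- expanding it to 6 if it carries 3
  patients, selecting it if it already carries 6 with at most 1 DLT, or
  treating a fresh cohort if it was never tried;
* de-escalating below the lowest dose ends the trial with no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "ThreePlusThreeSpec",
    "Path",
    "enumerate_paths",
    "oc_exact",
    "simulate_3p3",
    "comparator_spec_for_scenario",
]


@dataclass(frozen=True)
class ThreePlusThreeSpec:
    """Dose ladder and rule switches for the exact 3+3 comparator."""

    true_tox: tuple[float, ...]  # per dose, in escalation order
    labels: tuple[int, ...] | None = None  # e.g. regimen indices
    start: int = 0  # 0-based position of the first cohort's dose
    cohort: int = 3
    max_per_dose: int = 6
    select_top_on_three: bool = True  # 0/3 at the top dose selects it outright
    # a fresh cohort treated during de-escalation that shows 0/3 below an
    # already-toxic dose is selected outright instead of being expanded to 6
    select_below_toxic_on_three: bool = True
    # de-escalating onto a dose passed earlier with 0/3 selects it outright;
    # by default such a dose is expanded to 6 and must show <= 1/6
    select_deescalation_on_three: bool = False

    def __post_init__(self) -> None:
        if not self.true_tox:
            raise ValueError("at least one dose is required")
        if any(not 0 < p < 1 for p in self.true_tox):
            raise ValueError("true toxicities must lie strictly in (0, 1)")
        if not 0 <= self.start < len(self.true_tox):
            raise ValueError("start position outside the dose ladder")
        if self.labels is not None and len(self.labels) != len(self.true_tox):
            raise ValueError("one label per dose required")

    @property
    def n_doses(self) -> int:
        return len(self.true_tox)

    def label(self, pos: int) -> int:
        return self.labels[pos] if self.labels is not None else pos + 1


@dataclass(frozen=True)
class Path:
    """One complete trial trajectory with its exact probability.

    Cohort outcomes are recorded as decision categories ('0', '1', '2+' for
    a fresh cohort; 'ok' / '2+' for an expansion cohort) rather than exact
    DLT counts: every escalation decision depends only on the category, so
    aggregating over the counts within a category is exact for all
    selection probabilities and sample sizes.  ``exp_dlts`` carries the
    exact conditional expectation of the total DLT count on the path, which
    is all that the (linear) DLT-burden metric needs.
    """

    cohorts: tuple[tuple[int, str], ...]  # (dose position, outcome category)
    probability: float
    selected: int | None  # dose position, None = no selection
    n_total: int
    exp_dlts: float


def _binom_pmf(k: int, n: int, p: float) -> float:
    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def _tail(c: int, p: float, ks) -> tuple[float, float]:
    """(probability, conditional expected DLTs) of the outcome set ``ks``."""
    prob = sum(_binom_pmf(k, c, p) for k in ks)
    mean = sum(k * _binom_pmf(k, c, p) for k in ks) / prob if prob > 0 else 0.0
    return prob, mean


def enumerate_paths(spec: ThreePlusThreeSpec) -> list[Path]:
    """All trajectories of the 3+3 rules with their exact probabilities."""
    c = spec.cohort
    paths: list[Path] = []

    def treat_fresh(pos, n, toxic, prob, dlts, log):
        """First cohort of c at dose ``pos``; branch on 0 / 1 / 2+ DLTs."""
        p = spec.true_tox[pos]
        n2 = n[:pos] + (n[pos] + c,) + n[pos + 1 :]
        for cat, ks in (("0", (0,)), ("1", (1,)), ("2+", range(2, c + 1))):
            pk, ek = _tail(c, p, ks)
            if pk == 0.0:
                continue
            after_zero(pos, cat, n2, toxic, prob * pk, dlts + ek, log + ((pos, cat),))

    def after_zero(pos, cat, n, toxic, prob, dlts, log):
        if cat == "0":
            if pos == spec.n_doses - 1:
                if spec.select_top_on_three:
                    finish(pos, n, prob, dlts, log)
                else:
                    expand(pos, 0, n, toxic, prob, dlts, log)
            elif toxic[pos + 1]:
                if spec.select_below_toxic_on_three:
                    finish(pos, n, prob, dlts, log)
                else:
                    expand(pos, 0, n, toxic, prob, dlts, log)  # blocked above
            else:
                treat_fresh(pos + 1, n, toxic, prob, dlts, log)
        elif cat == "1":
            expand(pos, 1, n, toxic, prob, dlts, log)
        else:
            de_escalate(pos, n, toxic, prob, dlts, log)

    def expand(pos, y0, n, toxic, prob, dlts, log):
        """Second cohort of c at ``pos``; branch on total <= 1 vs >= 2 of 6."""
        p = spec.true_tox[pos]
        n2 = n[:pos] + (n[pos] + c,) + n[pos + 1 :]
        ok_ks = range(0, 2 - y0)  # outcomes keeping the 6-patient total <= 1
        tox_ks = range(2 - y0, c + 1)
        p_ok, e_ok = _tail(c, p, ok_ks)
        p_tox, e_tox = _tail(c, p, tox_ks)
        if p_ok > 0:
            cleared(pos, n2, toxic, prob * p_ok, dlts + e_ok, log + ((pos, "ok"),))
        if p_tox > 0:
            de_escalate(pos, n2, toxic, prob * p_tox, dlts + e_tox, log + ((pos, "2+"),))

    def cleared(pos, n, toxic, prob, dlts, log):
        """Dose ``pos`` carries 6 patients with at most one DLT."""
        if pos == spec.n_doses - 1 or toxic[pos + 1]:
            finish(pos, n, prob, dlts, log)
        else:
            treat_fresh(pos + 1, n, toxic, prob, dlts, log)

    def de_escalate(pos, n, toxic, prob, dlts, log):
        toxic = toxic[:pos] + (True,) + toxic[pos + 1 :]
        lower = pos - 1
        if lower < 0:
            finish(None, n, prob, dlts, log)
            return
        if n[lower] == 0:
            treat_fresh(lower, n, toxic, prob, dlts, log)
        elif n[lower] == c:
            # it was passed with 0/3 on the way up
            if spec.select_deescalation_on_three:
                finish(lower, n, prob, dlts, log)
            else:
                expand(lower, 0, n, toxic, prob, dlts, log)
        else:  # already 6 patients with <= 1 DLT (else we would not be here)
            finish(lower, n, prob, dlts, log)

    def finish(selected, n, prob, dlts, log):
        paths.append(
            Path(
                cohorts=log,
                probability=prob,
                selected=selected,
                n_total=int(sum(n)),
                exp_dlts=dlts,
            )
        )

    treat_fresh(
        spec.start,
        (0,) * spec.n_doses,
        (False,) * spec.n_doses,
        1.0,
        0.0,
        (),
    )
    return paths


def comparator_spec_for_scenario(
    scenario,
    regimens: Sequence[int] = tuple(range(11, 21)),
    start_regimen: int = 18,
    **switches,
) -> ThreePlusThreeSpec:
    """Build the comparator ladder from a simulation scenario.

    The default ladder is the high-backbone regimens 11..20 assumed
    monotone in index order, starting -- like the model-based design -- at
    regimen 18.  ``switches`` forwards any rule switch of
    :class:`ThreePlusThreeSpec`.
    """
    regimens = tuple(regimens)
    return ThreePlusThreeSpec(
        true_tox=tuple(scenario.true_tox[i - 1] for i in regimens),
        labels=regimens,
        start=regimens.index(start_regimen),
        **switches,
    )


def oc_exact(
    spec: ThreePlusThreeSpec,
    optimal_set: set[int] | frozenset[int],
    correct_band: tuple[float, float] = (0.20, 0.35),
    overtox_bound: float = 0.35,
) -> dict:
    """Exact selection-category probabilities and trial-size moments.

    ``optimal_set`` holds dose labels (regimen indices when the spec carries
    labels); correctness and over-toxicity are judged from the true DLT
    probabilities of the selected dose.
    """
    paths = enumerate_paths(spec)
    total = sum(p.probability for p in paths)
    optimal = correct = overtoxic = none = 0.0
    exp_n = exp_dlt_prop = 0.0
    lo, hi = correct_band
    for p in paths:
        exp_n += p.probability * p.n_total
        exp_dlt_prop += p.probability * (p.exp_dlts / p.n_total)
        if p.selected is None:
            none += p.probability
            continue
        tox = spec.true_tox[p.selected]
        if spec.label(p.selected) in optimal_set:
            optimal += p.probability
        if lo - 1e-12 <= tox <= hi + 1e-12:
            correct += p.probability
        if tox > overtox_bound + 1e-12:
            overtoxic += p.probability
    return {
        "total_probability": total,
        "optimal_pct": 100.0 * optimal,
        "correct_pct": 100.0 * correct,
        "overtoxic_pct": 100.0 * overtoxic,
        "no_selection_pct": 100.0 * none,
        "dlt_pct": 100.0 * exp_dlt_prop,
        "mean_sample_size": exp_n,
        "n_paths": len(paths),
    }


def simulate_3p3(
    spec: ThreePlusThreeSpec, n_rep: int, rng: np.random.Generator
) -> dict:
    """Monte-Carlo version of the same rules (cross-check for the exact
    enumeration; the production results come from enumerate_paths)."""
    counts = {"optimal": 0, "none": 0}
    sel_counts = np.zeros(spec.n_doses, dtype=int)
    n_tot = 0
    for _ in range(n_rep):
        selected, n_used = _simulate_once(spec, rng)
        n_tot += n_used
        if selected is None:
            counts["none"] += 1
        else:
            sel_counts[selected] += 1
    return {
        "selection_freq": sel_counts / n_rep,
        "no_selection_freq": counts["none"] / n_rep,
        "mean_sample_size": n_tot / n_rep,
    }


def _simulate_once(spec, rng):
    c = spec.cohort
    n = [0] * spec.n_doses
    y = [0] * spec.n_doses
    toxic = [False] * spec.n_doses
    pos = spec.start
    while True:
        k = int(rng.binomial(c, spec.true_tox[pos]))
        n[pos] += c
        y[pos] += k
        if n[pos] == c:
            if y[pos] == 0:
                if pos == spec.n_doses - 1:
                    if spec.select_top_on_three:
                        return pos, sum(n)
                    continue
                if toxic[pos + 1]:
                    if spec.select_below_toxic_on_three:
                        return pos, sum(n)
                    continue  # expand in place
                pos += 1
            elif y[pos] == 1:
                continue  # expand in place
            else:
                result = _descend(pos, n, y, toxic, spec)
                if result is not True:
                    return result, sum(n)
                pos -= 1
        else:
            if y[pos] <= 1:
                if pos == spec.n_doses - 1 or toxic[pos + 1]:
                    return pos, sum(n)
                pos += 1
            else:
                result = _descend(pos, n, y, toxic, spec)
                if result is not True:
                    return result, sum(n)
                pos -= 1


def _descend(pos, n, y, toxic, spec):
    """Mark the dose toxic; True = continue at pos-1, else terminal result."""
    toxic[pos] = True
    lower = pos - 1
    if lower < 0:
        return None
    if n[lower] == spec.max_per_dose:
        return lower
    if n[lower] == spec.cohort and spec.select_deescalation_on_three:
        return lower
    return True
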