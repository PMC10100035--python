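"""Shared brute-force oracle for the admissible-set predicate."""

import numpy as np

from pocrm3d.escalation import admissible_set


class StubResults:
    def __init__(self, model, overdose_prob):
        self.model = model
        self.overdose_prob = np.asarray(overdose_prob)


def brute_force_admissible(grid, design, overdose_prob, current, dlts):
    """Checks the four escalation restrictions regimen by regimen from raw
    grid coordinates; intentionally shares no code with the production
    predicate."""
    cur = grid[current]
    out = set()
    for reg in grid:
        if not overdose_prob[reg.index - 1] < design.c_overdose:
            continue
        ups = []
        if reg.n_dose > cur.n_dose:
            ups.append("n")
        if reg.m_dose > cur.m_dose:
            ups.append("m")
        if reg.schedule.intensity > cur.schedule.intensity:
            ups.append("s")
        if ups:
            if len(ups) != 1:
                continue
            if reg.avg_weekly_dose > 2 * cur.avg_weekly_dose:
                continue
            if reg.m_dose > 2 * cur.m_dose:
                continue
        if dlts >= 1 and (
            reg.avg_weekly_dose > cur.avg_weekly_dose or reg.n_dose > cur.n_dose
        ):
            continue
        out.add(reg.index)
    return out


def check_states(model, rng, n_states=500):
    for _ in range(n_states):
        overdose = rng.uniform(0, 0.6, size=len(model.grid))
        current = int(rng.integers(1, len(model.grid) + 1))
        dlts = int(rng.integers(0, 4))
        stub = StubResults(model, overdose)
        got = admissible_set(stub, current, dlts)
        want = brute_force_admissible(
            model.grid, model.design, overdose, current, dlts
        )
        assert got == want, (current, dlts)
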