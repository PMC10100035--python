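"""Feasibility, candidate generation and prior elicitation of orderings."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pocrm3d.grid import build_default_grid, known_partial_order
from pocrm3d.orderings import (
    DriverAssumption,
    GroupRankConstraint,
    GroupSumConstraint,
    Ordering,
    OrderingSet,
    PairConstraint,
    default_group_constraints,
    default_pair_constraints,
    elicit_prior_probabilities,
    generate_candidate_orderings,
    implied_pair_probability,
    is_feasible,
    ordering_from_assumption,
    reconstruct_trial_orderings,
    wages_conaway_orderings,
)

BY_COLUMNS = (1, 11, 6, 16, 2, 12, 7, 17, 3, 13, 8, 18, 4, 14, 9, 19, 5, 15, 10, 20)


class TestFeasibility:
    def test_backbone_dominant_example_is_feasible(self, partial_order):
        # the schedule-driver ordering communicated to the trial team
        seq = (1, 2, 3, 6, 4, 5, 7, 8, 9, 10, 11, 12, 13, 16, 14, 15, 17, 18, 19, 20)
        assert is_feasible(Ordering(sequence=seq), partial_order)

    def test_swapped_known_pair_is_infeasible(self, partial_order):
        # placing 16 before 11 violates backbone-dose monotonicity at fixed
        # (M = 30, S2 -> S1 is not the violation: 11 < 16 is known)
        seq = list(range(1, 21))
        i, j = seq.index(11), seq.index(16)
        seq[i], seq[j] = seq[j], seq[i]
        assert not is_feasible(Ordering(sequence=tuple(seq)), partial_order)

    def test_topological_sorts_are_feasible(self, grid, partial_order, rng):
        """Any linear extension produced by a randomised topological sort
        (an independent oracle of feasibility) passes is_feasible."""
        known = partial_order.known_less_toxic
        for _ in range(25):
            remaining = set(grid.indices)
            seq = []
            while remaining:
                ready = sorted(
                    n
                    for n in remaining
                    if not any((m, n) in known for m in remaining if m != n)
                )
                pick = int(rng.choice(ready))
                seq.append(pick)
                remaining.remove(pick)
            assert is_feasible(Ordering(sequence=tuple(seq)), partial_order)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            Ordering(sequence=(1, 1, 3))


class TestCandidateGeneration:
    def test_generated_orderings_all_feasible(self, grid, partial_order):
        assumptions = [
            DriverAssumption(
                "backbone then average weekly dose",
                key=lambda r: (r.n_dose, r.avg_weekly_dose, r.schedule.intensity),
            ),
        ]
        out = generate_candidate_orderings(grid, partial_order, assumptions)
        assert out.R >= 1
        for o in out.orderings:
            assert is_feasible(o, partial_order)
        assert abs(out.prior_probs.sum() - 1.0) < 1e-12

    def test_infeasible_assumption_names_violated_pair(self, grid, partial_order):
        bad = DriverAssumption(
            "single dose first",  # violates e.g. 13 < 17
            key=lambda r: (r.m_dose, r.schedule.intensity, r.n_dose),
        )
        with pytest.raises(ValueError, match=r"\(\d+, \d+\)"):
            ordering_from_assumption(grid, bad, partial_order)

    def test_by_columns_robustness_ordering_produced(self, grid, partial_order):
        traversals = {o.sequence: o.label for o in wages_conaway_orderings(grid)}
        assert BY_COLUMNS in traversals
        # feasible under within-agent monotonicity, but it contradicts the
        # clinician-asserted diagonal dominances (e.g. 14 before 18)
        from pocrm3d.grid import known_partial_order

        monotone_only = known_partial_order(grid, diagonal_dominance=False)
        assert is_feasible(Ordering(sequence=BY_COLUMNS), monotone_only)
        assert not is_feasible(Ordering(sequence=BY_COLUMNS), partial_order)

    def test_reconstruction_is_feasible_with_unit_mass(self, orderings, partial_order):
        assert orderings.R == 10
        orderings.validate_feasibility(partial_order)
        assert abs(orderings.prior_probs.sum() - 1.0) < 1e-9


class TestImpliedPairProbability:
    def test_certain_ordering(self):
        os_ = OrderingSet(
            (Ordering(sequence=(1, 2), prior_prob=1.0),)
        )
        assert implied_pair_probability(os_, (1, 2)) == 1.0

    def test_even_split(self):
        os_ = OrderingSet(
            (
                Ordering(sequence=(1, 2), prior_prob=0.5),
                Ordering(sequence=(2, 1), prior_prob=0.5),
            )
        )
        assert implied_pair_probability(os_, (1, 2)) == pytest.approx(0.5)

    def test_identical_pair_rejected(self, orderings):
        with pytest.raises(ValueError):
            implied_pair_probability(orderings, (3, 3))

    @given(st.integers(1, 20), st.integers(1, 20))
    def test_complementary_pairs_sum_to_one(self, a, b):
        os_ = reconstruct_trial_orderings()
        if a == b:
            return
        total = implied_pair_probability(os_, (a, b)) + implied_pair_probability(
            os_, (b, a)
        )
        assert total == pytest.approx(1.0)

    def test_reconstruction_implies_elicited_probabilities(self, orderings):
        """The bundled priors reproduce the elicited anti-diagonal targets."""
        for c in default_pair_constraints():
            assert implied_pair_probability(orderings, (c.a, c.b)) == pytest.approx(
                c.target_prob, abs=1e-9
            )

    def test_reconstruction_satisfies_group_constraints(self, orderings):
        q = orderings.prior_probs
        assert 0.67 <= q[:5].sum() <= 0.75
        assert max(q[8], q[9]) <= min(q[:8])


class TestElicitation:
    def _two_orderings(self):
        return OrderingSet(
            (
                Ordering(sequence=(1, 2), prior_prob=0.5, label="ab"),
                Ordering(sequence=(2, 1), prior_prob=0.5, label="ba"),
            )
        )

    def test_one_free_pair_matches_1d_grid_oracle(self):
        os_ = self._two_orderings()
        target = 0.9
        out = elicit_prior_probabilities(
            os_, [PairConstraint(1, 2, target)], step=0.01
        )
        # oracle: exhaustive 1-D grid over the mass q of the ordering that
        # ranks regimen 2 more toxic (the first one)
        grid = np.arange(0, 101) / 100
        oracle = grid[np.argmin((grid - target) ** 2)]
        assert out.prior_probs[0] == pytest.approx(oracle)
        assert out.prior_probs[1] == pytest.approx(1 - oracle)

    def test_zero_loss_at_uniform_returns_uniform(self):
        os_ = self._two_orderings()
        out = elicit_prior_probabilities(os_, [PairConstraint(1, 2, 0.5)])
        assert np.allclose(out.prior_probs, [0.5, 0.5])

    def test_empty_constraints_give_uniform(self, orderings):
        out = elicit_prior_probabilities(orderings, [])
        assert np.allclose(out.prior_probs, 0.1)

    def test_output_beats_uniform_and_respects_groups(self, orderings):
        constraints = default_pair_constraints()
        groups = default_group_constraints()
        out = elicit_prior_probabilities(orderings, constraints, groups)
        q = out.prior_probs
        assert abs(q.sum() - 1.0) < 1e-9
        assert 0.67 - 1e-9 <= q[:5].sum() <= 0.75 + 1e-9
        assert max(q[8], q[9]) <= min(q[:8]) + 1e-9

        def loss(probs):
            s = orderings.with_priors(probs)
            return sum(
                (implied_pair_probability(s, (c.a, c.b)) - c.target_prob) ** 2
                for c in constraints
            )

        assert loss(q) <= loss(np.full(10, 0.1)) + 1e-12

    def test_matches_exhaustive_search_small_r(self):
        """Coordinate refinement agrees with brute force on a 3-ordering set."""
        os_ = OrderingSet(
            tuple(
                Ordering(sequence=seq, prior_prob=1 / 3)
                for seq in [(1, 2, 3), (2, 1, 3), (3, 2, 1)]
            )
        )
        constraints = [PairConstraint(1, 2, 0.65), PairConstraint(2, 3, 0.8)]
        exhaustive = elicit_prior_probabilities(
            os_, constraints, step=0.05, exhaustive_max_r=5
        )
        refined = elicit_prior_probabilities(
            os_, constraints, step=0.05, exhaustive_max_r=0
        )

        def loss(out):
            return sum(
                (implied_pair_probability(out, (c.a, c.b)) - c.target_prob) ** 2
                for c in constraints
            )

        assert loss(refined) <= loss(exhaustive) + 1e-9

    def test_infeasible_groups_raise(self):
        os_ = self._two_orderings()
        with pytest.raises(ValueError):
            elicit_prior_probabilities(
                os_,
                [PairConstraint(1, 2, 0.5)],
                [GroupSumConstraint((1,), lower=0.8, upper=0.9),
                 GroupSumConstraint((2,), lower=0.8, upper=0.9)],
            )


def test_csv_round_trip(tmp_path, orderings):
    path = tmp_path / "orderings.csv"
    orderings.to_csv(str(path))
    back = OrderingSet.from_csv(str(path))
    assert back.labels == orderings.labels
    assert [o.sequence for o in back.orderings] == [
        o.sequence for o in orderings.orderings
    ]
    assert np.allclose(back.prior_probs, orderings.prior_probs)


def test_bundled_fixture_file_matches_reconstruction():
    from importlib.resources import files

    bundled = OrderingSet.from_csv(
        str(files("pocrm3d.data") / "orderings_reconstructed.csv")
    )
    fresh = reconstruct_trial_orderings()
    assert [o.sequence for o in bundled.orderings] == [
        o.sequence for o in fresh.orderings
    ]
    assert np.allclose(bundled.prior_probs, fresh.prior_probs)
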