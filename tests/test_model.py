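"""The Bayesian core: working models, likelihood, posterior, summaries."""

import numpy as np
import pytest

from pocrm3d.design import DesignParams, Skeleton, skeleton_from_spacing
from pocrm3d.model import (
    AlphaPosterior,
    PartialOrderCRM,
    PriorSpec,
    TrialData,
    WorkingModel,
    criterion_delta,
    log_likelihood,
    model_average_summaries,
    ordering_posteriors,
    posterior_alpha,
    select_ordering,
    toxicity_summaries,
    working_model,
)
from pocrm3d.orderings import Ordering, OrderingSet

PRINTED_SKELETON = (
    0.01, 0.05, 0.09, 0.13, 0.17, 0.21, 0.25, 0.29, 0.33, 0.37,
    0.41, 0.45, 0.49, 0.53, 0.57, 0.61, 0.65, 0.69, 0.75, 0.80,
)


class TestSkeleton:
    def test_calibrated_spacing_reproduces_printed_values(self):
        skel = skeleton_from_spacing(0.04, 18, (0.75, 0.80))
        assert np.allclose(skel.values, PRINTED_SKELETON)

    def test_plain_arithmetic_sequence(self):
        skel = skeleton_from_spacing(0.04, 18)
        assert len(skel) == 18
        assert skel.values[-1] == pytest.approx(0.69)

    def test_values_leaving_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            skeleton_from_spacing(0.5, 18)

    def test_non_increasing_tail_rejected(self):
        with pytest.raises(ValueError):
            skeleton_from_spacing(0.04, 18, (0.60,))


class TestWorkingModel:
    def test_toy_dual_agent_reordering(self):
        """Two-by-two example: the second ordering swaps the middle pair."""
        skel = Skeleton(values=(0.10, 0.20, 0.30, 0.40))
        # combinations indexed (A1B1, A2B1, A1B2, A2B2)
        ordering2 = Ordering(sequence=(1, 3, 2, 4))
        wm = working_model(skel, ordering2)
        assert wm.pi == (0.10, 0.30, 0.20, 0.40)

    def test_identity_ordering_keeps_skeleton(self):
        skel = Skeleton(values=(0.1, 0.2, 0.3))
        wm = working_model(skel, Ordering(sequence=(1, 2, 3)))
        assert wm.pi == skel.values

    def test_output_is_permutation_of_skeleton(self, rng):
        skel = skeleton_from_spacing(0.04, 18, (0.75, 0.80))
        seq = tuple(rng.permutation(np.arange(1, 21)).tolist())
        wm = working_model(skel, Ordering(sequence=seq))
        assert sorted(wm.pi) == sorted(skel.values)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            working_model(Skeleton(values=(0.1, 0.2)), Ordering(sequence=(1, 2, 3)))


def _single_regimen_data(n, y, k=1):
    return TrialData.from_cohorts([(1, n, y)], n_regimens=k)


class TestLogLikelihood:
    def test_no_dlts_closed_form(self):
        wm = WorkingModel(ordering_index=1, pi=(0.5,))
        ll = log_likelihood(wm, 0.0, _single_regimen_data(3, 0))
        assert ll == pytest.approx(np.log(0.125))

    def test_all_dlts_symmetry(self):
        wm = WorkingModel(ordering_index=1, pi=(0.5,))
        ll = log_likelihood(wm, 0.0, _single_regimen_data(3, 3))
        assert ll == pytest.approx(np.log(0.125))

    def test_empty_data_is_flat(self):
        wm = WorkingModel(ordering_index=1, pi=(0.2, 0.5))
        alphas = np.linspace(-3, 3, 7)
        assert np.allclose(log_likelihood(wm, alphas, TrialData.empty(2)), 0.0)

    def test_untried_regimens_do_not_contribute(self):
        wm2 = WorkingModel(ordering_index=1, pi=(0.5, 0.9))
        wm1 = WorkingModel(ordering_index=1, pi=(0.5,))
        data2 = TrialData.from_cohorts([(1, 3, 1)], n_regimens=2)
        assert log_likelihood(wm2, 0.7, data2) == pytest.approx(
            log_likelihood(wm1, 0.7, _single_regimen_data(3, 1))
        )


PRIOR = PriorSpec(mu=1.5, sigma2=1.0 / 1.5)


class TestPosteriorAlpha:
    def test_empty_data_returns_prior(self):
        wm = WorkingModel(ordering_index=1, pi=(0.2, 0.5))
        post = posterior_alpha(wm, PRIOR, TrialData.empty(2))
        assert post.evidence == pytest.approx(1.0, abs=1e-9)
        assert post.alpha_hat == pytest.approx(PRIOR.mu, abs=1e-9)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_dense_riemann_oracle_agreement(self, rng):
        """Simpson evidence and mean match a 20001-point Riemann sum."""
        from scipy import stats

        for _ in range(10):
            pi = tuple(sorted(rng.uniform(0.05, 0.8, size=4)))
            wm = WorkingModel(ordering_index=1, pi=pi)
            n = rng.integers(0, 8, size=4)
            y = np.array([rng.integers(0, ni + 1) for ni in n])
            data = TrialData.from_cohorts(
                [(i + 1, int(ni), int(yi)) for i, (ni, yi) in enumerate(zip(n, y)) if ni],
                n_regimens=4,
            )
            post = posterior_alpha(wm, PRIOR, data)
            lo = PRIOR.mu - 10 * PRIOR.sigma
            hi = PRIOR.mu + 10 * PRIOR.sigma
            a = np.linspace(lo, hi, 20001)
            h = a[1] - a[0]
            dens = stats.norm.pdf(a, PRIOR.mu, PRIOR.sigma) * np.exp(
                log_likelihood(wm, a, data)
            )
            evidence = float(np.sum(dens) * h)
            mean = float(np.sum(dens * a) * h / evidence)
            assert post.evidence == pytest.approx(evidence, rel=1e-5)
            assert post.alpha_hat == pytest.approx(mean, rel=1e-5)

    def test_all_dlts_pull_alpha_down(self):
        wm = WorkingModel(ordering_index=1, pi=(0.3,))
        post = posterior_alpha(wm, PRIOR, _single_regimen_data(6, 6))
        assert post.alpha_hat < PRIOR.mu


class TestOrderingPosteriors:
    def _models(self):
        return [
            WorkingModel(ordering_index=1, pi=(0.2, 0.4)),
            WorkingModel(ordering_index=2, pi=(0.4, 0.2)),
        ]

    def test_empty_data_returns_priors(self):
        q = ordering_posteriors(self._models(), [0.3, 0.7], PRIOR, TrialData.empty(2))
        assert np.allclose(q, [0.3, 0.7], atol=1e-9)

    def test_identical_models_keep_priors(self):
        models = [
            WorkingModel(ordering_index=1, pi=(0.2, 0.4)),
            WorkingModel(ordering_index=2, pi=(0.2, 0.4)),
        ]
        data = TrialData.from_cohorts([(1, 3, 1), (2, 3, 2)], n_regimens=2)
        q = ordering_posteriors(models, [0.25, 0.75], PRIOR, data)
        assert np.allclose(q, [0.25, 0.75])

    def test_posteriors_sum_to_one(self):
        data = TrialData.from_cohorts([(1, 6, 1), (2, 6, 4)], n_regimens=2)
        q = ordering_posteriors(self._models(), [0.5, 0.5], PRIOR, data)
        assert q.sum() == pytest.approx(1.0)

    def test_consistency_recovers_generating_ordering(self, model, rng):
        """With ample data simulated under one ordering, that ordering's
        posterior probability wins in most replicates."""
        r_true = 9  # the through-the-grid ordering: most distinct ranks
        pi_true = model.pi[r_true - 1]
        tried = [11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
        wins = 0
        n_rep = 10
        for _ in range(n_rep):
            cohorts = [
                (i, 30, int(rng.binomial(30, pi_true[i - 1]))) for i in tried
            ]
            res = model.fit(TrialData.from_cohorts(cohorts, model.K))
            wins += res.r_star == r_true
        assert wins > n_rep / 2


class TestSelectOrdering:
    def test_argmax(self):
        assert select_ordering([0.2, 0.5, 0.3]) == 2

    def test_tie_breaks_to_lowest_index(self):
        assert select_ordering([0.5, 0.5]) == 1

    def test_random_tie_break_is_seeded(self):
        rng = np.random.default_rng(5)
        picks = {select_ordering([0.5, 0.5], tie="random", rng=rng) for _ in range(20)}
        assert picks == {1, 2}


class TestToxicitySummaries:
    def test_point_mass_above_threshold(self):
        wm = WorkingModel(ordering_index=1, pi=(0.5,))
        table = toxicity_summaries(wm, AlphaPosterior.point_mass(0.0), (0.20, 0.35))
        assert table.loc[1, "prob_overdose"] == pytest.approx(1.0)
        assert table.loc[1, "p_hat"] == pytest.approx(0.5)

    def test_point_mass_below_threshold(self):
        wm = WorkingModel(ordering_index=1, pi=(0.2,))
        table = toxicity_summaries(wm, AlphaPosterior.point_mass(0.0), (0.20, 0.35))
        assert table.loc[1, "prob_overdose"] == pytest.approx(0.0)

    def test_interval_probabilities_partition(self):
        wm = WorkingModel(ordering_index=1, pi=tuple(PRINTED_SKELETON))
        post = posterior_alpha(wm, PRIOR, TrialData.from_cohorts([(18, 3, 1)], 20))
        table = toxicity_summaries(wm, post, (0.20, 0.35))
        total = (
            table["prob_underdose"] + table["prob_target"] + table["prob_overdose"]
        )
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_invalid_bounds_rejected(self):
        wm = WorkingModel(ordering_index=1, pi=(0.5,))
        with pytest.raises(ValueError):
            toxicity_summaries(wm, AlphaPosterior.point_mass(0.0), (0.5, 0.2))


class TestCriterionDelta:
    def test_zero_at_target(self):
        gamma = 0.275
        wm = WorkingModel(ordering_index=1, pi=(gamma,))
        delta = criterion_delta(wm, AlphaPosterior.point_mass(0.0), gamma, 0.6)
        assert delta[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_closed_form(self):
        # (0.5 - 0.275)^2 / (0.5^0.6 * 0.5^1.4) = 0.050625 / 0.25
        wm = WorkingModel(ordering_index=1, pi=(0.5,))
        delta = criterion_delta(wm, AlphaPosterior.point_mass(0.0), 0.275, 0.6)
        assert delta[0] == pytest.approx(0.2025)

    def test_near_squared_distance_ranking_at_b_2gamma(self):
        """For b = 2*gamma and a tight posterior the delta ranking agrees
        with the squared-distance ranking of the estimated risks."""
        gamma = 0.275
        pi = (0.05, 0.15, 0.25, 0.30, 0.45, 0.60)
        wm = WorkingModel(ordering_index=1, pi=pi)
        post = AlphaPosterior.point_mass(0.02)
        delta = criterion_delta(wm, post, gamma, b=2 * gamma)
        p = np.asarray(pi) ** np.exp(0.02)
        sq = (p - gamma) ** 2
        assert list(np.argsort(delta)) == list(np.argsort(sq))


class TestModelAveraging:
    def test_single_ordering_equals_plain_summaries(self):
        wm = WorkingModel(ordering_index=1, pi=(0.2, 0.5))
        data = TrialData.from_cohorts([(2, 3, 1)], 2)
        avg = model_average_summaries([wm], [1.0], PRIOR, data, (0.2, 0.35), 0.275, 0.6)
        post = posterior_alpha(wm, PRIOR, data)
        plain = toxicity_summaries(wm, post, (0.2, 0.35))
        assert np.allclose(avg["p_hat"], plain["p_hat"])

    def test_average_lies_between_extremes(self):
        models = [
            WorkingModel(ordering_index=1, pi=(0.2, 0.5)),
            WorkingModel(ordering_index=2, pi=(0.5, 0.2)),
        ]
        data = TrialData.from_cohorts([(1, 3, 1)], 2)
        avg = model_average_summaries(
            models, [0.5, 0.5], PRIOR, data, (0.2, 0.35), 0.275, 0.6
        )
        lo = np.minimum.reduce(
            [
                toxicity_summaries(m, posterior_alpha(m, PRIOR, data), (0.2, 0.35))[
                    "p_hat"
                ].to_numpy()
                for m in models
            ]
        )
        hi = np.maximum.reduce(
            [
                toxicity_summaries(m, posterior_alpha(m, PRIOR, data), (0.2, 0.35))[
                    "p_hat"
                ].to_numpy()
                for m in models
            ]
        )
        assert np.all(avg["p_hat"] >= lo - 1e-12)
        assert np.all(avg["p_hat"] <= hi + 1e-12)


class TestModelObject:
    def test_vectorised_fit_matches_standalone_path(self, model):
        """The fast engine and the per-ordering reference implementation
        compute identical posteriors and summaries."""
        data = TrialData.from_cohorts([(18, 3, 1), (14, 3, 0)], model.K)
        res = model.fit(data)
        prior = PriorSpec(model.design.mu, model.design.sigma2)
        for r in range(model.R):
            wm = WorkingModel(ordering_index=r + 1, pi=tuple(model.pi[r]))
            post = posterior_alpha(wm, prior, data)
            assert res.evidence[r] == pytest.approx(post.evidence, rel=1e-9)
            assert res.alpha_hat[r] == pytest.approx(post.alpha_hat, rel=1e-9)
            table = toxicity_summaries(
                wm, post, (model.design.target_lower, model.design.target_upper)
            )
            assert np.allclose(
                res.per_ordering_p_hat[r], table["p_hat"], rtol=1e-8
            )
            assert np.allclose(
                res.per_ordering_prob_over[r],
                table["prob_overdose"],
                atol=2e-6,
            )
        q_ref = ordering_posteriors(
            [
                WorkingModel(ordering_index=r + 1, pi=tuple(model.pi[r]))
                for r in range(model.R)
            ],
            model.orderings.prior_probs,
            prior,
            data,
        )
        assert np.allclose(res.ordering_posteriors, q_ref, atol=1e-10)

    def test_extra_dlt_never_lowers_risk_estimates(self, model):
        """Adding one DLT (n fixed) raises every regimen's posterior risk
        under a fixed ordering."""
        base = model.fit(TrialData.from_cohorts([(18, 6, 1)], model.K))
        more = model.fit(TrialData.from_cohorts([(18, 6, 2)], model.K))
        r = base.r_star - 1
        assert np.all(
            more.per_ordering_p_hat[r] >= base.per_ordering_p_hat[r] - 1e-12
        )

    def test_p_hat_monotone_within_ordering(self, model):
        res = model.fit(TrialData.from_cohorts([(18, 3, 1)], model.K))
        for r in range(model.R):
            seq = model.orderings.orderings[r].sequence
            p_sorted = res.per_ordering_p_hat[r][[i - 1 for i in seq]]
            assert np.all(np.diff(p_sorted) >= -1e-12)

    def test_model_averaged_vector_is_convex_combination(self, model):
        data = TrialData.from_cohorts([(18, 3, 2)], model.K)
        res = model.fit(data, model_averaging=True)
        stacked = res.per_ordering_p_hat
        assert np.all(res.p_hat <= stacked.max(axis=0) + 1e-12)
        assert np.all(res.p_hat >= stacked.min(axis=0) - 1e-12)

    def test_summary_table_shape_and_flags(self, model):
        res = model.fit(TrialData.from_cohorts([(18, 3, 0)], model.K))
        table = res.summary()
        assert len(table) == model.K
        assert table["recommended"].sum() == 1
        assert table.loc[table["recommended"]].index[0] in set(
            table.loc[table["admissible"]].index
        )
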