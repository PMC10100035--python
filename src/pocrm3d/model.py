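"""Bayesian core of the partial-ordering CRM.

Under each candidate ordering r the design uses the one-parameter power
working model

    p_ir = pi_ir ** exp(alpha_r),        alpha_r ~ N(mu, sigma^2),

where the pi_ir are the skeleton values reassigned to regimens according to
the toxicity ranks of ordering r.  After each cohort the likelihood of the
accumulated per-regimen DLT counts is combined with the normal prior to give
(i) the posterior of alpha under every ordering, (ii) the posterior
probability of each ordering being the correct one (proportional to prior
probability times marginal likelihood), and (iii) per-regimen toxicity
summaries -- posterior mean DLT risk, underdose/target/overdose interval
probabilities, and the allocation criterion delta.

All integrals are one-dimensional and are evaluated by deterministic
composite-Simpson quadrature on [mu - 10 sigma, mu + 10 sigma]; there is no
Monte Carlo anywhere in the inference, so decision paths are exactly
reproducible.

The user-facing entry point is :class:`PartialOrderCRM`, a model object
built from a regimen grid, an ordering set and design parameters, whose
``fit`` method returns a :class:`POCRMResults` carrying estimates,
uncertainty summaries and the escalation decision helpers.  The
module-level functions mirror the individual inferential steps on a single
working model and are convenient for testing and didactic use; the model
class computes exactly the same quantities vectorised across orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignParams, Skeleton
from .grid import RegimenGrid, build_default_grid
from .orderings import Ordering, OrderingSet, default_orderings

__all__ = [
    "TrialData",
    "WorkingModel",
    "PriorSpec",
    "AlphaPosterior",
    "working_model",
    "log_likelihood",
    "posterior_alpha",
    "ordering_posteriors",
    "select_ordering",
    "toxicity_summaries",
    "criterion_delta",
    "model_average_summaries",
    "PartialOrderCRM",
    "POCRMResults",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialData:
    """Accumulated per-regimen patient and DLT counts.

    The cohort log is the source of truth; the per-regimen totals n and y
    are derived from it, which keeps the two representations consistent by
    construction.
    """

    n_regimens: int
    cohort_log: tuple[tuple[int, int, int], ...] = ()  # (regimen, size, DLTs)

    def __post_init__(self) -> None:
        for regimen, size, dlts in self.cohort_log:
            if not 1 <= regimen <= self.n_regimens:
                raise ValueError(f"regimen {regimen} outside 1..{self.n_regimens}")
            if not 0 <= dlts <= size:
                raise ValueError(f"cohort ({regimen}, {size}, {dlts}) has y > n")

    @classmethod
    def empty(cls, n_regimens: int) -> "TrialData":
        return cls(n_regimens=n_regimens)

    @classmethod
    def from_cohorts(
        cls, cohorts: Sequence[tuple[int, int, int]], n_regimens: int
    ) -> "TrialData":
        return cls(n_regimens=n_regimens, cohort_log=tuple(cohorts))

    def add_cohort(self, regimen: int, size: int, dlts: int) -> "TrialData":
        return TrialData(
            n_regimens=self.n_regimens,
            cohort_log=self.cohort_log + ((regimen, size, dlts),),
        )

    @property
    def n(self) -> np.ndarray:
        out = np.zeros(self.n_regimens, dtype=int)
        for regimen, size, _ in self.cohort_log:
            out[regimen - 1] += size
        return out

    @property
    def y(self) -> np.ndarray:
        out = np.zeros(self.n_regimens, dtype=int)
        for regimen, _, dlts in self.cohort_log:
            out[regimen - 1] += dlts
        return out

    @property
    def total_n(self) -> int:
        return sum(size for _, size, _ in self.cohort_log)

    @property
    def total_dlts(self) -> int:
        return sum(dlts for _, _, dlts in self.cohort_log)

    @property
    def last_cohort(self) -> tuple[int, int, int] | None:
        return self.cohort_log[-1] if self.cohort_log else None


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior N(mu, sigma2) on the working-model parameter alpha."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("prior variance must be positive")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@dataclass(frozen=True)
class WorkingModel:
    """Skeleton values reassigned to regimens under one ordering."""

    ordering_index: int
    pi: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)


def working_model(skeleton: Skeleton, ordering: Ordering) -> WorkingModel:
    """Assign skeleton value k to the regimen at toxicity rank k of the ordering."""
    if len(skeleton) != len(ordering.sequence):
        raise ValueError(
            f"skeleton has {len(skeleton)} values but the ordering covers "
            f"{len(ordering.sequence)} regimens"
        )
    pi = np.empty(len(skeleton))
    for rank, regimen in enumerate(ordering.sequence):
        pi[regimen - 1] = skeleton.values[rank]
    return WorkingModel(ordering_index=0, pi=tuple(pi))


# ---------------------------------------------------------------------------
# Likelihood and posterior for a single working model
# ---------------------------------------------------------------------------


def log_likelihood(wm: WorkingModel, alpha, data: TrialData):
    """Binomial log likelihood of the accumulated counts at parameter alpha.

    Regimens with no patients contribute nothing.  Where the modelled DLT
    probability is numerically one while non-DLT outcomes were observed the
    log likelihood is -inf (a documented value, not an error).
    """
    alpha = np.asarray(alpha, dtype=float)
    pi = wm.as_array()
    n, y = data.n, data.y
    tried = n > 0
    if not tried.any():
        return np.zeros_like(alpha) if alpha.ndim else 0.0
    logpi = np.log(pi[tried])
    e = np.exp(alpha)
    logp = np.multiply.outer(e, logpi)  # (..., K_tried)
    with np.errstate(divide="ignore"):
        log1mp = np.log(-np.expm1(logp))
    ll = logp @ y[tried] + log1mp @ (n - y)[tried].astype(float)
    return ll if alpha.ndim else float(ll)


class AlphaPosterior:
    """Posterior of alpha on a deterministic quadrature grid.

    Carries the node locations, the normalised density and Simpson weights,
    and exposes means of functionals and the posterior CDF.  A point-mass
    "posterior" is available for degenerate checks.
    """

    def __init__(
        self,
        alpha: np.ndarray,
        weights: np.ndarray,
        evidence: float,
        density: np.ndarray | None = None,
    ):
        self.alpha = alpha
        #: posterior probability mass attached to each node (sums to ~1)
        self.weights = weights
        self.evidence = evidence
        #: normalised posterior density at the nodes (None for point masses)
        self.density = density

    @classmethod
    def point_mass(cls, alpha: float) -> "AlphaPosterior":
        return cls(np.array([alpha]), np.array([1.0]), evidence=1.0)

    @property
    def alpha_hat(self) -> float:
        return float(self.weights @ self.alpha / self.weights.sum())

    def mean_of(self, values: np.ndarray) -> float:
        """Posterior mean of a functional tabulated on the nodes."""
        return float(self.weights @ values / self.weights.sum())

    def cdf(self, a) -> np.ndarray:
        """P(alpha <= a) by cumulative trapezoid of the posterior density."""
        if self.alpha.size == 1:
            return np.where(np.asarray(a, dtype=float) >= self.alpha[0], 1.0, 0.0)
        cum = _cumulative_trapezoid(self.alpha, self.density)
        return np.interp(a, self.alpha, cum)


def _cumulative_trapezoid(alpha: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Normalised cumulative trapezoid integral of a density on a grid."""
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(alpha))]
    )
    return cum / cum[-1]


def _simpson_weights(n_points: int, h: float) -> np.ndarray:
    if n_points % 2 == 0 or n_points < 3:
        raise ValueError("Simpson rule needs an odd number of nodes >= 3")
    w = np.ones(n_points)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def posterior_alpha(
    wm: WorkingModel,
    prior: PriorSpec,
    data: TrialData,
    n_quad: int = 2001,
    width: float = 10.0,
) -> AlphaPosterior:
    """Posterior of alpha by Simpson quadrature on [mu - w*sigma, mu + w*sigma].

    With no data the posterior equals the prior and the evidence is 1 (up to
    the negligible truncation of the normal tails).
    """
    lo, hi = prior.mu - width * prior.sigma, prior.mu + width * prior.sigma
    alpha = np.linspace(lo, hi, n_quad)
    h = (hi - lo) / (n_quad - 1)
    base = _simpson_weights(n_quad, h) * stats.norm.pdf(
        alpha, loc=prior.mu, scale=prior.sigma
    )
    lik = np.exp(log_likelihood(wm, alpha, data))
    unnorm = base * lik
    evidence = float(unnorm.sum())
    if not np.isfinite(evidence) or evidence <= 0:
        raise FloatingPointError(
            f"quadrature failed: evidence = {evidence} "
            f"(total n = {data.total_n}, y = {data.total_dlts})"
        )
    density = (
        stats.norm.pdf(alpha, loc=prior.mu, scale=prior.sigma) * lik / evidence
    )
    return AlphaPosterior(alpha, unnorm / evidence, evidence, density=density)


def ordering_posteriors(
    models: Sequence[WorkingModel],
    q0: Sequence[float],
    prior: PriorSpec,
    data: TrialData,
    **quad_kwargs,
) -> np.ndarray:
    """Posterior probability of each ordering: q_r proportional to q0_r * evidence_r."""
    q0 = np.asarray(q0, dtype=float)
    if abs(q0.sum() - 1.0) > 1e-9:
        raise ValueError("ordering priors must sum to 1")
    evidence = np.array(
        [posterior_alpha(wm, prior, data, **quad_kwargs).evidence for wm in models]
    )
    total = (q0 * evidence).sum()
    if total <= 0:
        raise FloatingPointError("all marginal likelihoods vanished")
    return q0 * evidence / total


def select_ordering(
    q: Sequence[float], tie: str = "lowest", rng: np.random.Generator | None = None
) -> int:
    """Index (1-based) of the most probable ordering.

    Ties are broken toward the lowest index by default; ``tie='random'``
    randomises among the tied orderings using the supplied generator.
    """
    q = np.asarray(q, dtype=float)
    top = np.flatnonzero(q >= q.max() - 1e-12)
    if tie == "lowest" or len(top) == 1:
        return int(top[0]) + 1
    if tie == "random":
        if rng is None:
            raise ValueError("tie='random' needs an explicit rng")
        return int(rng.choice(top)) + 1
    raise ValueError(f"unknown tie rule {tie!r}")


def toxicity_summaries(
    wm: WorkingModel,
    posterior: AlphaPosterior,
    bounds: tuple[float, float],
) -> pd.DataFrame:
    """Per-regimen posterior toxicity summaries.

    Because p = pi**exp(alpha) is strictly decreasing in alpha, interval
    probabilities are computed exactly through the alpha-quantile mapping:
    P(p > c) = P(alpha < alpha_c) with pi**exp(alpha_c) = c.
    """
    lower, upper = bounds
    if not (0 < lower < upper < 1):
        raise ValueError("bounds must satisfy 0 < lower < upper < 1")
    pi = wm.as_array()
    e = np.exp(posterior.alpha)
    p = pi[None, :] ** e[:, None]  # (nodes, K)
    w = posterior.weights / posterior.weights.sum()
    p_hat = w @ p
    alpha_low = np.log(np.log(lower) / np.log(pi))
    alpha_up = np.log(np.log(upper) / np.log(pi))
    prob_over = posterior.cdf(alpha_up)
    prob_under = 1.0 - posterior.cdf(alpha_low)
    prob_target = 1.0 - prob_over - prob_under
    return pd.DataFrame(
        {
            "p_hat": p_hat,
            "prob_underdose": prob_under,
            "prob_target": prob_target,
            "prob_overdose": prob_over,
        },
        index=pd.RangeIndex(1, len(pi) + 1, name="regimen"),
    )


def criterion_delta(
    wm: WorkingModel,
    posterior: AlphaPosterior,
    gamma: float,
    b: float,
) -> np.ndarray:
    """Allocation criterion: penalised expected squared distance to target.

    delta_i = E[(p_i - gamma)^2] / (p_hat_i^b (1 - p_hat_i)^(2-b)), where
    the expectation and p_hat are taken under the posterior of alpha.  The
    numerator carries the estimation uncertainty (variance plus squared
    bias); the asymmetric denominator, evaluated at the posterior mean,
    penalises overdosing more severely than underdosing for b < 1.  For a
    point-mass posterior this reduces to the plain penalised squared
    distance, and for b = 2*gamma the induced ranking is close to the
    squared-distance ranking.
    """
    if not 0 < b < 2:
        raise ValueError("asymmetry b must lie in (0, 2)")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    pi = wm.as_array()
    e = np.exp(posterior.alpha)
    p = pi[None, :] ** e[:, None]
    w = posterior.weights / posterior.weights.sum()
    p_hat = w @ p
    mse = w @ (p - gamma) ** 2
    return mse / (p_hat**b * (1.0 - p_hat) ** (2.0 - b))


def model_average_summaries(
    models: Sequence[WorkingModel],
    q0: Sequence[float],
    prior: PriorSpec,
    data: TrialData,
    bounds: tuple[float, float],
    gamma: float,
    b: float,
    **quad_kwargs,
) -> pd.DataFrame:
    """Ordering-averaged summaries: each quantity weighted by the posterior
    probability of the ordering it was computed under."""
    q = ordering_posteriors(models, q0, prior, data, **quad_kwargs)
    acc = None
    for weight, wm in zip(q, models):
        post = posterior_alpha(wm, prior, data, **quad_kwargs)
        table = toxicity_summaries(wm, post, bounds)
        table["delta"] = criterion_delta(wm, post, gamma, b)
        acc = table * weight if acc is None else acc + table * weight
    return acc


# ---------------------------------------------------------------------------
# The model object (vectorised across orderings)
# ---------------------------------------------------------------------------


class PartialOrderCRM:
    """Partial-ordering CRM model for a regimen grid.

    Parameters
    ----------
    grid : RegimenGrid, optional
        The combination-schedule grid (defaults to the trial's 20 regimens).
    orderings : OrderingSet, optional
        Candidate toxicity orderings with prior probabilities (defaults to
        the bundled reconstruction of the trial's ten orderings).
    design : DesignParams, optional
        Skeleton, prior, overdose threshold, target range, criterion
        asymmetry, cohort and sample sizes (defaults to the calibrated
        trial design).
    n_quad, quad_width
        Simpson quadrature resolution and half-width in prior SDs.

    All alpha-independent quantities (working-model probabilities over the
    quadrature grid, their logs and squares, the interval thresholds) are
    precomputed once, which makes repeated fitting inside simulations cheap.
    """

    def __init__(
        self,
        grid: RegimenGrid | None = None,
        orderings: OrderingSet | None = None,
        design: DesignParams | None = None,
        n_quad: int = 2001,
        quad_width: float = 10.0,
    ):
        self.grid = grid or build_default_grid()
        self.orderings = orderings or default_orderings(self.grid)
        self.design = design or DesignParams()
        if len(self.design.skeleton) != len(self.grid):
            raise ValueError("skeleton length must match the number of regimens")
        if self.orderings.K != len(self.grid):
            raise ValueError("orderings must cover every grid regimen")

        d = self.design
        skel = d.skeleton.as_array()
        ranks = self.orderings.rank_matrix()  # (R, K)
        self.pi = skel[ranks]  # pi[r, i-1]

        lo = d.mu - quad_width * d.sigma
        hi = d.mu + quad_width * d.sigma
        self.alpha = np.linspace(lo, hi, n_quad)
        h = (hi - lo) / (n_quad - 1)
        self._norm_pdf = stats.norm.pdf(self.alpha, loc=d.mu, scale=d.sigma)
        self._base_w = _simpson_weights(n_quad, h) * self._norm_pdf

        e = np.exp(self.alpha)
        self._logpi = np.log(self.pi)  # (R, K)
        logp = self._logpi[:, :, None] * e[None, None, :]  # (R, K, M)
        with np.errstate(divide="ignore"):
            self._log1mp = np.log(-np.expm1(logp))
        self._p = np.exp(logp)
        self._psq = self._p * self._p
        # alpha-thresholds of the target bounds: p > c  <=>  alpha < alpha_c
        self._alpha_lower = np.log(np.log(d.target_lower) / self._logpi)
        self._alpha_upper = np.log(np.log(d.target_upper) / self._logpi)

    @property
    def R(self) -> int:
        return self.orderings.R

    @property
    def K(self) -> int:
        return len(self.grid)

    def empty_data(self) -> TrialData:
        return TrialData.empty(self.K)

    def _log_lik_grid(self, data: TrialData) -> np.ndarray:
        """(R, n_quad) log likelihood of the data on the quadrature grid."""
        n, y = data.n.astype(float), data.y.astype(float)
        e = np.exp(self.alpha)
        term_y = (self._logpi @ y)[:, None] * e[None, :]
        term_ny = np.tensordot(self._log1mp, n - y, axes=([1], [0]))
        return term_y + term_ny

    def fit(self, data: TrialData | None = None, model_averaging: bool = False) -> "POCRMResults":
        """Update the model on accumulated trial data.

        Returns a :class:`POCRMResults` with per-ordering posteriors and
        per-regimen summaries under the most probable ordering (default) or
        averaged over orderings with their posterior probabilities
        (``model_averaging=True``).
        """
        data = data if data is not None else self.empty_data()
        if data.n_regimens != self.K:
            raise ValueError("data covers a different number of regimens")
        ll = self._log_lik_grid(data)
        lik = np.exp(ll)
        evidence = lik @ self._base_w  # (R,)
        if not np.all(np.isfinite(evidence)) or np.all(evidence <= 0):
            raise FloatingPointError("marginal likelihood quadrature failed")
        q0 = self.orderings.prior_probs
        q = q0 * evidence
        q /= q.sum()

        w = self._base_w[None, :] * lik  # unnormalised posterior masses (R, M)
        w_sum = w.sum(axis=1)
        w_norm = w / w_sum[:, None]
        alpha_hat = w_norm @ self.alpha
        p_hat = np.einsum("rkm,rm->rk", self._p, w_norm)
        p_sq = np.einsum("rkm,rm->rk", self._psq, w_norm)

        # posterior CDF of alpha per ordering, for the interval probabilities
        dens = self._norm_pdf[None, :] * lik
        cum = np.concatenate(
            [
                np.zeros((self.R, 1)),
                np.cumsum(
                    0.5 * (dens[:, 1:] + dens[:, :-1]) * np.diff(self.alpha)[None, :],
                    axis=1,
                ),
            ],
            axis=1,
        )
        cum /= cum[:, -1][:, None]

        def cdf_at(thresholds: np.ndarray) -> np.ndarray:
            out = np.empty_like(thresholds)
            for r in range(self.R):
                out[r] = np.interp(thresholds[r], self.alpha, cum[r])
            return out

        prob_over = cdf_at(self._alpha_upper)
        prob_under = 1.0 - cdf_at(self._alpha_lower)
        prob_target = 1.0 - prob_over - prob_under

        d = self.design
        mse = p_sq - 2.0 * d.gamma * p_hat + d.gamma**2
        delta = mse / (p_hat**d.b * (1.0 - p_hat) ** (2.0 - d.b))

        return POCRMResults(
            model=self,
            data=data,
            evidence=evidence,
            ordering_posteriors_=q,
            alpha_hat=alpha_hat,
            per_ordering_p_hat=p_hat,
            per_ordering_prob_under=prob_under,
            per_ordering_prob_target=prob_target,
            per_ordering_prob_over=prob_over,
            per_ordering_delta=delta,
            model_averaging=model_averaging,
        )


@dataclass(frozen=True)
class POCRMResults:
    """Fit results: posteriors over orderings and per-regimen summaries.

    Per-regimen vectors (``p_hat``, ``overdose_prob``, ``delta``, ...) are
    reported under the most probable ordering r*, or -- when the fit was made
    with ``model_averaging=True`` -- as posterior-probability-weighted
    averages over all orderings.
    """

    model: PartialOrderCRM
    data: TrialData
    evidence: np.ndarray  # (R,) marginal likelihoods
    ordering_posteriors_: np.ndarray  # (R,)
    alpha_hat: np.ndarray  # (R,) posterior means of alpha
    per_ordering_p_hat: np.ndarray  # (R, K)
    per_ordering_prob_under: np.ndarray
    per_ordering_prob_target: np.ndarray
    per_ordering_prob_over: np.ndarray
    per_ordering_delta: np.ndarray
    model_averaging: bool = False

    @property
    def ordering_posteriors(self) -> np.ndarray:
        return self.ordering_posteriors_

    @property
    def r_star(self) -> int:
        """1-based index of the most probable ordering (ties -> lowest)."""
        return select_ordering(self.ordering_posteriors_)

    def _mix(self, per_ordering: np.ndarray) -> np.ndarray:
        if self.model_averaging:
            return self.ordering_posteriors_ @ per_ordering
        return per_ordering[self.r_star - 1]

    @property
    def p_hat(self) -> np.ndarray:
        return self._mix(self.per_ordering_p_hat)

    @property
    def underdose_prob(self) -> np.ndarray:
        return self._mix(self.per_ordering_prob_under)

    @property
    def target_prob(self) -> np.ndarray:
        return self._mix(self.per_ordering_prob_target)

    @property
    def overdose_prob(self) -> np.ndarray:
        return self._mix(self.per_ordering_prob_over)

    @property
    def delta(self) -> np.ndarray:
        return self._mix(self.per_ordering_delta)

    def safe_set(self) -> set[int]:
        """Regimens passing overdose control: P(p > upper) < c_overdose."""
        c = self.model.design.c_overdose
        return {
            i + 1 for i, v in enumerate(self.overdose_prob) if v < c
        }

    # Escalation helpers (full rule set lives in pocrm3d.escalation)
    def admissible_set(
        self, current: int | None = None, dlts_in_current_cohort: int | None = None
    ) -> set[int]:
        from . import escalation

        current = current if current is not None else self._current_regimen()
        dlts = (
            dlts_in_current_cohort
            if dlts_in_current_cohort is not None
            else self._last_dlts()
        )
        return escalation.admissible_set(self, current, dlts)

    def recommend(
        self, current: int | None = None, dlts_in_current_cohort: int | None = None
    ) -> int | None:
        from . import escalation

        current = current if current is not None else self._current_regimen()
        dlts = (
            dlts_in_current_cohort
            if dlts_in_current_cohort is not None
            else self._last_dlts()
        )
        return escalation.recommend_next(
            self.admissible_set(current, dlts), self.delta, self
        )

    def final_selection(self, apply_move_restrictions: bool = False) -> int | None:
        from . import escalation

        return escalation.final_selection(
            self, apply_move_restrictions=apply_move_restrictions
        )

    def _current_regimen(self) -> int:
        last = self.data.last_cohort
        if last is None:
            return self.model.design.start_regimen
        return last[0]

    def _last_dlts(self) -> int:
        last = self.data.last_cohort
        return 0 if last is None else last[2]

    def summary(self) -> pd.DataFrame:
        """Per-regimen report: counts, toxicity estimates, interval
        probabilities, criterion values and admissibility."""
        grid = self.model.grid
        admissible = self.admissible_set()
        recommended = self.recommend()
        df = pd.DataFrame(
            {
                "n_dose_mg": [r.n_dose for r in grid],
                "m_dose_mg": [r.m_dose for r in grid],
                "schedule": [r.schedule.value for r in grid],
                "avg_weekly_dose_mg": [r.avg_weekly_dose for r in grid],
                "n": self.data.n,
                "dlts": self.data.y,
                "p_hat": self.p_hat,
                "prob_underdose": self.underdose_prob,
                "prob_target": self.target_prob,
                "prob_overdose": self.overdose_prob,
                "delta": self.delta,
                "admissible": [r.index in admissible for r in grid],
                "recommended": [r.index == recommended for r in grid],
            },
            index=pd.Index([r.index for r in grid], name="regimen"),
        )
        return df

    def __repr__(self) -> str:
        mode = "model-averaged" if self.model_averaging else f"r*={self.r_star}"
        return (
            f"<POCRMResults n={self.data.total_n} dlts={self.data.total_dlts} "
            f"{mode} q={np.round(self.ordering_posteriors_, 3)}>"
        )
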