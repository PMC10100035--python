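# Methods

## The dose-finding problem and the model

The trial escalates three things at once: the dose of a backbone agent N
(100 / 200 mg), the single dose of a novel agent M (30 / 60 / 90 / 130 /
180 mg), and M's administration schedule (S1 continuous daily; S2
intermittent, about half the intensity over the 28-day DLT window). Each of
the 20 regimens is summarised by three coordinates plus the derived average
weekly dose of M (7 x single dose under S1, 3.5 x under S2). Toxicity is
known to be monotone in each coordinate with the others fixed, and the
clinical team additionally asserted the diagonal dominance "schedule
intensification plus a strictly higher average weekly dose outweighs a drop
in the single dose" (so the S2/130 regimen is surely less toxic than the
S1/90 one at the same backbone dose). Everything else -- the anti-diagonal
pairs -- is a priori unordered. `pocrm3d.grid.known_partial_order` derives
this partial order from the coordinates; a flag drops the diagonal
assertions, leaving the weaker within-agent monotonicity under which
ordering *feasibility* is defined.

The inferential engine is a partial-ordering CRM. A candidate complete
ordering `r` assigns each regimen a toxicity rank; the skeleton value of
that rank, powered by `exp(alpha_r)`, is the regimen's DLT probability.
`alpha_r` has a N(mu, sigma^2) prior. After each cohort the marginal
likelihood of every ordering updates its probability of being correct;
summaries are computed under the modal ordering (or, in the model-averaging
variant, averaged over orderings with their posterior probabilities).

## Candidate orderings and their priors (a reconstruction)

The trial's ten orderings appear only in unpublished supplementary
material, so the bundled set is a reconstruction from the published
assumption descriptions, shipped as an editable fixture
(`data/orderings_reconstructed.csv`), not asserted to be the trial's exact
list. Orderings 1-5 treat the backbone dose as the dominant driver (all
N=100 regimens before all N=200 ones) and differ in the within-block
trade-off between schedule, average weekly dose and single dose; orderings
6-8 let the backbone dominate only up to a moderate average dose of M;
orderings 9-10 are low-prior through-the-grid traversals (by average
weekly dose, and by plain grid index). All ten respect the full clinical
partial order.

Two published facts pin the reconstruction down further. First, the prior
probabilities must imply the elicited anti-diagonal pair probabilities
(90/50/80/65 for the four high-backbone pairs, mirrored at the low
backbone) under the group constraints that orderings 1-5 jointly carry
67-75% of the mass and orderings 9-10 are individually the least probable.
The bundled priors (0.24, 0.10, 0.19, 0.10, 0.10, 0.10, 0.09, 0.04, 0.02,
0.02) are a zero-loss solution of that elicitation problem. Second, the
published individual-trial behaviour -- after 1/3 DLTs at the start the
model de-escalates to the higher-average-dose anti-diagonal neighbour (14),
not the lower one (17) -- requires the leading ordering to rank regimens by
backbone dose and then by total average weekly dose, which is how the
reconstruction orders its first (most probable) candidate. The elicitation
search itself (`elicit_prior_probabilities`) minimises the sum of squared
differences between implied and elicited pair probabilities on a
discretised simplex (step 0.01): exhaustively for up to five orderings,
and by deterministic pairwise-exchange refinement from the uniform and
group-extreme starting points beyond that, with lexicographic tie-breaking
for full determinism.

## Design parameters

| parameter | default | meaning |
|---|---|---|
| skeleton | 0.01 + 0.04 i (i = 0..17), then 0.75, 0.80 | standardised risks per rank |
| mu | 1.50 | prior mean of alpha |
| sigma^2 | 1/1.50 | prior variance of alpha (see below) |
| c_overdose | 0.25 | overdose-control threshold for P(p > 0.35) |
| target range | (0.20, 0.35), gamma = 0.275 | target DLT band and its midpoint |
| b | 0.60 | criterion asymmetry (overdosing penalised harder) |
| cohort size / max n | 3 / 48 | accrual structure |
| start regimen | 18 (N=200, M=90, S1) | first cohort's regimen |

The published design account states the prior variance both as 1.00 (the
chosen calibration option) and 1.50 (the accompanying text), and defines
the calibration by binding first-cohort requirements: after 0/3 DLTs at the
start, regimen 19 must be the recommendation with 20 still inadmissible;
after 1/3, regimens 14 and 17 must be admissible with 18 not. Under this
package's deterministic posterior neither printed value meets the 0-DLT
requirement (the posterior P(p_20 > 0.35) is 0.222 at 1.00 and 0.190 at
1.50, both below the 0.25 threshold). The original computations ran in
JAGS, which parametrises the normal by *precision*; reading the text value
1.50 as a precision gives sigma^2 = 1/1.50 ~= 0.667, under which every
published first-cohort decision holds with clear margins. That value is the
default, and both printed alternatives remain selectable. The calibration
filter itself is implemented in
`pocrm3d.simulate.first_cohort_constraints_hold` and `calibrate`.

## Numerical choices

* **Quadrature.** All integrals over alpha use composite Simpson on
  [mu - 10 sigma, mu + 10 sigma] with 2001 nodes; the truncated normal mass
  is ~1e-23 and the evidence agrees with a 20001-point Riemann sum to 1e-5
  relative. Interval probabilities use the exact quantile mapping -- p is
  strictly decreasing in alpha, so P(p > c) is the posterior CDF of alpha
  at the threshold, evaluated by cumulative trapezoid of the density.
* **The allocation criterion.** The design criterion is a penalised squared
  distance to the target, `delta_i = E[(p_i - gamma)^2] /
  (phat_i^b (1 - phat_i)^(2-b))`. Taking the posterior expectation of the
  *whole* ratio instead is ill-defined under this model: `E[p^-b]` diverges
  (double-exponentially in the upper alpha tail), so any truncated
  quadrature of it would be dominated by the truncation point. The form
  used here is finite, carries the estimation uncertainty in the numerator
  (variance plus squared bias), coincides with the penalised squared
  distance at point-mass posteriors, and for b = 2 gamma ranks regimens
  like the plain squared distance.
* **Ties.** The modal ordering resolves ties toward the lowest index (a
  seeded randomised rule is available); recommendation ties resolve toward
  the regimen with the smaller estimated risk, then the lower index.
* **Zero criterion values in randomised allocation** are replaced by one
  tenth of the smallest positive value in the admissible set so the 1/delta
  weights stay finite.

## Simulation study and its scope

Scenarios assign each regimen a true DLT probability; the optimal set
(closest to 27.5%) and the correct band [20%, 35%] are derived from the
probabilities. Simulated trials draw binomial DLT counts per cohort of 3 up
to 48 patients, refit after every cohort, and allocate by the criterion
minimiser ("next best") or by 1/delta-weighted randomisation within the
admissible set; a trial stops early only when no regimen in the grid passes
overdose control. The terminal selection is the criterion minimiser among
all safe regimens under the final fit, with no relative-move restrictions
(the restricted variant is available); early-stopped trials contribute no
selection. One master seed spawns an independent stream per scenario.

At 200 replicates per scenario the next-best rule reproduces the published
mean operating characteristics within Monte-Carlo tolerance (optimal ~43%
vs 39%, correct ~69% vs 68%, overly toxic ~20% vs 21%, DLT burden ~30% vs
28%). The within-admissible randomisation, implemented literally as
1/delta weights over the full admissible set, *raises* the overly-toxic
selection rate instead of lowering it: with the finite criterion the deep
de-escalation regimens keep non-negligible weight, the allocation drifts
low and the top of the grid stays data-poor. The published evaluation,
whose criterion was the divergent expected ratio estimated by MCMC,
effectively gave sub-therapeutic regimens near-zero weight. This behaviour
difference is inherent to the criterion definition, not a tuning issue,
and is left as documented.

The generator emulates exactly the published study conditions (cohort
binomial outcomes, fixed accrual, no patient covariates). It does not model
DLT attribution, partial cohorts, intra-patient modification, or committee
overrides -- so passing tests demonstrate the decision engine's arithmetic
and its operating characteristics under idealised accrual, not clinical
performance.

## The exact 3+3 comparator

The comparator enumerates every trajectory of the 3+3-with-de-escalation
rules on a monotone ladder of regimens; branch probabilities are products
of binomial cohort probabilities, so all operating characteristics are
exact. Cohort outcomes are aggregated into decision categories (0, 1, 2+
DLTs), which is lossless for selection probabilities and sample sizes; the
expected DLT count is carried alongside. The published description of the
comparator is incomplete (it lists ten regimen indices while calling them
nine and names neither the start dose nor the rule variant), so the rule
set is switch-configurable. Defaults: ladder = regimens 11-20 in index
order, start at regimen 18, a clean 0/3 at the top dose selects it
outright, a fresh cohort treated during de-escalation is selected on 0/3
(expanded to six on 1/3), and a dose already cleared with 0/3 on the way up
is expanded to six when de-escalation returns to it. Under these defaults
the scenario-1 row of the published comparator table is reproduced to
rounding; the mean optimal percentage and the scenario-8 overly-toxic
percentage land within about four points of the published values, and no
switch combination examined reproduces the whole block simultaneously --
scenario families with a mildly toxic first de-escalation dose demand rarer
selection there, while the very toxic scenarios demand more frequent
selection during descent, which no DLT-count-based rule can do at once.

## Dose-transition pathways

`build_dtp` enumerates all hypothetical DLT outcomes of the next cohorts
and runs the full fit/admissibility/recommendation cycle at every node, so
pathway branches are bit-identical to sequential engine runs (this is
asserted in the tests). For communication the admissible set is condensed:
several admissible high-backbone regimens are shown alone; a single one is
shown with the low-backbone regimens within halving of the current average
dose; otherwise everything is shown. A branch terminates when nothing is
admissible.

## Known limitations

* The ordering set and its priors are a reconstruction; quantities that
  depend on the exact supplementary list (the "used" pair probabilities,
  ordering-level posterior trajectories) are reproduced in structure, not
  verbatim.
* The one-parameter power model shares a single alpha across regimens per
  ordering; it is a working model for decision-making, not a generative
  model of the grid.
* The exact 3+3 rule set is the closest documented variant, not a verified
  copy of the reference implementation.
* Only complete cohorts of fixed size are modelled.
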