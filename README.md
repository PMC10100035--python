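# pocrm3d

Bayesian dose-finding engine for a three-dimensional Phase I escalation
problem: two agents given in combination -- a backbone agent N at 100 or
200 mg and a novel agent M at 30--180 mg -- with M administered either
continuously (schedule S1) or intermittently at roughly half the intensity
(S2). The 20 combination-schedule *regimens* cannot be linearly ordered by
toxicity a priori: toxicity rises with either dose and with schedule
intensification, but "anti-diagonal" trade-offs (a higher single dose of M
under the gentler schedule versus a lower dose given continuously) have an
unknown order.

The package implements the partial-ordering continual reassessment method
(POCRM) for this setting, for trial statisticians designing or evaluating
such studies. Under each candidate toxicity ordering `r` the DLT risk of
regimen `i` follows a one-parameter power working model

    p_ir = pi_ir ** exp(alpha_r),      alpha_r ~ N(mu, sigma^2),

where the `pi_ir` are a fixed skeleton permuted to match the ordering. After
each cohort the posterior probability of each ordering (prior times marginal
likelihood) is updated; under the most probable ordering every regimen gets
a posterior mean DLT risk, underdose/target/overdose probabilities, an
overdose-control flag `P(p_i > 0.35) < 0.25`, and an asymmetric penalised
squared-distance criterion `delta_i` that drives the recommendation. Four
escalation restrictions (overdose control, one dimension up at a time, no
more than doubling the dose of M, no dose increase after a DLT) define the
admissible set a safety committee chooses from. Alongside the model the
package ships:

* `pocrm3d.orderings` -- candidate-ordering construction from clinical
  driver assumptions and a grid-search elicitation of ordering priors from
  pairwise probability statements;
* `pocrm3d.simulate` -- full-trial simulation, operating characteristics
  over twenty bundled toxicity scenarios, and the design-calibration filter;
* `pocrm3d.three_plus_three` -- an *exact* (path-enumeration) 3+3
  comparator with documented rule switches;
* `pocrm3d.dtp` -- dose-transition pathways: the decision tree of model
  recommendations over all hypothetical DLT outcomes of the next cohorts.

All posteriors are computed by deterministic one-dimensional quadrature, so
every decision path is exactly reproducible.

## Worked example

```python
from pocrm3d import PartialOrderCRM, TrialData

model = PartialOrderCRM()          # trial grid, reconstructed orderings,
                                   # calibrated design (start regimen 18)
res = model.fit(TrialData.from_cohorts([(18, 3, 1)], model.K))
print(res.r_star, res.recommend(18, 1))
print(res.summary().loc[[13, 14, 17, 18],
      ["p_hat", "prob_overdose", "delta", "admissible"]].round(3))
```

prints

```
1 14
         p_hat  prob_overdose  delta  admissible
regimen
13       0.153          0.098  0.129        True
14       0.216          0.195  0.096        True
17       0.182          0.139  0.109        True
18       0.301          0.366  0.100       False
```

After one DLT in the first cohort of three at the starting regimen (18),
the most probable ordering is the backbone-then-average-dose one (`r* = 1`);
regimen 18 itself fails overdose control (`P(p > 0.35) = 0.37 >= 0.25`), the
anti-diagonal de-escalations 14 and 17 are admissible, and the criterion
recommends regimen 14 -- the estimated risk closest to the 27.5% target.
With zero DLTs instead, the model escalates to regimen 19 while regimen 20
is still inadmissible.

The same engine drives the command line:

```bash
pocrm3d dtp --depth 2            # dose-transition pathways
pocrm3d simulate --n-sim 200 --seed 1 --out out/
pocrm3d oc-table --out out/      # exact 3+3 comparator rows
pocrm3d elicit                   # ordering priors from pairwise statements
pocrm3d fixtures --out fixtures/ # grid / orderings / scenario CSVs
```

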