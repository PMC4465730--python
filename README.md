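# paypref

A discrete choice experiment (DCE) toolkit for studying how healthcare
stakeholders — physicians, policy makers, healthcare executives and
researchers — trade off the outcomes a payment-system reform may produce
across eleven health-system performance domains (clinical effectiveness and
patient safety, best-practice service use, care equity, coordination,
patient centeredness, timeliness, short- and long-term cost containment,
provider wellness, innovation, and gaming of the system).

The package implements the full study pipeline:

1. **Design** — Bayesian D-optimal *partial-profile* paired choice sets:
   each set shows two hypothetical outcome profiles in which at most 5 of
   the 11 domains differ (the rest are held constant to limit cognitive
   burden). Planned constants follow an attribute-balance plan; the varying
   levels are optimized by coordinate exchange against the expected
   log-determinant of the multinomial logit (MNL) information matrix,
   averaged over a multivariate-normal prior that encodes outcome ordering
   and loss aversion. Dominated pairs are excluded.
2. **Simulation** — a synthetic population with the study's marginal
   characteristics (547 respondents, overlapping stakeholder roles, five
   geographical areas, 87% choice-set completion) answering their survey
   block under a configurable "truth" with subgroup interaction effects.
3. **Estimation** — maximum-likelihood conditional logit. With forced pairs
   and unlabeled alternatives the MNL reduces exactly to a binary logit on
   the effects-coded profile difference; respondent covariates enter only
   through interactions with attribute codes.
4. **Reporting** — likelihood-ratio attribute tests; relative importance
   `-log p`, rescaled so the most significant domain scores 100; and
   "golden standard" standardization of all marginal utilities by the
   absolute value of the coefficient for a deterioration in effectiveness
   and patient safety, so that reference reads exactly −1.
5. **Scenarios** — total utility of any outcome configuration per
   (area, role) subgroup, the status-quo baseline, relative differences
   `(U_after − U_before)/U_before`, and cross-stakeholder alignment.

## The model

Utility of profile *j* in choice set *s* for respondent *i* is linear in the
effects-coded outcome levels:

```
u_ij = Σ_k  β_k(i) · x_jk ,     β(i) = β_main + Σ_g z_ig · β_g
```

where each 3-level domain contributes two effects-coded columns (positive →
(1,0), no change → (0,1), negative → (−1,−1), so level utilities sum to zero
within each domain) and `z_ig` are subgroup indicators or standardized
covariates. Choice follows the MNL rule `P(1) = e^{u1}/(e^{u1}+e^{u2})`.
The design criterion is `E_β [ log det M(X, β) ]` with
`M = Σ_s X_sᵀ(diag(p_s) − p_s p_sᵀ)X_s`.

## Worked example

```python
import paypref as pp
from paypref.model import ConditionalLogit, ModelSpec

schema = pp.study_schema()                      # the 11 study domains
prior = pp.build_ordered_prior(schema, draws=256, seed=11)
design = pp.optimize_design(schema, prior, n_sets=54, n_varying_max=5,
                            n_blocks=3, restarts=2, seed=7)
truth = pp.study_truth_default(schema)
population = pp.generate_population(547, seed=5)
data = pp.simulate_choices(design, population, truth, seed=9)

pooled = ConditionalLogit(data, ModelSpec()).fit()
print(pooled.importance_table()[["attribute", "p_value", "scaled_importance"]].head(3))
```

prints (the most important domain is pinned to 100 by construction; the
p-values are LR-test tail probabilities):

```
           attribute       p_value  scaled_importance
effectiveness_safety 2.463027e-107         100.000000
      long_term_cost  5.496341e-72          66.842612
   provider_wellness  2.201026e-55          51.269232
```

Standardized utilities put every level on the golden-standard scale
(`pooled.standardized_utilities().triple("effectiveness_safety")` →
`(0.89, 0.11, -1.0)`: improving effectiveness is worth +0.89, a
deterioration is the −1 reference). Fitting the subgroup interaction model
and comparing the reform scenario against the status quo:

```python
spec = ModelSpec(interactions=tuple(truth.interactions))
full = ConditionalLogit(data, spec).fit()
report = pp.utility_report(full, schema, pp.reform_scenario_default(schema))
print(report[report["area"] == "canada"])
```

```
  area         role  u_status_quo  u_scenario  relative_difference  baseline_negative
canada    physician      0.238106    0.978704                 3.11              False
canada policy_maker      0.090231    0.967557                 9.72              False
canada    executive      0.234526    0.736115                 2.14              False
canada   researcher      0.259680    1.022802                 2.94              False
```

Each row sums the subgroup's standardized marginal utilities at the
scenario's outcome levels; `relative_difference` is the utility gain of the
reform relative to the status-quo baseline, rounded half-up to 2 decimals.
`pp.alignment_change(report, "physician", "policy_maker")` then reports
whether the utility gap between two stakeholder groups narrows under the
reform.

The same pipeline is available from the shell:

```bash
paypref design --sets 54 --max-varying 5 --blocks 3 --restarts 4 --seed 7 --out design.csv
paypref simulate --design design.csv --n 547 --out data/
paypref fit --respondents data/respondents.csv --choices data/choices.csv --out fit.json
paypref scenario --fit fit.json --out scenario_utilities.csv
paypref run-all --config run.yaml          # everything, with a manifest
```

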