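# Methods

This note documents the models, algorithms and default parameters behind
`paypref`, the design choices that were genuinely open, and what the
synthetic-data tests do and do not establish.

## Choice model

Respondents face forced pairs of unlabeled partial profiles over K domains,
each with three ordered outcome levels (positive, no change, negative).
Domains are effects-coded with two columns per domain — positive → (1, 0),
no change → (0, 1), negative → (−1, −1) — so the three level utilities of a
domain sum to zero and all three are reportable coefficients. Dummy coding
would have folded one level into an implicit baseline; effects coding was
chosen because status-quo utilities are themselves of interest (they are
small but not zero in fitted models, and the status-quo scenario's total
utility is built from them).

Choice probabilities are multinomial logit. For a forced pair the model
collapses exactly to a binary logit on the coded profile difference
`d_s = x_s1 − x_s2`; respondent-level main effects cancel, which is why
respondent covariates (stakeholder roles, geographical area, age, seniority,
sex, payment forms in use) can only enter interacted with attribute codes.
Continuous covariates are standardized to mean 0, SD 1 before interaction;
the scaling of binary indicators is left alone.

## Design generation

**Attribute balance.** With at most `m` varying domains per set, each set
receives `K − m` planned constants ('\*'). Per-domain constancy counts are
forced to `⌊n_sets(K−m)/K⌋` or that value plus one — for the study geometry
(K = 11, 54 sets, m = 5) every domain is planned-constant in 29 or 30 sets.
Assignment is a seeded greedy (largest remaining quota first, pair-count
penalty as tie-break) followed by a first-improvement swap descent that
minimizes the sum of squared pair co-constancy counts at fixed per-domain
counts. On the exactly solvable case (K = 4, 6 sets, 2 constants) the
descent attains every unordered pair exactly once; at study geometry it
reaches a local optimum with pair counts spread over at most 4 around the
mean of 14.7, which is the documented balance tolerance of this builder.
Planned constants are displayed at the neutral no-change level in both
profiles (a configuration choice; any shared level carries no information
in a paired MNL).

**Criterion.** The Bayesian D-criterion is the mean over prior draws of
`log det M(X, β)` with `M = Σ_s p_s1 p_s2 d_s d_sᵀ`. A draw whose matrix is
singular (smallest eigenvalue ≤ largest / 1e10) makes the criterion −∞.

**Prior.** A multivariate normal over the coded coefficients encodes, per
domain of a-priori rank r: level utilities `(+g_r, 0, −λ g_r)` with
`g_r = base_gap · rank_decay^(r−1)` and loss-aversion multiplier λ ≥ 1.
Because effects coding spans only zero-sum utility triples, the target is
projected by least squares (equivalently, centered); ordering and loss
aversion survive the projection. Defaults: `base_gap = 1.0`, `λ = 1.5`,
`rank_decay = 0.9`, `sd = 0.5` (diagonal covariance), 512 draws. These are
configurable, not canonical: they reproduce the intended qualitative
structure — positive preferred to no change preferred to negative, avoidance
weighed more than improvement, geometrically decaying gaps across ranks —
with no claim of matching any specific historical prior. The a-priori rank
is taken to be the domain's position in the published domain table, the
only ordering available. The study schema's reference pair (deterioration
in effectiveness and patient safety) anchors downstream standardization.

**Coordinate exchange.** From a seeded random non-dominated start, each
set × varying-domain × profile position is swept, trying all three levels
and accepting strict criterion improvement only (incumbent retained on
ties, which prevents cycling); convergence is a full sweep with no accepted
move, capped at 50 sweeps, best of `restarts` starts kept. Candidate moves
are scored with a rank-2 determinant update (matrix determinant lemma) per
prior draw; the state is refactorized on every acceptance so numerical
drift cannot accumulate. Moves that would create a set in which one profile
weakly dominates the other under the prior-mean level ordering are never
accepted (dominated pairs elicit no trade-off information); with a
point-mass prior at zero the ordering is flat and the constraint is
vacuous. Varying domains whose levels coincide in both optimized profiles
are recorded as incidental ('§') constants. Blocks are dealt round-robin
over the optimized set order — the blocking rule was open, and round-robin
makes block sizes exactly equal without further optimization.

On a two-domain, four-set, full-profile toy problem the optimizer attains
the exhaustive-search optimum over all paired designs; at study geometry
it clearly beats the best of 100 random feasible designs sharing its
balance plan.

## Synthetic respondents and choices

The generator emulates the study's structure: 547 respondents; overlapping
roles (physician 67%, policy maker 22%, executive 34%, researcher 30%);
areas Canada 10%, Eastern Europe 9%, Western Europe 25%, Oceania 18%, US
37%; 31% female; age 50 ± 11 (truncated 25–85); seniority 23 ± 11
(truncated at 0 and capped at age); seven overlapping payment forms; three
survey blocks dealt round-robin; each of a respondent's 18 sets answered
independently with probability 0.87 (unanswered sets drop both rows).
Role indicators are Bernoulli with rates adjusted by a fixed point so the
margins *conditional on having at least one role* hit the targets —
naively redrawing role-less respondents would inflate every share.

Characteristics are sampled independently of one another: only marginal
frequencies are available, no joint distribution. This is the generator's
main idealization — real role/area/age dependence, respondent-level
dropout, and any non-MNL choice behavior (inattention, lexicographic
rules) are absent. Passing tests therefore establish that the pipeline
recovers the data-generating process *when the MNL model is true*, not
that the model is adequate for any particular survey.

The default truth assigns level-utility triples on the standardized scale
(deterioration of effectiveness ≈ −1 before standardization, so
standardized outputs read like the truth). Avoidance outweighs improvement
in every domain except long-term cost containment and gaming, whose
improvement dominates and whose status-quo utilities are slightly
negative; effectiveness is by far dominant; magnitudes are set so that at
the study's sample size all eleven domains remain clearly significant —
matching the reported study conditions. Interaction offsets carry the
reported heterogeneity signs (physicians weight effectiveness avoidance,
coordination, provider wellness and timeliness up and short-term cost
containment down; policy makers shift gaming toward improvement;
executives weight provider wellness up; researchers weight effectiveness
and long-term cost containment up; Oceania weights effectiveness most and
Canada least).

## Estimation

Newton's method with step halving from β = 0 on the strictly concave
paired-difference log-likelihood; convergence when the gradient max-norm
drops below 1e−6; a cap of 100 iterations. The covariance is the inverse
observed information at the optimum (pseudo-inverse with a warning if
singular); coefficients beyond ±50 are flagged as possible separation.
Columns with no within-set variation anywhere are rejected up front with
the offending labels — an attribute that never varies is unidentifiable in
a conditional logit. The estimator is checked in the test suite against
statsmodels' independent binary-logit implementation on the same
differenced matrix (agreement ~1e−10).

The likelihood-ratio test of a domain refits the model with that domain's
two main-effect columns removed, retaining any interaction columns, and
refers `2(LL_full − LL_reduced)` to chi-square with 2 degrees of freedom.
Note that in a model with many interactions this is a *conditional* test:
collinearity between a domain's codes and its own subgroup interactions
(e.g. a 67% physician share) absorbs part of the main effect. The
importance ranking reported by the pipeline is therefore computed from the
pooled main-effects fit, where the LR test measures a domain's overall
significance; the interaction fit drives the subgroup scenario tables.

## Reporting scales

Relative importance is `−log p` rescaled as `100 · log p / log p_min`, so
the smallest-p domain scores exactly 100 and the scale is invariant to the
logarithm base. p-values are floored at 1e−300 with a flag (large
simulated samples genuinely underflow). Standardization divides every
level utility by the absolute pooled main-effect utility of the reference
pair; the same pooled denominator is used for subgroup contexts so that
physician vs non-physician (etc.) utilities remain on one scale. The
reference maps to −1 exactly, and the transform is exactly invariant to
rescaling all coefficients by any c > 0.

Scenario total utility sums the context's standardized utilities at the
scenario's levels (exactly additive over domain partitions). Relative
difference is `(U_after − U_before)/U_before`, displayed rounded half-up
to 2 decimals. A negative baseline flips the sign of the ratio's intuitive
"gain" reading; report rows carry a `baseline_negative` flag and such
cells should be interpreted with care rather than compared across rows.
Subgroup utilities for an (area, role) cell combine main effects with the
area and role offsets additively — no area × role terms are modeled.

## Problem sizes and numerical defaults

The test suite runs the design optimizer at the full study geometry
(54 sets, 4 restarts, 256 prior draws — about half a minute), parameter
recovery over 20 study-scale replicates, and test calibration over 200
datasets of 250 respondents × 12 sets on a 4-domain schema — sizes chosen
to keep the whole suite comfortably fast on one CPU while staying in the
regime where the asymptotic calibration of the LR test holds. Coverage is
asserted two ways: mean coverage across coefficients ≥ 0.90, and each
coefficient above the Bonferroni-adjusted exact-binomial lower band at
family level 0.05 — with 20 replicates per coefficient a fixed 90%
cutoff would false-alarm on a correct implementation too often across ~44
simultaneous coefficients.

## Known limitations

* Margins-only population model (no joint dependence structure; role
  overlap beyond the margins is unmodeled).
* Missingness is independent per choice set; respondent-level dropout is
  not modeled.
* No mixed-logit / latent-class heterogeneity: subgroup differences are
  fixed interaction effects.
* The generated design matches the published design's *structural*
  properties (set counts, blocking, partial-profile width, attribute
  balance, non-dominance), not its literal choice sets; likewise the prior
  reproduces the stated qualitative ordering, not specific historical
  values.
* No opt-out alternative and no labeled alternatives, by design of the
  study format.
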