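# Methods

This note records the statistical procedures the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and estimation

**Graded response model.** Ordered categories 0..C−1; cumulative logistic
trace lines with slope `a` and strictly increasing thresholds
`b_1..b_{C−1}`; category probabilities are differences of adjacent
cumulative curves with the conventions P*₀ ≡ 1, P*_C ≡ 0. All
probabilities are clipped to [1e−12, 1−1e−12] before logs or divisions.
Item information uses Samejima's closed form
I(θ) = Σ_j (P*'_j − P*'_{j+1})² / P_j with P*'_j = a·P*_j(1−P*_j); the
test suite verifies it against a finite-difference oracle (the expected
negative second derivative of the log category likelihood) to 1e−6.

**Marginal maximum likelihood.** The latent metric is identified by a
fixed population distribution, default N(0, 1), represented by 49 equally
spaced quadrature points on [−6, 6] with renormalized normal weights —
a common default for polytomous MML; both range and resolution are
configurable. EM alternates posterior node weights (E-step) with
independent per-item maximizations of the expected complete-data
log-likelihood (M-step). The M-step is a bounded quasi-Newton
(L-BFGS-B, analytic gradient, ≤15 inner iterations) on the
reparameterization (log a, b₁, log gaps), which enforces a > 0 and
threshold order by construction; a partial M-step preserves the
generalized-EM monotonicity of the marginal log-likelihood, which the
suite asserts at tolerance 1e−8. Convergence: maximum absolute parameter
change < 1e−4, cap 500 cycles (a capped run is flagged and warned, not
errored — in the EM tail all parameters move together by ~1e−4/cycle
while estimates are stable to well below their standard errors).
Missing responses contribute nothing to any likelihood. Starting values:
a = 1.5 and thresholds from inverse-logistic transforms of observed
cumulative proportions. An item with an unobserved category is an error
by default; `on_unobserved="collapse"` renumbers the observed codes and
fits that item with fewer categories. Plain ML is the default; a config
prior block (lognormal on a, normal on b) switches on MAP estimation.

**Standard errors.** Outer-product-of-gradients (empirical cross-product)
approximation to the observed information of the marginal likelihood:
per-respondent scores are posterior expectations of the complete-data
scores; the full-parameter OPG matrix is inverted and per-item blocks
retained. The suite checks the resulting slope SEs against a
parametric-bootstrap SD (80 replicates) within 25 %, and the n-scaling
(quadrupling n halves SEs). The supplemented-EM refinement is not
implemented; see DIF below for where that matters and what is done
instead.

## Diagnostics

**S-X² item fit.** Respondents are grouped by rest score (summed score
excluding the item under test). Model-expected category proportions per
rest-score group come from the recursive summed-score distribution over
the quadrature grid, weighted by the population prior. Adjacent score
groups are merged from the extremes inward until every group's smallest
expected cell reaches 1 (configurable); remaining sparse category cells
are merged with adjacent cells within the row. df = cells − C (the
item's parameter count) − groups, floored at 1. p-values are BH-adjusted
across items at level 0.01. Rest scores require complete response
vectors, so incomplete respondents are dropped for this statistic only —
the convention the original analyses used under ~5 % missingness is not
stated anywhere we could follow. Under a correctly specified model the
unadjusted flag rate at p < 0.01 falls in the [0.002, 0.03] band the
acceptance suite asserts (40 replicates, m = 10, n = 1000). Power
caveat: an item that merely loads partially on a second dimension is
refit by the unidimensional model with an attenuated slope whose
rest-score margins are nearly correct, so S-X² has little power against
that mechanism; the reliable symptom is the slope attenuation itself.
Category-order violations, by contrast, are detected decisively.

**Local dependence.** For each item pair, the observed C×C cross-table of
the jointly observed respondents is compared with the model-expected
table obtained by integrating the product of the two items' category
probabilities over the posterior-weighted trait distribution. Cells with
expected count < 1 are merged with adjacent cells; the Pearson X² is
standardized as (X² − df)/√(2 df) with df = (rows−1)(cols−1) after
collapsing. Pairs ≥ 10 are flagged; [5, 10) is reported as borderline
but never auto-flagged (borderline values can reflect category
sparseness rather than true dependence). Under the null the statistics
center near 0; a shared-nuisance pair at strength 0.7 exceeds 10 with
high power at n = 2000 (asserted at 5/6 replicates).

**Model fit.** −2LL from the marginal likelihood; AIC = −2LL + 2k and
BIC = −2LL + k ln(n) as exact identities. M2 is the limited-information
statistic on all first- and second-order category margins (categories
1..C−1, no collapsing): the margin covariance Γ is assembled from joint
category probabilities (conditional independence given θ for disjoint
item sets, exact joint evaluation for overlapping margin pairs), the
Jacobian Δ from analytic parameter derivatives, and
M2 = n·e'(Γ⁻¹ − Γ⁻¹Δ(Δ'Γ⁻¹Δ)⁻¹Δ'Γ⁻¹)e with df = margins − parameters;
RMSEA = √(max(0, (M2 − df)/(df·n))). M2 uses complete cases (the sample
margin vector needs a single n) and is skipped with a warning beyond
2500 margins (≈ 22 five-category items) — for the 51-item bank the
margin system (20 604) is far past what a desk machine can invert, and
the original software's margin/df convention is not reproduced here in
any case (our df for a 10-item five-category form is 710). Under a
correctly specified model M2 ≈ df and RMSEA ≤ 0.05, which the suite
asserts.

**Reliability.** Cronbach's alpha from the pairwise-available covariance
matrix (incomplete data stay in); marginal reliability as 1 minus the
mean EAP posterior variance under the population prior.

## Differential item functioning

Two groups, labels "reference"/"focal"; respondents without a label are
dropped from DIF only. Items lacking a category in either group are
excluded from testing with a warning.

Anchor parameters come from a pooled calibration of both groups. For
each candidate item and each group, the candidate's (a, b₁..b_{C−1}) are
re-estimated **jointly with that group's latent mean and SD** while every
other item stays fixed at its pooled values (the candidate is excluded
from its own anchor set). The omnibus Wald χ² (df = C) uses the item
block of the joint OPG inverse from each group, so the uncertainty of the
group metric propagates into the test. This matters: fixing the group
distribution at its own estimate and treating the item covariances as if
the metric were known makes the test severely conservative (observed
null flag rate 0 of 240 at p < 0.01), because estimating the group mean
from the same data removes the common metric noise that the naive
covariance still counts — the same issue the supplemented-EM refinement
addresses in the original software. With the joint covariance the null
flag rate is ~0.008 at nominal 0.01 and the p-distribution is close to
uniform (computed in the acceptance suite).

Flagged items (omnibus p < 0.01) get constrained Wald tests: slope
difference (df 1) and joint threshold difference (df C−1). A significant
slope test classifies the item as non-uniform DIF regardless of the
threshold test; a significant threshold test alone as uniform. If the
omnibus is significant but neither follow-up is, the flag is kept and
attributed to the stronger component. No anchors are pre-selected:
iteration 1 anchors on all items (leave-one-out); subsequent iterations
anchor on the currently unflagged set, re-estimating group distributions
and parameters, until the flagged set repeats (cap 10 iterations; an
oscillating set keeps the union with a warning). The flow is exactly
symmetric in the group labels, and DIF magnitude is reported graphically
(per-category curve overlays plus the mean area between expected-score
curves); no effect-size cutoff is imposed.

## Synthetic data

The generator draws θ ~ N(mean, sd), samples each item's response by
inverting the category CDF with per-cell uniforms, and masks cells
missing-completely-at-random. Each item's draws use a dedicated uniform
stream, so injections change only the targeted columns under a shared
seed. The default emulation profile mirrors the published study's
descriptives — n = 825, ~5.5 % missingness, a 49/51 two-group split —
and every stochastic call is reproducible from its seed.

Structural violations: **DIF** injection shifts a focal item's thresholds
and/or scales its slope (a uniform shift preserves threshold order by
construction). **Local dependence** uses a testlet-style shared nuisance
factor: the pair is generated from (θ + s·u)/√(1+s²) with u ~ N(0,1)
shared within respondent, keeping unit marginal trait variance while
adding pair covariance beyond the trait — the structure the LD statistic
targets, unlike response copying. **Misfit** either generates an item
from 0.5·θ + 0.866·η (unidimensionality violation; detectable mainly as
slope attenuation, see above) or swaps the generating probabilities of
middle categories 1 and 2 (ordering violation; detected by S-X² and by a
non-monotone category-2 endorsement across θ deciles).

What the generator does **not** emulate: non-normal trait distributions,
informative (non-MCAR) missingness, response styles or careless
responders (response times are only covered by the cleaning-rule test
vectors), multidimensional structure beyond the single injected nuisance
factors, and sampling designs. Passing tests therefore show the pipeline
is correct under its own assumptions and detects the injected violations
— not that real PRO data meet those assumptions.

The packaged fixture transcribes the published 51-item calibration
(slopes, thresholds, item-fit statistics and flags, local-dependence
partner lists, gender-DIF flags), the DSM-5 content map and the two
published 10-item forms, with printed Unicode minus signs preserved in
the JSON and normalized on load. Where the published table's layout is
ambiguous about which form a row's checkmark belongs to, the fixture
follows the assignment consistent with the published coverage counts
(9 of 11 and 5 of 11) and form sizes; one item appears on both forms.
Of note, the printed threshold b₄ = 9.39 of the weight-loss item lies
outside the default quadrature range, so its upper thresholds are
recovered only approximately (the fixture tests relax tolerances there).

## Short forms

Exclusion combines the flag sets: misfit ∪ DIF, plus every locally
dependent item except one designated keeper per LD set (the highest
slope among members carrying no other flag; ties break on item id).
Expert-style overrides re-admit named items with a recorded reason; an
override of an unflagged item is a warned no-op. The ledger accounts for
each bank item exactly once (eligible / excluded-with-reasons /
retained-by-override).

`content_first` walks the content criteria in map order, taking the
highest-slope eligible item per uncovered criterion, then fills by slope
rank; `precision_first` takes top-slope items, breaking slope ties
within 0.05 toward items covering uncovered criteria (the band makes the
content nudge explicit and testable). Both are deterministic. The
packaged published forms are the literal transcribed item lists, not
strategy output. Form comparison refits each form's columns, reports
alpha, −2LL, AIC, BIC, RMSEA, M2 and the test information curve, and
fills Δ(−2LL) only between nested forms.

## Problem sizes and numerics

The test and acceptance suites run their simulations at desk scale:
parameter recovery at n = 2000–5000; S-X² type-I at 40 replicates
(m = 10, n = 1000); DIF type-I at 24 replicates (n = 750/group); power
checks at 6–8 replicates with strong injections; the bootstrap SE check
at 80 replicates. Error-rate bands are asserted on the pooled item-level
counts, where the binomial noise at these sizes is well inside the
asserted intervals. Column-permutation equivariance of the calibration
is asserted at 1e−8 rather than bitwise, reflecting the floating-point
accumulation order of the E-step sums.

## Limitations

Unidimensional GRM only (no multidimensional, nominal or guessing
models); two DIF groups; no CAT simulation or optimal test assembly; no
T-score linking to external metrics; S-X² and M2 require complete (or
complete-case) data; OPG standard errors rather than supplemented-EM
(the DIF covariance construction above is the load-bearing substitute);
M2's margin convention differs from the original software's, so printed
M2/df values from that software are not comparable.
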