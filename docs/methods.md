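# Methods

## Model

`scdforecast` fits a discrete, time-homogeneous dynamic Bayesian network over
17 categorical variables per time slice, with slices five years apart. The
schema (`build_default_registry`) fixes each variable's domain and role:

* **dynamic** (hardwired temporal self-edge): age group (9 bins, 40–80),
  fruit/vegetable consumption (3), smoking (3), alcohol (4), LTPA (2),
  insomnia (3), BMI (3);
* **static**: gender (2), education (3);
* **health**: hypertension, high cholesterol, diabetes, mental disorders,
  pain (binary no/yes);
* **outcome**: concentration, memory, learning (binary good/declined).

BMI uses three levels (underweight merged with recommended healthy weight),
matching how the cohort's marginals are tabulated. Phase spacing is treated
as uniform 5-year steps. All computation uses 0-based category codes with
`-1` for item non-response; there is no imputation.

### Structure learning

Same-slice structure is learned under the fixed expert ordering (age,
gender, education, fruit/veg, smoking, alcohol, LTPA, insomnia, BMI,
hypertension, high cholesterol, diabetes, mental disorders, pain,
concentration, memory, learning): a node may only take parents that precede
it, which makes the search an independent per-node subset choice and
guarantees acyclicity. Each node receives the subset of at most
`max_parents` (default 3) candidates maximizing the qNML family score;
ties break toward smaller subsets, then lexicographic parent names. The
temporal self-edges of the dynamic variables are not searched; they are
hardwired, and the 3-parent cap applies to intra-slice parents only.

The qNML score of a family is the log-NML of the joint child+parents column
minus the log-NML of the parents column, each treated as one categorical
over its full declared product domain (structural zeros count toward the
domain size — the criterion is defined on the model's domain, not the
observed support). The multinomial parametric complexity C(n, k) is computed
**exactly**: C(n, 1) = 1, C(n, 2) by its binomial sum, then the two-term
recurrence C(n, k) = C(n, k−1) + n/(k−2) · C(n, k−2), carried in log space
(`logaddexp`), stable to ~1e−9 relative and overflow-free for any n, k a
cohort can produce. Exactness was chosen over the usual asymptotic
approximation because family sample sizes here are at most a few tens of
thousands and an exact value can be tested against brute-force composition
sums.

**Case policy.** All candidate subsets of one node are scored on the records
complete for the child *and its entire candidate pool* (`case_policy="node"`,
the default). Scoring each candidate on its own available cases
(`case_policy="family"`) is offered but not default: log-NML scales roughly
like −n·H, so a candidate set containing high-missingness parents is scored
on fewer records and thereby looks spuriously good — with realistic item
non-response that policy reliably selects the most-missing variables as
parents everywhere. Parameter estimation, by contrast, *is* family-wise
available-case (see below); only model selection needs a common support.

### Parameter estimation

Initial-slice CPTs condition each node on its learned intra-slice parents
and are counted over all person-phase records complete for that family
(phases pooled — the model is time-homogeneous). Transition CPTs exist for
the dynamic variables only and condition on the previous-slice self plus the
intra-slice parents, counted over consecutive-phase pairs of the same person
(a gap, e.g. phases 2→4, contributes nothing). Every CPT row is smoothed
with a per-cell Dirichlet prior of 1/2 (Jeffreys-style):
p = (n_cell + ½)/(n_row + k/2), so no probability is exactly zero and empty
rows fall back to uniform. The age-group transition is not estimated: age is
exogenous bookkeeping and advances deterministically one bin per slice,
absorbing at 80. Non-temporal nodes (statics, health, outcomes) have no
transition CPT and are regenerated each slice from their intra-slice
parents; static variables are instead carried forward explicitly at
forecast time (below).

### Inference and forecasting

Within one slice the network is small (≤17 nodes, ≤9 states), so posterior
marginals are computed exactly by variable elimination with a greedy
min-fill ordering; the implementation is checked against full joint
enumeration to 1e−9 in the tests. Evidence with zero probability raises an
error rather than returning NaNs.

Forecasting follows the model's transition rule: slice 0 conditions the
initial CPTs on the user's evidence (age group is required — it is the
dynamic model's initial parameter); for each later slice, every variable's
**marginal MAP state** (ties toward the lower category index) from the
previous slice feeds the transition CPTs, age increments deterministically,
and the slice's posteriors are recomputed. Only the point summary crosses
slice boundaries — full distributions are kept within a slice — which keeps
complexity linear in the horizon and avoids compounding uncertainty.
Design choices worth noting:

* **Future evidence is an intervention.** Evidence at slices ≥ 1 ("target
  evidence") replaces the variable's CPD in that slice with a point mass
  (do-style) instead of being conditioned on. Conditioning would make any
  target that contradicts a (near-)deterministic transition impossible;
  replacement is exactly the "user choice overrides the propagated state"
  semantics a what-if calculator needs. Slice-0 evidence conditions
  normally.
* **Static variables are carried forward** as evidence from their
  previous-slice value: a person's gender and education do not get
  re-generated five years later.
* **MAP is per-variable marginal mode**, not joint MAP; with the
  near-point-mass posteriors propagated here the distinction is minor, and
  the per-variable form matches the propagation rule's intent.
* If the forecast horizon would push age past its absorbing top bin, the
  forecast stops there with a warning.

### Risk tools

`compare_scenarios` forecasts under current and target evidence (identical
at slice 0 by contract), reads the outcome probability at the requested
slice, and reports the absolute reduction in percentage points and the odds
ratio OR = [p_t/(1−p_t)]/[p_c/(1−p_c)]. Credible intervals resample every
CPT row from its Dirichlet posterior (Gamma(counts + α) normalized — the
deterministic age transition is never resampled), rerun both forecasts per
draw, and take equal-tailed quantiles; the construction is the package's own
choice of posterior-uncertainty propagation, deterministic for a fixed seed.

The decision heatmap pins each modifiable factor (fruit/veg, smoking,
alcohol, LTPA, BMI, insomnia) to each of its levels at slice 1, on top of
any committed choices, and forecasts the outcome one slice ahead. Each row's
delta is taken against that row's **status-quo cell** (the committed level if
committed, else the factor's slice-0 level, likewise pinned), so the
status-quo delta is exactly zero and cells are compared like-for-like
(pinned vs pinned); a delta against the unpinned baseline forecast would be
contaminated by the pin-vs-marginalize difference. The matrix-level baseline
risk is the committed-only forecast, which makes the dynamic-update
identity exact: after committing a cell, the new matrix's risk at that
factor equals that cell's risk. Delta rendering bins at ±1/±5 percentage
points (presentation only).

Cross- and autocorrelations of the binary outcome/health indicators are
estimated by forward sampling full trajectories (sampling propagates sampled
states, not MAP states — it is the reference distribution, also used for the
Monte-Carlo consistency tests); constant indicators yield NaN rather than an
error.

### Evaluation

AUROC uses the Mann–Whitney pair formulation (ties half-credited).
Cross-validation partitions *individuals* into k seeded folds — repeated
measures of one person never straddle the train/test boundary — and per fold
reruns the entire structure search and CPT fit on the training individuals.
Held-out person-phases with an observed outcome are scored with the
posterior probability of the adverse category given the phase's observed
non-outcome covariates; the other two SCD outcomes are excluded from the
conditioning set. Rows with fully observed covariates take a vectorized
path that enumerates only the outcome block (valid because outcome nodes
never parent non-outcome nodes under the ordering); rows with missing
covariates use cached exact inference.

## Synthetic cohort generator

The generator emulates the *style* of a five-phase occupational survey
panel: n individuals, baseline age uniform over the tabulated 40–60
distribution (advancing one bin per phase), 80% women, education drawn once,
lifestyle factors evolving by sticky first-order Markov kernels, outcomes
and health conditions drawn per phase from an additive category-log-odds
(logistic) model, then item non-response and monotone dropout (once out,
always out, default hazard 0.06/step, optionally higher after a
declined-memory phase).

Two calibration mechanisms make the defaults faithful to the published
descriptive tables shipped in `data/generator_defaults.yaml`:

* **Factor kernels.** Each dynamic factor uses K_t = p_t·I + (1−p_t)·1 r_tᵀ,
  with the redraw distribution r_t solved from the marginal recursion so the
  per-phase marginals hit the configured targets exactly. The configured
  persistence (default 0.8) acts as a *cap*: where a tabulated category
  shrinks faster than the cap allows (current smoking, high-risk alcohol),
  the step's keep-probability is lowered just enough to stay feasible.
  Setting persistence to 1 freezes the factor entirely.
* **Outcome intercepts.** For each outcome and phase, the intercept of the
  logistic model is solved numerically (brentq on the sampled linear
  predictors) so the realized prevalence matches the configured target
  *whatever effects are planted*. Planted effects therefore change
  dependence structure, not marginals.

The SCD outcomes are only tabulated at the last two phases of the source
tables; phases 1–3 use a gentle ramp toward the first tabulated value.
Default planted effects are a protective LTPA log-odds of −0.35, a U-shaped
4-level alcohol vector (+0.30, 0, +0.10, +0.40), and small age/gender/
lifestyle terms; recovery experiments override these explicitly (e.g.
LTPA = ln 0.5 for the planted-OR-0.5 experiment).

Because the outcome model is additive in log-odds rather than itself a
Bayesian network, the ground truth (conditional ORs, U-shapes, null
configurations) is analytic and independent of the estimator under test.
What the generator does **not** emulate: the real joint dependence structure
among lifestyle factors, non-monotone panel return (the real cohort's phase
4 regained respondents), longer first-phase spacing, and
informative item non-response. Passing recovery tests therefore demonstrate
estimator correctness under the stated mechanism, not real-data validity.

A note on scenario ORs: a planted conditional OR of 0.5 yields a pipeline
scenario OR nearer ~0.55–0.6, because the current scenario's factor value at
the future slice is a persistence-weighted mixture rather than pure
"inactive" (plus mild non-collapsibility from marginalized covariates). The
recovery acceptance band (0.35, 0.7) brackets this attenuated value.

## Problem sizes and tolerances

Structure-search and recovery experiments in the test suite run at up to
20,000 individuals × 5 phases (~90,000 person-phase records after dropout),
which the exhaustive search handles in a few seconds per fit; the null
cross-validation experiment uses 2,000 individuals with k=5. Probability
rows are validated to sum to 1 within 1e−12; exact-inference equivalence is
asserted at 1e−9; the regret recurrence is compared with brute-force
composition sums at 1e−9 relative. Serialization round trips are exact
(counts are integers; probabilities survive JSON's repr round trip
bit-for-bit).

## Known limitations

* MAP propagation is a point approximation between slices; forecasts
  understate between-slice uncertainty by construction (the credible
  intervals capture parameter uncertainty only).
* qNML scores of one node's candidates share a common support, but the
  supports of *different* nodes still differ (available-case philosophy);
  total structure scores are comparable only between structures learned on
  the same table.
* The expert ordering is a hard constraint: genuinely reversed dependencies
  cannot be recovered, by design.
* Scenario ORs are conditional on the supplied evidence profile and are not
  population-marginal effect estimates; the observational caveat of any
  such calculator applies.
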