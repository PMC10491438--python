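# Methods

## Model structure

The model evaluates triage of suspected large-vessel-occlusion (LVO)
stroke — direct transfer to the angiography suite (DTAS) versus initial
transfer to the emergency room (ITER) — for a cohort entering at age 74
with a 10-year horizon (1 decision-tree year + 9 Markov years). Health is
tracked in five modified-Rankin-Scale bands (mRS 0–1, 2–3, 4, 5, death):
mRS 0 and 1 are pooled because trials report "excellent outcome" as
mRS 0–1, and mRS 2 and 3 carry similar utilities and costs. The 1-year mRS
distribution — not the 90-day one — anchors the Markov model, because
functional state still moves substantially between 90 days and 1 year and
is assumed stable (apart from ageing and mortality) afterwards.

**Decision tree.** Triage is a Bernoulli split at `p_lvo` (base case
147/174 ≈ 0.845, the trial's confirmation rate among suspected LVO).
Confirmed patients receive the strategy's acute diagnosis+treatment cost
and draw a 90-day mRS state; the 90-day vector is propagated to 1 year by
a row-stochastic 5×5 matrix that allows improvement, deterioration and
death. Year-1 care costs and QALYs accrue on the 1-year (post-transition)
distribution: the 1-year state is the model's anchor, and the alternative
(averaging the 90-day and 1-year states) adds a convention without data to
pin it down. Non-LVO patients contribute only the strategy-specific
diagnostic cost; their downstream costs and outcomes are assumed identical
between strategies and are excluded from totals (identical terms cancel
from every increment). `options.include_non_lvo_outcomes` plus a
`non_lvo` profile adds an identical yearly cost/QALY stream to both arms
for presentation-comparable totals.

**Markov engine.** Within each annual cycle, mortality acts first and mRS
transition applies to survivors only. This ordering keeps the two data
sources orthogonal: transition matrices describe mRS change conditional on
survival, while mortality comes from a separate life-table construction.
State- and age-specific death risk combines the national life table with
mRS hazard ratios on the annual survival scale,
`q(s,a) = 1 − (1 − q0(a))^{HR_s}`, which stays a probability for any
HR ≥ 0 (a log-rate proportional-hazards form; for the q0 ≲ 0.1 range of a
74–84-year table the two differ only in the third decimal). The annual
matrix is restricted to living destinations and row-renormalized before
use, so death never enters twice. Ages beyond the tabulated range clamp to
the last entry (`options.allow_age_clamp=False` turns that into a
validation error).

**Accrual and discounting.** Rewards accrue on end-of-cycle occupancy by
default; `options.accrual="start"` and `options.half_cycle_correction`
(the exact average of the two, by linearity) are provided because the
convention shifts totals by low single-digit percent and upstream
implementations rarely document it. No half-cycle correction by default:
with annual cycles over 9 years it is second-order. Cycle k (calendar year
1+k) discounts at `(1+r)^{−k}` with r = 4%/year for costs and 1.5%/year
for QALYs; year 1 is the undiscounted present. The useful closed form for
checks: a permanent state with utility u contributes
`u·(1 + Σ_{k=1..9} 1.015^{−k}) = u·9.360517320132` QALYs.

## Outcomes

ΔC and ΔE are differences of unrounded totals; the ICER is their ratio
when the intervention is costlier-and-better or cheaper-and-worse, and a
dominance label otherwise (a negative ICER is uninterpretable). Rounded
increments are shown only in reports — dividing them does not reproduce the
unrounded ICER, which is why presentation-grade increments and the ICER can
look mutually inconsistent at the dollar level. "Cost-effective at λ"
means strictly positive net monetary benefit `λ·ΔE − ΔC`; NMB handles all
four quadrants without sign pathologies, ties count as not cost-effective.
Computation is entirely in EUR; USD output multiplies by the fixed 2021
rate 1.1827 (thresholds €50,000/€80,000 ↔ $59,135/$94,616). No inflation
indexing is performed: inputs are declared to be 2021 values.

## Sensitivity analyses

**One-way / tornado.** A parameter is set to each end of its range (±20%
of base where no range is given, matching the published sensitivity
convention) with everything else at base case, and the pipeline re-runs.
When the parameter is one component p→p′ of a probability vector, every
other component is scaled by (1−p′)/(1−p) — the proportional repair that
keeps the vector exactly on the simplex, applied identically when the
varied component is death. Entries sort by |ICER(low) − ICER(high)|.

**Scenarios.** 1: `p_lvo = 0.42` (positive predictive value of a
prehospital RACE score > 4); 2: `p_lvo = 0.12` (LVO incidence among all
FAST-positive suspected strokes); 3: 4 Markov years. Overrides are applied
to a copy and touch nothing else.

**PSA.** Each of 10,000 draws samples every parameter with a declared
distribution — Dirichlet for whole outcome vectors and transition rows
(default: vectors sampled jointly; concentrations = source effective
sample sizes, trial arms 74/73 for 90-day outcomes), beta for scalar
probabilities and utilities, gamma for costs and hazard ratios — rebuilds
the parameter set, runs both strategies and records (ΔC, ΔE). Where only a
mean is known, beta/gamma hyperparameters are moment-matched with
SE = 20% of the mean. Draws are reproducible from the seed (package
default 20230905). Acceptability curves report the fraction of draws with
NMB > 0 on a $0–$150,000 grid ($1,000 steps, Dutch thresholds included
exactly); the two strategies' curves are exact complements.

## Synthetic data and what the tests show

`generate_parameter_set` draws full parameter sets with the structure of
the real inputs: Dirichlet outcome vectors around a proportional-odds
(ordinal logit) treatment shift with trial-sized concentrations,
diagonally dominant Dirichlet transition rows, ordered utilities, gamma
costs (scale set by Dutch post-stroke care magnitudes), and a Gompertz
life table `q0(a) = 1 − exp(−α e^{β(a−70)})`, α = 0.012, β = 0.09 —
roughly Dutch old-age mortality. Defaults mirror the study conditions:
arms of 74/73, entry age 74, 9 Markov years, 10,000-iteration PSA.

The generator emulates the *shape* of the evidence, not its values: passing
tests demonstrate that the engine conserves probability mass, discounts
correctly, matches closed forms in degenerate limits, and agrees with an
independent patient-level microsimulation (200,000 patients, 3 standard
errors) — they do not validate any specific clinical parameterization.
The packaged example file likewise carries real values only where the
source publication prints them in its text (confirmation rate, the DTAS
90-day P(mRS 0–1) = 0.2838 recovered as the midpoint of its published
22.70%–34.06% ±20% range, economic settings, scenario definitions); all
supplementary-table quantities are placeholders flagged
SYNTHETIC-PLACEHOLDER in the file itself, so results computed from it characterize the model, not the
published Dutch analysis. Transcribing the supplement into the same schema
is all that is needed to evaluate the latter.

The microsimulation mirrors the cohort engine event for event (triage
Bernoulli, categorical 90-day and 1-year states, death-then-transition
cycles, end-of-cycle accrual) but shares no code with the matrix
recursion; it intentionally supports only the default accrual
configuration, which is the one it validates.

## Numerical choices and edge cases

- Probability vectors and matrix rows must sum to 1 within 1e-9; DEAD is
  absorbing (row (0,0,0,0,1)) and carries no hazard ratio, utility 0, cost 0.
- Validation collects *all* violations before reporting, so a broken file
  is fixable in one pass.
- An annual-matrix row with zero mass on living destinations is an error
  only if survivors actually occupy it (renormalization would be 0/0).
- A degenerate renormalization (varied component carries all the mass)
  raises rather than guessing; bounds that leave [0,1] after repair raise.
- `markov_years = 0` is allowed and reduces exactly to the decision tree.
- Utility ordering u(mRS0–1) ≥ … ≥ u(mRS5) is enforced as a sanity check,
  overridable with `utilities.allow_unordered`.
- Monte Carlo problem sizes used by the shipped checks — 10,000 PSA draws,
  200,000 microsimulated patients, 1,000 random parameter sets for
  conservation — keep every Monte Carlo standard error well inside the
  asserted bands while a full run stays in the tens of seconds.

## Known limitations

- No tunnel states, time-varying utilities, or recurrent-stroke events
  beyond what the annual transition matrix encodes; no procedural
  complications for non-LVO patients.
- Two strategies only — no multi-way efficiency frontier, no EVPI.
- The acute cost per strategy is a single aggregate; if thrombolysis/
  thrombectomy unit costs and rates are known separately, fold the
  rate-weighted sum into `costs.acute_lvo` upstream.
- 90-day outcome distributions are taken to be conditional on confirmed
  LVO (the tree branches on confirmation first); if a source reports them
  over all randomized patients, renormalize before entry.
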