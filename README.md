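# dtas-cea

Decision-analytic cost-effectiveness model comparing two triage strategies
for patients with suspected large-vessel-occlusion (LVO) ischemic stroke:

- **DTAS** — direct transfer to the angiography suite (flat-panel CT to rule
  out hemorrhage, thrombolysis where indicated, immediate thrombectomy once
  angiography confirms the occlusion), and
- **ITER** — initial transfer to the emergency room (CT/CTA first, then
  transfer to the angiography suite when eligible),

from a health-care-payer perspective. It is written for health economists
and stroke-workflow researchers who want a transparent, scriptable
alternative to spreadsheet/TreeAge implementations of this model family.

## Model

A 1-year decision tree feeds a 9-year Markov cohort model over five health
states defined by modified Rankin Scale (mRS) bands: mRS 0–1, mRS 2–3,
mRS 4, mRS 5 and death.

1. **Decision tree (year 1).** A suspected-LVO patient has a confirmed
   occlusion with probability `p_lvo`. Confirmed patients draw a 90-day mRS
   outcome from the strategy-specific trial distribution, then transition to
   a 1-year mRS state through a 90-day→1-year matrix (early recovery and
   deterioration both happen). Year-1 cost is
   `p_lvo·(c_acute + Σ_s π_1y(s)·c_annual(s)) + (1−p_lvo)·c_diag`; non-LVO
   patients contribute only the strategy-specific diagnostic cost because
   their downstream care is assumed identical across strategies.
2. **Markov model (years 2–10).** Annual cycles with mortality applied
   first — `q(s,a) = 1 − (1 − q0(a))^{HR_s}` combining a national life table
   `q0(a)` with mRS-specific hazard ratios — then mRS transitions among
   survivors. Costs discount at 4%/year and QALYs at 1.5%/year,
   `(1+r)^{−k}` for cycle k, year 1 undiscounted.
3. **Outcomes.** ΔC, ΔE, the ICER ΔC/ΔE (dominance labels when the signs
   disagree), and net monetary benefit `NMB(λ) = λ·ΔE − ΔC` at the Dutch
   thresholds €50,000 ($59,135) and €80,000 ($94,616) per QALY. All
   computation is in EUR; USD is a fixed-rate (1.1827) reporting conversion.
4. **Uncertainty.** One-way sensitivity analyses (±20% default ranges,
   probability vectors repaired back onto the simplex) ordered into a
   tornado; three scenarios (RACE>4-only triage `p_lvo = 0.42`,
   all-FAST-positive triage `p_lvo = 0.12`, 4-year Markov horizon); and a
   10,000-draw probabilistic sensitivity analysis (Dirichlet outcome
   vectors and transition rows, beta probabilities/utilities, gamma costs)
   summarized as cost-effectiveness acceptability curves.

A patient-level microsimulation (`dtas_cea.synthetic.microsimulate`)
re-implements the identical event sequence by Monte Carlo sampling and is
used in the tests as an independent oracle for the cohort engine.

## Worked example

The packaged parameter file mixes values printed in the source
publication's text (trial confirmation rate 147/174, DTAS 90-day
P(mRS 0–1) = 0.2838, age 74, horizon, discounting, thresholds, exchange
rate, scenario definitions) with clearly flagged synthetic placeholders for
everything that publication reports only in supplementary tables (see
`notes.provenance` inside the file, and the methods note). With it:

```bash
$ dtas-cea report --scenarios base,1,2,3
scenario strategy  total_cost_usd  total_qaly delta_cost_usd delta_qaly icer_usd_per_qaly
    base     DTAS           71337        2.41           2497       0.29              8578
    base     ITER           68840        2.12
       1     DTAS           37011        1.20           2252       0.14             15564
       1     ITER           34758        1.05
       2     DTAS           12771        0.34           2080       0.04             50296
       2     ITER           10691        0.30
       3     DTAS           52268        1.54           1581       0.18              8600
       3     ITER           50687        1.36
```

Reading the base-case block: per suspected-LVO patient over 10 years, DTAS
costs $2,497 more and yields 0.29 more QALYs than ITER, an ICER of
$8,578/QALY — cost-effective at both Dutch thresholds (these numbers
reflect the placeholder inputs, not the published Dutch results). Scenarios
1 and 2 dilute the confirmed-LVO fraction, so the acute-pathway gain is
spread over more non-LVO patients and the ICER rises; scenario 3 truncates
the horizon over which QALY gains accumulate.

Other entry points: `dtas-cea validate | year-one | run | cea | owsa |
psa | ceac | scenario | synth`, each with `--params`, `--scenario`,
`--seed`, `--out`; `owsa/psa/ceac` also take `--plot` for tornado /
cost-effectiveness-plane / CEAC figures.

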