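# Methods

## Model structure and assumptions

The model is a one-year, cohort-level decision tree with four root-to-leaf
paths per strategy: {high-risk management (HRM), low-risk management (LRM)}
× {suicide, survival}.  It is intentionally minimal:

- **One-year horizon, no discounting.**  `time_horizon_years` is validated
  to equal 1; there is no Markov extension.
- **Death by other causes is excluded** — it would be identical in both
  arms and cancel out of every incremental quantity.
- **Nonfatal self-harm is excluded**: no data link the assessment
  strategies to self-harm rates, so neither its costs nor its disutilities
  appear.
- **Suicide at midpoint.**  Decedents accrue half a year of their branch
  utility — including the HRM decrement where applicable.  Whether the
  original analysis applied the decrement to decedents' half-year is not
  recoverable; charging it is the simplest reading consistent with the
  halving rule, and at annual risks below 2% the choice moves expected
  QALYs by under 10⁻³.
- **The suicide cost (£260)** is the direct emergency/health cost, charged
  once at the event in the assessment year.

## Parameters

All base-case inputs ship in `src/oxmis_cea/data/base_case.yaml` (flat
key–value YAML; a config with `base_case: true` may override individual
fields).  Probabilities are annual, costs in GBP, utilities on the 0–1
scale.

| parameter | base | meaning |
|---|---|---|
| `p_high_oxmis` | 0.25 | flag rate of the tool = 1 − specificity (0.75) |
| `p_high_clinical` | 0.50 | HRM assignment under unstructured judgment |
| `p_suicide_high` | 0.017 | annual risk in the tool's high-risk stratum |
| `p_suicide_overall` | 0.008 | 12-month suicide incidence in SMI |
| `hrm_risk_reduction` | 0.10 | relative risk reduction from HRM |
| `cost_oxmis` / `cost_clinical_assessment` | 57 / 253 | assessment costs |
| `cost_hrm` / `cost_lrm` | 1615 / 0 | management package costs |
| `cost_suicide` | 260 | direct cost of a suicide event |
| `utility_smi` / `utility_decrement_hrm` | 0.77 / 0.05 | utility and HRM disutility |
| `wtp_threshold` | 20000 | GBP/QALY for NMB and the CEAC (NICE convention; configurable) |

The HRM cost is taken as the published aggregate £1,615 even though its
stated components (4 × £343 reviews + £253 psychosocial assessment) sum to
£1,625; the aggregate is treated as authoritative and the discrepancy left
unresolved.

Two branch risks are not stated anywhere and are **reconstructions**:

1. **Tool-arm low-risk branch.**  Solved from the mixture constraint
   `p_high·p_suicide_high + (1−p_high)·p_low = p_suicide_overall`, giving
   0.005 at base case.  This closes the model while preserving the 0.8%
   population incidence, and reproduces the published strategy mean costs
   to the pound.  Infeasible combinations (implied `p_low` < 0 or
   `p_low` > `p_suicide_high`) raise a validation error.
2. **Clinical-arm branches.**  Clinical flagging is treated as carrying no
   risk information: both branches start at the population incidence
   0.008, with the 10% reduction applied in the HRM branch.  This is
   consistent with the evidence that unstructured clinical ratings
   discriminate poorly, and reproduces the published £1,062 mean.

## Sequential scenario

The scenario arm applies the tool after clinical judgment.  The published
description gives only the pre-test (0.5) and post-test (0.69)
probabilities that a clinical high-risk call is a true positive; the module
implements the standard odds-scale machinery (`prob_to_odds`, LR+ =
sensitivity/(1 − specificity), post-test odds = pre-test odds × LR) and
accepts either a post-test probability directly (default 0.69, whose
implied LR+ is 0.69/0.31 ≈ 2.226) or a sensitivity/specificity pair.  The
mapping from post-test probability to the HRM entry rate is **not**
published; this package uses `p_hrm = 1 − posttest` (0.31 at base case),
the unique simple mapping that reproduces the published £250 per-person
saving.  Branch risks are those of the tool arm (0.017 high, derived 0.005
low), and every patient pays both assessment costs (£310).  The semantic
reading of the 0.5 pre-test value is unusual (it coincides with the HRM
assignment rate, not a predictive value); treat scenario outputs as
conditional on this reconstruction.

## Sensitivity analysis

Six parameters are varied, matching the published list: `cost_oxmis`,
`cost_hrm`, `cost_suicide`, `utility_decrement_hrm`, `p_high_oxmis`,
`p_suicide_high`.  The source's dispersion table is not recoverable, so:

- **PSA** draws each varied parameter independently from a moment-matched
  distribution — beta for probabilities and the disutility, gamma for
  costs (standard health-economics practice) — with default sd = 20% of the
  mean, overridable per parameter.  Joint draws violating a model
  invariant (most often an infeasible mixture: sampled `p_high ×
  p_suicide_high > p_suicide_overall`) are rejected and resampled, with
  the count reported and a hard cap of 10⁶ attempts to surface
  miscalibrated specs.  At base calibration about 0.6% of draws are
  rejected, so the truncation bias is negligible.  The CEAC reports the
  fraction of draws with positive NMB on a 0–50,000 GBP/QALY grid.
- **One-way analysis** uses symmetric ±25% ranges around base case,
  overridable.  Varying `p_high_oxmis` re-derives the low-branch risk from
  the mixture constraint, keeping each one-way model internally
  consistent.

Because the dispersions and ranges are assumptions, the published PSA
proportions (99.96% cost-saving; 61% dominant / 35% cheaper-but-less
effective / 2.4% inferior) and one-way ICER range (−£101,036 to −£19,769)
are calibration targets, not reproducible values.  Under this package's
defaults the PSA is effectively 100% dominant, and the published split
cannot be recovered without the unpublished inputs.  Likewise the tornado
ordering differs: here ΔQALY ≈ 0.25 × `utility_decrement_hrm` (the arms'
mortality effects nearly cancel, so the QALY gain is almost entirely the
avoided disutility), which makes the ICER inversely proportional to the
decrement and hence most sensitive to it; the published analysis found the
tool's flag probability most influential, an ordering that presumably
reflects its own ranges and QALY conventions.  The qualitative finding
that the suicide event cost matters least does hold here (its one-way span
is ~£500 of ICER against ~£25,000 for the decrement).

A related, documented irreproducibility: the published base-case mean ICER
(−£58,109) implies ΔQALY ≈ 0.0103, whereas this reconstruction yields
0.0125 (ICER ≈ −£47,922).  The exact branch-risk and utility conventions
behind the published denominator cannot be recovered; both analyses agree
the tool strategy is dominant, which is the decision-relevant conclusion.

## Microsimulation oracle

`simulate_cohort` draws per-patient Bernoulli flags and suicide outcomes at
the tree's branch probabilities and accrues payoffs by the same rules as
the cohort model (decedents: branch utility × 0.5), so its means are
unbiased for the analytic expectations — the package's primary
cross-validation.  The default oracle size of 200,000 patients keeps the
3-standard-error band on mean cost to about ±£5 while running in well
under a second.  The generator emulates only what the cohort model
contains: independent, homogeneous patients with identical branch risks
and utilities, no within-year event timing beyond the midpoint rule, and
no self-harm pathway.  Agreement between simulator and tree therefore
validates the arithmetic, not the model's fidelity to real patient
trajectories.

## Numerical choices

- Dual-route verification: the closed-form expectations are checked
  against explicit four-path enumeration at 10⁻¹² relative tolerance on
  randomized valid parameter sets.
- All validation is eager (dataclass `__post_init__`), so invalid states
  are unrepresentable; errors name the offending field and invariant.
- Display rounding (costs to the nearest pound, QALYs to 2 dp) happens
  only at the CLI/report layer; every CSV/JSON artifact carries full
  precision.
- ICERs are never reported bare: a negative ICER is ambiguous between the
  dominant (SE) and dominated (NW) quadrants, so every result carries its
  quadrant label.  Quadrant boundaries use strict inequalities for
  dominance; zero-Δ draws fall into the adjacent trade-off quadrant so the
  four proportions always partition the draws exactly.
- Seeded `numpy.random.Generator` throughout; identical seeds give
  bit-identical cohorts, PSA draw tables and summaries.

## Limitations

One-year horizon; no self-harm costs or utilities; treatment effect and
HRM composition are stylized; the sequential scenario rests on the
reconstruction above; PSA dispersions are assumptions.  Results beyond the
deterministic base case should be read as uncertainty characterization of
*this* reconstruction, not of the original analysis.
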