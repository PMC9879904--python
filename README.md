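# oxmis-cea

A decision-analytic cost-effectiveness model for structured suicide risk
assessment in people with severe mental illness (SMI: schizophrenia-spectrum
disorders or bipolar disorder).

Suicide risk assessment in secondary mental health care is usually done by
unstructured clinical judgment, which discriminates poorly: roughly half of
patients end up on an intensive "high-risk management" (HRM) plan.  A
validated probabilistic prediction tool (OxMIS, specificity 0.75) flags only
25% of patients, concentrating HRM — and its cost and treatment disutility —
on a genuinely enriched stratum.  This package asks the health-economics
question: over a one-year horizon, what does replacing (or supplementing)
clinical judgment with the tool do to NHS costs and quality-adjusted life
years (QALYs)?

## The model

Each strategy is a two-level decision tree.  A patient pays the assessment
cost, is assigned HRM with probability *p*<sub>HRM</sub> (cost £1,615,
utility decrement 0.05) or low-risk management (no extra cost), and then
either survives the year or dies by suicide at the branch-specific annual
risk.  HRM reduces suicide risk by a conservative relative 10%.  Expected
cost and QALYs per patient are

&nbsp;&nbsp;E[C] = c<sub>assess</sub> + p<sub>HRM</sub>·c<sub>HRM</sub> + (1−p<sub>HRM</sub>)·c<sub>LRM</sub> + p<sub>suicide</sub>·c<sub>suicide</sub>

&nbsp;&nbsp;E[Q] = p<sub>HRM</sub>·q(u−d, π<sub>H</sub>(1−r)) + (1−p<sub>HRM</sub>)·q(u, π<sub>L</sub>), &nbsp; q(u, π) = (1−π)·u + π·u/2

with utility u = 0.77, decrement d = 0.05, and decedents accruing half a
year of utility (suicide at midpoint).  The tool arm's high-risk branch
starts at π<sub>H</sub> = 0.017; its low-risk branch is closed by the
mixture constraint p<sub>HRM</sub>·π<sub>H</sub> + (1−p<sub>HRM</sub>)·π<sub>L</sub> = 0.008, the 12-month
suicide incidence in SMI.  Strategies are compared by incremental cost,
incremental QALYs, the ICER (ΔC/ΔQ), net monetary benefit, and CE-plane
quadrant.  A likelihood-ratio update (pre-test 0.5 → post-test 0.69) builds
a sequential clinical-then-tool scenario; tornado and Monte Carlo
probabilistic sensitivity analyses (beta/gamma moment-matched
distributions) quantify parameter uncertainty; a patient-level
microsimulation provides a brute-force cross-check of the analytic
expectations.  See `docs/methods.md` for assumptions and reconstruction
choices.

## Worked example

```
$ oxmis-cea base-case
oxmis: mean cost 463 GBP, mean QALYs 0.75, suicide risk 0.0076
clinical: mean cost 1,062 GBP, mean QALYs 0.74, suicide risk 0.0076
incremental (tool vs clinical):
  incremental cost: -600 GBP
  incremental QALYs: +0.01
  ICER: -47,922 GBP/QALY (intervention dominant)
  NMB at 20,000 GBP/QALY: +850 GBP
```

Assessing with the tool costs £463 per patient against £1,062 for clinical
judgment — a saving of about £600 driven almost entirely by halving the HRM
rate — while QALYs rise slightly (+0.01) because fewer low-risk patients
bear the treatment disutility.  Cheaper *and* more effective means the tool
strategy dominates; the negative ICER is a saving per QALY gained and is
always reported with its CE-plane quadrant.  The sequential scenario
(`oxmis-cea scenario`) keeps the clinical assessment and adds the tool,
saving £250 per patient.  `oxmis-cea psa --n 10000`, `oxmis-cea tornado`
and `oxmis-cea microsim` write draw-level, tornado and patient-level CSVs
plus a run manifest; the same functionality is available from Python via
`oxmis_cea.psa_run`, `one_way_sa`, `simulate_cohort`, etc.

Equivalently in Python:

```python
import oxmis_cea as ox
params = ox.base_case()
tool = ox.evaluate_strategy(ox.make_oxmis_strategy(params))
usual = ox.evaluate_strategy(ox.make_clinical_strategy(params))
print(ox.incremental(tool, usual, wtp=params.wtp_threshold))
```

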