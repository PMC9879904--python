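"""Decision-tree engine: strategy construction and cohort expectations.

Each assessment strategy is a two-level tree.  At the root every patient
pays the assessment cost; a chance node then assigns high-risk management
(HRM) with probability ``p_hrm`` or low-risk management (LRM) otherwise; a
second chance node in each branch decides survival over the one-year
horizon.  Suicide is assumed to occur at the midpoint of the year, so
decedents accrue half a year of their branch utility.

The tree exists in two equivalent forms: :func:`evaluate_strategy` computes
the closed-form cohort expectation, and :func:`enumerate_paths` spells out
the four root-to-leaf paths with their probabilities and payoffs.  The two
are compared against each other in the test suite, and the path
representation also drives the patient-level microsimulation.
"""

from __future__ import annotations

import dataclasses

from .parameters import ParameterError, ParameterSet, derive_p_suicide_low

__all__ = [
    "StrategySpec",
    "StrategyOutcome",
    "PathOutcome",
    "make_oxmis_strategy",
    "make_clinical_strategy",
    "apply_treatment_effect",
    "branch_qaly",
    "enumerate_paths",
    "evaluate_strategy",
]


@dataclasses.dataclass(frozen=True)
class StrategySpec:
    """One arm of the comparison: costs, branch probabilities and utilities.

    ``p_suicide_hrm_pre`` is the suicide risk in the HRM branch *before* the
    treatment effect; the post-treatment risk is
    ``p_suicide_hrm_pre * (1 - hrm_risk_reduction)``.  The LRM branch
    receives no treatment effect.
    """

    name: str
    assessment_cost: float
    p_hrm: float
    p_suicide_hrm_pre: float
    p_suicide_lrm: float
    hrm_risk_reduction: float
    cost_hrm: float
    cost_lrm: float
    cost_suicide: float
    utility_base: float
    utility_hrm_decrement: float

    def __post_init__(self) -> None:
        for name in ("p_hrm", "p_suicide_hrm_pre", "p_suicide_lrm",
                     "hrm_risk_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]; got {v!r}")
        for name in ("assessment_cost", "cost_hrm", "cost_lrm", "cost_suicide"):
            v = getattr(self, name)
            if v < 0.0:
                raise ParameterError(f"{name} must be non-negative; got {v!r}")
        if not 0.0 <= self.utility_base <= 1.0:
            raise ParameterError(
                f"utility_base must lie in [0, 1]; got {self.utility_base!r}")
        if self.utility_base - self.utility_hrm_decrement < 0.0:
            raise ParameterError(
                "HRM-branch utility would be negative: "
                f"{self.utility_base} - {self.utility_hrm_decrement}")

    @property
    def p_suicide_hrm(self) -> float:
        """Post-treatment suicide risk in the HRM branch."""
        return apply_treatment_effect(self.p_suicide_hrm_pre,
                                      self.hrm_risk_reduction)

    @property
    def utility_hrm(self) -> float:
        return self.utility_base - self.utility_hrm_decrement


@dataclasses.dataclass(frozen=True)
class StrategyOutcome:
    """Cohort expectation for one strategy over the one-year horizon."""

    name: str
    expected_cost: float
    expected_qaly: float
    p_suicide: float

    def to_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class PathOutcome:
    """One root-to-leaf path: probability and per-patient payoffs."""

    label: str
    flagged_high: bool
    died_by_suicide: bool
    probability: float
    cost: float
    qaly: float


def apply_treatment_effect(p_pre: float, reduction: float) -> float:
    """Relative risk reduction: returns ``p_pre * (1 - reduction)``."""
    if not 0.0 <= p_pre <= 1.0:
        raise ParameterError(f"p_pre must lie in [0, 1]; got {p_pre!r}")
    if not 0.0 <= reduction <= 1.0:
        raise ParameterError(f"reduction must lie in [0, 1]; got {reduction!r}")
    return p_pre * (1.0 - reduction)


def branch_qaly(utility: float, p_die: float) -> float:
    """Expected QALYs in one management branch over the one-year horizon.

    Survivors accrue the branch utility for the full year; decedents accrue
    half of it, suicide being assumed completed at the midpoint:
    ``(1 - p_die) * utility + p_die * utility / 2``.
    """
    if not 0.0 <= utility <= 1.0:
        raise ParameterError(f"utility must lie in [0, 1]; got {utility!r}")
    if not 0.0 <= p_die <= 1.0:
        raise ParameterError(f"p_die must lie in [0, 1]; got {p_die!r}")
    return (1.0 - p_die) * utility + p_die * (utility / 2.0)


def make_oxmis_strategy(params: ParameterSet) -> StrategySpec:
    """Structured-tool arm: flag rate 1 - specificity, enriched HRM branch.

    The HRM branch starts at the tool's high-risk-stratum risk; the LRM
    branch risk is derived so the cohort reproduces the overall incidence.
    """
    return StrategySpec(
        name="oxmis",
        assessment_cost=params.cost_oxmis,
        p_hrm=params.p_high_oxmis,
        p_suicide_hrm_pre=params.p_suicide_high,
        p_suicide_lrm=derive_p_suicide_low(
            params.p_high_oxmis, params.p_suicide_high, params.p_suicide_overall
        ),
        hrm_risk_reduction=params.hrm_risk_reduction,
        cost_hrm=params.cost_hrm,
        cost_lrm=params.cost_lrm,
        cost_suicide=params.cost_suicide,
        utility_base=params.utility_smi,
        utility_hrm_decrement=params.utility_decrement_hrm,
    )


def make_clinical_strategy(params: ParameterSet) -> StrategySpec:
    """Unstructured-judgment arm: uninformative flagging.

    Clinical flagging is treated as carrying no risk information, so both
    branches start at the population incidence; HRM then applies the
    treatment effect.
    """
    return StrategySpec(
        name="clinical",
        assessment_cost=params.cost_clinical_assessment,
        p_hrm=params.p_high_clinical,
        p_suicide_hrm_pre=params.p_suicide_overall,
        p_suicide_lrm=params.p_suicide_overall,
        hrm_risk_reduction=params.hrm_risk_reduction,
        cost_hrm=params.cost_hrm,
        cost_lrm=params.cost_lrm,
        cost_suicide=params.cost_suicide,
        utility_base=params.utility_smi,
        utility_hrm_decrement=params.utility_decrement_hrm,
    )


def enumerate_paths(spec: StrategySpec) -> list[PathOutcome]:
    """The four root-to-leaf paths with probabilities and payoffs.

    Decedents accrue half a year of their branch utility (including the HRM
    decrement where applicable); the suicide cost is charged once at the
    event.
    """
    paths = []
    for flagged, p_branch, mgmt_cost, utility, p_die in (
        (True, spec.p_hrm, spec.cost_hrm, spec.utility_hrm, spec.p_suicide_hrm),
        (False, 1.0 - spec.p_hrm, spec.cost_lrm, spec.utility_base,
         spec.p_suicide_lrm),
    ):
        for died, p_outcome in ((True, p_die), (False, 1.0 - p_die)):
            paths.append(
                PathOutcome(
                    label=f"{'hrm' if flagged else 'lrm'}/"
                          f"{'suicide' if died else 'survive'}",
                    flagged_high=flagged,
                    died_by_suicide=died,
                    probability=p_branch * p_outcome,
                    cost=spec.assessment_cost + mgmt_cost
                         + (spec.cost_suicide if died else 0.0),
                    qaly=utility * (0.5 if died else 1.0),
                )
            )
    return paths


def evaluate_strategy(spec: StrategySpec) -> StrategyOutcome:
    """Closed-form cohort expectation of cost, QALYs and suicide risk."""
    p_die_hrm = spec.p_suicide_hrm
    p_suicide = spec.p_hrm * p_die_hrm + (1.0 - spec.p_hrm) * spec.p_suicide_lrm
    expected_cost = (
        spec.assessment_cost
        + spec.p_hrm * spec.cost_hrm
        + (1.0 - spec.p_hrm) * spec.cost_lrm
        + p_suicide * spec.cost_suicide
    )
    expected_qaly = (
        spec.p_hrm * branch_qaly(spec.utility_hrm, p_die_hrm)
        + (1.0 - spec.p_hrm) * branch_qaly(spec.utility_base, spec.p_suicide_lrm)
    )
    return StrategyOutcome(
        name=spec.name,
        expected_cost=expected_cost,
        expected_qaly=expected_qaly,
        p_suicide=p_suicide,
    )
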