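"""Likelihood-ratio updating and the sequential assessment scenario.

The scenario analysis models using the structured tool *after* clinical
judgment rather than instead of it.  The probability that a clinician's
high-risk call is correct is treated as a pre-test probability, updated
through the tool's positive likelihood ratio (LR+ = sensitivity /
(1 - specificity)) on the odds scale:

    post-test odds = pre-test odds x LR+

The resulting post-test probability maps to the sequential arm's HRM entry
probability as ``p_hrm = 1 - posttest``.  This mapping is a reconstruction
(the published description does not spell it out); it is the unique simple
choice that reproduces the reported per-person saving of the sequential
scenario, and is flagged as such in the methods note.
"""

from __future__ import annotations

import dataclasses

from .parameters import ParameterError, ParameterSet, derive_p_suicide_low
from .tree import StrategySpec

__all__ = [
    "TestCharacteristics",
    "DEFAULT_POSTTEST",
    "prob_to_odds",
    "odds_to_prob",
    "positive_likelihood_ratio",
    "posttest_probability",
    "make_sequential_strategy",
]

#: Published post-test probability that a clinical high-risk call is a true
#: positive after the structured tool is applied (pre-test 0.5).
DEFAULT_POSTTEST = 0.69


@dataclasses.dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity and specificity of a binary risk classifier."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]; got {v!r}")


def prob_to_odds(p: float) -> float:
    """Convert a probability to odds, ``p / (1 - p)``."""
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"p must lie in [0, 1) for finite odds; got {p!r}")
    return p / (1.0 - p)


def odds_to_prob(odds: float) -> float:
    """Convert odds back to a probability, ``odds / (1 + odds)``."""
    if odds < 0.0:
        raise ParameterError(f"odds must be non-negative; got {odds!r}")
    return odds / (1.0 + odds)


def positive_likelihood_ratio(tc: TestCharacteristics) -> float:
    """LR+ = sensitivity / (1 - specificity); undefined at specificity 1."""
    if tc.specificity >= 1.0:
        raise ParameterError(
            "positive likelihood ratio is undefined at specificity 1 "
            "(no false positives)")
    return tc.sensitivity / (1.0 - tc.specificity)


def posttest_probability(pretest: float, lr: float) -> float:
    """Update a pre-test probability through a likelihood ratio.

    Works on the odds scale; monotone increasing in ``lr``, with ``lr = 1``
    leaving the probability unchanged.
    """
    if lr < 0.0:
        raise ParameterError(f"likelihood ratio must be non-negative; got {lr!r}")
    return odds_to_prob(prob_to_odds(pretest) * lr)


def make_sequential_strategy(
    params: ParameterSet,
    posttest: float = DEFAULT_POSTTEST,
) -> StrategySpec:
    """Clinical-judgment-then-structured-tool arm.

    Every patient pays both assessment costs.  The HRM entry probability is
    ``1 - posttest`` (the reconstruction documented in the module docstring);
    branch suicide risks are those of the structured-tool arm, with the
    low-risk branch derived from the overall-incidence constraint at the
    tool's own flag rate.
    """
    if not 0.0 <= posttest <= 1.0:
        raise ParameterError(f"posttest must lie in [0, 1]; got {posttest!r}")
    return StrategySpec(
        name="sequential",
        assessment_cost=params.cost_clinical_assessment + params.cost_oxmis,
        p_hrm=1.0 - posttest,
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
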