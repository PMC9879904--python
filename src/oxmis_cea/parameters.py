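"""Model inputs for the suicide-risk-assessment cost-effectiveness model.

This module is the single source of truth for the base case: annual
probabilities of suicide, assessment and management costs (GBP), and the
utility weights used to compute QALYs over the one-year horizon.  Every
other module receives a validated :class:`ParameterSet` rather than loose
numbers.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "base_case",
    "derive_p_suicide_low",
    "p_flag_from_specificity",
]


class ParameterError(ValueError):
    """Raised when a model input is missing or violates a model invariant."""


_PROBABILITY_FIELDS = (
    "p_high_oxmis",
    "p_high_clinical",
    "p_suicide_high",
    "p_suicide_overall",
    "hrm_risk_reduction",
)
_COST_FIELDS = (
    "cost_oxmis",
    "cost_clinical_assessment",
    "cost_hrm",
    "cost_lrm",
    "cost_suicide",
)
_UTILITY_FIELDS = ("utility_smi", "utility_decrement_hrm", "utility_death")

#: Fields a config file must supply unless it requests the packaged base case.
REQUIRED_FIELDS = _PROBABILITY_FIELDS + _COST_FIELDS + _UTILITY_FIELDS


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """All base-case model inputs with validation.

    Attributes
    ----------
    p_high_oxmis
        Proportion of patients assigned high-risk management (HRM) when the
        structured tool is used; equals one minus the tool's specificity.
    p_high_clinical
        Proportion assigned HRM under unstructured clinical judgment.
    p_suicide_high
        Annual suicide probability in the tool's high-risk stratum, before
        any treatment effect.
    p_suicide_overall
        Twelve-month suicide incidence in the severe-mental-illness
        population; used to close the low-risk branch by mixture algebra.
    hrm_risk_reduction
        Relative reduction in suicide risk conferred by HRM.
    cost_oxmis, cost_clinical_assessment
        Cost (GBP) of the structured-tool and unstructured assessments.
    cost_hrm, cost_lrm
        Cost (GBP) of the high- and low-risk management packages.
    cost_suicide
        Direct emergency/health cost (GBP) charged once at a suicide event.
    utility_smi
        Annual utility of living with severe mental illness.
    utility_decrement_hrm
        Disutility of high-risk management (treatment side effects).
    utility_death
        Utility of the death-by-suicide state.
    time_horizon_years
        Fixed at 1; the model is defined only for a single year.
    wtp_threshold
        Willingness-to-pay (GBP/QALY) used for net monetary benefit and the
        acceptability curve.
    """

    p_high_oxmis: float = 0.25
    p_high_clinical: float = 0.5
    p_suicide_high: float = 0.017
    p_suicide_overall: float = 0.008
    hrm_risk_reduction: float = 0.10
    cost_oxmis: float = 57.0
    cost_clinical_assessment: float = 253.0
    cost_hrm: float = 1615.0
    cost_lrm: float = 0.0
    cost_suicide: float = 260.0
    utility_smi: float = 0.77
    utility_decrement_hrm: float = 0.05
    utility_death: float = 0.0
    time_horizon_years: float = 1.0
    wtp_threshold: float = 20000.0

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]; got {v!r}")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ParameterError(f"{name} must be non-negative; got {v!r}")
        for name in _UTILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]; got {v!r}")
        if self.utility_smi - self.utility_decrement_hrm < 0.0:
            raise ParameterError(
                "utility_smi - utility_decrement_hrm must be non-negative; got "
                f"{self.utility_smi} - {self.utility_decrement_hrm}"
            )
        if self.p_suicide_high < self.p_suicide_overall:
            raise ParameterError(
                "p_suicide_high must be at least p_suicide_overall "
                "(the high-risk stratum is enriched); got "
                f"{self.p_suicide_high} < {self.p_suicide_overall}"
            )
        if self.time_horizon_years != 1.0:
            raise ParameterError(
                "time_horizon_years must equal 1 (the model is defined only "
                f"for one year); got {self.time_horizon_years!r}"
            )
        if self.wtp_threshold < 0.0:
            raise ParameterError(
                f"wtp_threshold must be non-negative; got {self.wtp_threshold!r}"
            )

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with ``changes`` applied and invariants re-checked."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @property
    def p_suicide_low(self) -> float:
        """Low-risk-branch suicide risk implied by the overall incidence."""
        return derive_p_suicide_low(
            self.p_high_oxmis, self.p_suicide_high, self.p_suicide_overall
        )


def derive_p_suicide_low(
    p_high: float, p_suicide_high: float, p_suicide_overall: float
) -> float:
    """Solve the mixture constraint for the low-risk-branch suicide risk.

    The model states the high-risk-stratum risk and the population-wide
    incidence; the low-risk branch is closed by solving

        p_high * p_suicide_high + (1 - p_high) * p_low = p_suicide_overall

    for ``p_low``, so that the cohort reproduces the overall incidence.

    Raises
    ------
    ParameterError
        If the implied ``p_low`` is negative (the high-risk stratum alone
        already exceeds the overall incidence) or exceeds ``p_suicide_high``.
    """
    if not 0.0 <= p_high < 1.0:
        raise ParameterError(f"p_high must lie in [0, 1); got {p_high!r}")
    p_low = (p_suicide_overall - p_high * p_suicide_high) / (1.0 - p_high)
    if p_low < 0.0:
        raise ParameterError(
            "mixture constraint cannot be satisfied: "
            f"p_high*p_suicide_high = {p_high * p_suicide_high:.6g} exceeds "
            f"p_suicide_overall = {p_suicide_overall:.6g} (implied p_low < 0)"
        )
    if p_low > p_suicide_high:
        raise ParameterError(
            "mixture constraint yields a low-risk branch riskier than the "
            f"high-risk branch (p_low = {p_low:.6g} > {p_suicide_high:.6g})"
        )
    return p_low


def p_flag_from_specificity(specificity: float) -> float:
    """Probability of a high-risk flag implied by a test's specificity.

    With a rare outcome, nearly all assessed patients are true negatives, so
    the proportion flagged high-risk is approximately the false-positive
    rate, ``1 - specificity``.
    """
    if not 0.0 <= specificity <= 1.0:
        raise ParameterError(f"specificity must lie in [0, 1]; got {specificity!r}")
    return 1.0 - specificity


def base_case() -> ParameterSet:
    """The packaged base-case parameter set."""
    return load_parameters(_packaged_base_case())


def _packaged_base_case() -> dict[str, Any]:
    text = resources.files("oxmis_cea").joinpath("data/base_case.yaml").read_text()
    return yaml.safe_load(text)


def load_parameters(config: Mapping[str, Any] | str | Path) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config mapping or file.

    ``config`` may be a mapping or a path to a YAML file with a flat
    namespace of the :class:`ParameterSet` field names.  A config containing
    ``base_case: true`` starts from the packaged base case and may override
    individual fields; otherwise every required field must be present.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, Mapping):
            raise ParameterError(f"config file {config} is not a key-value mapping")
        config = loaded

    data = dict(config)
    use_base = bool(data.pop("base_case", False))
    if use_base:
        merged = _packaged_base_case()
        merged.pop("base_case", None)
        merged.update(data)
        data = merged

    unknown = set(data) - {f.name for f in dataclasses.fields(ParameterSet)}
    if unknown:
        raise ParameterError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    missing = [name for name in REQUIRED_FIELDS if name not in data]
    if missing:
        raise ParameterError(f"missing required parameter(s): {', '.join(missing)}")
    try:
        numeric = {k: float(v) for k, v in data.items()}
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"non-numeric parameter value: {exc}") from exc
    return ParameterSet(**numeric)
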