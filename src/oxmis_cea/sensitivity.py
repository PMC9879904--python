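"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis moves each parameter to the ends of its range with all
others held at base case and records the ICER at each end.  Probabilistic
sensitivity analysis (PSA) draws all varied parameters jointly and
independently from moment-matched distributions — beta for probabilities
and the utility decrement, gamma for costs, the standard health-economics
choice — rebuilds both strategy arms per draw, and summarises the cloud of
incremental pairs on the cost-effectiveness plane, including the
cost-effectiveness acceptability curve (CEAC).

The published analysis varied six parameters (tool cost, high-risk
management cost, suicide cost, the management disutility, the tool's flag
probability, and the high-risk-stratum suicide risk); their dispersions are
not recoverable from the source, so the default standard deviation is 20%
of each mean, overridable per parameter.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import make_sequential_strategy
from .metrics import classify_quadrant, incremental
from .parameters import ParameterError, ParameterSet
from .tree import (
    StrategySpec,
    evaluate_strategy,
    make_clinical_strategy,
    make_oxmis_strategy,
)

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "TornadoRow",
    "VARIED_PARAMETERS",
    "moment_match",
    "sample_parameter",
    "default_psa_specs",
    "psa_run",
    "default_one_way_ranges",
    "one_way_sa",
]

#: Parameters varied by default, as in the published sensitivity analysis.
VARIED_PARAMETERS = (
    "cost_oxmis",
    "cost_hrm",
    "cost_suicide",
    "utility_decrement_hrm",
    "p_high_oxmis",
    "p_suicide_high",
)

_MAX_ATTEMPTS = 1_000_000  # hard cap on rejection-resampling

_SCENARIOS = ("oxmis", "sequential")


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter, moment-matched to mean/sd."""

    parameter: str
    family: str  # "beta", "gamma" or "fixed"
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterError(
                f"unknown distribution family {self.family!r} for "
                f"{self.parameter}")
        if self.family != "fixed" and self.sd <= 0.0:
            raise ParameterError(
                f"{self.parameter}: sd must be positive for a "
                f"{self.family} distribution")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ParameterError(
                f"{self.parameter}: beta requires mean in (0, 1); got "
                f"{self.mean!r}")
        if self.family == "gamma" and self.mean <= 0.0:
            raise ParameterError(
                f"{self.parameter}: gamma requires a positive mean; got "
                f"{self.mean!r}")


def moment_match(family: str, mean: float, sd: float = 0.0) -> dict[str, float]:
    """Distribution parameters matching a given mean and standard deviation.

    beta:  alpha = m * (m(1-m)/s^2 - 1), beta = (1-m) * (m(1-m)/s^2 - 1),
           feasible only when s^2 < m(1-m).
    gamma: shape = (m/s)^2, scale = s^2/m.
    fixed: degenerate point mass at the mean.
    """
    if family == "fixed":
        return {"value": mean}
    if family == "beta":
        var = sd * sd
        if var >= mean * (1.0 - mean):
            raise ParameterError(
                f"infeasible beta variance: sd^2 = {var:.6g} >= "
                f"m(1-m) = {mean * (1.0 - mean):.6g}")
        common = mean * (1.0 - mean) / var - 1.0
        return {"alpha": mean * common, "beta": (1.0 - mean) * common}
    if family == "gamma":
        return {"shape": (mean / sd) ** 2, "scale": sd * sd / mean}
    raise ParameterError(f"unknown distribution family {family!r}")


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value for a parameter from its moment-matched distribution."""
    pars = moment_match(spec.family, spec.mean, spec.sd)
    if spec.family == "fixed":
        return pars["value"]
    if spec.family == "beta":
        return float(rng.beta(pars["alpha"], pars["beta"]))
    return float(rng.gamma(pars["shape"], pars["scale"]))


def default_psa_specs(
    params: ParameterSet,
    cv: float = 0.20,
    overrides: Mapping[str, DistributionSpec] | None = None,
) -> tuple[DistributionSpec, ...]:
    """Default distributions for the six varied parameters.

    Beta for probabilities and the utility decrement, gamma for costs, each
    with standard deviation ``cv`` times its base-case mean.  ``overrides``
    replaces the spec for individual parameters.
    """
    overrides = dict(overrides or {})
    specs = []
    for name in VARIED_PARAMETERS:
        if name in overrides:
            specs.append(overrides.pop(name))
            continue
        mean = getattr(params, name)
        family = "gamma" if name.startswith("cost_") else "beta"
        if mean == 0.0:
            specs.append(DistributionSpec(name, "fixed", mean))
        else:
            specs.append(DistributionSpec(name, family, mean, cv * mean))
    if overrides:
        raise ParameterError(
            "overrides for parameters not varied by default: "
            + ", ".join(sorted(overrides)))
    return tuple(specs)


@dataclasses.dataclass(frozen=True)
class PSAResult:
    """Monte Carlo cloud of incremental pairs with CE-plane summaries.

    ``draws`` has one row per draw: the sampled parameter values, the
    incremental cost and QALY pair, and its CE-plane quadrant.  Quadrant
    proportions partition the draws exactly (``prop_dominant`` = SE,
    ``prop_sw`` = SW, ``prop_inferior`` = NW, ``prop_ne`` = NE);
    ``prop_cost_saving`` is the fraction with negative incremental cost.
    ``ceac`` maps each willingness-to-pay threshold to the fraction of draws
    with positive net monetary benefit.
    """

    n_draws: int
    seed: int
    scenario: str
    draws: pd.DataFrame
    prop_cost_saving: float
    prop_dominant: float
    prop_sw: float
    prop_inferior: float
    prop_ne: float
    ceac: dict[float, float]
    n_rejected: int

    def summary_dict(self) -> dict[str, float | int | str]:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "scenario": self.scenario,
            "prop_cost_saving": self.prop_cost_saving,
            "prop_dominant": self.prop_dominant,
            "prop_sw": self.prop_sw,
            "prop_inferior": self.prop_inferior,
            "prop_ne": self.prop_ne,
            "mean_delta_cost": float(self.draws["delta_cost"].mean()),
            "mean_delta_qaly": float(self.draws["delta_qaly"].mean()),
            "n_rejected": self.n_rejected,
        }


def _strategy_pair(
    params: ParameterSet, scenario: str
) -> tuple[StrategySpec, StrategySpec]:
    """Intervention/comparator pair for a scenario selector."""
    if scenario == "oxmis":
        return make_oxmis_strategy(params), make_clinical_strategy(params)
    if scenario == "sequential":
        return make_sequential_strategy(params), make_clinical_strategy(params)
    raise ParameterError(
        f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")


def psa_run(
    params: ParameterSet,
    specs: Sequence[DistributionSpec],
    n: int,
    seed: int,
    scenario: str = "oxmis",
    ceac_thresholds: Iterable[float] | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis by Monte Carlo simulation.

    For each of ``n`` draws, all varied parameters are sampled jointly and
    independently, both strategy arms are rebuilt, and the incremental pair
    recorded.  A joint draw that violates a model invariant (for example, a
    sampled flag rate and stratum risk whose mixture would imply a negative
    low-risk branch risk) is rejected and resampled; the rejection count is
    reported.  Identical seeds give identical results.
    """
    if n < 1:
        raise ParameterError(f"n must be at least 1; got {n!r}")
    if scenario not in _SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
    names = [s.parameter for s in specs]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate parameter in distribution specs")
    rng = np.random.default_rng(seed)

    rows: list[dict[str, float]] = []
    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    rejected = 0
    attempts = 0
    i = 0
    while i < n:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise ParameterError(
                f"exceeded {_MAX_ATTEMPTS} sampling attempts after {rejected} "
                "rejections; the distribution specs are likely miscalibrated")
        draw = {s.parameter: sample_parameter(s, rng) for s in specs}
        try:
            drawn = params.replace(**draw)
            intervention, comparator = _strategy_pair(drawn, scenario)
        except ParameterError:
            rejected += 1
            continue
        inc = incremental(
            evaluate_strategy(intervention), evaluate_strategy(comparator),
            wtp=params.wtp_threshold,
        )
        delta_cost[i] = inc.delta_cost
        delta_qaly[i] = inc.delta_qaly
        rows.append({"draw": i, **draw,
                     "delta_cost": inc.delta_cost,
                     "delta_qaly": inc.delta_qaly,
                     "quadrant": inc.quadrant})
        i += 1

    draws = pd.DataFrame(rows)
    quad = draws["quadrant"]
    prop = {q: float((quad == q).mean()) for q in ("SE", "SW", "NW", "NE")}

    if ceac_thresholds is None:
        ceac_thresholds = np.arange(0.0, 50_001.0, 1_000.0)
    thresholds = np.asarray(list(ceac_thresholds), dtype=float)
    # NMB > 0 per draw and threshold, vectorized over the threshold grid
    nmb = thresholds[:, None] * delta_qaly[None, :] - delta_cost[None, :]
    ceac = {float(t): float(frac) for t, frac in
            zip(thresholds, (nmb > 0.0).mean(axis=1))}

    return PSAResult(
        n_draws=n,
        seed=seed,
        scenario=scenario,
        draws=draws,
        prop_cost_saving=float((delta_cost < 0.0).mean()),
        prop_dominant=prop["SE"],
        prop_sw=prop["SW"],
        prop_inferior=prop["NW"],
        prop_ne=prop["NE"],
        ceac=ceac,
        n_rejected=rejected,
    )


@dataclasses.dataclass(frozen=True)
class TornadoRow:
    """One parameter's one-way sensitivity: ICER at each end of its range."""

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    quadrant_at_low: str
    quadrant_at_high: str
    span: float

    def to_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)


def default_one_way_ranges(
    params: ParameterSet, rel: float = 0.25
) -> dict[str, tuple[float, float]]:
    """Symmetric ±``rel`` ranges around base case for the varied parameters."""
    return {
        name: (getattr(params, name) * (1.0 - rel),
               getattr(params, name) * (1.0 + rel))
        for name in VARIED_PARAMETERS
    }


def one_way_sa(
    params: ParameterSet,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    scenario: str = "oxmis",
) -> list[TornadoRow]:
    """One-way deterministic sensitivity analysis (tornado).

    Each parameter is set to the low and then the high end of its range with
    everything else at base case; both arms are re-evaluated and the ICER
    recorded with its CE-plane quadrant.  Rows are sorted by descending ICER
    span, so the most influential parameter comes first.
    """
    if ranges is None:
        ranges = default_one_way_ranges(params)
    rows = []
    for name, (low, high) in ranges.items():
        icers: list[float] = []
        quads: list[str] = []
        for value in (low, high):
            try:
                varied = params.replace(**{name: value})
                intervention, comparator = _strategy_pair(varied, scenario)
            except ParameterError as exc:
                raise ParameterError(
                    f"one-way range for {name} violates a model invariant: "
                    f"{exc}") from exc
            inc = incremental(
                evaluate_strategy(intervention), evaluate_strategy(comparator),
                wtp=params.wtp_threshold,
            )
            icers.append(inc.icer)
            quads.append(inc.quadrant)
        rows.append(
            TornadoRow(
                parameter=name,
                low_value=low,
                high_value=high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
                quadrant_at_low=quads[0],
                quadrant_at_high=quads[1],
                span=abs(icers[1] - icers[0]),
            )
        )
    rows.sort(key=lambda r: r.span, reverse=True)
    return rows
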