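"""Treatment arms and dose-escalation / de-escalation scenario variants.

The two comparator arms share a state space: the ``no_ada`` arm starts 100%
unwell on chronic steroid therapy (biologic unavailable, colectomy avoided
as long as possible); the ``ada`` arm starts 100% in the adalimumab
induction state. The arms differ in their pouchitis sub-model: patients in
the ``ada`` arm reach pouchitis with prior anti-TNF exposure, so their
retention series carries a 15% response discount and their complication
state recovers less often.

Dose escalation (40 mg weekly instead of every other week) is modelled as a
scenario on the ``ada`` arm: maintenance-of-response follows the
dose-escalated retention series, and the response state is priced at
escalated dosing. De-escalation returns the successfully de-escalated
fraction of responders to standard-dose pricing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

from .economics import EconResult, ICERResult, accumulate, compute_icer
from .markov_engine import run_cohort
from .model_spec import (
    ModelSpec,
    RetentionSeries,
    SeriesRef,
    TransitionRow,
    load_model_spec,
)

__all__ = [
    "EscalationPolicy",
    "DeescalationPolicy",
    "AnalysisRequest",
    "AnalysisResult",
    "build_arm",
    "apply_escalation",
    "apply_deescalation",
    "run_analysis",
    "load_fixture",
    "ADA_UNIT_COST",
    "RESPONSE_STATE",
]

#: CA$ per 40 mg adalimumab dose.
ADA_UNIT_COST = 740.36
#: 40 mg every other week over a 13-week cycle.
STANDARD_DOSES_PER_CYCLE = 6
#: Weeks per model cycle (3 months).
WEEKS_PER_CYCLE = 13.0

RESPONSE_STATE = "ada_response"
ESCALATED_SERIES_NAME = "dose_escalated"

#: Real-life maintenance of response after dose escalation (Crohn's-derived),
#: % still responding by 3-month cycle, plateau at cycle 20.
DOSE_ESCALATED_VALUES = (
    93.8, 80.5, 73.7, 69.1, 65.8, 63.2, 61.1, 59.4, 57.8, 56.5, 55.3,
    54.3, 53.3, 52.5, 51.7, 51.0, 50.3, 49.7, 49.1, 48.5, 48.0,
)

HORIZON_YEARS_TO_CYCLES = {5: 20, 10: 40, 15: 60}
ARMS = ("no_ada", "ada")
SCENARIOS = ("base", "escalation", "deescalation")
RESPONSE_UTILITIES = (0.79, 0.82)


@dataclass(frozen=True)
class EscalationPolicy:
    """Dose-escalation assumptions.

    Half of maintained patients require escalation, after a mean 59.3 (±70.5)
    weeks on therapy. ``escalated_cost_multiplier`` scales the drug component
    of the response-state cost (weekly dosing doubles the number of 40 mg
    doses per cycle).
    """

    fraction_escalated: float = 0.50
    mean_time_to_escalation_weeks: float = 59.3
    sd_time_to_escalation_weeks: float = 70.5
    escalated_retention: RetentionSeries = field(
        default_factory=lambda: RetentionSeries(
            ESCALATED_SERIES_NAME, DOSE_ESCALATED_VALUES
        )
    )
    escalated_cost_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_escalated <= 1.0:
            raise ValueError("fraction_escalated outside [0, 1]")

    def escalation_cycle(self) -> int:
        """Mean time to escalation rounded to the nearest 3-month cycle."""
        return round(self.mean_time_to_escalation_weeks / WEEKS_PER_CYCLE)

    def escalated_cost(self, standard_cost: float) -> float:
        extra = (self.escalated_cost_multiplier - 1.0) * (
            STANDARD_DOSES_PER_CYCLE * ADA_UNIT_COST
        )
        return standard_cost + extra


@dataclass(frozen=True)
class DeescalationPolicy:
    """De-escalation is attempted in 54% of escalated responders and succeeds
    in 63% of attempts; successes return to standard-dose pricing."""

    fraction_attempted: float = 0.54
    fraction_successful: float = 0.63

    def __post_init__(self) -> None:
        for v in (self.fraction_attempted, self.fraction_successful):
            if not 0.0 <= v <= 1.0:
                raise ValueError("de-escalation fractions must lie in [0, 1]")

    @property
    def effective_fraction(self) -> float:
        return self.fraction_attempted * self.fraction_successful


@dataclass(frozen=True)
class AnalysisRequest:
    """One cell of the analysis grid."""

    horizon_cycles: int = 40
    response_utility: float = 0.79
    scenario: Literal["base", "escalation", "deescalation"] = "base"

    def __post_init__(self) -> None:
        if self.horizon_cycles not in HORIZON_YEARS_TO_CYCLES.values():
            raise ValueError(
                f"horizon_cycles must be one of {sorted(HORIZON_YEARS_TO_CYCLES.values())}"
            )
        if self.response_utility not in RESPONSE_UTILITIES:
            raise ValueError(f"response_utility must be one of {RESPONSE_UTILITIES}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")


def load_fixture(name: str) -> ModelSpec:
    """Load one of the packaged arm configurations by name."""
    ref = resources.files("uccea") / "fixtures" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_model_spec(path)


def build_arm(arm: str, request: AnalysisRequest) -> ModelSpec:
    """Assemble one arm's ModelSpec for an analysis request.

    The response-utility variant (time trade-off 0.79 vs visual rating scale
    0.82) substitutes the utility of the primary adalimumab response state
    only; the pouchitis response state keeps its own printed utility.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    spec = load_fixture("uc_no_ada" if arm == "no_ada" else "uc_ada")
    spec = spec.with_horizon(request.horizon_cycles)
    resp = spec.states[RESPONSE_STATE]
    spec = spec.with_state(replace(resp, annual_utility=request.response_utility))
    if arm == "ada" and request.scenario in ("escalation", "deescalation"):
        policy = EscalationPolicy()
        spec = apply_escalation(spec, policy)
        if request.scenario == "deescalation":
            spec = apply_deescalation(spec, policy, DeescalationPolicy())
    return spec


def apply_escalation(spec: ModelSpec, policy: EscalationPolicy) -> ModelSpec:
    """Rewire the adalimumab response state for the dose-escalation scenario.

    Maintenance of response follows the dose-escalated retention series from
    treatment start (the series is itself measured on an escalation-managed
    population), and the response state is priced at escalated dosing. A
    policy with ``fraction_escalated == 0`` is the identity.
    """
    if policy.fraction_escalated == 0.0:
        return spec
    if RESPONSE_STATE not in spec.states:
        raise ValueError(f"spec {spec.name!r} has no {RESPONSE_STATE!r} state")
    series = dict(spec.retention_series)
    series[policy.escalated_retention.name] = policy.escalated_retention

    row = spec.transitions[RESPONSE_STATE]
    entries = tuple(
        replace(e, series=policy.escalated_retention.name)
        if isinstance(e, SeriesRef) and e.role == "stay"
        else e
        for e in row.entries
    )
    state = spec.states[RESPONSE_STATE]
    std_cost = state.cost_per_cycle
    esc_cost = policy.escalated_cost(std_cost)
    spec = replace(spec, retention_series=series, metadata={
        **spec.metadata,
        "scenario": "escalation",
        "standard_response_cost": std_cost,
        "escalated_response_cost": esc_cost,
    })
    spec = spec.with_state(replace(state, cost_per_cycle=esc_cost))
    return spec.with_row(TransitionRow(row.from_state, entries, row.residence_clock))


def apply_deescalation(
    spec: ModelSpec, esc: EscalationPolicy, deesc: DeescalationPolicy
) -> ModelSpec:
    """Blend the response-state cost for the de-escalation scenario.

    The effective fraction (attempted x successful) of escalated responders
    is repriced at standard dosing; unsuccessful attempts stay escalated.
    Retention is unchanged — de-escalation succeeds precisely in patients who
    keep responding.
    """
    if spec.metadata.get("scenario") != "escalation":
        raise ValueError("apply_deescalation requires an escalated spec")
    f = deesc.effective_fraction
    std = float(spec.metadata["standard_response_cost"])
    escc = float(spec.metadata["escalated_response_cost"])
    blended = f * std + (1.0 - f) * escc
    state = spec.states[RESPONSE_STATE]
    spec = replace(spec, metadata={**spec.metadata, "scenario": "deescalation"})
    return spec.with_state(replace(state, cost_per_cycle=blended))


@dataclass(frozen=True)
class AnalysisResult:
    request: AnalysisRequest
    no_ada: EconResult
    ada: EconResult
    icer: ICERResult


def run_analysis(request: AnalysisRequest) -> AnalysisResult:
    """Build both arms, run the cohorts, and compute the incremental ratio."""
    econ = {}
    for arm in ARMS:
        spec = build_arm(arm, request)
        econ[arm] = accumulate(run_cohort(spec))
    return AnalysisResult(
        request=request,
        no_ada=econ["no_ada"],
        ada=econ["ada"],
        icer=compute_icer(econ["ada"], econ["no_ada"]),
    )
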