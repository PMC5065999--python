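"""Discounted cost and QALY accumulation, and incremental ratios.

Accounting conventions: state membership is counted at cycle start (no
half-cycle correction); each cycle of occupancy earns the state's per-cycle
cost and one quarter of its annual utility, discounted at the cycle-start
factor ``(1 + r)^(-k * cycle_length_years)``. Death carries no recurring cost
or utility, but the transition into death is charged, once, with the cost of
the predecessor state, discounted at the destination cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_engine import CohortTrace, collapse_id
from .model_spec import ModelSpec

__all__ = ["EconResult", "ICERResult", "discount_factor", "accumulate", "compute_icer"]


def discount_factor(cycle: int, annual_rate: float, cycle_length_years: float = 0.25) -> float:
    """Present-value factor ``(1 + r)^(-cycle * cycle_length_years)``."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle * cycle_length_years))


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one arm, with per-cycle contributions."""

    total_cost: float
    total_qalys: float
    cost_per_cycle: np.ndarray
    qalys_per_cycle: np.ndarray

    def rounded(self) -> tuple[float, float]:
        """(cost to nearest $1,000, QALYs to 3 decimals) — reporting convention."""
        return round(self.total_cost, -3), round(self.total_qalys, 3)


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness of intervention vs comparator."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str  # "ratio", "dominant", "dominated", "undefined"

    @property
    def rounded_icer(self) -> float | None:
        if self.icer is None:
            return None
        return round(self.icer, -3)


def accumulate(
    trace: CohortTrace,
    spec: ModelSpec | None = None,
    cost_overrides: dict[str, float] | None = None,
    utility_overrides: dict[str, float] | None = None,
) -> EconResult:
    """Accumulate discounted costs and QALYs from a cohort trace.

    ``cost_overrides`` / ``utility_overrides`` substitute values per
    (collapsed) state id without touching the trace — the sensitivity module
    relies on this to reprice a fixed trace under sampled parameters.
    """
    espec = trace.spec
    if spec is not None and set(map(collapse_id, espec.states)) != set(spec.states):
        raise ValueError("trace was not produced from the given spec")
    ids = trace.state_ids
    H = espec.horizon_cycles
    co = cost_overrides or {}
    uo = utility_overrides or {}

    cost_vec = np.array(
        [co.get(collapse_id(s), espec.states[s].cost_per_cycle) for s in ids]
    )
    util_vec = np.array(
        [
            0.0
            if espec.states[s].is_death
            else uo.get(collapse_id(s), espec.states[s].annual_utility)
            for s in ids
        ]
    )
    # death states accrue no recurring cost either
    for i, s in enumerate(ids):
        if espec.states[s].is_death:
            cost_vec[i] = 0.0

    disc = np.array(
        [discount_factor(k, espec.annual_discount_rate, espec.cycle_length_years) for k in range(H + 1)]
    )
    occ = trace.occupancy[:H]
    cost_k = disc[:H] * (occ @ cost_vec)
    # one-time death cost at the predecessor's rate, discounted at arrival cycle
    cost_k = cost_k + disc[1 : H + 1] * (trace.death_flows @ cost_vec)
    qaly_k = disc[:H] * (occ @ util_vec) * espec.cycle_length_years
    return EconResult(
        total_cost=float(cost_k.sum()),
        total_qalys=float(qaly_k.sum()),
        cost_per_cycle=cost_k,
        qalys_per_cycle=qaly_k,
    )


def compute_icer(intervention: EconResult, comparator: EconResult) -> ICERResult:
    """Incremental cost per QALY gained, intervention minus comparator.

    Dominance cases are labelled rather than divided: an intervention that is
    cheaper and more effective is ``dominant``; costlier and less (or equally)
    effective is ``dominated``; equal effectiveness with equal or higher cost
    but no extra cost is ``undefined``.
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys
    if dq == 0.0:
        label = "undefined" if dc == 0.0 else ("dominated" if dc > 0 else "dominant")
        return ICERResult(delta_cost=dc, delta_qalys=dq, icer=None, label=label)
    if dq > 0 and dc <= 0:
        return ICERResult(delta_cost=dc, delta_qalys=dq, icer=dc / dq, label="dominant")
    if dq < 0 and dc >= 0:
        return ICERResult(delta_cost=dc, delta_qalys=dq, icer=None, label="dominated")
    return ICERResult(delta_cost=dc, delta_qalys=dq, icer=dc / dq, label="ratio")
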