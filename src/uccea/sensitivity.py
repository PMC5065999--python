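"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-runs the full incremental comparison with a single
parameter at the low and high end of its uncertainty interval: probabilities
between their 95% CI bounds (a default ±25% relative interval where no CI is
printed), costs at ±25%, utilities at ± their printed interval half-width.
Because every row carries a complement entry, perturbing one probability is
absorbed by the row's remainder.

The probabilistic analysis samples costs from normal distributions and
utilities from beta distributions (utilities near zero are transformed to
decrements 1 − u and sampled from a gamma), with interval half-widths read
as 95% intervals (SD = half-width / 1.96). Transition probabilities stay at
base values. Each arm's parameters are drawn independently — the resulting
spread in incremental QALYs, not just costs, is what flattens the
cost-effectiveness acceptability curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .economics import accumulate, compute_icer, discount_factor
from .markov_engine import collapse_id, run_cohort
from .model_spec import FixedProb, ModelSpec, TransitionRow
from .scenarios import ARMS, AnalysisRequest, RESPONSE_STATE, build_arm

__all__ = [
    "ParameterRef",
    "DistributionSpec",
    "TornadoEntry",
    "CEACPoint",
    "PSAResult",
    "list_parameters",
    "parameter_bounds",
    "one_way",
    "tornado",
    "sample_psa",
    "ceac",
]

#: Utilities below this are "close to zero": sampled as gamma decrements.
GAMMA_UTILITY_THRESHOLD = 0.40
#: Printed uncertainty intervals are read as 95% intervals.
Z_95 = 1.959963984540054
#: Relative interval for costs and for probabilities without a printed CI.
DEFAULT_RELATIVE_HALFWIDTH = 0.25


@dataclass(frozen=True)
class ParameterRef:
    """Reference to one uncertain model input.

    kind ``"cost"`` / ``"utility"``: per-state; kind ``"prob"``: one fixed
    transition probability identified by (from_state, to_state).
    """

    kind: str
    state: str
    to_state: str | None = None

    def __str__(self) -> str:
        if self.kind == "prob":
            return f"prob[{self.state}->{self.to_state}]"
        return f"{self.kind}[{self.state}]"


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for a cost or utility parameter."""

    parameter: ParameterRef
    family: str  # "normal" | "beta" | "gamma_on_decrement" | "fixed"
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed" or self.sd == 0.0:
            return np.full(size, self.mean)
        if self.family == "normal":
            return np.clip(rng.normal(self.mean, self.sd, size), 0.0, None)
        if self.family == "beta":
            m, var = self.mean, self.sd**2
            if var >= m * (1 - m):
                raise ValueError(f"{self.parameter}: variance too large for a beta")
            a = m * ((m * (1 - m)) / var - 1.0)
            b = (1 - m) * a / m
            return rng.beta(a, b, size)
        if self.family == "gamma_on_decrement":
            dec = 1.0 - self.mean
            shape = (dec / self.sd) ** 2
            scale = self.sd**2 / dec
            return np.clip(1.0 - rng.gamma(shape, scale, size), 0.0, 1.0)
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def distribution_mean(self) -> float:
        """Exact mean of the sampling distribution (moment-matching check)."""
        return self.mean


def utility_distribution(parameter: ParameterRef, mean: float, halfwidth: float) -> DistributionSpec:
    """Beta for utilities far from zero, gamma on the decrement otherwise."""
    sd = halfwidth / Z_95
    if sd == 0.0:
        return DistributionSpec(parameter, "fixed", mean, 0.0)
    family = "beta" if mean >= GAMMA_UTILITY_THRESHOLD else "gamma_on_decrement"
    return DistributionSpec(parameter, family, mean, sd)


def cost_distribution(parameter: ParameterRef, mean: float, rel_halfwidth: float) -> DistributionSpec:
    sd = rel_halfwidth * mean / Z_95
    if sd <= 0.0:
        return DistributionSpec(parameter, "fixed", mean, 0.0)
    return DistributionSpec(parameter, "normal", mean, sd)


# ---------------------------------------------------------------------------
# one-way (deterministic) sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: ParameterRef
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        if math.isnan(self.icer_at_low) or math.isnan(self.icer_at_high):
            return math.nan
        return abs(self.icer_at_high - self.icer_at_low)


def list_parameters(request: AnalysisRequest) -> list[ParameterRef]:
    """All uncertain inputs of the two-arm comparison, in a stable order."""
    specs = [build_arm(arm, request) for arm in ARMS]
    params: list[ParameterRef] = []
    seen: set[ParameterRef] = set()
    for spec in specs:
        for sid, st in spec.states.items():
            if st.is_death:
                continue
            if st.cost_per_cycle > 0 and st.cost_uncertainty > 0:
                ref = ParameterRef("cost", sid)
                if ref not in seen:
                    seen.add(ref)
                    params.append(ref)
            if st.utility_halfwidth > 0:
                ref = ParameterRef("utility", sid)
                if ref not in seen:
                    seen.add(ref)
                    params.append(ref)
        for sid, row in spec.transitions.items():
            for e in row.entries:
                if isinstance(e, FixedProb):
                    ref = ParameterRef("prob", sid, e.to_state)
                    if ref not in seen:
                        seen.add(ref)
                        params.append(ref)
    return params


def parameter_bounds(spec: ModelSpec, ref: ParameterRef) -> tuple[float, float] | None:
    """Low/high inputs for one parameter in one arm's spec, or None if the
    parameter does not occur in this arm."""
    if ref.kind == "cost":
        st = spec.states.get(ref.state)
        if st is None:
            return None
        hw = st.cost_uncertainty
        return st.cost_per_cycle * (1 - hw), st.cost_per_cycle * (1 + hw)
    if ref.kind == "utility":
        st = spec.states.get(ref.state)
        if st is None:
            return None
        u, hw = st.annual_utility, st.utility_halfwidth
        return max(u - hw, 0.0), min(u + hw, 1.0)
    row = spec.transitions.get(ref.state)
    if row is None:
        return None
    for e in row.entries:
        if isinstance(e, FixedProb) and e.to_state == ref.to_state:
            if e.ci_low is not None:
                lo, hi = e.ci_low, e.ci_high
            else:
                lo = e.percent * (1 - DEFAULT_RELATIVE_HALFWIDTH)
                hi = e.percent * (1 + DEFAULT_RELATIVE_HALFWIDTH)
            other_fixed = sum(
                f.percent
                for f in row.entries
                if isinstance(f, FixedProb) and f.to_state != ref.to_state
            )
            # keep the row feasible: the complement cannot go negative
            hi = min(hi, 100.0, 100.0 - other_fixed)
            lo = max(min(lo, hi), 0.0)
            return lo, hi  # type: ignore[return-value]
    return None


def _with_parameter(spec: ModelSpec, ref: ParameterRef, value: float) -> ModelSpec:
    if ref.kind == "cost":
        return spec.with_state(replace(spec.states[ref.state], cost_per_cycle=value))
    if ref.kind == "utility":
        return spec.with_state(replace(spec.states[ref.state], annual_utility=value))
    row = spec.transitions[ref.state]
    entries = tuple(
        replace(e, percent=value, ci_low=None, ci_high=None)
        if isinstance(e, FixedProb) and e.to_state == ref.to_state
        else e
        for e in row.entries
    )
    return spec.with_row(TransitionRow(row.from_state, entries, row.residence_clock))


def _icer_with(
    specs: dict[str, ModelSpec], ref: ParameterRef | None, which: int | None
) -> float:
    econ = {}
    for arm, spec in specs.items():
        if ref is not None:
            bounds = parameter_bounds(spec, ref)
            if bounds is not None:
                spec = _with_parameter(spec, ref, bounds[which])  # type: ignore[index]
        econ[arm] = accumulate(run_cohort(spec))
    res = compute_icer(econ["ada"], econ["no_ada"])
    return res.icer if res.icer is not None else math.nan


def one_way(request: AnalysisRequest, parameter: ParameterRef) -> TornadoEntry:
    """Re-run the comparison with one parameter at its low and high bound.

    The parameter is moved in every arm in which it occurs (shared states
    move together; a probability whose base value differs by arm moves to
    each arm's own bound); all other inputs stay at base values.
    """
    specs = {arm: build_arm(arm, request) for arm in ARMS}
    bounds = [b for b in (parameter_bounds(s, parameter) for s in specs.values()) if b]
    if not bounds:
        raise KeyError(f"unknown or certain parameter {parameter}")
    return TornadoEntry(
        parameter=parameter,
        low_input=min(b[0] for b in bounds),
        high_input=max(b[1] for b in bounds),
        icer_at_low=_icer_with(specs, parameter, 0),
        icer_at_high=_icer_with(specs, parameter, 1),
    )


@dataclass(frozen=True)
class TornadoResult:
    entries: tuple[TornadoEntry, ...]  # sorted by descending spread
    base_icer: float

    @property
    def min_icer(self) -> float:
        return min(
            min(e.icer_at_low, e.icer_at_high)
            for e in self.entries
            if not math.isnan(e.spread)
        )

    @property
    def max_icer(self) -> float:
        return max(
            max(e.icer_at_low, e.icer_at_high)
            for e in self.entries
            if not math.isnan(e.spread)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": [str(e.parameter) for e in self.entries],
                "low_input": [e.low_input for e in self.entries],
                "high_input": [e.high_input for e in self.entries],
                "icer_at_low": [e.icer_at_low for e in self.entries],
                "icer_at_high": [e.icer_at_high for e in self.entries],
                "spread": [e.spread for e in self.entries],
            }
        )


def tornado(request: AnalysisRequest, parameters: Iterable[ParameterRef] | None = None) -> TornadoResult:
    """One-way analysis over all uncertain parameters, widest spread first."""
    params = list(parameters) if parameters is not None else list_parameters(request)
    specs = {arm: build_arm(arm, request) for arm in ARMS}
    base = _icer_with(specs, None, None)
    entries = [one_way(request, p) for p in params]
    entries.sort(key=lambda e: (not math.isnan(e.spread), e.spread), reverse=True)
    return TornadoResult(entries=tuple(entries), base_icer=base)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Per-draw discounted (cost, QALY) pairs for both arms."""

    request: AnalysisRequest
    n_draws: int
    seed: int
    cost: dict[str, np.ndarray]  # arm -> (n_draws,)
    qalys: dict[str, np.ndarray]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost["ada"] - self.cost["no_ada"]

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys["ada"] - self.qalys["no_ada"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "cost_no_ada": self.cost["no_ada"],
                "qalys_no_ada": self.qalys["no_ada"],
                "cost_ada": self.cost["ada"],
                "qalys_ada": self.qalys["ada"],
            }
        )


def arm_distributions(spec: ModelSpec) -> list[DistributionSpec]:
    """Cost and utility distributions for every (non-death) state of an arm."""
    dists: list[DistributionSpec] = []
    for sid, st in spec.states.items():
        if st.is_death:
            continue
        if st.cost_per_cycle > 0:
            dists.append(
                cost_distribution(ParameterRef("cost", sid), st.cost_per_cycle, st.cost_uncertainty)
            )
        if st.annual_utility > 0:
            dists.append(
                utility_distribution(ParameterRef("utility", sid), st.annual_utility, st.utility_halfwidth)
            )
    return dists


def _occupancy_weights(spec: ModelSpec):
    """Discounted occupancy and death-flow weights per collapsed state.

    Cost = c · (w_occ + w_death); QALYs = u · w_occ × cycle length. The trace
    does not depend on costs or utilities, so repricing each PSA draw is a
    dot product.
    """
    trace = run_cohort(spec)
    espec = trace.spec
    H = espec.horizon_cycles
    disc = np.array(
        [discount_factor(k, espec.annual_discount_rate, espec.cycle_length_years) for k in range(H + 1)]
    )
    w_occ: dict[str, float] = {}
    w_death: dict[str, float] = {}
    occ_w = disc[:H] @ trace.occupancy[:H]
    death_w = disc[1 : H + 1] @ trace.death_flows
    for i, sid in enumerate(trace.state_ids):
        base = collapse_id(sid)
        w_occ[base] = w_occ.get(base, 0.0) + occ_w[i]
        w_death[base] = w_death.get(base, 0.0) + death_w[i]
    return w_occ, w_death


def sample_psa(
    request: AnalysisRequest,
    n_draws: int = 10_000,
    seed: int = 0,
    specs: dict[str, ModelSpec] | None = None,
) -> PSAResult:
    """Monte-Carlo repricing of both arms under sampled costs and utilities.

    Transition probabilities stay at base values, so each arm's cohort trace
    is computed once and every draw reprices it. Arms are sampled
    independently. Deterministic given ``seed``. ``specs`` substitutes
    custom arm models (e.g. with modified uncertainty metadata) for the
    request-built fixtures.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cost: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    for arm in ARMS:
        spec = specs[arm] if specs is not None else build_arm(arm, request)
        w_occ, w_death = _occupancy_weights(spec)
        c = np.zeros(n_draws)
        q = np.zeros(n_draws)
        for dist in arm_distributions(spec):
            draws = dist.sample(rng, n_draws)
            sid = dist.parameter.state
            if dist.parameter.kind == "cost":
                c += draws * (w_occ.get(sid, 0.0) + w_death.get(sid, 0.0))
            else:
                q += draws * w_occ.get(sid, 0.0) * spec.cycle_length_years
        cost[arm] = c
        qalys[arm] = q
    return PSAResult(request=request, n_draws=n_draws, seed=seed, cost=cost, qalys=qalys)


# ---------------------------------------------------------------------------
# cost-effectiveness acceptability


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """P(net monetary benefit > 0) at each willingness-to-pay threshold.

    NMB = wtp × ΔQALY − ΔCost per draw; the probability is the fraction of
    draws in which the intervention arm has positive NMB.
    """
    dq = psa.delta_qalys
    dc = psa.delta_cost
    return [
        CEACPoint(wtp=float(w), probability_cost_effective=float(np.mean(w * dq - dc > 0.0)))
        for w in wtp_grid
    ]
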