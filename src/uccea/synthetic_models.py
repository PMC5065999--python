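"""Random cohort models and a per-patient microsimulation oracle.

The generator produces structurally valid models — arbitrary state graphs
with complement-resolved rows, optional retention-series dynamics, and a
reachable absorbing death state — so the cohort engine and the economics
accounting can be exercised on inputs unrelated to any particular disease
model. The microsimulation estimates the same discounted cost and QALY
totals by simulating individual patient trajectories; cohort trace and
microsimulation are two estimators of the same quantity and must agree
within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .economics import discount_factor
from .markov_engine import build_matrix, expand_tunnels
from .model_spec import (
    PLATEAU_CYCLE,
    Complement,
    FixedProb,
    HealthState,
    ModelSpec,
    RetentionSeries,
    SeriesRef,
    TransitionRow,
)

__all__ = ["GeneratorConfig", "generate_model", "microsimulate", "MicrosimResult"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the random model generator.

    ``n_states`` counts all states including the death state (minimum 2: one
    alive state decaying into death, the geometric-decay family). Cost and
    utility ranges default to the span seen in published inflammatory-bowel-
    disease models: up to the cost of a colectomy cycle, utilities between a
    severe flare and sustained remission.
    """

    n_states: int = 6
    include_death: bool = True
    fraction_time_varying: float = 0.0
    cost_range: tuple[float, float] = (0.0, 37_159.0)
    utility_range: tuple[float, float] = (0.16, 0.82)
    horizon_cycles: int = 40
    annual_discount_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not self.include_death:
            raise ValueError("a death state is required")
        if not 0.0 <= self.fraction_time_varying <= 1.0:
            raise ValueError("fraction_time_varying outside [0, 1]")


def _random_series(rng: np.random.Generator, name: str) -> RetentionSeries:
    """Non-increasing retention values in (0, 100] with a cycle-20 plateau."""
    start = rng.uniform(55.0, 95.0)
    decays = rng.uniform(0.93, 1.0, size=PLATEAU_CYCLE)
    values = start * np.concatenate([[1.0], np.cumprod(decays)])
    values = np.maximum(np.round(values, 1), 0.1)
    # rounding can break monotonicity at the last decimal; enforce it
    values = np.minimum.accumulate(values)
    return RetentionSeries(name=name, values_by_cycle=tuple(float(v) for v in values))


def generate_model(config: GeneratorConfig) -> ModelSpec:
    """Draw a random, valid ModelSpec. Deterministic given ``config.seed``.

    Every alive state keeps a direct edge to death, so the absorbing state is
    always reachable; each row's probabilities are a Dirichlet draw with the
    largest entry serving as the complement.
    """
    rng = np.random.default_rng(config.seed)
    n_alive = config.n_states - 1
    alive = [f"s{i}" for i in range(n_alive)]
    ids = alive + ["death"]

    n_tv = int(round(config.fraction_time_varying * n_alive))
    time_varying = set(rng.choice(n_alive, size=n_tv, replace=False).tolist()) if n_tv else set()

    states: dict[str, HealthState] = {}
    rows: dict[str, TransitionRow] = {}
    series: dict[str, RetentionSeries] = {}

    for i, sid in enumerate(alive):
        cost = float(rng.uniform(*config.cost_range))
        util = float(rng.uniform(*config.utility_range))
        states[sid] = HealthState(
            id=sid,
            label=f"synthetic state {i}",
            cost_per_cycle=round(cost, 2),
            annual_utility=round(util, 4),
            utility_halfwidth=round(min(util, 1 - util) * float(rng.uniform(0.1, 0.9)), 4),
        )
        # targets: death, plus up to three alive states (self allowed)
        k = int(rng.integers(1, min(3, n_alive) + 1))
        others = rng.choice(n_alive, size=k, replace=False)
        targets = ["death"] + [alive[j] for j in others]
        if i in time_varying:
            if sid not in targets[1:]:
                targets.append(sid)
            sname = f"retention_{sid}"
            series[sname] = _random_series(rng, sname)
            fixed_targets = [t for t in targets if t != sid]
            # fixed exits must leave room for the series maximum
            room = 1.0 - series[sname].values_by_cycle[0] / 100.0
            raw = rng.dirichlet(np.ones(len(fixed_targets)))
            fixed_p = raw * room * float(rng.uniform(0.3, 0.9))
            entries: list = [SeriesRef(to_state=sid, series=sname, role="stay")]
            comp_at = int(rng.integers(0, len(fixed_targets)))
            for j, t in enumerate(fixed_targets):
                if j == comp_at:
                    entries.append(Complement(to_state=t))
                else:
                    entries.append(FixedProb(to_state=t, percent=round(float(fixed_p[j]) * 100, 4)))
            rows[sid] = TransitionRow(sid, tuple(entries), residence_clock=True)
        else:
            probs = rng.dirichlet(np.ones(len(targets)))
            comp_at = int(np.argmax(probs))
            entries = []
            for j, t in enumerate(targets):
                if j == comp_at:
                    entries.append(Complement(to_state=t))
                else:
                    entries.append(FixedProb(to_state=t, percent=round(float(probs[j]) * 100, 4)))
            rows[sid] = TransitionRow(sid, tuple(entries))

    states["death"] = HealthState(
        id="death", label="death", cost_per_cycle=0.0, annual_utility=0.0,
        is_death=True, cost_uncertainty=0.0,
    )
    return ModelSpec(
        name=f"synthetic_{config.seed}",
        states=states,
        transitions=rows,
        retention_series=series,
        initial_distribution={alive[0]: 1.0},
        horizon_cycles=config.horizon_cycles,
        annual_discount_rate=config.annual_discount_rate,
        metadata={"generator_seed": config.seed},
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Sample means and standard errors from individual-patient simulation."""

    n_patients: int
    mean_cost: float
    se_cost: float
    mean_qalys: float
    se_qalys: float
    state_ids: tuple[str, ...]
    occupancy: np.ndarray  # empirical (horizon+1, n) proportions


def microsimulate(spec: ModelSpec, n_patients: int, seed: int = 0) -> MicrosimResult:
    """Estimate discounted per-patient cost and QALYs by simulating
    trajectories one cycle at a time.

    Uses the same resolved per-cycle probabilities as the cohort engine but
    as sampling distributions: each patient walks the chain, accruing
    discounted state costs and utilities at cycle start and the one-time
    predecessor-valued death cost at the transition into death.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    espec = expand_tunnels(spec)
    ids = tuple(espec.states)
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    H = espec.horizon_cycles
    death_mask = np.array([espec.states[s].is_death for s in ids])
    cost_vec = np.array(
        [0.0 if espec.states[s].is_death else espec.states[s].cost_per_cycle for s in ids]
    )
    util_vec = np.array(
        [0.0 if espec.states[s].is_death else espec.states[s].annual_utility for s in ids]
    )
    disc = np.array(
        [discount_factor(k, espec.annual_discount_rate, espec.cycle_length_years) for k in range(H + 1)]
    )

    state = np.zeros(n_patients, dtype=np.int64)
    start_ids, start_p = zip(*espec.initial_distribution.items())
    state[:] = rng.choice([index[s] for s in start_ids], size=n_patients, p=list(start_p))

    cost = np.zeros(n_patients)
    qalys = np.zeros(n_patients)
    occupancy = np.zeros((H + 1, n))
    for k in range(H):
        occupancy[k] = np.bincount(state, minlength=n) / n_patients
        cost += disc[k] * cost_vec[state]
        qalys += disc[k] * util_vec[state] * espec.cycle_length_years
        active = np.bincount(state, minlength=n) > 0
        _, P = build_matrix(espec, k, active=active)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0  # guard against float round-off in the last bin
        u = rng.random(n_patients)
        new_state = np.empty_like(state)
        for s in np.unique(state):
            sel = state == s
            new_state[sel] = np.searchsorted(cum[s], u[sel], side="right")
        died = death_mask[new_state] & ~death_mask[state]
        cost[died] += disc[k + 1] * cost_vec[state[died]]
        state = new_state
    occupancy[H] = np.bincount(state, minlength=n) / n_patients

    sq = np.sqrt(n_patients)
    return MicrosimResult(
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / sq),
        mean_qalys=float(qalys.mean()),
        se_qalys=float(qalys.std(ddof=1) / sq),
        state_ids=ids,
        occupancy=occupancy,
    )
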