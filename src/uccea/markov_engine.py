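"""Cohort engine: tunnel expansion and cycle-by-cycle trace computation.

The engine is time-inhomogeneous: the transition matrix is rebuilt every
cycle, so retention-series-driven probabilities can vary with model time.
States whose series clock measures time-in-state (``residence_clock``) are
expanded into a chain of 21 cycle-indexed tunnel copies; the last copy is
self-referential and represents the retention plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .model_spec import (
    PLATEAU_CYCLE,
    Complement,
    FixedProb,
    ModelSpec,
    RetentionSeries,
    SeriesRef,
    TransitionRow,
    resolve_row,
)

__all__ = ["CohortTrace", "retention_to_conditional", "expand_tunnels", "run_cohort"]

TUNNEL_SEP = "~"


def retention_to_conditional(series: RetentionSeries, k: int) -> float:
    """One-cycle conditional retention S(k+1)/S(k) from a cumulative series.

    Interprets the series values as survival-curve points (fraction still in
    response through cycle ``k``) and returns the probability of remaining in
    response one more cycle. At or beyond the plateau the conditional
    retention is 1.0 (no further loss).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= PLATEAU_CYCLE:
        return 1.0
    s_k = series.value_at(k)
    if s_k == 0:
        raise ZeroDivisionError(f"series {series.name!r}: S({k}) = 0")
    return series.value_at(k + 1) / s_k


def _tunnel_id(state_id: str, t: int) -> str:
    return f"{state_id}{TUNNEL_SEP}{t}"


def collapse_id(expanded_id: str) -> str:
    """Map a tunnel-copy id back to its original state id."""
    return expanded_id.split(TUNNEL_SEP, 1)[0]


def expand_tunnels(spec: ModelSpec) -> ModelSpec:
    """Replace each residence-clock state by a chain of 21 tunnel copies.

    All inbound edges are redirected to copy 0; the stay entry of copy ``t``
    targets copy ``t + 1`` (copy 20 targets itself, the plateau). Costs and
    utilities are copied unchanged, so collapsing tunnel occupancy reproduces
    the original state's occupancy. Specs without residence-clock states are
    returned unchanged.
    """
    tunnel_states = [sid for sid, row in spec.transitions.items() if row.residence_clock]
    if not tunnel_states:
        return spec

    states = dict(spec.states)
    rows = dict(spec.transitions)
    init = dict(spec.initial_distribution)

    for sid in tunnel_states:
        base_state = states.pop(sid)
        base_row = rows.pop(sid)
        stay_targets = {
            e.to_state
            for e in base_row.entries
            if isinstance(e, SeriesRef) and e.role == "stay" and e.to_state == sid
        }
        if not stay_targets:
            raise ValueError(
                f"residence-clock state {sid!r} has no series-driven self entry"
            )
        for t in range(PLATEAU_CYCLE + 1):
            tid = _tunnel_id(sid, t)
            states[tid] = replace(base_state, id=tid, label=f"{base_state.label} [t={t}]")
            entries = []
            for e in base_row.entries:
                target = e.to_state
                if target == sid:
                    target = _tunnel_id(sid, min(t + 1, PLATEAU_CYCLE))
                if isinstance(e, FixedProb):
                    entries.append(replace(e, to_state=target))
                elif isinstance(e, Complement):
                    entries.append(Complement(to_state=target))
                else:
                    entries.append(replace(e, to_state=target))
            rows[tid] = TransitionRow(
                from_state=tid, entries=tuple(entries), residence_clock=True
            )
        if sid in init:
            init[_tunnel_id(sid, 0)] = init.pop(sid)

    # redirect inbound edges from non-tunnel rows to copy 0
    expanded_set = set(tunnel_states)
    for sid, row in list(rows.items()):
        new_entries = []
        changed = False
        for e in row.entries:
            if e.to_state in expanded_set:
                changed = True
                new_entries.append(replace(e, to_state=_tunnel_id(e.to_state, 0)))
            else:
                new_entries.append(e)
        if changed:
            rows[sid] = TransitionRow(
                from_state=sid, entries=tuple(new_entries), residence_clock=row.residence_clock
            )

    return replace(
        spec, states=states, transitions=rows, initial_distribution=init
    )


@dataclass
class CohortTrace:
    """State-occupancy proportions by cycle, on the expanded state space.

    ``occupancy`` has ``horizon_cycles + 1`` rows; row ``k`` is the cohort
    distribution at the start of cycle ``k``. ``death_flows[k, i]`` is the
    proportion of the cohort moving from expanded state ``i`` into a death
    state during the transition out of cycle ``k`` (needed to charge the
    one-time predecessor-valued death cost).
    """

    spec: ModelSpec  # the expanded spec the trace was computed from
    state_ids: tuple[str, ...]
    occupancy: np.ndarray
    death_flows: np.ndarray

    @property
    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.state_ids)}

    def collapsed(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Occupancy with tunnel copies summed back into their base state."""
        order: list[str] = []
        for s in self.state_ids:
            base = collapse_id(s)
            if base not in order:
                order.append(base)
        out = np.zeros((self.occupancy.shape[0], len(order)))
        col = {s: i for i, s in enumerate(order)}
        for i, s in enumerate(self.state_ids):
            out[:, col[collapse_id(s)]] += self.occupancy[:, i]
        return tuple(order), out

    def occupancy_of(self, state_id: str) -> np.ndarray:
        """Per-cycle occupancy of a (collapsed) state id."""
        cols = [i for i, s in enumerate(self.state_ids) if collapse_id(s) == state_id]
        if not cols:
            raise KeyError(state_id)
        return self.occupancy[:, cols].sum(axis=1)

    def to_frame(self):
        """Collapsed trace as a pandas DataFrame (one row per cycle)."""
        import pandas as pd

        names, occ = self.collapsed()
        df = pd.DataFrame(occ, columns=list(names))
        df.insert(0, "cycle", np.arange(occ.shape[0]))
        df["death_flow"] = np.append(self.death_flows.sum(axis=1), np.nan)
        return df


def build_matrix(
    spec: ModelSpec, cycle: int, active: "np.ndarray | None" = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """Transition matrix for one cycle on the (already expanded) state space.

    Rows are resolved lazily: with an ``active`` mask, unoccupied states get
    a self-loop instead of being resolved, so a row that would only be
    inconsistent at a cycle where its state cannot be occupied (e.g. a
    response row before anyone can have responded) never trips the
    complement check.
    """
    ids = tuple(spec.states)
    index = {s: i for i, s in enumerate(ids)}
    P = np.zeros((len(ids), len(ids)))
    for sid in ids:
        row = spec.transitions.get(sid)
        if row is None or (active is not None and not active[index[sid]]):
            # absorbing state without explicit row, or unoccupied state
            P[index[sid], index[sid]] = 1.0
            continue
        residence = 0
        if row.residence_clock and TUNNEL_SEP in sid:
            residence = int(sid.rsplit(TUNNEL_SEP, 1)[1])
        try:
            probs = resolve_row(row, cycle, residence, spec)
        except Exception as exc:
            raise type(exc)(f"cycle {cycle}: {exc}") from exc
        for to, p in probs.items():
            P[index[sid], index[to]] += p
    return ids, P


def run_cohort(spec: ModelSpec) -> CohortTrace:
    """Propagate the cohort over ``spec.horizon_cycles`` cycles.

    The input spec may contain residence-clock states; tunnels are expanded
    internally. Deterministic given the spec.
    """
    expanded = expand_tunnels(spec)
    ids = tuple(expanded.states)
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    H = expanded.horizon_cycles
    death_cols = [index[s] for s in ids if expanded.states[s].is_death]

    occ = np.zeros((H + 1, n))
    dflow = np.zeros((H, n))
    x = np.zeros(n)
    for sid, p in expanded.initial_distribution.items():
        x[index[sid]] = p
    occ[0] = x
    for k in range(H):
        _, P = build_matrix(expanded, k, active=x > 0)
        dflow[k] = x * P[:, death_cols].sum(axis=1)
        for c in death_cols:  # a death state does not "flow into death" again
            dflow[k, c] = 0.0
        x = x @ P
        if abs(x.sum() - 1.0) > 1e-10:
            raise AssertionError(f"cycle {k}: occupancy sums to {x.sum()!r}")
        occ[k + 1] = x
    return CohortTrace(spec=expanded, state_ids=ids, occupancy=occ, death_flows=dflow)
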