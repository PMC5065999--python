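"""Markov cohort model specification: states, transitions, retention series.

A model is a set of health states, one outgoing transition row per
non-absorbing state, and optional cycle-indexed retention series that drive
time-varying maintenance-of-response probabilities. Probabilities are stored
as percentages, exactly as they appear in published input tables, and are
converted to fractions when a row is resolved for a given cycle.

Every transition row carries exactly one *complement* entry (written ``"#"``
in configuration files): its probability is whatever remains after all fixed
and series-driven entries are accounted for, so resolved rows always sum to
one.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "HealthState",
    "FixedProb",
    "Complement",
    "SeriesRef",
    "TransitionRow",
    "RetentionSeries",
    "ModelSpec",
    "ModelValidationError",
    "load_model_spec",
    "resolve_row",
    "apply_retention_discount",
    "PLATEAU_CYCLE",
]

#: Cycle index beyond which retention series hold their last value.
PLATEAU_CYCLE = 20

_SUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """A model configuration violates the schema or an invariant."""


@dataclass(frozen=True)
class HealthState:
    """A health state with a per-cycle cost and an annual utility weight.

    ``cost_per_cycle`` is in CA$ per 3-month cycle; ``annual_utility`` is the
    preference weight in [0, 1] accrued per full year of occupancy.
    ``cost_uncertainty`` is a relative 95%-interval half-width (e.g. 0.25 for
    ±25%); ``utility_halfwidth`` is the absolute half-width of the utility's
    95% interval. Both feed the sensitivity analyses.
    """

    id: str
    label: str
    cost_per_cycle: float
    annual_utility: float
    is_death: bool = False
    cost_uncertainty: float = 0.25
    utility_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_utility <= 1.0:
            raise ModelValidationError(
                f"state {self.id!r}: annual_utility {self.annual_utility} outside [0, 1]"
            )
        if self.cost_per_cycle < 0:
            raise ModelValidationError(f"state {self.id!r}: negative cost_per_cycle")
        if self.is_death and self.annual_utility != 0.0:
            raise ModelValidationError(f"death state {self.id!r} must have utility 0")


@dataclass(frozen=True)
class FixedProb:
    """A fixed transition probability in percent, with optional 95% CI bounds."""

    to_state: str
    percent: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ModelValidationError(
                f"probability {self.percent} to {self.to_state!r} outside [0, 100]"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ModelValidationError(f"entry to {self.to_state!r}: one-sided CI")
        if self.ci_low is not None:
            if not self.ci_low <= self.percent <= self.ci_high:  # type: ignore[operator]
                raise ModelValidationError(
                    f"entry to {self.to_state!r}: CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket {self.percent}"
                )


@dataclass(frozen=True)
class Complement:
    """The unique remainder entry of a row."""

    to_state: str


@dataclass(frozen=True)
class SeriesRef:
    """A transition probability driven by a :class:`RetentionSeries`.

    role ``"stay"``: the probability of maintaining response for one more
    cycle, read off the series at the row's clock (residence time for tunnel
    rows, cycles-since-response-onset otherwise).

    role ``"entry"``: the probability of *entering* response from another
    state, read at series cycle 0 regardless of clock.
    """

    to_state: str
    series: str
    role: str = "stay"

    def __post_init__(self) -> None:
        if self.role not in ("stay", "entry"):
            raise ModelValidationError(f"series role {self.role!r} not in {{stay, entry}}")


Entry = FixedProb | Complement | SeriesRef


@dataclass(frozen=True)
class TransitionRow:
    """Outgoing transition entries from one state.

    ``residence_clock`` marks rows whose series-driven probabilities are
    indexed by time-in-state rather than model time; the engine expands such
    states into tunnel copies.
    """

    from_state: str
    entries: tuple[Entry, ...]
    residence_clock: bool = False

    def __post_init__(self) -> None:
        n_comp = sum(isinstance(e, Complement) for e in self.entries)
        if n_comp != 1:
            raise ModelValidationError(
                f"row {self.from_state!r}: {n_comp} complement entries (exactly 1 required)"
            )
        fixed_sum = sum(e.percent for e in self.entries if isinstance(e, FixedProb))
        if fixed_sum > 100.0 + 1e-9:
            raise ModelValidationError(
                f"row {self.from_state!r}: fixed entries sum to {fixed_sum:.4f}% > 100%"
            )
        targets = [e.to_state for e in self.entries]
        if len(set(targets)) != len(targets):
            raise ModelValidationError(f"row {self.from_state!r}: duplicate target state")

    @property
    def complement_target(self) -> str:
        return next(e.to_state for e in self.entries if isinstance(e, Complement))


@dataclass(frozen=True)
class RetentionSeries:
    """Fraction (%) of patients still responding, indexed by cycle 0..20.

    Values are non-increasing; the cycle-20 value is the plateau used for all
    later cycles.
    """

    name: str
    values_by_cycle: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values_by_cycle
        if len(v) != PLATEAU_CYCLE + 1:
            raise ModelValidationError(
                f"series {self.name!r}: expected {PLATEAU_CYCLE + 1} values, got {len(v)}"
            )
        if any(not 0.0 < x <= 100.0 for x in v):
            raise ModelValidationError(f"series {self.name!r}: values must lie in (0, 100]")
        if any(b > a + 1e-9 for a, b in zip(v, v[1:])):
            raise ModelValidationError(f"series {self.name!r}: values must be non-increasing")

    @property
    def plateau_value(self) -> float:
        return self.values_by_cycle[PLATEAU_CYCLE]

    def value_at(self, cycle: int) -> float:
        """Series value (%) at ``cycle``, holding the plateau beyond cycle 20."""
        if cycle < 0:
            raise ValueError("cycle must be >= 0")
        return self.values_by_cycle[min(cycle, PLATEAU_CYCLE)]


@dataclass(frozen=True)
class ModelSpec:
    """A complete, validated cohort model for one treatment arm."""

    name: str
    states: Mapping[str, HealthState]
    transitions: Mapping[str, TransitionRow]
    retention_series: Mapping[str, RetentionSeries]
    initial_distribution: Mapping[str, float]
    cycle_length_years: float = 0.25
    annual_discount_rate: float = 0.05
    horizon_cycles: int = 40
    retention_mode: str = "per_cycle"  # or "conditional"
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_spec(self)

    # -- convenience ------------------------------------------------------
    @property
    def death_states(self) -> tuple[str, ...]:
        return tuple(s for s, st in self.states.items() if st.is_death)

    def with_horizon(self, horizon_cycles: int) -> "ModelSpec":
        return replace(self, horizon_cycles=horizon_cycles)

    def with_state(self, state: HealthState) -> "ModelSpec":
        states = dict(self.states)
        states[state.id] = state
        return replace(self, states=states)

    def with_row(self, row: TransitionRow) -> "ModelSpec":
        rows = dict(self.transitions)
        rows[row.from_state] = row
        return replace(self, transitions=rows)

    def resolve(self, state_id: str, cycle: int, residence_time: int = 0) -> dict[str, float]:
        return resolve_row(self.transitions[state_id], cycle, residence_time, self)

    def to_dict(self) -> dict:
        """Normalized plain-data dump (for audit diffing and round-trips)."""
        return _spec_to_dict(self)

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# validation


def validate_spec(spec: ModelSpec) -> None:
    ids = set(spec.states)
    for sid, row in spec.transitions.items():
        if sid not in ids:
            raise ModelValidationError(f"transition row for undeclared state {sid!r}")
        for e in row.entries:
            if e.to_state not in ids:
                raise ModelValidationError(
                    f"row {sid!r}: target state {e.to_state!r} is not declared"
                )
            if isinstance(e, SeriesRef) and e.series not in spec.retention_series:
                raise ModelValidationError(
                    f"row {sid!r}: unknown retention series {e.series!r}"
                )
    for sid, st in spec.states.items():
        if st.is_death:
            row = spec.transitions.get(sid)
            if row is not None:
                ok = all(
                    (isinstance(e, (FixedProb, Complement)) and e.to_state == sid)
                    for e in row.entries
                )
                if not ok:
                    raise ModelValidationError(
                        f"death state {sid!r} may only transition to itself"
                    )
        elif sid not in spec.transitions:
            raise ModelValidationError(f"non-absorbing state {sid!r} has no transition row")
    total = sum(spec.initial_distribution.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ModelValidationError(f"initial distribution sums to {total}, not 1")
    for sid in spec.initial_distribution:
        if sid not in ids:
            raise ModelValidationError(f"initial distribution names unknown state {sid!r}")
    if not any(st.is_death for st in spec.states.values()):
        raise ModelValidationError("model has no absorbing death state")
    if not _reaches_death(spec):
        raise ModelValidationError("no death state is reachable from the initial states")
    if spec.retention_mode not in ("per_cycle", "conditional"):
        raise ModelValidationError(f"unknown retention_mode {spec.retention_mode!r}")


def _reaches_death(spec: ModelSpec) -> bool:
    frontier = [s for s, p in spec.initial_distribution.items() if p > 0]
    seen = set(frontier)
    while frontier:
        sid = frontier.pop()
        if spec.states[sid].is_death:
            return True
        for e in spec.transitions.get(sid, TransitionRow(sid, (Complement(sid),))).entries:
            if e.to_state not in seen:
                seen.add(e.to_state)
                frontier.append(e.to_state)
    return False


def unreachable_states(spec: ModelSpec) -> tuple[str, ...]:
    """States carrying no initial mass and no inbound edge from a reachable
    state; reported in the model dump for audit."""
    frontier = [s for s, p in spec.initial_distribution.items() if p > 0]
    seen = set(frontier)
    while frontier:
        sid = frontier.pop()
        row = spec.transitions.get(sid)
        if row is None:
            continue
        for e in row.entries:
            if e.to_state not in seen:
                seen.add(e.to_state)
                frontier.append(e.to_state)
    return tuple(sorted(set(spec.states) - seen))


# ---------------------------------------------------------------------------
# resolution


def resolve_row(
    row: TransitionRow, cycle: int, residence_time: int, spec: ModelSpec
) -> dict[str, float]:
    """Resolve a row to a probability map (fractions summing to exactly 1).

    Series-driven ``stay`` entries are evaluated at ``residence_time`` for
    residence-clock rows and at ``cycle - 1`` (clamped at 0) otherwise: the
    series indexes time since response began, which lags model time by the
    one-cycle induction period. ``entry`` references always use the series
    cycle-0 value.

    Raises
    ------
    ModelValidationError
        If the non-complement entries exceed probability 1, which would force
        a negative complement.
    """
    if cycle < 0 or residence_time < 0:
        raise ValueError("cycle and residence_time must be >= 0")
    out: dict[str, float] = {}
    comp_target: str | None = None
    fixed_sum = 0.0
    for e in row.entries:
        if isinstance(e, FixedProb):
            out[e.to_state] = e.percent / 100.0
            fixed_sum += e.percent / 100.0
        elif isinstance(e, Complement):
            comp_target = e.to_state
    if fixed_sum > 1.0 + _SUM_TOL:
        raise ModelValidationError(
            f"row {row.from_state!r} at cycle {cycle} (residence {residence_time}): "
            f"fixed entries sum to {fixed_sum:.6f} > 1, complement would be negative"
        )
    for e in row.entries:
        if not isinstance(e, SeriesRef):
            continue
        series = spec.retention_series[e.series]
        if e.role == "entry":
            value = series.value_at(0) / 100.0
        else:
            clock = residence_time if row.residence_clock else max(cycle - 1, 0)
            if spec.retention_mode == "per_cycle":
                value = series.value_at(clock) / 100.0
            else:
                from .markov_engine import retention_to_conditional

                value = retention_to_conditional(series, clock)
        # the row's fixed exits are competing risks: maintenance can claim
        # only the probability mass they leave behind
        out[e.to_state] = out.get(e.to_state, 0.0) + min(
            value, max(1.0 - sum(out.values()), 0.0)
        )
    assert comp_target is not None
    out[comp_target] = out.get(comp_target, 0.0) + max(1.0 - sum(out.values()), 0.0)
    return out


def apply_retention_discount(series: RetentionSeries, discount: float) -> RetentionSeries:
    """Scale every series value by ``1 - discount``, rounding half-up to one
    decimal so derived series match their printed fixture counterparts.

    Used to derive the maintenance probabilities of patients re-treated after
    prior anti-TNF exposure (a 15% response discount) from the anti-TNF-naive
    series.
    """
    if not 0.0 <= discount < 1.0:
        raise ValueError(f"discount {discount} outside [0, 1)")
    factor = decimal.Decimal(str(1.0 - discount))
    vals = tuple(
        float(
            (decimal.Decimal(str(v)) * factor).quantize(
                decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
            )
        )
        for v in series.values_by_cycle
    )
    return RetentionSeries(name=f"{series.name}_discounted", values_by_cycle=vals)


# ---------------------------------------------------------------------------
# loading / serialization


def load_model_spec(config_path: str | Path) -> ModelSpec:
    """Load and validate a model from a YAML (or JSON) configuration file."""
    path = Path(config_path)
    data = yaml.safe_load(path.read_text())
    return spec_from_dict(data, default_name=path.stem)


def spec_from_dict(data: Mapping, default_name: str = "model") -> ModelSpec:
    if not isinstance(data, Mapping):
        raise ModelValidationError("model config must be a mapping")
    series = {}
    for name, sdata in (data.get("series") or {}).items():
        series[name] = RetentionSeries(name=name, values_by_cycle=tuple(sdata["values"]))

    states: dict[str, HealthState] = {}
    rows: dict[str, TransitionRow] = {}
    for sdata in data.get("states", ()):
        sid = sdata["id"]
        if sid in states:
            raise ModelValidationError(f"duplicate state id {sid!r}")
        states[sid] = HealthState(
            id=sid,
            label=sdata.get("label", sid),
            cost_per_cycle=float(sdata.get("cost_per_cycle", 0.0)),
            annual_utility=float(sdata.get("annual_utility", 0.0)),
            is_death=bool(sdata.get("is_death", False)),
            cost_uncertainty=float(sdata.get("cost_uncertainty", 0.25)),
            utility_halfwidth=float(sdata.get("utility_halfwidth", 0.0)),
        )
        tdata = sdata.get("transitions")
        if tdata is not None:
            entries: list[Entry] = []
            for ent in tdata:
                entries.append(_entry_from_dict(sid, ent))
            rows[sid] = TransitionRow(
                from_state=sid,
                entries=tuple(entries),
                residence_clock=bool(sdata.get("residence_clock", False)),
            )
    return ModelSpec(
        name=data.get("name", default_name),
        states=states,
        transitions=rows,
        retention_series=series,
        initial_distribution={k: float(v) for k, v in data["initial_distribution"].items()},
        cycle_length_years=float(data.get("cycle_length_years", 0.25)),
        annual_discount_rate=float(data.get("annual_discount_rate", 0.05)),
        horizon_cycles=int(data.get("horizon_cycles", 40)),
        retention_mode=data.get("retention_mode", "per_cycle"),
        metadata=data.get("metadata", {}),
    )


def _entry_from_dict(sid: str, ent: Mapping) -> Entry:
    if "to" not in ent:
        raise ModelValidationError(f"row {sid!r}: transition entry missing 'to'")
    to = ent["to"]
    if "series" in ent:
        return SeriesRef(to_state=to, series=ent["series"], role=ent.get("role", "stay"))
    p = ent.get("p")
    if p == "#":
        return Complement(to_state=to)
    if p is None:
        raise ModelValidationError(f"row {sid!r}: entry to {to!r} has no probability")
    ci = ent.get("ci")
    return FixedProb(
        to_state=to,
        percent=float(p),
        ci_low=None if ci is None else float(ci[0]),
        ci_high=None if ci is None else float(ci[1]),
    )


def _entry_to_dict(e: Entry) -> dict:
    if isinstance(e, FixedProb):
        d: dict = {"to": e.to_state, "p": e.percent}
        if e.ci_low is not None:
            d["ci"] = [e.ci_low, e.ci_high]
        return d
    if isinstance(e, Complement):
        return {"to": e.to_state, "p": "#"}
    return {"to": e.to_state, "series": e.series, "role": e.role}


def _spec_to_dict(spec: ModelSpec) -> dict:
    states = []
    for sid in spec.states:
        st = spec.states[sid]
        d: dict = {
            "id": st.id,
            "label": st.label,
            "cost_per_cycle": st.cost_per_cycle,
            "annual_utility": st.annual_utility,
            "cost_uncertainty": st.cost_uncertainty,
            "utility_halfwidth": st.utility_halfwidth,
        }
        if st.is_death:
            d["is_death"] = True
        row = spec.transitions.get(sid)
        if row is not None:
            if row.residence_clock:
                d["residence_clock"] = True
            d["transitions"] = [_entry_to_dict(e) for e in row.entries]
        states.append(d)
    return {
        "name": spec.name,
        "cycle_length_years": spec.cycle_length_years,
        "annual_discount_rate": spec.annual_discount_rate,
        "horizon_cycles": spec.horizon_cycles,
        "retention_mode": spec.retention_mode,
        "initial_distribution": dict(spec.initial_distribution),
        "series": {
            name: {"values": list(s.values_by_cycle)}
            for name, s in spec.retention_series.items()
        },
        "states": states,
        "audit": {"unreachable_states": list(unreachable_states(spec))},
    }
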