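"""The clearing-sequence simulator.

Each replicate run walks the properties in the scenario's order.  A
property draws a target total cleared fraction from U(30%, 70%) and then
clears its units in strictly decreasing suitability — the whole unit if
headroom allows, otherwise the partial area that exactly exhausts the
binding cap — until the draw is met or clearable land runs out.  The run
ends when the catchment cap is reached (immediately in ``truncate`` mode;
after the crossing property finishes in ``complete_last_property`` mode)
or when every property has been processed.  Unconstrained runs keep the
target draws and the buffer/protection/suitability exclusions but ignore
all four percentage caps and never stop early.

Randomness is replayable at the finest grain: the ordering stream of run
``i`` is seeded by (seed, i, "order") and the target stream of property
``p`` in run ``i`` by (seed, i, "target", p), so draws do not shift if the
iteration is refactored or a property is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import (CapLedger, CapPolicy, ClearingEvent, allowable_clearing,
                     apply_clearing, init_ledger, is_clearable)
from .landscape import Landscape
from .scenarios import ScenarioSpec, draw_property_target, order_properties

__all__ = [
    "RunResult",
    "simulate_property",
    "simulate_run",
    "run_scenario",
]

#: Clearing below this area (ha) is considered complete / not worth an event.
AREA_EPS = 1e-6

_ORDER_TAG = 0
_TARGET_TAG = 1


@dataclass
class RunResult:
    """Outcome of one replicate run."""

    run_id: int
    events: list[ClearingEvent]
    unit_cleared: dict[int, float]
    property_cleared: dict[int, float]
    targets: dict[int, float]
    order: list[int]
    ledger: CapLedger

    @property
    def total_new_cleared_ha(self) -> float:
        return float(sum(self.property_cleared.values()))

    def selected_properties(self) -> list[int]:
        """Properties with positive simulated (new) clearing."""
        return [p for p, a in self.property_cleared.items() if a > AREA_EPS]


class _SimIndex:
    """Per-landscape precomputation: clearable units of each property in
    clearing order (suitability desc, ties by type_id then unit_id asc)."""

    def __init__(self, landscape: Landscape) -> None:
        units = landscape.units
        clearable = units[
            (units["buffered"] == 0)
            & (units["protected"] == 0)
            & (units["existing_cleared"] == 0)
            & (units["suitability"] > 0)
        ].sort_values(["suitability", "type_id", "unit_id"],
                      ascending=[False, True, True], kind="mergesort")
        self.by_property: dict[int, list[tuple[int, int, int, float]]] = {}
        for row in clearable.itertuples(index=False):
            self.by_property.setdefault(int(row.prop_id), []).append(
                (int(row.unit_id), int(row.sc_id), int(row.type_id),
                 float(row.area_ha)))


class _UnitView:
    """Lightweight clearable-unit record accepted by the engine."""

    __slots__ = ("unit_id", "prop_id", "sc_id", "type_id", "area_ha")
    buffered = 0
    protected = 0
    existing_cleared = 0
    suitability = 1  # clearable by construction

    def __init__(self, unit_id: int, prop_id: int, sc_id: int,
                 type_id: int, area_ha: float) -> None:
        self.unit_id = unit_id
        self.prop_id = prop_id
        self.sc_id = sc_id
        self.type_id = type_id
        self.area_ha = area_ha


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def simulate_property(
    landscape: Landscape,
    ledger: CapLedger,
    policy: CapPolicy,
    prop_id: int,
    target_fraction: float,
    _index: _SimIndex | None = None,
) -> list[ClearingEvent]:
    """Clear one property toward its target total cleared fraction.

    Units are processed in strictly decreasing suitability; each is cleared
    by the minimum of its area, the remaining draw, and the allowable area
    under the caps.  Returns the events generated (the ledger is updated in
    place).
    """
    if not (0 <= target_fraction <= 1):
        raise ValueError(f"target_fraction {target_fraction} outside [0, 1]")
    if prop_id not in ledger.prop_baseline:
        raise KeyError(f"unknown property {prop_id}")
    index = _index if _index is not None else _SimIndex(landscape)

    prop_area = ledger.prop_baseline[prop_id]
    remaining = target_fraction * prop_area - ledger.prop_cleared[prop_id]
    events: list[ClearingEvent] = []
    if remaining <= AREA_EPS:
        return events

    for unit_id, sc_id, type_id, area_ha in index.by_property.get(prop_id, []):
        unit = _UnitView(unit_id, prop_id, sc_id, type_id, area_ha)
        amount = allowable_clearing(ledger, policy, unit, remaining)
        if amount > AREA_EPS:
            apply_clearing(ledger, unit, amount)
            events.append(ledger.event_log[-1])
            remaining -= amount
        if remaining <= AREA_EPS:
            break
    return events


def simulate_run(
    landscape: Landscape,
    policy: CapPolicy,
    spec: ScenarioSpec,
    run_index: int,
    _index: _SimIndex | None = None,
) -> RunResult:
    """One replicate: order the properties, draw targets, clear under the
    ledger, stop at the catchment cap (constrained runs only)."""
    policy = replace(policy, constrained=spec.constrained)
    index = _index if _index is not None else _SimIndex(landscape)
    ledger = init_ledger(landscape, policy)
    ledger.run_id = run_index

    order = order_properties(landscape, spec.ordering,
                             _rng(spec.seed, run_index, _ORDER_TAG))
    cap_area = policy.catchment_cap * ledger.catchment_baseline
    stop_eps = max(AREA_EPS, cap_area * 1e-12)

    targets: dict[int, float] = {}
    property_cleared: dict[int, float] = {}
    events: list[ClearingEvent] = []

    for prop_id in order:
        if policy.constrained and ledger.catchment_cleared >= cap_area - stop_eps:
            break
        target = draw_property_target(
            _rng(spec.seed, run_index, _TARGET_TAG, prop_id), policy)
        targets[prop_id] = target
        prop_events = simulate_property(landscape, ledger, policy,
                                        prop_id, target, _index=index)
        if prop_events:
            property_cleared[prop_id] = float(
                sum(e.area_ha for e in prop_events))
            events.extend(prop_events)

    unit_cleared: dict[int, float] = {}
    for e in events:
        unit_cleared[e.unit_id] = unit_cleared.get(e.unit_id, 0.0) + e.area_ha

    return RunResult(
        run_id=run_index,
        events=events,
        unit_cleared=unit_cleared,
        property_cleared=property_cleared,
        targets=targets,
        order=order,
        ledger=ledger,
    )


def run_scenario(
    landscape: Landscape,
    policy: CapPolicy,
    spec: ScenarioSpec,
) -> list[RunResult]:
    """All replicate runs of one scenario.  Identical inputs produce
    identical results; each run is independently reproducible."""
    index = _SimIndex(landscape)
    return [simulate_run(landscape, policy, spec, i, _index=index)
            for i in range(spec.n_runs)]


def results_to_frame(results: list[RunResult],
                     landscape: Landscape | None = None) -> pd.DataFrame:
    """Concatenated event log over runs (columns run_id, step, prop_id,
    unit_id, area_ha, plus unit attributes when a landscape is given)."""
    from .engine import events_to_frame
    frames = [events_to_frame(r.events, landscape) for r in results]
    if not frames:
        return pd.DataFrame(columns=["run_id", "step", "prop_id",
                                     "unit_id", "area_ha"])
    return pd.concat(frames, ignore_index=True)
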