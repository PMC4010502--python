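"""Cap ledger for the cascade rules.

The cascade rules are a nested hierarchy of clearing caps: no property may
exceed 70% cleared, no sub-catchment 40%, no vegetation type 30% (of its
pre-clearing extent), and the whole catchment 20%; stream, wetland, river
and rainforest buffers are closed to clearing entirely.  Once a feature
reaches its cap, no further clearing is permitted for that feature — but a
feature that *starts* above its cap (from historical clearing that predates
the guidelines) keeps what it has and simply receives no new clearing
("grandfathering").

The :class:`CapLedger` tracks cleared area and baseline (denominator) area
for every feature at every cap level, and answers the one question the
simulator asks: how much of a given unit may be cleared right now.
Existing clearing counts toward every accumulator and every denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

from .landscape import Landscape

__all__ = [
    "CAP_EPS",
    "CapPolicy",
    "ClearingEvent",
    "CapLedger",
    "CapViolationError",
    "init_ledger",
    "is_clearable",
    "allowable_clearing",
    "apply_clearing",
    "events_to_frame",
]

#: Relative tolerance on all cap comparisons (float area arithmetic).
CAP_EPS = 1e-6

OVERSHOOT_MODES = ("complete_last_property", "truncate")


class CapViolationError(RuntimeError):
    """A clearing event exceeded the allowable area — an implementation bug
    if raised from simulator output."""


@dataclass(frozen=True)
class CapPolicy:
    """The cap fractions and target-draw bounds of the clearing guidelines.

    ``overshoot_mode`` controls how the catchment cap terminates a run:
    ``complete_last_property`` lets the property whose clearing crosses the
    cap finish its draw (reported totals then slightly exceed the cap, as
    on the real landscape), while ``truncate`` clamps the final clearing
    event exactly at the cap.  ``constrained=False`` disables the four
    percentage caps but never the buffer/protection/suitability exclusions.
    """

    property_cap: float = 0.70
    subcatchment_cap: float = 0.40
    vegetation_cap: float = 0.30
    catchment_cap: float = 0.20
    target_lower: float = 0.30
    target_upper: float = 0.70
    overshoot_mode: str = "complete_last_property"
    constrained: bool = True

    def __post_init__(self) -> None:
        for name in ("property_cap", "subcatchment_cap",
                     "vegetation_cap", "catchment_cap"):
            cap = getattr(self, name)
            if not (0 < cap <= 1):
                raise ValueError(f"{name}={cap} outside (0, 1]")
        if not (0 <= self.target_lower <= self.target_upper <= 1):
            raise ValueError(
                f"target bounds ({self.target_lower}, {self.target_upper}) "
                f"must satisfy 0 <= lower <= upper <= 1")
        if self.overshoot_mode not in OVERSHOOT_MODES:
            raise ValueError(f"overshoot_mode must be one of {OVERSHOOT_MODES}")


@dataclass(frozen=True)
class ClearingEvent:
    run_id: int
    step: int
    prop_id: int
    unit_id: int
    area_ha: float


@dataclass
class CapLedger:
    """Cleared-area accumulators and baseline denominators per feature.

    ``cleared``/``baseline`` are dicts keyed by feature id for the
    ``property``, ``subcatchment`` and ``vegtype`` levels; the catchment
    level is a pair of scalars.  ``event_log`` records every clearing
    event applied since initialisation, so any accumulator can be audited
    by replay.
    """

    policy: CapPolicy
    prop_cleared: dict[int, float]
    prop_baseline: dict[int, float]
    sc_cleared: dict[int, float]
    sc_baseline: dict[int, float]
    veg_cleared: dict[int, float]
    veg_baseline: dict[int, float]
    catchment_cleared: float
    catchment_baseline: float
    event_log: list[ClearingEvent] = field(default_factory=list)
    run_id: int = 0

    def catchment_fraction(self) -> float:
        return self.catchment_cleared / self.catchment_baseline

    def catchment_headroom(self) -> float:
        return max(0.0, self.policy.catchment_cap * self.catchment_baseline
                   - self.catchment_cleared)

    def new_cleared_ha(self) -> float:
        return float(sum(e.area_ha for e in self.event_log))


def init_ledger(landscape: Landscape, policy: CapPolicy) -> CapLedger:
    """Initialise accumulators from existing clearing.

    Baselines: property = total property area (buffered, protected and
    unsuitable land included); sub-catchment = total sub-catchment area;
    vegetation type = pre-clearing extent; catchment = total catchment
    area.  Existing-cleared unit areas seed every accumulator, so features
    historically cleared beyond their cap start with zero headroom.
    """
    units = landscape.units
    cleared = units[units["existing_cleared"] == 1]

    prop_baseline = dict(zip(landscape.properties["prop_id"].astype(int),
                             landscape.properties["total_area_ha"].astype(float)))
    sc_baseline = dict(zip(landscape.sub_catchments["sc_id"].astype(int),
                           landscape.sub_catchments["total_area_ha"].astype(float)))
    veg_baseline = dict(zip(landscape.veg_types["type_id"].astype(int),
                            landscape.veg_types["pre_clearing_area_ha"].astype(float)))

    def _sums(col: str) -> dict[int, float]:
        s = cleared.groupby(col)["area_ha"].sum()
        return {int(k): float(v) for k, v in s.items()}

    prop_clr = _sums("prop_id")
    sc_clr = _sums("sc_id")
    veg_clr = _sums("type_id")

    return CapLedger(
        policy=policy,
        prop_cleared={p: prop_clr.get(p, 0.0) for p in prop_baseline},
        prop_baseline=prop_baseline,
        sc_cleared={s: sc_clr.get(s, 0.0) for s in sc_baseline},
        sc_baseline=sc_baseline,
        veg_cleared={t: veg_clr.get(t, 0.0) for t in veg_baseline},
        veg_baseline=veg_baseline,
        catchment_cleared=float(cleared["area_ha"].sum()),
        catchment_baseline=landscape.catchment_area_ha,
    )


def _get(unit: Any, name: str):
    if isinstance(unit, Mapping):
        return unit[name]
    return getattr(unit, name)


def is_clearable(unit: Any) -> bool:
    """A unit is open to clearing iff it is not buffered, not protected,
    not already cleared, and has suitability > 0 (nobody invests in
    clearing land with no production value)."""
    return (
        not _get(unit, "buffered")
        and not _get(unit, "protected")
        and not _get(unit, "existing_cleared")
        and _get(unit, "suitability") > 0
    )


def _headroom(cap: float, baseline: float, cleared: float) -> float:
    return max(0.0, cap * baseline - cleared)


def allowable_clearing(
    ledger: CapLedger,
    policy: CapPolicy,
    unit: Any,
    property_remaining_ha: float = math.inf,
) -> float:
    """Maximum area of ``unit`` that may be cleared right now.

    The minimum of the unit's area, the property's remaining draw, and the
    cap headrooms of the unit's property, sub-catchment and vegetation
    type.  The catchment headroom joins the minimum only in ``truncate``
    mode; in ``complete_last_property`` mode the catchment cap is enforced
    between properties by the simulator, so the crossing property may
    finish its draw.  With ``constrained=False`` all four cap headrooms
    are infinite (buffer/protection/suitability exclusions are handled by
    :func:`is_clearable`, not here).
    """
    amount = min(float(_get(unit, "area_ha")), property_remaining_ha)
    if not policy.constrained:
        return max(0.0, amount)
    prop = int(_get(unit, "prop_id"))
    sc = int(_get(unit, "sc_id"))
    veg = int(_get(unit, "type_id"))
    amount = min(
        amount,
        _headroom(policy.property_cap, ledger.prop_baseline[prop],
                  ledger.prop_cleared[prop]),
        _headroom(policy.subcatchment_cap, ledger.sc_baseline[sc],
                  ledger.sc_cleared[sc]),
        _headroom(policy.vegetation_cap, ledger.veg_baseline[veg],
                  ledger.veg_cleared[veg]),
    )
    if policy.overshoot_mode == "truncate":
        amount = min(amount, ledger.catchment_headroom())
    return max(0.0, amount)


def apply_clearing(ledger: CapLedger, unit: Any, area_ha: float) -> CapLedger:
    """Clear ``area_ha`` of ``unit``: bump all four accumulators and append
    the event.  Raises :class:`CapViolationError` if the area exceeds what
    the ledger currently allows (beyond float tolerance)."""
    if area_ha <= 0:
        raise CapViolationError(f"clearing area must be positive, got {area_ha}")
    allowed = allowable_clearing(ledger, ledger.policy, unit)
    if area_ha > allowed * (1 + CAP_EPS) + 1e-9:
        raise CapViolationError(
            f"unit {int(_get(unit, 'unit_id'))}: requested {area_ha:.6f} ha "
            f"exceeds allowable {allowed:.6f} ha")
    prop = int(_get(unit, "prop_id"))
    ledger.prop_cleared[prop] += area_ha
    ledger.sc_cleared[int(_get(unit, "sc_id"))] += area_ha
    ledger.veg_cleared[int(_get(unit, "type_id"))] += area_ha
    ledger.catchment_cleared += area_ha
    ledger.event_log.append(ClearingEvent(
        run_id=ledger.run_id,
        step=len(ledger.event_log) + 1,
        prop_id=prop,
        unit_id=int(_get(unit, "unit_id")),
        area_ha=float(area_ha),
    ))
    return ledger


def events_to_frame(events: list[ClearingEvent],
                    landscape: Landscape | None = None) -> pd.DataFrame:
    """Event log as a DataFrame; joining a landscape adds the unit's
    suitability, vegetation type and sub-catchment."""
    df = pd.DataFrame(
        [(e.run_id, e.step, e.prop_id, e.unit_id, e.area_ha) for e in events],
        columns=["run_id", "step", "prop_id", "unit_id", "area_ha"],
    )
    if landscape is not None:
        meta = landscape.units.set_index("unit_id")[
            ["suitability", "type_id", "sc_id"]]
        df = df.join(meta, on="unit_id")
    return df
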