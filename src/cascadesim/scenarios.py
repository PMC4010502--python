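"""Property orderings and per-property clearing-target draws.

Because the caps are nested, the order in which properties take up their
clearing options determines who gets to clear at all: early movers can
exhaust a sub-catchment or vegetation-type cap and lock out their
neighbours.  Four orderings are modelled:

``random``
    Uniform shuffle — the baseline.
``nonaboriginal_large_first``
    Non-aboriginal (private + government) properties from largest to
    smallest, then aboriginal properties largest to smallest.  Reflects no
    short-term development plans on aboriginal land and deep pockets on
    large holdings for environmental impact assessments.
``nonaboriginal_small_first``
    Same tenure partition, both halves smallest to largest — assessments
    as a barrier to large properties instead.
``directed``
    All properties by area-weighted mean suitability, descending,
    regardless of tenure — clearing steered onto the most productive land.

Every selected property draws a clearing target from a uniform
distribution between the guideline lower and upper bounds (30–70% by
default).  The draw is the target *total* cleared fraction of the
property, existing clearing included, so a property already cleared past
its draw clears nothing new.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CapPolicy
from .landscape import Landscape

__all__ = [
    "ORDERINGS",
    "ScenarioSpec",
    "order_properties",
    "property_mean_suitability",
    "property_mean_suitability_all",
    "draw_property_target",
]

ORDERINGS = ("random", "nonaboriginal_large_first",
             "nonaboriginal_small_first", "directed")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: an ordering rule, whether the percentage
    caps apply, the replicate count, and the top-level seed."""

    ordering: str = "random"
    constrained: bool = True
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ordering not in ORDERINGS:
            raise ValueError(f"ordering must be one of {ORDERINGS}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def property_mean_suitability_all(landscape: Landscape) -> pd.Series:
    """Area-weighted mean suitability per property over ALL of the
    property's land, clearable or not (indexed by prop_id)."""
    units = landscape.units
    w = units["area_ha"] * units["suitability"]
    num = w.groupby(units["prop_id"]).sum()
    den = units.groupby("prop_id")["area_ha"].sum()
    return (num / den).astype(float)


def property_mean_suitability(landscape: Landscape, prop_id: int) -> float:
    means = property_mean_suitability_all(landscape)
    if prop_id not in means.index:
        raise KeyError(f"unknown property {prop_id}")
    return float(means.loc[prop_id])


def order_properties(landscape: Landscape, ordering: str,
                     rng: np.random.Generator) -> list[int]:
    """Return a permutation of all property ids under the given rule.

    Ties in size or mean suitability break by ascending prop_id; government
    tenure sorts with the non-aboriginal block.
    """
    props = landscape.properties
    ids = props["prop_id"].astype(int).to_numpy()

    if ordering == "random":
        return [int(i) for i in rng.permutation(np.sort(ids))]

    if ordering == "directed":
        means = property_mean_suitability_all(landscape)
        order = sorted(ids, key=lambda p: (-means.loc[p], p))
        return [int(p) for p in order]

    if ordering in ("nonaboriginal_large_first", "nonaboriginal_small_first"):
        area = dict(zip(ids, props["total_area_ha"].astype(float)))
        abo = set(props.loc[props["tenure"] == "aboriginal", "prop_id"].astype(int))
        non_ab = [p for p in ids if p not in abo]
        ab = [p for p in ids if p in abo]
        if ordering == "nonaboriginal_large_first":
            key = lambda p: (-area[p], p)
        else:
            key = lambda p: (area[p], p)
        return [int(p) for p in sorted(non_ab, key=key) + sorted(ab, key=key)]

    raise ValueError(f"unknown ordering {ordering!r}")


def draw_property_target(rng: np.random.Generator, policy: CapPolicy) -> float:
    """One draw from Uniform[target_lower, target_upper]: the property's
    target total cleared fraction."""
    if policy.target_lower == policy.target_upper:
        return float(policy.target_lower)
    return float(rng.uniform(policy.target_lower, policy.target_upper))
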