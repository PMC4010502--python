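"""Scenario summary statistics.

These reproduce the reporting conventions of catchment-scale clearing
analyses: per-scenario property counts and tenure splits of *new*
clearing, per-sub-catchment and per-vegetation-type cleared percentages
*including* existing clearing (against total area and pre-clearing extent
respectively), rank correlations between scenarios across vegetation
types, the most and least cleared vegetation types, and the share of the
catchment a single property can clear under the property cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import Landscape
from .simulate import RunResult

__all__ = [
    "ScenarioSummary",
    "VegTypeSummary",
    "summarize_properties",
    "percent_cleared_by_subcatchment",
    "percent_cleared_by_vegtype",
    "spearman_matrix",
    "extreme_vegtypes",
    "single_property_share",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ScenarioSummary:
    """Run-averaged property statistics for one scenario.  Cleared areas
    count new (simulated) clearing only; the tenure split sums to the
    total."""

    avg_n_properties_with_clearing: float
    avg_size_of_clearing_properties_ha: float
    avg_total_new_cleared_ha: float
    avg_cleared_aboriginal_ha: float
    avg_cleared_nonaboriginal_ha: float
    avg_selected_property_suitability: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"statistic": list(vars(self)), "value": list(vars(self).values())})


def summarize_properties(results: list[RunResult],
                         landscape: Landscape) -> ScenarioSummary:
    """Average, over runs, the number/size/tenure/suitability statistics of
    properties that cleared land.

    "Properties with clearing" are those with positive new-cleared area in
    a run.  Average suitability is area-weighted over *all* land of the
    selected properties (clearable or not); average size is the mean total
    area of selected properties within a run, then averaged across runs.
    """
    if not results:
        raise ValueError("need at least one run")
    props = landscape.properties.set_index("prop_id")
    units = landscape.units
    suit_num = (units["area_ha"] * units["suitability"]).groupby(
        units["prop_id"]).sum()
    abo = set(props.index[props["tenure"] == "aboriginal"])

    n_sel, sizes, totals, abo_ha, nonabo_ha, suits = [], [], [], [], [], []
    for r in results:
        selected = r.selected_properties()
        n_sel.append(len(selected))
        totals.append(sum(r.property_cleared.values()))
        abo_ha.append(sum(a for p, a in r.property_cleared.items() if p in abo))
        nonabo_ha.append(sum(a for p, a in r.property_cleared.items()
                             if p not in abo))
        if selected:
            sel_area = float(props.loc[selected, "total_area_ha"].sum())
            sizes.append(sel_area / len(selected))
            suits.append(float(suit_num.loc[selected].sum()) / sel_area)

    return ScenarioSummary(
        avg_n_properties_with_clearing=float(np.mean(n_sel)),
        avg_size_of_clearing_properties_ha=float(np.mean(sizes)) if sizes else 0.0,
        avg_total_new_cleared_ha=float(np.mean(totals)),
        avg_cleared_aboriginal_ha=float(np.mean(abo_ha)),
        avg_cleared_nonaboriginal_ha=float(np.mean(nonabo_ha)),
        avg_selected_property_suitability=float(np.mean(suits)) if suits else 0.0,
    )


def percent_cleared_by_subcatchment(results: list[RunResult],
                                    landscape: Landscape) -> pd.DataFrame:
    """Mean percentage cleared per sub-catchment (existing plus new, over
    total sub-catchment area), with the existing-only baseline in a
    ``current_pct`` column and a catchment ``Total`` row appended."""
    if not results:
        raise ValueError("need at least one run")
    units = landscape.units
    sc_area = landscape.sub_catchments.set_index("sc_id")["total_area_ha"]
    existing = (units[units["existing_cleared"] == 1]
                .groupby("sc_id")["area_ha"].sum()
                .reindex(sc_area.index, fill_value=0.0))
    unit_sc = units.set_index("unit_id")["sc_id"]

    per_run = []
    for r in results:
        new = pd.Series(r.unit_cleared, dtype=float)
        new_by_sc = (new.groupby(new.index.map(unit_sc)).sum()
                     .reindex(sc_area.index, fill_value=0.0)
                     if len(new) else pd.Series(0.0, index=sc_area.index))
        per_run.append((existing + new_by_sc) / sc_area * 100.0)
    mean_pct = pd.concat(per_run, axis=1).mean(axis=1)

    out = pd.DataFrame({
        "sc_id": sc_area.index,
        "current_pct": (existing / sc_area * 100.0).values,
        "mean_pct": mean_pct.values,
    })
    catchment = sc_area.sum()
    total_new = np.mean([sum(r.unit_cleared.values()) for r in results])
    out.loc[len(out)] = ["Total", existing.sum() / catchment * 100.0,
                         (existing.sum() + total_new) / catchment * 100.0]
    return out


@dataclass(frozen=True)
class VegTypeSummary:
    per_type: pd.DataFrame          # type_id, current_pct, mean_pct
    mean_pct: float                 # across types
    sd_pct: float                   # across types

    def pct_vector(self) -> pd.Series:
        return self.per_type.set_index("type_id")["mean_pct"]


def percent_cleared_by_vegtype(results: list[RunResult],
                               landscape: Landscape,
                               population_sd: bool = True) -> VegTypeSummary:
    """Mean percentage cleared per vegetation type (existing plus new,
    against the pre-clearing extent), and the mean and standard deviation
    of those percentages across types.

    Types with zero pre-clearing extent are excluded with a warning.  The
    cross-type SD is the population SD by default (``population_sd=False``
    switches to the n-1 sample form).
    """
    if not results:
        raise ValueError("need at least one run")
    vt = landscape.veg_types
    zero = vt[vt["pre_clearing_area_ha"] <= 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} vegetation type(s) with zero "
                      f"pre-clearing extent: {zero['type_id'].tolist()}")
        vt = vt[vt["pre_clearing_area_ha"] > 0]
    pre = vt.set_index("type_id")["pre_clearing_area_ha"]
    existing = vt.set_index("type_id")["existing_cleared_ha"]
    unit_type = landscape.units.set_index("unit_id")["type_id"]

    per_run = []
    for r in results:
        new = pd.Series(r.unit_cleared, dtype=float)
        new_by_type = (new.groupby(new.index.map(unit_type)).sum()
                       .reindex(pre.index, fill_value=0.0)
                       if len(new) else pd.Series(0.0, index=pre.index))
        per_run.append((existing + new_by_type) / pre * 100.0)
    mean_pct = pd.concat(per_run, axis=1).mean(axis=1)

    per_type = pd.DataFrame({
        "type_id": pre.index,
        "current_pct": (existing / pre * 100.0).values,
        "mean_pct": mean_pct.values,
    }).reset_index(drop=True)
    ddof = 0 if population_sd else 1
    return VegTypeSummary(
        per_type=per_type,
        mean_pct=float(mean_pct.mean()),
        sd_pct=float(mean_pct.std(ddof=ddof)),
    )


def spearman_matrix(vectors: dict[str, pd.Series | np.ndarray]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations (average ranks on ties) between
    per-type cleared-percentage vectors, one per scenario.

    Returns (rho, p) DataFrames with unit diagonal.  A constant vector has
    undefined rank correlation and yields NaN against every other vector.
    """
    names = list(vectors)
    arrays = {k: np.asarray(vectors[k], dtype=float) for k in names}
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("all vectors must have equal length")
    (n,) = lengths
    if n < 3:
        raise ValueError("need vectors of length >= 3")
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))),
                        index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if np.ptp(arrays[a]) == 0 or np.ptp(arrays[b]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(arrays[a], arrays[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def extreme_vegtypes(per_type_pct: pd.Series, k: int = 5
                     ) -> tuple[pd.Series, pd.Series]:
    """The k most and k least cleared vegetation types (ties broken by
    ascending type_id).  ``per_type_pct`` is indexed by type_id."""
    if k > len(per_type_pct):
        raise ValueError(f"k={k} exceeds the number of types ({len(per_type_pct)})")
    df = per_type_pct.rename("pct").rename_axis("type_id").reset_index()
    top = df.sort_values(["pct", "type_id"], ascending=[False, True],
                         kind="mergesort").head(k)
    bottom = df.sort_values(["pct", "type_id"], ascending=[True, True],
                            kind="mergesort").head(k)
    return (top.set_index("type_id")["pct"], bottom.set_index("type_id")["pct"])


def single_property_share(property_area_ha: float, catchment_area_ha: float,
                          property_cap: float,
                          catchment_cap: float = 0.20) -> tuple[float, float]:
    """How much of the catchment one property can clear on its own.

    Returns ``(pct_of_catchment, pct_of_catchment_cap)``: the property cap
    applied to the property's area as a percentage of the catchment, and
    that figure as a percentage of the catchment-wide clearing cap.  The
    largest holding in a catchment can command a strikingly large slice of
    the total allowance.
    """
    if property_area_ha <= 0 or catchment_area_ha <= 0:
        raise ValueError("areas must be positive")
    if not (0 < property_cap <= 1) or not (0 < catchment_cap <= 1):
        raise ValueError("caps must be in (0, 1]")
    pct_catchment = property_cap * property_area_ha / catchment_area_ha * 100.0
    pct_of_cap = pct_catchment / (catchment_cap * 100.0) * 100.0
    return pct_catchment, pct_of_cap
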