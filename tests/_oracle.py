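"""Naive brute-force reimplementation of the clearing loop, used as an
independent oracle.

Every headroom is recomputed from scratch by summing the full unit table
and event list at every step — no ledger, no caching — so agreement with
the engine is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def naive_run(landscape, policy, order_targets):
    """Simulate clearing for (prop_id, target_fraction) pairs in order.

    Returns a list of (prop_id, unit_id, area_ha) events.
    """
    units = {int(r.unit_id): r._asdict()
             for r in landscape.units.itertuples(index=False)}
    prop_area = dict(zip(landscape.properties["prop_id"].astype(int),
                         landscape.properties["total_area_ha"].astype(float)))
    sc_area = dict(zip(landscape.sub_catchments["sc_id"].astype(int),
                       landscape.sub_catchments["total_area_ha"].astype(float)))
    veg_pre = dict(zip(landscape.veg_types["type_id"].astype(int),
                       landscape.veg_types["pre_clearing_area_ha"].astype(float)))
    catchment_area = float(landscape.sub_catchments["total_area_ha"].sum())
    events: list[tuple[int, int, float]] = []

    def cleared(key=None, value=None):
        s = 0.0
        for u in units.values():
            if u["existing_cleared"] and (key is None or u[key] == value):
                s += u["area_ha"]
        for _, uid, a in events:
            if key is None or units[uid][key] == value:
                s += a
        return s

    for prop_id, target in order_targets:
        if policy.constrained and \
                cleared() >= policy.catchment_cap * catchment_area - 1e-6:
            break
        remaining = target * prop_area[prop_id] - cleared("prop_id", prop_id)
        clearable = [u for u in units.values()
                     if u["prop_id"] == prop_id and not u["buffered"]
                     and not u["protected"] and not u["existing_cleared"]
                     and u["suitability"] > 0]
        clearable.sort(key=lambda u: (-u["suitability"], u["type_id"],
                                      u["unit_id"]))
        for u in clearable:
            if remaining <= 1e-6:
                break
            allow = min(u["area_ha"], remaining)
            if policy.constrained:
                allow = min(
                    allow,
                    max(0.0, policy.property_cap * prop_area[prop_id]
                        - cleared("prop_id", prop_id)),
                    max(0.0, policy.subcatchment_cap * sc_area[u["sc_id"]]
                        - cleared("sc_id", u["sc_id"])),
                    max(0.0, policy.vegetation_cap * veg_pre[u["type_id"]]
                        - cleared("type_id", u["type_id"])),
                )
                if policy.overshoot_mode == "truncate":
                    allow = min(allow, max(0.0, policy.catchment_cap
                                           * catchment_area - cleared()))
            if allow > 1e-6:
                events.append((prop_id, int(u["unit_id"]), float(allow)))
                remaining -= allow
    return events


def naive_spearman(x, y):
    """Spearman's rho with average ranks on ties, from first principles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average of positions
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)
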