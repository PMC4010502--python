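"""Seeded synthetic landscapes with the Daly catchment's statistical shape.

The generator emulates the tabular structure of the real catchment: about
5.2 Mha, 13% protected, the available remainder split 10/30/60 between
government, aboriginal and private tenure, a few hundred properties with a
heavy-tailed size distribution (100–400,000 ha, mean ~15,000 ha) spanning
at most two of 16 sub-catchments, 98 vegetation types nested in 15 broad
groups, 5.4% existing clearing concentrated on a minority of properties
(per-property 1–100% cleared, mean ~25%), stream/wetland buffer zones, and
a 0–400 suitability index whose zero mass and catchment mean are tuned so
that ~44% of the catchment is clearable and mean suitability is ~178.

No spatial autocorrelation is modelled: the cascade rules never consult
adjacency, so only the joint distribution of suitability, vegetation,
tenure and sub-catchment matters.  Entity-level totals are derived from
the generated unit table, so every conservation invariant holds by
construction, and all areas are quantised to 1e-6 ha so that written CSV
files are byte-identical across runs with the same seed.

Three tiny deterministic fixtures (``tiny3``, ``capbound``,
``singleprop``) with hand-specified areas are provided for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import (Landscape, LandscapeError, build_landscape,
                        UNIT_COLUMNS, UNIT_KEY)

__all__ = [
    "GeneratorConfig",
    "generate_landscape",
    "generate_fixture",
    "audit_generated",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("tiny3", "capbound", "singleprop")

#: Broad vegetation-group labels typical of north-Australian savanna mapping.
GROUP_NAMES = [
    "Closed Forest", "Eucalypt Woodland", "Mixed Woodland",
    "E. miniata / E. tetrodonta", "Eucalypt Open Woodland",
    "Sandstone Plateau Open Woodland", "Lancewood", "Melaleuca Woodland",
    "Alluvial Woodland", "Non-eucalypt Low Woodland", "Shrubland",
    "Grassland", "Littoral", "Riparian Forest", "Floodplain Wetland",
]

_MIN_PARCEL_HA = 50.0   # avoid sliver parcels when splitting across sub-catchments
_MIN_PIECE_HA = 1e-4    # pieces below this are dropped outright


@dataclass(frozen=True)
class GeneratorConfig:
    """Targets and laws for the synthetic landscape.

    The defaults are the catchment-scale conditions of the study system;
    ``audit_generated`` reports realised-versus-target statistics and
    flags any relative error above 10%.
    """

    catchment_area_ha: float = 5.2e6
    protected_fraction: float = 0.13
    tenure_mix: Mapping[str, float] = field(default_factory=lambda: {
        "government": 0.10, "aboriginal": 0.30, "private": 0.60})
    n_properties: int = 347
    property_size_mean_ha: float = 15_000.0
    property_size_sigma: float = 1.4
    property_size_min_ha: float = 100.0
    property_size_max_ha: float = 400_000.0
    n_subcatchments: int = 16
    n_veg_types: int = 98
    n_veg_groups: int = 15
    existing_cleared_fraction: float = 0.054
    cleared_fraction_min: float = 0.01
    cleared_fraction_max: float = 1.00
    cleared_beta_a: float = 2.0
    cleared_beta_b: float = 6.0
    buffered_fraction: float = 0.08
    mean_suitability: float = 178.0
    clearable_fraction: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "protected_fraction": self.protected_fraction,
            "existing_cleared_fraction": self.existing_cleared_fraction,
            "buffered_fraction": self.buffered_fraction,
            "clearable_fraction": self.clearable_fraction,
        }
        for name, f in fracs.items():
            if not (0 <= f <= 1):
                raise LandscapeError(f"{name}={f} outside [0, 1]")
        if abs(sum(self.tenure_mix.values()) - 1.0) > 1e-9:
            raise LandscapeError("tenure_mix fractions must sum to 1")
        if set(self.tenure_mix) != {"government", "aboriginal", "private"}:
            raise LandscapeError("tenure_mix must give government, aboriginal "
                                 "and private shares")
        if self.n_veg_types < self.n_veg_groups:
            raise LandscapeError("n_veg_types must be >= n_veg_groups")
        if self.n_properties * self.property_size_min_ha > self.catchment_area_ha:
            raise LandscapeError(
                "infeasible: n_properties x minimum property size exceeds the "
                "catchment area")
        if self.n_properties * self.property_size_max_ha < self.catchment_area_ha:
            raise LandscapeError(
                "infeasible: n_properties x maximum property size cannot tile "
                "the catchment")
        avail = (1.0 - self.protected_fraction - self.existing_cleared_fraction
                 - self.buffered_fraction)
        if self.clearable_fraction > avail + 1e-9:
            raise LandscapeError(
                f"clearable_fraction {self.clearable_fraction} exceeds the land "
                f"left after protection, buffers and existing clearing ({avail:.3f})")

    @property
    def zero_suitability_fraction(self) -> float:
        """Share of available (unprotected, unbuffered, uncleared) land at
        suitability 0, implied by the clearable-fraction target."""
        avail = (1.0 - self.protected_fraction - self.existing_cleared_fraction
                 - self.buffered_fraction)
        if avail <= 0:
            return 0.0
        return max(0.0, 1.0 - self.clearable_fraction / avail)

    @property
    def nonzero_suitability_mean(self) -> float:
        p0 = self.zero_suitability_fraction
        mu = self.mean_suitability / max(1e-12, 1.0 - p0)
        if not (1.0 < mu < 400.0):
            raise LandscapeError(
                f"mean_suitability {self.mean_suitability} is unattainable with "
                f"a zero-suitability share of {p0:.3f}")
        return mu

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise LandscapeError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


# ---------------------------------------------------------------------------
# helpers

def _fit_partition(raw: np.ndarray, total: float, lo: float, hi: float) -> np.ndarray:
    """Rescale positive draws to sum to ``total`` while respecting [lo, hi]
    per element (iterative proportional redistribution)."""
    n = len(raw)
    if not (n * lo <= total <= n * hi):
        raise LandscapeError(
            f"cannot partition {total:.0f} into {n} parts within [{lo}, {hi}]")
    x = raw * (total / raw.sum())
    x = np.clip(x, lo, hi)
    for _ in range(500):
        deficit = total - x.sum()
        if abs(deficit) <= 1e-9 * max(total, 1.0):
            break
        free = (x < hi - 1e-9) if deficit > 0 else (x > lo + 1e-9)
        if not free.any():
            break
        x[free] += deficit * (x[free] / x[free].sum())
        x = np.clip(x, lo, hi)
    return x


def _quantise(x: np.ndarray | float, decimals: int = 6):
    return np.round(x, decimals)


def _suit_pieces(rng: np.random.Generator, area: float, p0: float,
                 alpha: float, beta: float,
                 chunk_ha: float = 10_000.0) -> list[tuple[int, float]]:
    """Split an area into suitability pieces: a deterministic zero-index
    share of ``p0`` plus nonzero draws in chunks of at most ``chunk_ha``
    (stratifying the draws keeps the area-weighted mean suitability stable
    even for very large single pools)."""
    pieces: list[tuple[int, float]] = []
    zero = p0 * area
    if zero > _MIN_PIECE_HA:
        pieces.append((0, zero))
    nz = area - zero
    if nz > _MIN_PIECE_HA:
        m = max(1, int(np.ceil(nz / chunk_ha)))
        for a in np.full(m, nz / m):
            s = int(np.clip(1 + round(399 * rng.beta(alpha, beta)), 1, 400))
            pieces.append((s, float(a)))
    return pieces


def _suit_beta_params(config: GeneratorConfig) -> tuple[float, float]:
    mu = config.nonzero_suitability_mean
    frac = (mu - 1.0) / 399.0
    alpha = 2.2
    beta = alpha * (1.0 - frac) / frac
    return alpha, beta


# ---------------------------------------------------------------------------
# generator

def generate_landscape(config: GeneratorConfig) -> Landscape:
    """Generate a synthetic landscape; identical seeds give identical
    landscapes (and byte-identical CSV files once written)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_properties
    total_area = config.catchment_area_ha

    # --- property sizes: truncated log-normal rescaled to tile the catchment
    sigma = config.property_size_sigma
    mu = np.log(config.property_size_mean_ha) - sigma**2 / 2.0
    raw = rng.lognormal(mu, sigma, size=n)
    sizes = _fit_partition(np.clip(raw, config.property_size_min_ha,
                                   config.property_size_max_ha),
                           total_area, config.property_size_min_ha,
                           config.property_size_max_ha)
    sizes = _quantise(sizes)
    prop_ids = np.arange(1, n + 1)

    # --- protected land: a handful of large reserves, size-weighted
    prot_frac = np.zeros(n)
    remaining = config.protected_fraction * total_area
    if remaining > 0:
        weighted_order = rng.choice(n, size=n, replace=False, p=sizes / sizes.sum())
        for i in weighted_order:
            if remaining <= 1e-6:
                break
            amount = min(rng.uniform(0.5, 1.0) * sizes[i], remaining)
            prot_frac[i] = amount / sizes[i]
            remaining -= amount

    # --- existing clearing: a minority of properties, 1-100% each, mean ~25%
    clr_frac = np.zeros(n)
    remaining = config.existing_cleared_fraction * total_area
    lo, hi = config.cleared_fraction_min, config.cleared_fraction_max
    if remaining > 0:
        for i in rng.permutation(n):
            if remaining <= 1e-6:
                break
            headroom = 1.0 - prot_frac[i]
            if headroom < lo:
                continue
            f = lo + (hi - lo) * rng.beta(config.cleared_beta_a,
                                          config.cleared_beta_b)
            f = min(f, headroom)
            if f * sizes[i] > remaining:       # final property: land on target
                f = remaining / sizes[i]
                if f < lo:
                    break
            clr_frac[i] = f
            remaining -= f * sizes[i]

    # --- tenure: largest-available-first greedy against the mix targets
    avail = sizes * (1.0 - prot_frac)
    demand = {t: s * avail.sum() for t, s in config.tenure_mix.items()}
    tenure: dict[int, str] = {}
    for i in np.argsort(-avail, kind="stable"):
        t = max(sorted(demand), key=lambda k: demand[k])
        tenure[int(prop_ids[i])] = t
        demand[t] -= avail[i]

    # --- sub-catchments: Dirichlet areas; each property spans at most two
    sc_ids = np.arange(1, config.n_subcatchments + 1)
    sc_targets = rng.dirichlet(np.full(config.n_subcatchments, 2.0)) * total_area
    sc_remaining = sc_targets.copy()
    parcels: list[tuple[int, int, float]] = []  # (property index, sc index, area)
    queue = list(rng.permutation(n))

    # anchor one fitting property in every sub-catchment first
    for sc in np.argsort(sc_targets):
        pick = next((j for j in queue if sizes[j] <= sc_remaining[sc]), None)
        if pick is None:
            pick = min(queue, key=lambda j: sizes[j])
        queue.remove(pick)
        parcels.append((pick, int(sc), float(sizes[pick])))
        sc_remaining[sc] -= sizes[pick]

    for j in queue:
        a = float(sizes[j])
        fits = np.flatnonzero(sc_remaining >= a)
        if fits.size:
            p = sc_remaining[fits]
            sc = int(rng.choice(fits, p=p / p.sum()))
            parcels.append((j, sc, a))
            sc_remaining[sc] -= a
        else:
            sc1 = int(np.argmax(sc_remaining))
            first = float(max(sc_remaining[sc1], _MIN_PARCEL_HA))
            if a - first < _MIN_PARCEL_HA:
                parcels.append((j, sc1, a))
                sc_remaining[sc1] -= a
            else:
                first = float(_quantise(first))
                parcels.append((j, sc1, first))
                sc_remaining[sc1] -= first
                rest = a - first
                sc_remaining[sc1] -= 0.0
                order = np.argsort(-sc_remaining)
                sc2 = int(order[0]) if int(order[0]) != sc1 else int(order[1])
                parcels.append((j, sc2, rest))
                sc_remaining[sc2] -= rest

    # --- vegetation catalogue: 98 types nested in 15 groups
    n_g, n_t = config.n_veg_groups, config.n_veg_types
    group_w = rng.dirichlet(np.full(n_g, 1.5))
    extra = rng.multinomial(n_t - n_g, group_w)
    type_groups: dict[int, int] = {}
    type_w = np.empty(n_t)
    tid = 1
    for g in range(n_g):
        count = 1 + int(extra[g])
        within = rng.dirichlet(np.full(count, 1.0))
        for k in range(count):
            type_groups[tid] = g + 1
            type_w[tid - 1] = group_w[g] * within[k]
            tid += 1

    # --- pools -> pieces
    prot_total = float((prot_frac * sizes).sum())
    clr_total = float((clr_frac * sizes).sum())
    rem_total = total_area - prot_total - clr_total
    b_star = min(1.0, config.buffered_fraction * total_area / max(rem_total, 1e-9))
    p0 = config.zero_suitability_fraction
    s_alpha, s_beta = _suit_beta_params(config)

    rows: list[tuple] = []  # prop_id, sc_id, type_id, suit, area, buf, prot, clr

    def _pick_type(chosen: np.ndarray, shares: np.ndarray) -> int:
        return int(chosen[rng.choice(len(chosen), p=shares)])

    for j, sc, area in parcels:
        pid = int(prop_ids[j])
        scid = int(sc_ids[sc])
        if area < 500:
            k = 1
        elif area < 5000:
            k = 2
        else:
            k = int(rng.integers(2, 5))
        chosen = rng.choice(n_t, size=k, replace=False, p=type_w) + 1
        shares = rng.dirichlet(np.full(k, 2.0))

        prot_a = prot_frac[j] * area
        clr_a = clr_frac[j] * area
        rem = area - prot_a - clr_a
        buf_a = b_star * rem
        avail_a = rem - buf_a

        for pool, flags in ((prot_a, (0, 1, 0)), (clr_a, (0, 0, 1)),
                            (buf_a, (1, 0, 0))):
            if pool > _MIN_PIECE_HA:
                t = _pick_type(chosen, shares)
                for s, a_k in _suit_pieces(rng, pool, p0, s_alpha, s_beta):
                    rows.append((pid, scid, t, s, a_k, *flags))
        for t, share in zip(chosen, shares):
            ta = avail_a * share
            if ta > _MIN_PIECE_HA:
                for s, a_k in _suit_pieces(rng, ta, p0, s_alpha, s_beta):
                    rows.append((pid, scid, int(t), s, a_k, 0, 0, 0))

    units = pd.DataFrame(rows, columns=["prop_id", "sc_id", "type_id",
                                        "suitability", "area_ha", "buffered",
                                        "protected", "existing_cleared"])

    # guarantee full vegetation coverage: split a large piece for any type
    # that no parcel happened to pick
    missing = sorted(set(type_groups) - set(units["type_id"]))
    if missing:
        counts = units["type_id"].value_counts()
        rich = units[units["type_id"].map(counts) >= 4]
        donors = rich.sort_values("area_ha", ascending=False).index[:len(missing)]
        for t, idx in zip(missing, donors):
            half = float(units.at[idx, "area_ha"]) / 2.0
            units.at[idx, "area_ha"] = half
            clone = units.loc[idx].copy()
            clone["type_id"] = t
            units = pd.concat([units, clone.to_frame().T], ignore_index=True)

    units["area_ha"] = _quantise(units["area_ha"].astype(float))
    units = units[units["area_ha"] > 0]
    units = (units.groupby(["prop_id", "sc_id", "type_id", "suitability",
                            "buffered", "protected", "existing_cleared"],
                           as_index=False)["area_ha"].sum())
    units = units.sort_values(["prop_id", "sc_id", "type_id", "suitability"],
                              ascending=[True, True, True, False],
                              kind="mergesort").reset_index(drop=True)
    units.insert(0, "unit_id", np.arange(1, len(units) + 1))

    names = {g + 1: GROUP_NAMES[g % len(GROUP_NAMES)] for g in range(n_g)}
    return build_landscape(units, tenure, type_groups, names,
                           sub_catchment_ids=sc_ids)


# ---------------------------------------------------------------------------
# deterministic fixtures

def generate_fixture(name: str) -> Landscape:
    """Tiny hand-specified landscapes with exact printed areas.

    ``tiny3``
        Three properties (two private, one aboriginal spanning both
        sub-catchments) totalling 10,000 ha, two vegetation types, one
        buffered unit, 1,000 ha of existing clearing.
    ``capbound``
        Two sub-catchments; the first starts at 60% cleared — above the
        40% sub-catchment cap — so it must receive no new clearing.
    ``singleprop``
        One 1,000 ha property with a single suitability-200 unit.
    """
    cols = UNIT_COLUMNS  # unit_id, prop_id, sc_id, type_id, suitability, area,...
    if name == "tiny3":
        data = [
            (1,  1, 1, 1, 300, 1000.0, 0, 0, 0),
            (2,  1, 1, 2, 100,  800.0, 0, 0, 0),
            (3,  1, 1, 1,   0,  200.0, 0, 0, 0),
            (4,  2, 1, 2, 250, 1000.0, 0, 0, 0),
            (5,  2, 2, 1, 250,  500.0, 0, 0, 0),
            (6,  2, 2, 2,  50, 1000.0, 0, 0, 0),
            (7,  2, 2, 1, 200,  500.0, 1, 0, 0),
            (8,  3, 2, 1, 150, 1000.0, 0, 0, 1),
            (9,  3, 2, 1, 350, 2000.0, 0, 0, 0),
            (10, 3, 2, 2,   0, 1500.0, 0, 0, 0),
            (11, 3, 2, 2, 150,  500.0, 0, 0, 0),
        ]
        tenures = {1: "private", 2: "aboriginal", 3: "private"}
        type_groups = {1: 1, 2: 1}
    elif name == "capbound":
        data = [
            (1, 1, 1, 1, 180,  600.0, 0, 0, 1),
            (2, 1, 1, 1, 300,  400.0, 0, 0, 0),
            (3, 2, 2, 1, 250, 4000.0, 0, 0, 0),
            (4, 2, 2, 2, 100, 5000.0, 0, 0, 0),
        ]
        tenures = {1: "private", 2: "private"}
        type_groups = {1: 1, 2: 1}
    elif name == "singleprop":
        data = [(1, 1, 1, 1, 200, 1000.0, 0, 0, 0)]
        tenures = {1: "private"}
        type_groups = {1: 1}
    else:
        raise LandscapeError(f"unknown fixture {name!r}; "
                             f"choose from {FIXTURE_NAMES}")
    units = pd.DataFrame(data, columns=cols)
    return build_landscape(units, tenures, type_groups,
                           {1: GROUP_NAMES[1]})


# ---------------------------------------------------------------------------
# audit

def audit_generated(landscape: Landscape, config: GeneratorConfig,
                    flag_rel_error: float = 0.10) -> pd.DataFrame:
    """Realised-versus-target statistics for a generated landscape.

    Returns a DataFrame with columns ``statistic, target, realized,
    rel_error, flag``; ``flag`` marks relative errors above
    ``flag_rel_error``.
    """
    units = landscape.units
    area = float(units["area_ha"].sum())
    prot = float(units.loc[units["protected"] == 1, "area_ha"].sum())
    buf = float(units.loc[units["buffered"] == 1, "area_ha"].sum())
    clr = float(units.loc[units["existing_cleared"] == 1, "area_ha"].sum())
    clearable_mask = ((units["buffered"] == 0) & (units["protected"] == 0)
                      & (units["existing_cleared"] == 0)
                      & (units["suitability"] > 0))
    clearable = float(units.loc[clearable_mask, "area_ha"].sum())
    mean_suit = float((units["area_ha"] * units["suitability"]).sum() / area)

    props = landscape.properties
    avail_by_prop = (units[units["protected"] == 0]
                     .groupby("prop_id")["area_ha"].sum())
    tenure_avail = {t: 0.0 for t in config.tenure_mix}
    for _, p in props.iterrows():
        tenure_avail[p["tenure"]] = tenure_avail.get(p["tenure"], 0.0) + \
            float(avail_by_prop.get(p["prop_id"], 0.0))
    avail_total = sum(tenure_avail.values())

    clearing = props[props["existing_cleared_ha"] > 1e-6]
    mean_clr_frac = float((clearing["existing_cleared_ha"]
                           / clearing["total_area_ha"]).mean()) if len(clearing) else 0.0

    rows = [
        ("protected_fraction", config.protected_fraction, prot / area),
        ("buffered_fraction", config.buffered_fraction, buf / area),
        ("existing_cleared_fraction", config.existing_cleared_fraction, clr / area),
        ("clearable_fraction", config.clearable_fraction, clearable / area),
        ("mean_suitability", config.mean_suitability, mean_suit),
        ("mean_property_size_ha", config.property_size_mean_ha,
         area / len(props)),
        ("mean_cleared_property_fraction",
         config.cleared_fraction_min + (config.cleared_fraction_max
                                        - config.cleared_fraction_min)
         * config.cleared_beta_a / (config.cleared_beta_a + config.cleared_beta_b),
         mean_clr_frac),
        ("n_properties", config.n_properties, len(props)),
        ("n_subcatchments", config.n_subcatchments,
         len(landscape.sub_catchments)),
        ("n_veg_types", config.n_veg_types,
         int((landscape.veg_types["pre_clearing_area_ha"] > 0).sum())),
        ("n_veg_groups", config.n_veg_groups, len(landscape.veg_groups)),
    ]
    for t in sorted(config.tenure_mix):
        rows.append((f"tenure_{t}_fraction", config.tenure_mix[t],
                     tenure_avail.get(t, 0.0) / max(avail_total, 1e-9)))

    df = pd.DataFrame(rows, columns=["statistic", "target", "realized"])
    df["rel_error"] = (df["realized"] - df["target"]).abs() / df["target"].abs()
    df["flag"] = df["rel_error"] > flag_rel_error
    return df
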