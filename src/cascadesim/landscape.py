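"""Tabular landscape model for clearing-cap simulation.

The atomic record is a *land unit*: a slice of one property that is
homogeneous in sub-catchment, vegetation type, suitability index and
clearing status.  All policy arithmetic in this package is area-based;
no geometry (polygons, rasters, projections) is carried.

Table schemas
-------------
``units``
    unit_id, prop_id, sc_id, type_id, suitability, area_ha,
    buffered (0/1), protected (0/1), existing_cleared (0/1)
``properties``
    prop_id, tenure {aboriginal, private, government}, total_area_ha,
    existing_cleared_ha (derived from units)
``sub_catchments``
    sc_id, total_area_ha, reserve_fraction, aboriginal_fraction
``veg_types``
    type_id, group_id, pre_clearing_area_ha, existing_cleared_ha (derived)
``veg_groups``
    group_id, name, pre_clearing_area_ha, cleared_area_ha

Pre-clearing extents are the denominators of the vegetation-type caps:
every unit of a vegetation type counts toward its pre-clearing extent,
whether or not the unit is currently cleared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REL_TOL",
    "TENURES",
    "SuitabilityProfile",
    "VegetationGroup",
    "VegetationType",
    "Landscape",
    "LandscapeError",
    "ParseError",
    "compute_suitability_index",
    "allocate_group_clearing_to_types",
    "build_landscape",
    "validate_landscape",
    "load_landscape",
    "write_landscape",
]

#: Relative tolerance used in all area-conservation checks.
REL_TOL = 1e-6

TENURES = ("aboriginal", "private", "government")

UNIT_COLUMNS = [
    "unit_id", "prop_id", "sc_id", "type_id", "suitability",
    "area_ha", "buffered", "protected", "existing_cleared",
]
UNIT_KEY = [
    "prop_id", "sc_id", "type_id", "suitability",
    "buffered", "protected", "existing_cleared",
]


class LandscapeError(ValueError):
    """Invalid landscape data or configuration."""


class ParseError(LandscapeError):
    """Malformed landscape file."""


@dataclass(frozen=True)
class SuitabilityProfile:
    """Percent suitability of a land system for the four assessed land uses.

    The four uses are improved pasture, irrigated field crops / perennial
    horticulture, irrigated annual horticulture, and rainfed field crops /
    perennial horticulture.  Each field is a percentage in [0, 100].
    """

    pasture_pct: float
    irrigated_crop_perennial_pct: float
    irrigated_annual_hort_pct: float
    rainfed_crop_perennial_pct: float

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not (0 <= value <= 100):
                raise LandscapeError(
                    f"SuitabilityProfile.{name}={value!r} outside [0, 100]"
                )


@dataclass
class VegetationGroup:
    """Broad vegetation group carrying the pre-clearing baseline."""

    group_id: int
    name: str
    pre_clearing_area_ha: float
    cleared_area_ha: float = 0.0


@dataclass
class VegetationType:
    """Mapped vegetation type, nested in exactly one broad group."""

    type_id: int
    group_id: int
    pre_clearing_area_ha: float
    existing_cleared_ha: float = 0.0


def compute_suitability_index(profile: SuitabilityProfile) -> float:
    """Overall clearing-suitability index: the sum of the four use-specific
    percent suitabilities.

    Ranges from 0 (completely unsuitable for every use) to 400 (completely
    suitable for every use).  Values above 100 indicate flexibility across
    multiple uses and hence relative demand for clearing.
    """
    return (
        profile.pasture_pct
        + profile.irrigated_crop_perennial_pct
        + profile.irrigated_annual_hort_pct
        + profile.rainfed_crop_perennial_pct
    )


def allocate_group_clearing_to_types(
    group: VegetationGroup,
    types: Sequence[VegetationType],
    rel_tol: float = REL_TOL,
) -> list[VegetationType]:
    """Distribute a group's cleared area uniformly over its member types.

    Vegetation mapping often lacks a type-level pre-clearing product; the
    group-level cleared area is then assumed to apply at a uniform rate to
    every member type, so each type receives
    ``pre_clearing * (group cleared / group pre-clearing)``.

    Returns new :class:`VegetationType` records with ``existing_cleared_ha``
    set; their sum equals ``group.cleared_area_ha`` exactly up to float
    rounding.
    """
    if group.pre_clearing_area_ha <= 0:
        raise LandscapeError(
            f"group {group.group_id}: pre-clearing area must be positive"
        )
    for t in types:
        if t.group_id != group.group_id:
            raise LandscapeError(
                f"type {t.type_id}: belongs to group {t.group_id}, "
                f"not {group.group_id}"
            )
    type_total = sum(t.pre_clearing_area_ha for t in types)
    if not np.isclose(type_total, group.pre_clearing_area_ha,
                      rtol=rel_tol, atol=0.0):
        raise LandscapeError(
            f"group {group.group_id}: member type pre-clearing areas sum to "
            f"{type_total:.6f} ha, expected {group.pre_clearing_area_ha:.6f} ha"
        )
    rate = group.cleared_area_ha / group.pre_clearing_area_ha
    return [replace(t, existing_cleared_ha=t.pre_clearing_area_ha * rate)
            for t in types]


@dataclass
class Landscape:
    """A complete tabular landscape (units plus entity tables)."""

    units: pd.DataFrame
    properties: pd.DataFrame
    sub_catchments: pd.DataFrame
    veg_types: pd.DataFrame
    veg_groups: pd.DataFrame

    @property
    def catchment_area_ha(self) -> float:
        return float(self.sub_catchments["total_area_ha"].sum())

    @property
    def existing_cleared_ha(self) -> float:
        mask = self.units["existing_cleared"] == 1
        return float(self.units.loc[mask, "area_ha"].sum())

    def copy(self) -> "Landscape":
        return Landscape(
            units=self.units.copy(),
            properties=self.properties.copy(),
            sub_catchments=self.sub_catchments.copy(),
            veg_types=self.veg_types.copy(),
            veg_groups=self.veg_groups.copy(),
        )

    def equals(self, other: "Landscape") -> bool:
        """Equality up to the 6-decimal quantisation applied when writing
        CSV files (integer and string columns must match exactly)."""
        pairs = [
            (self.units, other.units),
            (self.properties, other.properties),
            (self.sub_catchments, other.sub_catchments),
            (self.veg_types, other.veg_types),
            (self.veg_groups, other.veg_groups),
        ]
        for a, b in pairs:
            a = a.reset_index(drop=True)
            b = b.reset_index(drop=True)
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for col in a.columns:
                if a[col].dtype.kind == "f":
                    if not np.allclose(a[col], b[col], rtol=1e-9, atol=5e-7):
                        return False
                elif not a[col].equals(b[col]):
                    return False
        return True


def _normalise_units(units: pd.DataFrame) -> pd.DataFrame:
    units = units[UNIT_COLUMNS].copy()
    for col in ("unit_id", "prop_id", "sc_id", "type_id", "suitability",
                "buffered", "protected", "existing_cleared"):
        units[col] = units[col].astype(np.int64)
    units["area_ha"] = units["area_ha"].astype(float)
    return units.sort_values("unit_id", kind="mergesort").reset_index(drop=True)


def build_landscape(
    units: pd.DataFrame,
    tenures: Mapping[int, str],
    type_groups: Mapping[int, int],
    group_names: Mapping[int, str] | None = None,
    sub_catchment_ids: Iterable[int] | None = None,
) -> Landscape:
    """Assemble a :class:`Landscape` from a unit table, deriving every
    entity-level total by aggregation so that the conservation invariants
    hold by construction.

    ``tenures`` maps prop_id -> tenure; ``type_groups`` maps type_id ->
    group_id (and defines the full vegetation catalogue, including types
    that happen to have zero mapped area).
    """
    units = _normalise_units(units)

    unknown_tenure = set(tenures.values()) - set(TENURES)
    if unknown_tenure:
        raise LandscapeError(f"unknown tenure values: {sorted(unknown_tenure)}")
    missing_props = set(units["prop_id"]) - set(tenures)
    if missing_props:
        raise LandscapeError(f"units reference properties without tenure: "
                             f"{sorted(missing_props)[:5]}")
    missing_types = set(units["type_id"]) - set(type_groups)
    if missing_types:
        raise LandscapeError(f"units reference unknown vegetation types: "
                             f"{sorted(missing_types)[:5]}")

    cleared = units[units["existing_cleared"] == 1]

    prop_area = units.groupby("prop_id")["area_ha"].sum()
    prop_cleared = cleared.groupby("prop_id")["area_ha"].sum()
    properties = pd.DataFrame({
        "prop_id": prop_area.index,
        "tenure": [tenures[p] for p in prop_area.index],
        "total_area_ha": prop_area.values,
        "existing_cleared_ha": prop_cleared.reindex(prop_area.index, fill_value=0.0).values,
    }).reset_index(drop=True)

    sc_area = units.groupby("sc_id")["area_ha"].sum()
    if sub_catchment_ids is not None:
        sc_area = sc_area.reindex(sorted(sub_catchment_ids), fill_value=0.0)
    prot = units[units["protected"] == 1].groupby("sc_id")["area_ha"].sum()
    abo_props = {p for p, t in tenures.items() if t == "aboriginal"}
    abo = units[units["prop_id"].isin(abo_props)].groupby("sc_id")["area_ha"].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        reserve_frac = (prot.reindex(sc_area.index, fill_value=0.0) / sc_area).fillna(0.0)
        abo_frac = (abo.reindex(sc_area.index, fill_value=0.0) / sc_area).fillna(0.0)
    sub_catchments = pd.DataFrame({
        "sc_id": sc_area.index,
        "total_area_ha": sc_area.values,
        "reserve_fraction": reserve_frac.values,
        "aboriginal_fraction": abo_frac.values,
    }).reset_index(drop=True)

    all_types = sorted(type_groups)
    type_area = units.groupby("type_id")["area_ha"].sum().reindex(all_types, fill_value=0.0)
    type_cleared = cleared.groupby("type_id")["area_ha"].sum().reindex(all_types, fill_value=0.0)
    veg_types = pd.DataFrame({
        "type_id": all_types,
        "group_id": [type_groups[t] for t in all_types],
        "pre_clearing_area_ha": type_area.values,
        "existing_cleared_ha": type_cleared.values,
    })

    group_pre = veg_types.groupby("group_id")["pre_clearing_area_ha"].sum()
    group_clr = veg_types.groupby("group_id")["existing_cleared_ha"].sum()
    names = group_names or {}
    veg_groups = pd.DataFrame({
        "group_id": group_pre.index,
        "name": [names.get(g, f"veg_group_{g:02d}") for g in group_pre.index],
        "pre_clearing_area_ha": group_pre.values,
        "cleared_area_ha": group_clr.values,
    }).reset_index(drop=True)

    return Landscape(units, properties, sub_catchments, veg_types, veg_groups)


def _check_close(a: float, b: float, rel_tol: float = REL_TOL) -> bool:
    return bool(np.isclose(a, b, rtol=rel_tol, atol=1e-6))


def validate_landscape(landscape: Landscape) -> list[str]:
    """Check every structural invariant; return a list of human-readable
    violations (empty means the landscape is valid)."""
    v: list[str] = []
    units = landscape.units
    props = landscape.properties
    scs = landscape.sub_catchments
    vts = landscape.veg_types
    vgs = landscape.veg_groups

    missing = [c for c in UNIT_COLUMNS if c not in units.columns]
    if missing:
        return [f"units: missing columns {missing}"]

    for _, u in units[units["area_ha"] <= 0].iterrows():
        v.append(f"unit {int(u.unit_id)}: area_ha must be > 0 (got {u.area_ha})")
    bad_suit = units[(units["suitability"] < 0) | (units["suitability"] > 400)]
    for _, u in bad_suit.iterrows():
        v.append(f"unit {int(u.unit_id)}: suitability {int(u.suitability)} outside [0, 400]")
    for col in ("buffered", "protected", "existing_cleared"):
        bad = units[~units[col].isin((0, 1))]
        for _, u in bad.iterrows():
            v.append(f"unit {int(u.unit_id)}: {col} must be 0/1")
    both = units[(units["existing_cleared"] == 1) & (units["buffered"] == 1)]
    for _, u in both.iterrows():
        v.append(f"unit {int(u.unit_id)}: existing-cleared unit cannot be buffered")

    dup = units.duplicated(subset=UNIT_KEY, keep=False)
    if dup.any():
        ids = units.loc[dup, "unit_id"].tolist()
        v.append(f"units {ids}: duplicate (property, sub-catchment, type, "
                 f"suitability, flags) combinations")
    if units["unit_id"].duplicated().any():
        v.append("units: unit_id values are not unique")

    # foreign keys
    for col, table, key in (("prop_id", props, "prop_id"),
                            ("sc_id", scs, "sc_id"),
                            ("type_id", vts, "type_id")):
        unknown = set(units[col]) - set(table[key])
        if unknown:
            v.append(f"units: unknown {col} values {sorted(unknown)[:5]}")
    unknown_groups = set(vts["group_id"]) - set(vgs["group_id"])
    if unknown_groups:
        v.append(f"veg_types: unknown group_id values {sorted(unknown_groups)}")

    # tenure / size constraints
    bad_tenure = props[~props["tenure"].isin(TENURES)]
    for _, p in bad_tenure.iterrows():
        v.append(f"property {int(p.prop_id)}: unknown tenure {p.tenure!r}")
    small = props[props["total_area_ha"] < 100 * (1 - REL_TOL)]
    for _, p in small.iterrows():
        v.append(f"property {int(p.prop_id)}: total area {p.total_area_ha:.2f} ha "
                 f"below the 100 ha guideline threshold")

    for _, s in scs.iterrows():
        for col in ("reserve_fraction", "aboriginal_fraction"):
            if not (0 <= s[col] <= 1 + REL_TOL):
                v.append(f"sub-catchment {int(s.sc_id)}: {col} outside [0, 1]")

    # area conservation
    total = float(units["area_ha"].sum())
    if not _check_close(total, landscape.catchment_area_ha):
        v.append(f"catchment: unit areas sum to {total:.3f} ha, "
                 f"expected {landscape.catchment_area_ha:.3f} ha")

    prop_sum = units.groupby("prop_id")["area_ha"].sum()
    for _, p in props.iterrows():
        got = float(prop_sum.get(p.prop_id, 0.0))
        if not _check_close(got, p.total_area_ha):
            v.append(f"property {int(p.prop_id)}: unit areas sum to {got:.3f} ha, "
                     f"expected {p.total_area_ha:.3f} ha")

    sc_sum = units.groupby("sc_id")["area_ha"].sum()
    for _, s in scs.iterrows():
        got = float(sc_sum.get(s.sc_id, 0.0))
        if not _check_close(got, s.total_area_ha):
            v.append(f"sub-catchment {int(s.sc_id)}: unit areas sum to {got:.3f} ha, "
                     f"expected {s.total_area_ha:.3f} ha")

    cleared = units[units["existing_cleared"] == 1]
    pc = cleared.groupby("prop_id")["area_ha"].sum()
    for _, p in props.iterrows():
        got = float(pc.get(p.prop_id, 0.0))
        if not _check_close(got, p.existing_cleared_ha):
            v.append(f"property {int(p.prop_id)}: existing-cleared unit areas sum to "
                     f"{got:.3f} ha, expected {p.existing_cleared_ha:.3f} ha")

    type_sum = units.groupby("type_id")["area_ha"].sum()
    type_clr = cleared.groupby("type_id")["area_ha"].sum()
    for _, t in vts.iterrows():
        got = float(type_sum.get(t.type_id, 0.0))
        if not _check_close(got, t.pre_clearing_area_ha):
            v.append(f"vegetation type {int(t.type_id)}: unit areas sum to {got:.3f} ha, "
                     f"expected pre-clearing extent {t.pre_clearing_area_ha:.3f} ha")
        gotc = float(type_clr.get(t.type_id, 0.0))
        if not _check_close(gotc, t.existing_cleared_ha):
            v.append(f"vegetation type {int(t.type_id)}: cleared unit areas sum to "
                     f"{gotc:.3f} ha, expected {t.existing_cleared_ha:.3f} ha")
        if t.existing_cleared_ha > t.pre_clearing_area_ha * (1 + REL_TOL) + 1e-6:
            v.append(f"vegetation type {int(t.type_id)}: cleared area exceeds "
                     f"pre-clearing extent")

    g_pre = vts.groupby("group_id")["pre_clearing_area_ha"].sum()
    g_clr = vts.groupby("group_id")["existing_cleared_ha"].sum()
    for _, g in vgs.iterrows():
        if not _check_close(float(g_pre.get(g.group_id, 0.0)), g.pre_clearing_area_ha):
            v.append(f"vegetation group {int(g.group_id)}: member type pre-clearing "
                     f"areas do not sum to the group extent")
        if not _check_close(float(g_clr.get(g.group_id, 0.0)), g.cleared_area_ha):
            v.append(f"vegetation group {int(g.group_id)}: member type cleared "
                     f"areas do not sum to the group cleared area")

    return v


# ---------------------------------------------------------------------------
# CSV I/O

_FILES = {
    "units": "units.csv",
    "properties": "properties.csv",
    "sub_catchments": "subcatchments.csv",
    "veg_types": "vegtypes.csv",
    "veg_groups": "veggroups.csv",
}

_REQUIRED = {
    "units": UNIT_COLUMNS,
    "properties": ["prop_id", "tenure", "total_area_ha"],
    "sub_catchments": ["sc_id", "total_area_ha", "reserve_fraction",
                       "aboriginal_fraction"],
    "veg_types": ["type_id", "group_id", "pre_clearing_area_ha"],
    "veg_groups": ["group_id", "name", "pre_clearing_area_ha", "cleared_area_ha"],
}

_NUMERIC = {
    "units": [c for c in UNIT_COLUMNS],
    "properties": ["prop_id", "total_area_ha"],
    "sub_catchments": ["sc_id", "total_area_ha", "reserve_fraction",
                       "aboriginal_fraction"],
    "veg_types": ["type_id", "group_id", "pre_clearing_area_ha"],
    "veg_groups": ["group_id", "pre_clearing_area_ha", "cleared_area_ha"],
}


def _read_csv(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED[table] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in _NUMERIC[table]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(df.index[bad | df[col].isna()][0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric or missing value in column "
                             f"'{col}' at line {row}")
        df[col] = coerced
    return df


def load_landscape(directory: str | Path) -> Landscape:
    """Load a landscape from ``units.csv`` plus the four entity CSVs in
    ``directory``.  Derived columns (per-property and per-type existing
    cleared areas) are recomputed from the unit table."""
    directory = Path(directory)
    units = _normalise_units(_read_csv(directory / _FILES["units"], "units"))
    properties = _read_csv(directory / _FILES["properties"], "properties")
    sub_catchments = _read_csv(directory / _FILES["sub_catchments"], "sub_catchments")
    veg_types = _read_csv(directory / _FILES["veg_types"], "veg_types")
    veg_groups = _read_csv(directory / _FILES["veg_groups"], "veg_groups")

    for col, table, name in (("prop_id", properties, "properties.csv"),
                             ("sc_id", sub_catchments, "subcatchments.csv"),
                             ("type_id", veg_types, "vegtypes.csv")):
        unknown = set(units[col]) - set(table[col])
        if unknown:
            rows = units.index[units[col].isin(unknown)][0] + 2
            raise ParseError(
                f"{directory / _FILES['units']}: {col} value(s) "
                f"{sorted(unknown)[:5]} (first at line {rows}) not present in {name}")
    unknown_groups = set(veg_types["group_id"]) - set(veg_groups["group_id"])
    if unknown_groups:
        raise ParseError(f"{directory / _FILES['veg_types']}: group_id value(s) "
                         f"{sorted(unknown_groups)} not present in veggroups.csv")

    cleared = units[units["existing_cleared"] == 1]
    prop_clr = cleared.groupby("prop_id")["area_ha"].sum()
    properties = properties.copy()
    properties["existing_cleared_ha"] = (
        properties["prop_id"].map(prop_clr).fillna(0.0).astype(float))
    type_clr = cleared.groupby("type_id")["area_ha"].sum()
    veg_types = veg_types.copy()
    veg_types["existing_cleared_ha"] = (
        veg_types["type_id"].map(type_clr).fillna(0.0).astype(float))

    for df, key in ((properties, "prop_id"), (sub_catchments, "sc_id"),
                    (veg_types, "type_id"), (veg_groups, "group_id")):
        df[key] = df[key].astype(np.int64)
        df.sort_values(key, kind="mergesort", inplace=True)
        df.reset_index(drop=True, inplace=True)
    veg_types["group_id"] = veg_types["group_id"].astype(np.int64)

    return Landscape(units, properties, sub_catchments, veg_types, veg_groups)


def write_landscape(landscape: Landscape, directory: str | Path) -> dict[str, Path]:
    """Write the landscape as five UTF-8 CSV files with a fixed 6-decimal
    float format (so identical landscapes produce byte-identical files).
    Returns a mapping of table name to written path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(df: pd.DataFrame, cols: list[str], name: str) -> None:
        path = directory / _FILES[name]
        df[cols].to_csv(path, index=False, float_format="%.6f",
                        lineterminator="\n")
        written[name] = path

    _write(landscape.units, UNIT_COLUMNS, "units")
    _write(landscape.properties, _REQUIRED["properties"], "properties")
    _write(landscape.sub_catchments, _REQUIRED["sub_catchments"], "sub_catchments")
    _write(landscape.veg_types, _REQUIRED["veg_types"], "veg_types")
    _write(landscape.veg_groups, _REQUIRED["veg_groups"], "veg_groups")
    return written
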