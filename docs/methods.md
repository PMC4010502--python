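# Methods

## The clearing model

The simulator operates on a purely tabular landscape: geometry is reduced
to areas of *land units*, the atomic slices of a property that are
homogeneous in sub-catchment, vegetation type, suitability index and
clearing status.  This is faithful to how cascade-rule caps are actually
assessed — every cap is a percentage of an area — and means no adjacency
or shape information is needed.

Cap accounting follows four rules, each of which is a deliberate modelling
decision:

1. **Existing clearing counts toward every cap and every denominator.**
   Historically cleared land is represented as flagged units, so property,
   sub-catchment, vegetation-type and catchment accumulators all start
   from history.  This is what makes reported totals of ~20% decompose
   into ~5.4% existing plus ~14.6% simulated clearing, and what makes
   a 60%-cleared sub-catchment receive nothing new.
2. **Grandfathering.** Headroom is `max(0, cap x baseline - cleared)`;
   a feature initialised above its cap therefore has zero headroom but
   keeps its clearing.  No clawback is modelled.
3. **Baselines.** The property cap is measured against total property
   area, buffered/protected/unsuitable land included (the policy states a
   flat percentage with no qualifier); the vegetation-type cap is measured
   against pre-clearing extent, not current extent; sub-catchment and
   catchment caps use total areas.
4. **Partial units.** A unit is cleared whole when headroom allows and
   partially when a cap or the property's drawn target intervenes, so
   draws and caps are met exactly rather than to the nearest unit.

The per-property drawn target is the target **total** cleared fraction,
existing clearing included: a property already cleared past its draw
clears nothing new.  The draw band U(0.30, 0.70) reflects that historical
per-property clearing ranges from a few percent to complete, while the
70% upper bound is the policy cap itself.

The catchment cap can terminate a run in two ways.  In
`complete_last_property` mode (default) the property whose clearing
crosses the cap finishes its draw, so realised totals slightly exceed the
cap — matching how application-by-application approval would behave, and
how reported totals on the real landscape sit just above 20%.  In
`truncate` mode the catchment headroom joins the per-unit minimum, so the
final clearing event lands exactly on the cap; this is the mode used for
strict-bound verification.  This is also the one place the engine's
`allowable_clearing` depends on the overshoot mode: the catchment headroom
is excluded from the per-unit minimum in `complete_last_property` mode
(the stop is checked between properties instead), since including it there
would make overshoot impossible by construction.

### Randomness

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawn keys: the ordering stream of run *i* is
keyed by `(seed, i, 0)` and the target stream of property *p* in run *i*
by `(seed, i, 1, p)`.  Draws therefore do not shift if the iteration is
refactored, a property is skipped, or runs are re-executed individually.
Outputs are written with a fixed 6-decimal float format, so identical
seeds give byte-identical files.

## The synthetic landscape generator

The generator emulates the catchment-scale statistics of the study
system; its defaults are the study conditions, not free dials:

| parameter | default | rationale |
|---|---|---|
| catchment area | 5.2 Mha | study region size |
| protected fraction | 0.13 | national parks + Indigenous protected areas |
| tenure mix of available land | 10/30/60 gov/aboriginal/private | reported split |
| properties | 347 | see below |
| property size law | log-normal (sigma = 1.4), truncated to [100 ha, 400,000 ha], rescaled to tile the catchment; realised mean ~15,000 ha | reported size range and mean |
| sub-catchments | 16, Dirichlet(2) area shares | reported count; wide size spread |
| vegetation | 98 types in 15 groups, Dirichlet weights | reported catalogue |
| existing clearing | 5.4% of the catchment | reported level |
| per-property existing clearing | f = 0.01 + 0.99 x Beta(2, 6), mean ~0.257 | reported range 1–100% and mean 25%; see note |
| buffered fraction | 0.08 of the catchment | stream/wetland/river buffers; no published total, chosen once as plausible for a dense tropical drainage network |
| suitability | point mass at 0 plus Beta-scaled draws on 1–400 | catchment mean ~178 and ~44% clearable |

**Property count.** The reported mean property size (~15,000 ha) and the
catchment area fix the property count near 347; published
per-sub-catchment property counts sum to ~473, but those are
property-by-sub-catchment memberships (properties can span boundaries),
not distinct properties.  The generator assigns each property to at most
two sub-catchments.

**Existing clearing law.** Only the range (1–100%) and mean (25%) of
per-property historical clearing are reported.  A rescaled Beta(2, 6)
matches both while concentrating mass at light-to-moderate clearing, so
in a ~75-property clearing sample the most-cleared property typically
sits near — occasionally just above — the 70% property cap.  When a seed
does produce a property starting above 70%, it is grandfathered: the
simulator never adds to it, and the reported maximum per-property
percentage then reflects initialisation, not simulated clearing.

**Suitability.** The zero-suitability share of available land is set so
that clearable land (unprotected, unbuffered, uncleared, suitability > 0)
is ~44% of the catchment; the nonzero part is Beta-distributed on 1–400
with mean chosen so the overall area-weighted mean is ~178.  The zero
share is applied deterministically within each pool and nonzero draws are
stratified into chunks of at most 10,000 ha, which keeps the realised
area-weighted mean within a few index points of target without any
spatial model.

**Derived-totals construction.** Every entity-level total (property,
sub-catchment, vegetation type/group, catchment) is aggregated from the
generated unit table, so the conservation invariants hold by
construction and `validate_landscape` is a genuine check of any landscape
read from disk, not just generated ones.

**What the generator does not emulate.**  No spatial autocorrelation,
no contiguity of sub-catchments, no correlation of suitability with
tenure or with vegetation type beyond what random assignment induces, no
per-sub-catchment reproduction of published tenure/reserve percentages,
and a simplified buffer allocation (proportional across available land).
Consequently, tests passing on synthetic landscapes demonstrate the
*policy mechanics* — cap enforcement, grandfathering, ordering effects,
equity of tenure access under sequencing — not the specific published
per-sub-catchment or per-vegetation-type values, which depend on the real
GIS layers.

## Numerical choices

- Areas are float hectares; conservation checks use relative tolerance
  1e-6 (plus 1e-6 ha absolute), cap comparisons relative 1e-6, and
  clearing below 1e-6 ha is treated as complete.
- Ties in property size or mean suitability break by ascending property
  id; ties in unit suitability break by vegetation type id then unit id.
  Determinism requires a rule; none is published.
- The cross-type standard deviation of cleared percentages is the
  population SD (a `population_sd=False` switch gives the sample form);
  with 98 types the difference is negligible but a choice is required.
- "Average size of properties with clearing" is computed per run and then
  averaged over runs (run-then-average), matching per-scenario averages
  over replicates.
- Spearman correlations use average ranks on ties
  (`scipy.stats.spearmanr`); a constant vector yields NaN rather than an
  arbitrary value.
- Vegetation types with zero pre-clearing extent are excluded from
  percentage summaries with a warning (division by zero is meaningless,
  and such types can only arise in hand-built landscapes).

## Problem sizes

The default study configuration — 347 properties, ~2,700 units, 100
replicate runs — executes in a few seconds on one CPU, so tests and the
acceptance script use it directly.  Cross-checks against the naive
brute-force oracle, which recomputes every headroom by full table scans,
use the hand-specified fixtures and a 20-property synthetic landscape,
where the oracle's quadratic cost is immaterial.

## Known limitations

- No temporal dynamics: the simulation is a single sweep to policy
  saturation, not a year-by-year clearing trajectory.
- No behavioural model beyond ordering and the uniform draw: no land
  prices, no assessment-cost deterrence beyond the orderings that encode
  it qualitatively.
- Ad-hoc buffer-zone exemption approvals are not modelled (their extent
  and distribution are unknowable in advance).
- Government tenure is carried as a third class but grouped with
  non-aboriginal wherever a two-way tenure split is reported.
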