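# Methods

## Model structure and assumptions

The suitability model assumes climate is the primary determinant of where a
species can persist, and that a year of climatological normals (no
inter-annual variability) is enough to score a location. Monthly normals are
resampled to a fixed 52 x 7-day year: temperatures by linear interpolation
between month midpoints (cyclic over the 365-day year, evaluated at week
midpoints, day 3.5 + 7(w-1)), precipitation by pro-rating each month's total
over the days of the week's midpoint month. The 364- vs 365-day mismatch
changes annual precipitation by under 0.3%, well inside the 3% conservation
bound the tests enforce.

Soil moisture is a single-store bucket expressed as a fraction of capacity:

    sm_w = clamp(sm_{w-1} + (P_w - E_w) / capacity, 0, max_fraction)
    E_w  = evap_coeff * max(0, tavg_w)

iterated around the annual cycle from sm = 0.5 until one further pass
changes nothing (sup-norm < 1e-6) or 20 passes have run, which removes the
dependence on the starting value. The moisture thresholds SM0-SM3 apply
directly on this capacity-normalised scale, which is the only scale on which
values like SM0 = 0.007 and SM3 = 0.9 are meaningful together. Evaporative
demand linear in above-zero mean temperature is the simplest defensible
demand model; the humidity fields are carried through the data model but the
default budget does not use them. `max_fraction` above 1 represents
waterlogging beyond field capacity (default 2.5); setting it near or below 1
models a free-draining soil whose excess runs off.

Growth: trapezoidal temperature and moisture indices (0 at/below the lower
limit and at/above the upper limit, 1 on the optimal plateau, linear ramps),
evaluated on weekly mean temperature and soil moisture; the annual growth
index is the mean of the 52 weekly products. Growth responds to means;
survival limits are physiological extremes, so cold stress is evaluated on
weekly minimum temperature and heat stress on weekly maximum.

Stress: each stress accumulates `|rate| x exceedance_w x k_w` per week,
where `k_w` counts consecutive stressed weeks (reset by any stress-free
week), capped at 1. The superlinear-in-duration form realises an
accelerating ("exponential") annual accumulation with a single rate
parameter; at 1 the species cannot persist and EI is 0 regardless of
growth. The cold-stress rate THCS is stored signed (negative, as
conventionally printed) and applied by magnitude. No dry stress is defined
for this parameterisation.

EI combines growth and survival multiplicatively,
`EI = 100 x GI_A x (1-CS)(1-HS)(1-WS)`: it honours the 0-100 scale, is 100
exactly when growth is perfect and all stresses zero, and 0 exactly when any
stress saturates. Classification uses half-open upper-bound intervals
(EI = 10 is suitable, EI = 20 highly suitable), making the four categories a
partition.

### Default parameters (date palm)

DV0-DV3 = 14, 20, 39, 46 degC; SM0-SM3 = 0.007, 0.013, 0.81, 0.9;
TTCS = 4 degC with THCS = -0.01/week; TTHS = 46 degC with THHS = 0.9/week;
SMWS = 0.9 with HWS = 0.022/week. These ship as
`data/date_palm.params` and are the level-2 values of the screening table.

## Screening design

The design is the mixed-level L54(2^1 x 3^25) orthogonal array: 54 runs,
each three-level column perfectly balanced (18/18/18) and every pair of
three-level columns strength-2 (each of the 9 level pairs exactly 6 times).
The packaged CSV is produced by an Addelman-Kempthorne-style construction
over GF(3) (see `construct_l54`): rows are two copies of the full factorial
on (u, y2, y3); columns are u, the linear forms b.y + t u, and quadratic
forms b.y + t u + 2u^2, with the second copy evaluated with a modified
quadratic coefficient, doubled slope and slope-dependent shifts chosen so
the within-copy joint-distribution deficiencies of linear x quadratic pairs
cancel exactly. The loader re-validates every invariant exhaustively, so a
corrupted fixture cannot be used silently.

The 14 factors are assigned, in factor-table order, to the first 14
three-level columns. The fixture's column order is itself a design choice:
a near-saturated screening array must alias two-factor interactions onto
main-effect columns somewhere, but this array contains many strength-3
triples, and the columns are permuted so that each strongly interacting
factor pair — the two low-temperature knots, the two high-moisture knots,
and their temperature/moisture counterparts — sits on a "protected" pair
whose interaction is exactly balanced on every other assigned column. This
suppresses the dominant source of spurious sensitivity in the report. The
residual (higher-order and cross-pair) aliasing is of order 0.01-0.1 dB and
is the noise floor against which real effects must be read; this is an
inherent property of saturated Taguchi screening, not of this
implementation.

Runs are materialised by looking up each factor's level value; infeasible
combinations (an upper knot at or below its lower knot, e.g. DV2 = 45 with
DV3 = 40) are repaired by clamping the upper knot to the lower + 0.1 — a
degenerate ramp — and every repair is logged in the design object. A
consequence worth knowing: with the default level table, the SM3 = 0.6
level is only effective in runs where SM2 = 0.5 (any higher SM2 forces the
repair), so part of SM3's influence is structurally a joint effect with
SM2.

The response is the suitable + highly-suitable area in km^2 (spherical-band
cell areas, authalic radius 6371 km). The model is deterministic, so each
run is a single replicate and the larger-the-better signal-to-noise ratio
reduces to SN = 20 log10(y); a zero-area response is floored at 1 km^2
before the transform and flagged. Level means average the 18 runs at each
level; delta is max - min of the three means; ranks sort by delta with ties
broken by factor-table order; the optimum level is the argmax mean, with a
flag recording whether it coincides with the level holding the baseline
value.

## Synthetic climate generator

The generator emulates the structure of half-degree gridded climate
normals: 12 monthly values per cell for tmin, tmax, precipitation and
09:00/15:00 relative humidity. Geography is deliberately simple — an
equator-to-pole linear temperature lapse, a seasonal sinusoid with the warm
peak at the July midpoint (inverted south of the equator), a fixed diurnal
half-range (default 6 degC), annual precipitation interpolated between
latitudinal anchors with a winter-peaked seasonal profile, and humidity
monotone in the precipitation band. Noise is applied once per cell, to the
annual temperature mean (additive Gaussian) and to the annual precipitation
total (unit-mean lognormal), keeping seasonal shapes smooth while breaking
the longitudinal degeneracy of a purely banded field. Identical scenario
and seed give bit-identical output.

What the generator does not emulate: orography, coastlines and land/sea
masks, spatial autocorrelation of anomalies, covariance between temperature
and rainfall anomalies, and inter-annual variability. Tests passing on
these fields therefore demonstrate correctness of the model mechanics and
the screening machinery, not skill on real climate data.

### Control scenarios for parameter recovery

Two packaged scenarios make exactly one climatic axis limiting, so the
screening must recover the corresponding parameter family at the top of the
ranking; they are fixed study conditions (seed 0), paired with matching
bucket settings.

*Temperature-limited*: annual means run 12.5-39.4 degC across the grid with
zero diurnal range and a nearly flat season, so weekly minima never fall
below the highest cold-stress threshold (5 degC) and maxima never reach the
lowest heat-stress threshold (40 degC); no rainfall plus zero evaporative
demand pins soil moisture at 0.5, inside the moisture plateau of every
candidate parameter set. The cold flank of the suitability contour is
governed by DV0/DV1 and the hottest rows sit just below 40 degC where the
upper ramp (DV2 = 30 with DV3 = 40) pushes cells below the suitable
boundary, giving all four temperature knots genuine leverage.

*Moisture-limited*: temperature uniform at 28 degC (inside every candidate
optimal plateau, clear of all stress thresholds), monsoonal rainfall
(seasonality 1) ramping from arid through a wide near-balance margin to
humid, over a shallow free-draining bucket (capacity 150 mm, ceiling 0.62,
high evaporative demand). Near-balance cells' wet-season storage peaks
fall inside the SM0/SM1 knots; humid cells fill to the ceiling each wet
season and dry out completely each dry season, so whether they retain
enough growing weeks to stay suitable is controlled by SM2/SM3 (the ceiling
keeps wet-stress exceedance at 0.02, rendering SMWS/HWS nearly inert, as a
single-axis control requires). Verified over 15 generator seeds, the
temperature scenario recovers DV0-DV3 as the top four ranks in 15/15 and
the moisture scenario recovers SM0-SM3 in 14/15; the packaged seeds pass.
The near-miss is informative: SM1's level span (0.011-0.017 of capacity) is
about 1% of the bucket scale, so its physical leverage on an area response
is intrinsically small and can approach the residual aliasing floor.

## Numerical choices

- Trapezoid evaluation as `clip(min(rise, fall), 0, 1)`: continuous at the
  knots, exact at plateau edges.
- Classification boundaries at 10 and 20 are half-open upwards; EI = 0 is
  its own category; NaN climate yields a distinct no-data category excluded
  from areas and totals.
- Point-in-cell assignment is half-open `[west, east) x [south, north)`;
  a record on the grid's outer north/east edge is out of grid.
- Bucket iteration: 20-cycle cap with 1e-6 sup-norm tolerance; in all
  tested regimes convergence occurs within a handful of cycles except
  neutrally stable zero-flux cells, which remain at their initial value by
  construction.
- Degenerate repaired ramps (width 0.1) keep the trapezoid well-defined
  without special-casing; repairs are logged rather than silently applied.
- CSV output uses '.' decimals and UTF-8 regardless of locale; NetCDF is
  written in classic format; GeoTIFF output writes two pages (float EI,
  byte category) with WGS84 geographic tags.

## Known limitations

- The weekly interpolation and the bucket hydrology are declared model
  components of this package, not reconstructions of any proprietary
  implementation's internals; likewise the consecutive-week stress
  multiplier and the multiplicative EI composition.
- The area response only registers parameter changes that move cells across
  the suitable boundary (EI = 10); parameters whose effects stay interior
  to a category are invisible to the screening even when they change EI
  substantially. This is a property of area-based responses generally.
- Saturated screening aliases interactions onto main effects; the protected
  column assignment removes the leading terms but rankings of factors with
  deltas near the residual floor (~0.01-0.1 dB) should not be
  over-interpreted.
- Single replicate per run: the SN transform degenerates to a monotone map
  of the response, so "robustness" in the Taguchi sense is not separable
  from the mean response here.
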