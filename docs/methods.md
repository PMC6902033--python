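# Methods

This note documents the models, conventions, and numerical choices behind
planktrace, and what its synthetic-data tests do and do not demonstrate
about real data.

## Data model

An **SV table** is a nonnegative integer matrix of read counts, sequence
variants × samples; zero rows and columns are legal and preserved (a taxon
can be absent everywhere after filtering, and an empty sample is
information, not an error). **Sample metadata** carries the cruise month
(an opaque, explicitly ordered label — no date parsing), sampling depth
(m), size fraction (`large` ≥ 3 µm / `small` < 3 µm), and a depth zone.
**Taxonomy** is a semicolon-delimited lineage string per SV with an
optional trophic flag.

### Depth zones

Zones are assigned from depth by inclusive upper edges, a total function:

| zone | default interval |
| --- | --- |
| surface | ≤ 50 m (per-month override, e.g. ≤ 100 m during deep winter mixing) |
| epipelagic | ≤ 300 m |
| mesopelagic | ≤ 999 m |
| bathypelagic | ≤ 3,999 m |
| abyssopelagic | > 3,999 m |

Boundary values fall in the shallower zone. The sampled depths these bins
were designed around are 5/10 m (surface), ~200/300 m (epipelagic), 500 m
(mesopelagic), 1,000–2,000 m (bathypelagic) and 5,000 m+ (abyssopelagic);
the 999/3,999 m edges close the unsampled gaps at the conventional
1,000 m and 4,000 m bathypelagic limits. All edges are configuration.

## Filtering

`filter_phytoplankton` retains SVs whose lineage contains any of the
include tokens (default: Archaeplastida, Cryptophyta, Haptophyta,
Chlorarachniophyta, Heterokontophyta), then removes SVs whose lineage
matches an exclude token (default: dinoflagellate ranks, which mix many
heterotrophic and undescribed species) or whose trophic flag marks a known
heterotroph within an otherwise-phototrophic group. Matching is plain
substring containment on the lineage string: robust to rank-prefix
conventions, at the cost of requiring tokens that are unambiguous rank
names.

## Rarefaction

Rarefying to depth *d* draws exactly *d* of a sample's reads uniformly
without replacement, i.e. per-SV counts are multivariate hypergeometric
(implemented with numpy's `multivariate_hypergeometric` generator). Counts
stay integers, never exceed the originals, and column sums equal *d*
exactly. Samples below *d* are an error by default (`drop_below` discards
them instead). Presence/absence for attribution is assessed on whatever
table the caller passes — the intended workflow is filter → rarefy →
attribute, so presence is post-rarefaction, but nothing enforces this and
the raw-table variant is one call away.

## Provenance attribution

`first_detection` scans the ordered labels (months, or zones from shallow
to deep) and records, per SV, the earliest label whose sample group has a
positive summed count. `attribute_temporal` / `attribute_vertical` then
partition each target label's community by origin, weighting by reads or
by presence (richness). Conventions:

- Sample groups per label must be disjoint; the order is total, so there
  are no ties to break.
- A target with an all-zero community is reported with empty origins and
  status `"empty"` rather than NaN fractions.
- Temporal attribution restricts to one layer (default the surface
  layer) and optionally one size fraction; vertical attribution restricts
  to one month and fraction with one representative sample per zone, and
  accepts an explicit zone → sample override for depth substitutions
  (e.g. a 300 m bottle standing in for a lost 500 m sample).
- Vertical patterns: `P1_surface_to_deep` = present in the epipelagic
  (surface included) and reaching bathy- or abyssopelagic;
  `P2_epipelagic_only` = epipelagic but never bathy/abyssopelagic — an
  epipelagic+mesopelagic profile falls here, and the raw zone profile is
  attached to every record so users can re-bin; `P3_deep_only` = absent
  from the epipelagic, present at mesopelagic depth or below.
- Relative-abundance thresholds ("representative SVs", default 5 %) are
  inclusive (≥).

## Community statistics

Bray–Curtis dissimilarity `d(i,j) = 1 − 2·Σ min(x_i, x_j)/(Σ x_i + Σ x_j)`
is computed via scipy's pairwise-distance machinery; a pair of all-zero
samples has no defined distance (NaN, with a warning), while empty vs
non-empty is 1. PERMANOVA uses Anderson's pseudo-F from among/within sums
of squared distances and a seeded uniform label-permutation null with the
add-one convention `p = (1 + #{F* ≥ F}) / (1 + n_perm)`, so p is never 0;
the default 9,999 permutations resolves p down to 10⁻⁴. With discrete
count data, permutation ties make the test mildly conservative — the
standard behaviour. The read-total vs chlorophyll-a association is a
Pearson correlation with the usual t-based two-sided p.

## Particle backtracking

Motion is horizontal within one stored depth level (deep vertical
velocities are orders of magnitude smaller than horizontal ones at the
time scales of interest; no vertical interpolation is attempted) and
purely deterministic — no random-walk diffusion. Defaults: 90-day runs,
RK4 with dt = 3 h, particles seeded at 0.025° spacing over a box extending
0.25° in each cardinal direction (21² = 441 particles).

Numerical choices:

- Sphere of radius R = 6,371,000 m; no ellipsoid. Longitudes wrap modulo
  360° when locating grid cells.
- Bilinear interpolation in lon/lat, linear in time. At land-adjacent
  queries, land corners get zero weight and the remaining weights are
  renormalized (avoiding a spurious zero-velocity attraction at coasts);
  a query with all four corners on land beaches the particle, frozen at
  its last sea position. Leaving the grid hull — or the stored time range
  when the run is not declared `steady` — marks it exited. A particle
  flagged at any RK stage freezes at its start-of-step position.
- dt = 3 h at 1/10° grid spacing keeps the per-step displacement well
  under a cell width for realistic speeds (≤ 1 m s⁻¹), where RK4's
  fourth-order error is far below the interpolation error of the field
  itself.

## Synthetic data

### Communities

The generator emulates the structure the attribution analysis assumes,
one sample per month × zone × fraction. Per sample, taxon *groups* get
fixed total weight shares, and weights within a group are
gamma-overdispersed (shape = 1/dispersion; dispersion 0.5 by default —
realistic clumping without degenerate dominance); reads are a single
multinomial draw, so each sample's total is exact by construction.
Planted structure, with defaults:

- 60 **seed taxa**, present in every month's surface community;
- 20 **allochthonous taxa** (coastal-diatom lineages), present only in
  the mixing months (positions 2–3 of the 4-month cycle, mirroring a
  Feb/Apr mixing period) where they carry exactly fraction *f* (default
  0.5) of the phytoplankton weight — so the reads-basis new-origin
  fraction in the first mixing month is an unbiased estimator of *f*,
  up to multinomial noise and the rare loss of a seed taxon to a zero
  draw in the first month;
- deeper zones re-use the month's surface community thinned by per-zone
  export probabilities (0.9/0.6/0.4/0.3 from epipelagic to
  abyssopelagic), add 8 zone-endemic deep taxa carrying 30 % of the
  zone's weight, and decay total reads by 0.6 per zone step (10,000
  reads at the surface);
- a 5 % read share of decoys (dinoflagellates and flagged heterotrophs)
  exercises the taxonomic filter; because decoys hold their own weight
  share, filtering them out leaves the planted *f* unchanged.

What this does **not** emulate: sequencing error and chimeras, primer
bias, compositional coupling between fractions, patchy bloom dynamics, or
taxon-specific export timing. Passing the recovery tests shows the
estimator is correct *given* presence/absence semantics and multinomial
sampling — not that real communities satisfy those assumptions.

### Velocity fields

Analytic flows provide closed-form trajectory oracles:

- **uniform** — constant (u, v); with v = 0 the backward displacement is
  exactly u·T/(R cos φ)·180/π degrees.
- **solid_rotation** — rigid rotation *in longitude–latitude degree
  space*: u = −ω·Δlat·(π/180)·R·cos φ, v = ω·Δlon·(π/180)·R, giving
  d(Δlon)/dt = −ω·Δlat, d(Δlat)/dt = ω·Δlon, whose exact solution is a
  circle of conserved degree-radius. Default ω = 5 × 10⁻⁶ s⁻¹ (a 14.5-day
  eddy period, ~0.14 m s⁻¹ at 0.25° radius — a realistic mesoscale eddy).
  Radius-conservation and convergence-order checks run against the
  analytic flow directly, isolating the time integrator; sampling the
  flow onto a 1/10° grid adds a bilinear-interpolation error in the
  metric factor cos φ of order 10⁻⁴ relative radius drift over 90 days,
  which is checked separately at its own tolerance.
- **double_gyre** — the standard two-gyre stream function mapped onto a
  lon/lat box; divergence-free, closed box boundaries, optional
  time-periodic gyre-boundary oscillation.

Fields are written/read as CF-style NetCDF (classic format via xarray's
scipy engine; float64 values round-trip bit-exactly), with the land mask
stored explicitly and also inferrable from fill values.

## Problem sizes in tests and the acceptance script

Trajectory oracles use the full 441-particle box over 90 days; convergence
uses one particle at the box corner radius. Attribution enumeration uses
1,000 random 3 SV × 3 sample tables (exhaustively checkable by hand);
parameter recovery uses 200 generator seeds per planted fraction
f ∈ {0.1, 0.5, 0.9}; rarefaction calibration uses 10,000 resamples of a
3-SV, 100-read sample at depth 10 (small enough that the full multivariate
hypergeometric support can be enumerated exactly for the goodness-of-fit
reference); PERMANOVA calibration uses 1,000 exchangeable null datasets of
12 samples with 199 permutations each, where the add-one p-value's null
rejection probability at α = 0.05 is exactly 10/200. These sizes give
Monte-Carlo standard errors comfortably inside each check's tolerance
while the whole suite runs in well under a coffee break.

## Known limitations

- Attribution origin is presence-based; a single stray read (index
  hopping, contamination) re-assigns an SV's origin. Rarefaction
  mitigates but does not remove this; a minimum-count presence threshold
  would be a natural extension.
- Vertical attribution assumes one representative sample per zone;
  replicate bottles must be merged or selected by the caller.
- The integrator's per-level 2-D assumption ignores vertical shear
  sampled by sinking particles; trajectories describe water masses, not
  sinking aggregates.
- PERMANOVA is the one-factor form; multi-factor designs (fraction ×
  water column × period) must be run factor by factor.
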