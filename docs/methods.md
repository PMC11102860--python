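# Methods

## Model

The automaton tracks the binary confirmed-insecticide-resistance state on a
regular lattice of square cells (default 5 km) with a monthly time step.
The update for cell (i, j) is synchronous and deterministic:

```
new = (present_in_closed_moore_neighbourhood AND diffusion_rules_permit)
      OR emergence_rules_permit
```

with both rule evaluations taken at the cell's driver values at the current
step. The design resolves two points the verbal model description leaves
open:

* **Persistence runs through the diffusion gate.** A cell counts as its own
  neighbour for the presence test, so a confirmed cell persists exactly when
  the diffusion rules still permit it. Consequently a confirmed cell whose
  neighbours are confirmed but whose own conditions fail both rule channels
  reverts to 0 — the disappearance clause takes precedence over
  neighbourhood pressure. This is the minimal reading consistent with the
  rule that appearance *and* disappearance depend only on the current driver
  state.
* **Channel assignment.** Which rules gate diffusion versus spontaneous
  emergence is a modelling choice; by default every built-in rule serves
  both channels (`builtin_rulesets()`), and the two lists of `RuleSet` can
  be populated independently. Note that when a rule appears in the
  emergence list it dominates the corresponding diffusion behaviour: the
  state becomes driver-determined one step after initialisation.

Neighbourhoods are Moore (Chebyshev) with radius 1 by default, truncated at
the grid edge — geographic domains are not toroidal. With always-true
diffusion rules and no emergence the confirmed set at step k is exactly the
Chebyshev-radius-k dilation of the seed; this closed form anchors the
engine tests.

## Rules

Rules are conjunctions of threshold conditions combined disjunctively
(OR-of-ANDs): each rule describes one driver combination sufficient for
confirmed resistance. Interval conditions are closed on both ends (a range
"spanning 15 to 38 °C" includes the endpoints); "surpassing 0.76" is a
strict inequality. A condition on a missing or NaN driver value evaluates
to false and is logged: absent data never asserts resistance.

## Grid, time and interpolation

Cells are half-open squares, row index increasing with y, so every in-bounds
point belongs to exactly one cell. Coordinates are planar kilometres;
geographic data must be projected upstream (no CRS handling here). Yearly
driver series are anchored at January of their year, linearly interpolated
between anchors and held constant outside them; the January-anchor
convention is a reproducibility choice, since a yearly value could equally
denote an annual mean. Categorical layers (land cover) are stepped to the
nearest anchor — interpolating class codes is meaningless — with ties going
to the earlier year.

## WHO state classification

Bioassay mortality below 90 % is confirmed resistance; the published bands
"90–97 %" and "98–100 %" leave (97, 98) unassigned, so possible resistance
is taken as [90, 98) to make the partition exhaustive. Cell-year aggregation
is *any record confirmed*: a single confirmed bioassay marks the cell-year,
matching the model's exclusive focus on the confirmed state. The initial
lattice seeds every cell confirmed in the earliest observed year.

## Driver selection

PCA runs on the correlation matrix (drivers have incommensurate units).
Retained components are the smallest leading set with cumulative explained
variance strictly above 0.80 (with 1e-9 slack so an exact 0.80 tie does not
pass on float round-off); loadings are eigenvector coefficients with a
deterministic sign convention, and drivers loading above 0.25 in magnitude
on a retained component are kept. The Kaiser eigenvalue > 1 flags are
reported but not binding. Clustering uses distance 1 − |r| with average
linkage and a configurable flat cut (default 0.5); each cluster contributes
its member with the largest |r| against the confirmed-IR indicator, ties
broken lexicographically. The final continuous selection is the
intersection of PCA retention, |r| > 0.2 importance and cluster
representativeness; categorical drivers join when their contingency table
is chi-square-significant at p < 0.05 (no continuity correction). The
interaction order of the |r| > 0.2 screen and the 0.25 loading cut is an
interpretation; both filters are applied conjunctively and the full
provenance (correlations, loadings, clusters, flags) is kept in the report.

## Validation and calibration

Monthly states are bridged to yearly observations by an any-month rule.
Accuracy is evaluated **only at record-covered cells**: surveillance
coverage is sparse and scoring unobserved cells would fabricate true
negatives. Years without evaluated cells are undefined and excluded from
the mean (the dash convention of reported accuracy tables). Calibration is
an exhaustive search over a user-declared finite grid of per-condition
thresholds, maximising mean annual training accuracy, with a
first-encountered-maximum tie-break in declared iteration order; the
substituted value patches the named rule in both channels.

## Synthetic data

The generator emulates the study inputs from one integer seed. Continuous
layers are sums of six low-frequency random cosine surfaces, min-max scaled,
plus an optional seasonal sinusoid and 2 %-of-range white noise, clipped and
mapped into the declared physical range. Defaults: temperature 12–42 °C
with a 12 %-of-range seasonal cycle, precipitation 0–300 mm/month,
relative humidity 20–95 %, ITN/IRS coverage and crop fractions in [0, 1],
population density 0–2000 km⁻², NDVI 0–0.9, static elevation 0–2500 m and a
static 5-class categorical land-cover layer. Crop-fraction layers carry a
sparsity floor (55 % of the domain exactly zero for irrigated rice, 45 %
for vegetables, 30 % for cropland) so that rule predicates on crop presence
partition the domain non-trivially. Ground truth is the automaton's own
output under a planted rule set — truth is by construction inside the model
class, which is what makes exact recovery a meaningful engine check, and is
also the generator's main departure from reality: real resistance dynamics
include genetics, sampling bias and drivers outside any rule set, so
passing recovery tests demonstrates internal consistency, not real-world
predictive skill. Records sample distinct cells uniformly each year;
mortality is drawn uniformly from [40, 89.9] when the cell's annual truth
is confirmed and [90, 100] otherwise — bands chosen to be unambiguous under
the WHO cutpoints — with the band swapped at the label-noise probability,
coordinates jittered inside the cell and dates uniform over the year's
months. Tying the record band to the *annual* truth keeps noise-free
records exactly consistent with the any-month validation bridge.

## Problem sizes and numerics

The shipped tests and the acceptance script use 10×10 lattices for
oracle-equivalence sweeps, a 7×7 lattice for the closed-form diffusion
limit, 30×30 × 60-month scenarios (50 records/year, 20 seeds at 10 % label
noise) for end-to-end recovery, and a 20×20 × 36-month scenario for
calibration — sizes at which every property is exact or statistically
stable while the whole suite runs in seconds. Driver CSVs are written with
`%.17g` and read with round-trip float parsing so raster round trips are
bit-exact. All sub-streams of randomness derive from the scenario seed via
`numpy` seed sequences.

## Known limitations

No CRS support or geodesic areas; rules are crisp thresholds (no learned or
probabilistic rules); the automaton state is binary confirmed/not, so
possible-resistance dynamics are not modelled; calibration is exhaustive
enumeration, adequate for the small hand-declared candidate grids it is
meant for; state/driver TIFFs are plain multi-band rasters without geo-tags.
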