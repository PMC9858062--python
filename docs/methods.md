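# Methods

## Stay detection

A user's trajectory is a strictly time-ordered sequence of lon/lat points.
The detector runs a greedy anchored scan: anchor at point *i*, extend *j*
while every point stays within `d_max` of the *anchor* (not of its
predecessor); at the first violation or the end of the sequence the window
`p_i..p_{j-1}` is emitted as a stay iff its time span is at least `t_min`
(boundary inclusive, so "at least 5 minutes" reads literally). After an
emitted stay the anchor restarts at the violating point; after a rejected
window it advances by a single point, so a stay beginning inside a rejected
window is still found. Measuring from the anchor means a slow drift that
never leaves the initial radius is one stay, which matches the
stay-point-detection convention in the mobility literature. The
tests include a brute-force oracle (enumerate all windows, keep the valid
ones, select maximal non-overlapping windows left to right) and check
agreement on hundreds of randomised short trajectories.

Distances are haversine on a sphere of radius 6 371 000 m. At the 50 m
scales involved the difference from projected Euclidean distance is far
below GPS noise; a locally projected Euclidean metric (`metric="euclidean"`)
is exposed for comparison. Defaults: `d_max = 50` m, `t_min = 300` s. No
maximum-gap rule is applied inside a candidate window; gaps longer than an
hour are logged so users can audit sparse traces.

Degenerate inputs: sequences with fewer than two points yield no stays (a
single point has zero span and `t_min > 0`); duplicate records are dropped
at read time with a logged count; unparseable timestamps are fatal in
strict mode, otherwise skipped with their line numbers reported.

## Footfall and the recovery index

Stays are assigned to the unit polygon containing their centroid. Boundary
centroids are resolved by one fixed convention — among all units whose
closure covers the point, the smallest `unit_id` wins — so no stay is ever
double-counted between edge-adjacent cells; overlapping unit interiors are
rejected outright. A stay spanning midnight is attributed wholly to its
start date: the aggregation is daily and no splitting rule is defined at
that resolution, so the simplest deterministic choice is used. Footfall
counts stays, not unique users, by default (`count="users"` flips this);
counting stays is the reading consistent with footfall as a visit metric.

The recovery index divides each day's city-wide total by the mean daily
total over a benchmark window and scales to percent; a 7-day trailing
rolling mean (using whatever days exist at the series head) smooths the
weekly cycle. The index is invariant to rescaling all counts, and a zero
benchmark is a hard error rather than an infinity.

## HAZ delineation

Row standardisation uses the population standard deviation (divisor *t*,
not *t − 1*). Constant rows have no defined standardised pattern and are
excluded rather than imputed; they carry the sentinel label −1 in all
outputs and are dropped pairwise from partition comparisons. All-degenerate
matrices are a hard error.

Clustering is agglomerative with Euclidean distance on the standardised
rows. Ward linkage is the default — the natural companion of Euclidean
distance when clusters are meant to be variance-homogeneous — with
`average` and `complete` exposed. The cluster count is selected by
maximising the mean silhouette coefficient over a search range (default
[2, 15], wide enough to bracket the 5–8 zones typical of city-scale runs);
ties break toward fewer clusters. Silhouette is computed on the
standardised matrix with full pairwise distances, since that is the space
the clustering operates in. Agglomerative clustering has no random
initialisation, so a partition is a deterministic function of its input;
the tests assert this directly.

Labels are then ranked by descending mean daily raw footfall of member
units (raw, not standardised — ranking is about volume, standardisation
removed it), so label 0 is the busiest zone in every partition. Ranking
only permutes labels; memberships are untouched.

Per-phase delineation slices the matrix by the phase calendar and
re-standardises within each slice: a unit's zone in a phase reflects only
its pattern during that phase. Labels are per-partition ranks and carry no
correspondence across phases — cross-phase agreement is measured
statistically instead (below). Phases shorter than two days are rejected;
when a slice leaves fewer clusterable units than the requested `n_max`, the
range is clamped (logged) so sparse phases still delineate.

## Phase comparison

Two partitions are compared on the units clustered in both. The
cross-tabulation's Pearson χ² (no continuity correction — the statistic is
used descriptively) gives C = √(χ²/(χ²+N)) ∈ [0, 1): zero iff the table is
exactly independent, invariant under relabelling of either side, so the
per-partition rank ordering cannot bias it. Zero-margin rows/columns are
dropped before expected counts; a single-row or single-column table has
C = 0 by convention; expected counts below 5 trigger a warning, not a
correction.

## Urban association

The design matrix keeps the 11-column layout: ten land-use acreages plus
the supergroup as one integer-coded column. Integer coding (rather than
one-hot) preserves that width and keeps the importance decomposition
per-characteristic; a one-hot option exists with the caveat that it changes
how the importance total splits. Rows are ordered by sorted unit id, so the
design is independent of input row order.

Hyper-parameters (tree count ∈ {100, 200, 300}, depth ∈ {None, 4, 8, 16},
features-per-split ∈ {√p, log₂p, all, p/2}) are chosen by a seeded
randomised search of 15 configurations — "search with iterations" is read
as sampled draws, with an exhaustive-grid option — each scored by
stratified k-fold accuracy (default k = 10). The reported accuracy is the
best configuration's mean CV accuracy, labelled as such; the final model
refits on all rows. If the rarest label has fewer members than k the fold
count is reduced (warning); singleton classes fall back to unstratified
2-fold CV so small studies still complete. All randomness — search order,
fold shuffling, forests — derives from one seed.

Gini importance is the forest's mean decrease in impurity accumulated over
all splits and trees, normalised to sum to one; `gini_importance`
re-normalises defensively and errors on a forest with no splits. Under
label permutation the accuracy concentrates at the majority-class rate and
importances flatten; with the planted effect intact the informative column
ranks first. Both calibrations are asserted in the tests.

## Synthetic data

The generator emulates the structure the pipeline assumes, not a real
city. Units are rectangular grid cells laid out in a local metric frame
around a central-London origin and converted to lon/lat, so haversine
distances match nominal cell sizes. Each unit belongs to an archetype;
expected stays per unit-day are
`base_rate × weekday/weekend multiplier × phase multiplier`, with Poisson
counts. The packaged archetypes (busy-weekday, busy-weekend, flat,
recovering; base rates 4–6 stays/unit/day at demo scale) encode a drop to
roughly a third of baseline at the first lockdown with partial summer
recovery — the regime the recovery-index example reproduces (~37% at the
trough).

Planted stays become bursts of four points over ten minutes within a 20 m
jitter radius (strictly inside the 50 m / 5 min detection envelope),
centred at least 30 m inside their cell so the detected centroid cannot
drift across an edge. Transit points between consecutive stays are placed
150 m and 350 m from the stay centroid along the direction away from the
next stay: every transit point is >100 m from both adjacent stay centroids
and >50 m from its neighbouring transit point, so no transit point can
join, extend or seed a detected stay. Stays of one user are scheduled in
distinct 30-minute slots with a guaranteed ≥15-minute gap. These
constraints make the planted ledger an exact oracle: the detector must
recover precisely the planted stays, and the tests assert equality of
unit-day counts, totals and unit assignments.

Feature tables draw ten nonnegative acreage columns as truncated normals
around fixed baselines (noise SD 1.0); columns named in `feature_effect`
get per-archetype mean shifts (default: `lu_0` shifted 0–6 across the four
archetypes, a strong planted signal). The supergroup column is uniform over
its eight levels and archetype-independent, so the continuous effects alone
carry the association signal.

Two packaged studies fix the problem sizes: the end-to-end trajectory demo
(3×3 grid, 20 users, the full 424-day calendar; ~11.5 k planted stays from
~69 k points) and the association study (10×10 grid, 25 units per
archetype, footfall sampled directly from the rate model — at 100 units the
Poisson sampler is statistically identical to trajectory simulation plus
perfect detection, and orders of magnitude cheaper). Test scenarios for
planted-partition recovery raise base rates to 30 stays/unit/day so the
between-archetype separation is a documented multiple (~3×) of the Poisson
noise.

What the synthetic studies do *not* show: real GPS panels have device
noise, irregular sampling, urban canyons, home/work anchoring, uneven
population density and unit polygons far from rectangular; none of these
are modelled. Passing tests demonstrate the *method* is implemented
correctly and recovers planted structure under its stated assumptions, not
that real-city accuracies or zone counts will match any particular value.

## Calendar arithmetic

Day counts are inclusive of both endpoints; the first seven packaged
phases are consistent with that convention. The published count for the
eighth phase (51 days) disagrees with its own dates (53 by inclusive
arithmetic), and the published 422-day total likewise disagrees with the
424-day calendar span. The packaged calendar stores the dates as published
and keeps the published counts as `reported_days` metadata; duration
functions always return the arithmetic value, and the discrepancy is
asserted in the tests rather than silently corrected.

## Known limitations

Footfall is a visit count: it carries no origin–destination information and
cannot describe movement between units. Aggregation is daily; sub-daily
rhythms (commute peaks) are invisible. HAZs are non-contiguous by
construction — no spatial-contiguity constraint is offered. The
contingency coefficient is reported without significance testing, and its
upper bound depends on table dimensions, so values are comparable only
across tables of similar shape. Accuracy from the association stage is a
descriptive measure of association, not a causal statement about urban
form.
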