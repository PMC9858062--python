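# hazsense

**Dynamic human activity zones from GPS footfall.**

Mobile-phone GPS panels record where city dwellers pause — at work, in a
park, on a high street. `hazsense` turns those raw point streams into a
spatio-temporal account of urban activity and asks how it reorganised under
COVID-19-style policy restrictions. It is written for spatial-epidemiology
and urban-analytics researchers who want the full chain — stay detection,
footfall aggregation, activity zoning, and attribution to urban form — as a
tested, reproducible Python library rather than a one-off notebook.

The pipeline has three parts:

1. **Footfall detection.** For one user's time-ordered GPS sequence
   *P = (p₀, …, p_m)*, a *stay* is a maximal run of points that all lie
   within *d_max* of the run's first point and span at least *t_min*
   (defaults: 50 m, 5 min). Stays are counted per geospatial unit and day
   into the footfall matrix *A* (*m* units × *t* days). The city-wide daily
   total, as a percentage of its mean over a pre-pandemic benchmark window
   (2020-01-01 to 2020-02-29, 60 days), is the **recovery index**.
2. **HAZ delineation.** Each row of *A* is standardised,
   *B_ij = (A_ij − μ_i)/σ_i* with μ_i, σ_i the row mean and population SD,
   so clustering sees the *shape* of a unit's temporal profile, not its
   volume. Agglomerative clustering (Euclidean, Ward) groups units into
   *human activity zones*; the zone count *n* maximises the mean silhouette
   coefficient; labels are ranked so HAZ 0 is always the busiest. The
   procedure repeats per policy restriction phase (the packaged calendar
   holds the eight UK phases, 2020-01-01 to 2021-02-27), and partitions
   from different phases are compared with Pearson's contingency
   coefficient *C* = √(χ²/(χ²+N)).
3. **Urban association.** A random-forest classifier predicts each unit's
   HAZ label from 11 static features (ten land-use acreages + the
   socio-demographic supergroup). Cross-validated accuracy (stratified
   10-fold, 15 sampled hyper-parameter configurations) measures the global
   relationship; normalised Gini importance
   *I_G(v) = Σ_T Σ_τ Δi_v(τ, T)*, scaled so Σ I_G = 1, ranks the features.

Real GPS panels are proprietary, so the package ships a first-class
synthetic generator: planted stays inside grid-cell units whose daily rates
follow temporal *archetypes* (busy-weekday, busy-weekend, flat, recovering)
with per-phase multipliers, plus feature tables with planted associations.
The generator's planted-stay ledger is an *exact oracle* for the detector,
which is what makes the end-to-end pipeline testable.

## Worked example

```python
import hazsense as hz
from hazsense.synth import archetype_assignment
import datetime as dt

scenario = hz.demo_scenario(seed=1)              # 3x3 grid, 20 users, 8 phases
units = hz.generate_units(3, 3, 500)
assignment = archetype_assignment(units["unit_id"], scenario)
points, ledger = hz.generate_trajectories(scenario, units, assignment)

stays = hz.detect_stays_all(points, hz.StayParams())
assigned = hz.assign_stays_to_units(stays, units)
matrix = hz.build_footfall_matrix(assigned, units["unit_id"],
                                  scenario.calendar[0].start_date,
                                  scenario.calendar[-1].end_date)
rec = hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 2, 29))
print(len(stays), rec.benchmark, round(rec.rolling["2020-04-15"], 1))
```

prints `11505 46.6 37.4`: all 11,505 planted stays are recovered from
69,050 GPS points, the benchmark is 46.6 stays/day, and by mid-April 2020
the 7-day rolling recovery index sits at 37.4% — city-wide activity fell by
roughly two thirds after the first national lockdown, exactly the regime
the generator's phase multipliers encode. Clustering the same matrix
(`hz.delineate_hazs`) on a two-archetype scenario selects n = 2 zones with
adjusted Rand index 1.0 against the planted split, and the association
stage (`hz.fit_classifier`) on the packaged 100-unit study reaches 10-fold
CV accuracy 0.670 with the planted feature `lu_0` top-ranked at importance
0.536 (importances summing to 1). The `examples/` directory walks through
each capability as a runnable script, and `hazsense run-all` drives the
whole chain from a YAML config on the command line.

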