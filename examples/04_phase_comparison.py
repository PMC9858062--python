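"""Compare HAZ partitions across restriction phases.

Each phase gets its own HAZ partition (re-standardised within the phase);
Pearson's contingency coefficient C = sqrt(chi2/(chi2+N)) on the joint
label table quantifies how similar two phases' zonings are: 0 means the
partitions are independent, values near 1 mean units keep their zone.
"""

import hazsense as hz
from hazsense.synth import ArchetypeSpec

calendar = tuple(hz.default_calendar())
names = [p.name for p in calendar]

def mults(vals):
    return dict(zip(names, vals))

archetypes = (
    ArchetypeSpec("busy-weekday", 30, 1.5, 0.5, mults([1.0, 0.35, 0.6, 0.55, 0.5, 0.4, 0.45, 0.35])),
    ArchetypeSpec("busy-weekend", 30, 0.5, 1.5, mults([1.0, 0.45, 0.7, 0.6, 0.55, 0.6, 0.55, 0.45])),
    ArchetypeSpec("flat", 30, 1.0, 1.0, mults([1.0] * 8)),
    ArchetypeSpec("recovering", 30, 1.0, 1.0, mults([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1])),
)
scenario = hz.SyntheticScenario(
    archetypes=archetypes,
    n_units={a.name: 25 for a in archetypes},
    n_users=100,
    calendar=calendar,
    grid_rows=10,
    grid_cols=10,
    seed=11,
)
matrix, _ = hz.sample_footfall_matrix(scenario)
partitions = hz.delineate_per_phase(matrix, list(calendar), n_min=2, n_max=10)

for name, part in partitions.items():
    print(f"{name:32s} n={part.n} silhouette={part.silhouette:.3f}")

phase_parts = [partitions[p.name] for p in calendar]
cmatrix = hz.pairwise_matrix(phase_parts)
print("\npairwise contingency coefficients (first three phases):")
print(cmatrix.iloc[:3, :3].round(3).to_string())
print("\nhigh off-diagonal C: the same units fall in matching zones across "
      "those phases; the archetype structure persists through the calendar.")
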