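"""Attribute HAZ membership to static urban characteristics.

A random-forest classifier predicts each unit's HAZ label from 11 static
features (ten land-use acreages + the socio-demographic supergroup).
Cross-validated accuracy measures the global association; normalised Gini
importance ranks the features.  The generator plants the signal in lu_0,
so lu_0 should rank first.
"""

import hazsense as hz

scenario = hz.association_scenario(seed=3)
matrix, assignment = hz.sample_footfall_matrix(scenario)
partition = hz.delineate_hazs(hz.standardize_rows(matrix), matrix, 2, 15)
units = hz.generate_units(scenario.grid_rows, scenario.grid_cols, scenario.cell_size_m)
features = hz.generate_urban_features(units, assignment, scenario)

X, y = hz.build_design(features, partition)
result = hz.fit_classifier(X, y, cv_folds=10, n_param_draws=15, seed=3)
importances = hz.gini_importance(result)

print(f"design: {X.shape[0]} units x {X.shape[1]} features, {partition.n} HAZ labels")
print(f"10-fold CV accuracy: {result.cv_accuracy:.3f} (chosen: {result.best_params})")
print(f"importances sum to {importances.sum():.10f}; top three:")
print(importances.sort_values(ascending=False).head(3).round(3).to_string())
print("\nlu_0 carries the planted archetype effect, so it dominates; the "
      "remaining features share what is left of the (noise) signal.")
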