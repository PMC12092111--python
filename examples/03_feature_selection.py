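"""Run the three-stage feature selection on a synthetic cohort.

Stage 1 keeps PCs whose eigenvalues beat matched random data (parallel
analysis); stage 2 keeps features whose group Welch |t| >= 2; stage 3
repeats greedy forward selection under a 10-fold cross-validated naive
Bayes classifier and keeps the most frequently selected features.
"""

import numpy as np

import wavefeat as wf

dataset, truth = wf.generate_cohort(wf.CohortConfig(seed=42))
models = {v: wf.fit_variable_pca(dataset.variable_matrix(v), dataset.weights,
                                 variable=v) for v in wf.VARIABLES}

reference = wf.parallel_reference(dataset.n_trials, dataset.weights,
                                  n_reps=100, seed=1)
retained = {v: wf.parallel_analysis(models[v].eigenvalues, dataset.n_trials,
                                    dataset.weights, reference=reference)
            for v in wf.VARIABLES}
table = wf.build_score_table(dataset, models, retained)
print(f"parallel analysis: {sum(map(len, retained.values()))} of "
      f"{16 * 101} candidate (variable, PC) features survive")

screened = wf.screen_features(table)
print(f"Welch-t screening:  {int(screened['retained'].sum())} features with "
      f"|t| >= 2 survive")

selection = wf.sequential_selection(
    table, screened, n_iterations=200, seed=2,
    retained_after_parallel=[wf.FeatureId(*k) for k in table.feature_keys()])
print("\nmain features (selection frequency over 200 repetitions):")
for fid in selection.main_features:
    print(f"  {fid.label:>22s}  {selection.selection_frequency[fid]:4d}")
print("\nFrequent selection across random fold draws marks features whose "
      "group separation is stable, not a cross-validation accident; the "
      "planted variables "
      f"({', '.join(sorted({e.variable for e in truth}))}) should dominate.")
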