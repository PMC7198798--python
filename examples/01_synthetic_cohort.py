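"""Generate a synthetic two-group cytokine cohort and preprocess it.

Builds the default study-scale cohort (11 healthy controls, 12 ill
subjects, 16 plasma cytokines at 8 draws around peak exercise effort),
then runs the preprocessing chain: non-detect replacement, 3-min
interpolation, fold-change normalisation to the healthy resting baseline,
and slicing to the 4-h recovery window.
"""

import numpy as np

from immunet import default_cohort_spec, emit_cohort, preprocess

spec = default_cohort_spec(seed=1)
panel, truth = emit_cohort(spec)
print(f"panel: {len(panel.data)} records "
      f"({len(panel.subjects)} subjects x 16 cytokines x 8 draws)")

series = preprocess(panel)
lengths = {s.values.size for s in series}
fold_changes = np.concatenate([s.values for s in series])
print(f"preprocessed: {len(series)} recovery trajectories, "
      f"{sorted(lengths)} grid points each (3-min spacing over 0-240 min)")
print(f"fold-change range: {fold_changes.min():.2f} - {fold_changes.max():.2f} "
      "(1.0 = healthy resting level)")
# A value of 2.0 means that cytokine sits at twice the healthy-control
# resting concentration at that moment of recovery.
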