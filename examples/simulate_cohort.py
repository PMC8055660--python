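"""Generate a small synthetic aphasia cohort and look at what it contains.

The generator plants everything the downstream analysis is supposed to
recover: independent spatial sources mixed into each subject's BOLD
series, per-subject low-frequency power fractions (fALFF) for each source,
a multicollinear behavioral battery with ~3.3% missing baseline cells, and
bounded pre/post treatment scores driven by a known linear model.
"""

import numpy as np

from falff_prognosis import CohortConfig, make_cohort

cohort = make_cohort(CohortConfig(n_subjects=6, n_sources=3, seed=42))

print(f"subjects:           {len(cohort.scans)}")
print(f"scan shape (x,y,z,t): {cohort.scans[0].voxels.shape}, TR = "
      f"{cohort.scans[0].tr_seconds} s")
print(f"planted fALFF targets (subjects x sources):\n"
      f"{np.round(cohort.truth_falff, 3)}")
measures = [c for c in cohort.behavioral.columns if c != 'subject_id']
missing = cohort.behavioral[measures].isna().to_numpy().mean()
print(f"behavioral battery: {len(measures)} measures, "
      f"{100 * missing:.1f}% cells missing")
print(f"pre-treatment scores:  {np.round(cohort.pre_tsm, 3)}")
print(f"post-treatment scores: {np.round(cohort.post_tsm, 3)}")
# The post scores are clamp([0,1], 0.5*pre + weighted fALFF profile + noise);
# every stage downstream is judged by how well it recovers that structure.
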