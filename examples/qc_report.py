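"""Slice-wise tSNR quality control on a pair of runs.

tSNR (temporal signal-to-noise ratio) is mean signal over temporal
standard deviation; the per-scan summary weights each axial slice by its
brain-voxel count, and scans below 100 are excluded from analysis.
"""

import numpy as np

from falff_prognosis import Bold4D, qc_filter, select_best_run, slice_tsnr

rng = np.random.default_rng(7)
mask = np.ones((8, 8, 4), dtype=bool)

good = Bold4D(300 + 2.0 * rng.standard_normal((8, 8, 4, 60)), 2.0, mask, "good-run")
noisy = Bold4D(300 + 4.0 * rng.standard_normal((8, 8, 4, 60)), 2.0, mask, "noisy-run")

for scan in (good, noisy):
    report = slice_tsnr(scan)
    print(f"{scan.subject_id}: weighted tSNR = {report.weighted_tsnr:6.1f} "
          f"({'pass' if report.passed else 'FAIL'})")
# good-run sits near 300/2 = 150 and passes; noisy-run near 75 and fails.

retained, log = qc_filter([good, noisy])
print(f"retained after QC: {[s.subject_id for s in retained]}")
best = select_best_run([noisy, good])
print(f"best of the two runs: {best.subject_id}")
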