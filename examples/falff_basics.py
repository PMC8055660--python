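"""What fALFF measures, on signals whose answer is known analytically.

fALFF is the fraction of spectral power in the 0.01-0.08 Hz band. A slow
oscillation inside the band scores ~1, a fast one ~0, and white noise
scores the band's share of the positive-frequency axis:
(0.08 - 0.01) / 0.25 = 0.28 at TR = 2 s.
"""

import numpy as np

from falff_prognosis import component_falff, normalize_subject

t = np.arange(210) * 2.0  # 210 volumes at TR = 2 s
slow = np.sin(2 * np.pi * 0.05 * t)
fast = np.sin(2 * np.pi * 0.20 * t)
noise = np.random.default_rng(0).standard_normal(210)

print(f"0.05 Hz sinusoid: fALFF = {component_falff(slow, 2.0):.4f}  (expected ~1)")
print(f"0.20 Hz sinusoid: fALFF = {component_falff(fast, 2.0):.4f}  (expected ~0)")
print(f"white noise:      fALFF = {component_falff(noise, 2.0):.4f}  (expected ~0.28)")

raw = np.array([0.2, 0.2, 0.4])
print(f"sum-to-one standardization of {raw}: {normalize_subject(raw)}")
# Per-subject standardization turns absolute band power into a relative
# power profile, removing global scanner/physiology scaling differences.
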