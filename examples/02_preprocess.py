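"""Clean a contaminated pulse record: smoothing + baseline removal.

A clean record is polluted with white noise, a 50 Hz powerline tone and
0.25 Hz respiratory drift, then preprocessed.  The printed numbers show
how much of each contaminant survives.
"""

import numpy as np

from pulseseg import NoiseParams, generate_record, preprocess
from pulseseg.synthgen import PulseRecord

clean, _, _ = generate_record("normal", noise=NoiseParams.none(), seed=7)
fs, n = clean.fs, len(clean)
t = np.arange(n) / fs

rng = np.random.default_rng(7)
drift = 0.3 * np.sin(2 * np.pi * 0.25 * t + 0.5)
powerline = 0.05 * np.sin(2 * np.pi * 50 * t)
noisy = PulseRecord(
    clean.samples + drift + powerline + 0.05 * rng.standard_normal(n), fs=fs
)

out = preprocess(noisy)

basis = np.column_stack([np.sin(2 * np.pi * 0.25 * t), np.cos(2 * np.pi * 0.25 * t)])
coef, *_ = np.linalg.lstsq(basis, out.samples, rcond=None)
residual_drift = np.hypot(*coef)

a = clean.samples - clean.samples.mean()
b = out.samples - out.samples.mean()
corr = a @ b / np.sqrt((a @ a) * (b @ b))

print(f"injected drift amplitude : 0.300, residual after cleaning: {residual_drift:.3f}")
print(f"correlation with the clean record: {corr:.3f}")
print("High-frequency noise goes to the 20 Hz zero-phase low-pass; drift")
print("goes to the zeroed deepest bands of a 10-level sym8 decomposition.")
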