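"""Simulate and refit one MOLLI voxel.

Generates magnitude inversion-recovery samples with the pre-contrast
4(10)10 scheme at SNR 40, restores the polarity of the early samples,
fits the three-parameter model S(TI) = A - B exp(-TI/T1*) and applies
the Look-Locker correction T1 = T1* (B/A - 1).
"""

import numpy as np

import hepecv as h

truth_t1 = 593.3  # ms, a healthy liver
scheme = h.parse_scheme("4(10)10")
signal = h.simulate_signal(truth_t1, scheme, snr=40.0, seed=42)
result = h.fit_signal(signal)

print(f"truth T1          : {truth_t1:.1f} ms")
print(f"samples           : {len(signal.inversion_times)} TIs, "
      f"{signal.inversion_times.min():.0f}-{signal.inversion_times.max():.0f} ms")
print(f"flipped samples   : {result.polarity_flip_index} (below the null point)")
print(f"fitted A, B       : {result.a_amp:.4f}, {result.b_amp:.4f}")
print(f"apparent T1*      : {result.t1_star:.1f} ms")
print(f"corrected T1      : {result.t1_corrected:.1f} ms")
print(f"residual RMS      : {result.residual_rms:.4f} signal units")

noiseless = h.fit_signal(h.simulate_signal(truth_t1, scheme, snr=np.inf))
print(f"\nnoiseless refit   : {noiseless.t1_corrected:.3f} ms "
      "(round-trip error below 0.1 ms)")
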