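"""PLV, wPLI and transfer entropy on signals with known coupling.

Three scenarios: a phase-locked pair with a quarter-cycle lag (PLV and
wPLI both saturate), an uncoupled pair (both near their null floor), and
a lag-1 driven pair (transfer entropy is directional).
"""

import numpy as np

from neuroplex import (
    OscillatorSpec,
    analytic_band,
    gen_oscillators,
    plv,
    transfer_entropy,
    wpli,
)

coupling = np.array([[0.0, 1.0], [1.0, 0.0]])
lag = np.zeros((2, 2))
lag[0, 1] = np.pi / 2

locked = analytic_band(
    gen_oscillators(
        OscillatorSpec(n_rois=2, coupling=coupling, phase_lag=lag, noise_sd=0.0, seed=2)
    ),
    (8.0, 12.0),
)
print("phase-locked pair, 90 degree lag:")
print(f"  PLV  = {plv(locked.signals[0], locked.signals[1]):.3f}  (expected 1)")
print(f"  wPLI = {wpli(locked.signals[0], locked.signals[1]):.3f}  (expected 1)")

free = analytic_band(
    gen_oscillators(OscillatorSpec(n_rois=2, duration_s=120, seed=3)), (8.0, 12.0)
)
print("uncoupled pair (independent phase diffusion):")
print(f"  PLV  = {plv(free.signals[0], free.signals[1]):.3f}  (null floor, < 0.1)")

influence = np.zeros((2, 2))
influence[0, 1] = 0.9  # ROI 0 drives ROI 1 at a 1-sample lag
driven = analytic_band(
    gen_oscillators(
        OscillatorSpec(n_rois=2, directed_influence=influence, noise_sd=0.2, seed=4)
    ),
    (8.0, 12.0),
)
x = driven.signals.real
fwd = transfer_entropy(x[0], x[1])
rev = transfer_entropy(x[1], x[0])
print("lag-1 driven pair:")
print(f"  TE(0 -> 1) = {fwd:.4f} bits, TE(1 -> 0) = {rev:.4f} bits")
# The forward direction carries several times more predictive
# information than the reverse, recovering the planted drive.
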