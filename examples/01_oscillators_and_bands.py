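"""Simulate coupled ROI oscillators and anchor frequency bands at the alpha peak.

Generates a 4-ROI subject whose first two ROIs share a phase-coupled
alpha rhythm, detects the individual alpha frequency (IAF) from the
spectra, and prints the IAF-anchored band scheme.
"""

import numpy as np

from neuroplex import OscillatorSpec, define_bands, detect_iaf, gen_oscillators

coupling = np.zeros((4, 4))
coupling[0, 1] = coupling[1, 0] = 0.998  # a strongly phase-coupled pair

spec = OscillatorSpec(n_rois=4, iaf_hz=9.6, coupling=coupling, seed=1)
ts = gen_oscillators(spec)

iaf = detect_iaf(ts)
scheme = define_bands(iaf)

print(f"true alpha peak: {spec.iaf_hz:.2f} Hz, detected IAF: {iaf:.2f} Hz")
for name, (lo, hi) in scheme.bands.items():
    print(f"  {name:>6}: {lo:5.2f} - {hi:5.2f} Hz")
# The detected IAF should sit within one spectral bin (0.25 Hz) of the
# true peak, and every band edge is the IAF plus a fixed offset.
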