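"""Recover the acceptor->donor channel transform from fiducial beads.

The simulated image splitter offsets, rotates and rescales the acceptor
half slightly; multicolour beads visible in both channels calibrate the
affine map that the FRET pairing stage then uses.
"""

import math

import numpy as np

from fretspt import SimulationConfig, simulate_bead_movie, register_channels

theta = math.radians(0.4)
scale = 1.0008
misalignment = (scale * math.cos(theta), -scale * math.sin(theta), 0.08,
                scale * math.sin(theta), scale * math.cos(theta), -0.05)
config = SimulationConfig(field_size=(128, 128), seed=5,
                          acceptor_misalignment=misalignment)

beads = simulate_bead_movie(config, n_beads=12, n_frames=20)
transform = register_channels(beads)

print(f"matched fiducials: {transform.n_fiducials}")
print(f"rms residual: {transform.rms_residual_nm:.1f} nm")
print("fitted matrix:")
print(np.array_str(transform.matrix, precision=5))
print(f"fitted offset (um): {np.array_str(transform.offset, precision=4)}")
probe = np.array([10.0, 10.0])
M = np.array(misalignment).reshape(2, 3)
roundtrip = transform.apply(probe @ M[:, :2].T + M[:, 2])
print(f"probe (10, 10) um maps back with "
      f"{np.hypot(*(roundtrip - probe)) * 1000:.2f} nm error")
# Residuals of a few nm are far below the 250 nm pairing radius, so
# registration never limits donor/acceptor matching.
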