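"""Fit and apply a second-order chromatic-aberration map from bead positions.

Multicolor imaging shows the same fiducial bead at slightly different
positions in different color channels.  A full second-order bivariate
polynomial (nine coefficients per axis) maps one channel onto the reference;
here we distort a synthetic bead grid by a known polynomial field and recover
it to numerical precision.
"""

import numpy as np

import tricorr as tc

rng = np.random.default_rng(0)
grid = np.linspace(400.0, 9600.0, 6)
beads_488 = np.array([[x, y] for x in grid for y in grid]) + rng.uniform(-150, 150, (36, 2))

# a plausible chromatic distortion: offset + slight magnification + curvature
kx = np.array([75.0, 2e-3, 0.0, 1.002, -1e-6, 0.0, 3e-8, 0.0, 0.0])
ky = np.array([-40.0, 0.997, 2e-7, 1e-3, 2e-6, 0.0, 0.0, 0.0, 0.0])
x, y = beads_488[:, 0], beads_488[:, 1]
design = np.column_stack([x ** (j // 3) * y ** (j % 3) for j in range(9)])
beads_639 = np.column_stack([design @ kx, design @ ky])

pmap = tc.fit_polynomial_map(beads_639, beads_488, source="488", reference="639")
print(f"RMS residual over the fitting beads: {pmap.rms_residual_nm:.2e} nm")
print(f"max coefficient error (x axis): {np.abs(pmap.kx - kx).max():.2e}")

aligned = tc.apply_polynomial_map(pmap, beads_488)
print(f"max alignment error: {np.abs(aligned - beads_639).max():.2e} nm")
print(
    "\nResiduals at the picometre level show the distortion lies inside the\n"
    "model class and the centered/rescaled solve is numerically sound; on\n"
    "real beads the residual reports the remaining chromatic error."
)
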