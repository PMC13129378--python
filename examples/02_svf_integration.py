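"""Stationary-velocity-field integration by scaling and squaring.

An SVF is turned into a dense displacement field by halving it 7 times and
self-composing 7 times — the discrete exponential map.  Against a slow
256-step Euler flow integration the error is far below a tenth of a voxel,
and the resulting warp is effectively free of foldings (negative Jacobian
determinants).
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from mr4dctreg import (Grid, VelocityField, compose, integrate_svf,
                       integrate_svf_euler, jacobian_report)

grid = Grid((24, 24, 24))
rng = np.random.default_rng(0)
u = np.stack([gaussian_filter(rng.normal(size=grid.shape), 4.0)
              for _ in range(3)])
u = u / np.abs(u).max() * 3.0  # max 3-voxel velocity
svf = VelocityField(grid, u)

ddf = integrate_svf(svf, steps=7)
euler = integrate_svf_euler(svf, steps=256)
err = np.abs(ddf.u - euler.u).max()
print(f"max |scaling-and-squaring - Euler|: {err:.4f} voxels "
      "(agreement of the fast and the reference integrator)")

rep = jacobian_report(ddf)
print(f"foldings: {100 * rep.foldings_fraction:.4f}% of voxels, "
      f"std log-Jacobian: {rep.std_log_jacobian:.4f}")

inv = integrate_svf(VelocityField(grid, -u))
round_trip = compose(ddf, inv)
interior = (slice(None),) + (slice(4, -4),) * 3
print(f"forward-then-inverse residual (interior): "
      f"{np.abs(round_trip.u[interior]).max():.4f} voxels "
      "(near-diffeomorphism: negating the velocity inverts the warp)")
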