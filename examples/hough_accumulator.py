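"""Hough-transform input synapses as a spiking accumulator.

The input synapse map connects each pixel to the (rho, theta) cells whose
line passes through it, so post-synaptic spike counts realise the Hough
transform.  A vertical stroke should light up exactly one cell at
theta = 0.
"""

import numpy as np

from modlsm import (
    EncoderConfig,
    HoughLineGrid,
    ToyShapeSpec,
    build_line_hough,
    make_shape_image,
    poisson_encode,
)

grid = HoughLineGrid()
syn = build_line_hough(grid, (28, 28))
print(f"line grid: {grid.n_rho} rho x {grid.n_theta} theta = {syn.n_post} neurons, "
      f"{syn.n_synapses} synapses")

image = make_shape_image(ToyShapeSpec("vline", {"x": 9}))
raster = poisson_encode(image, EncoderConfig(n_steps=400), seed=0)

# drive the accumulator directly: each post cell counts its presynaptic spikes
w = syn.matrix()
votes = np.asarray(w @ raster.counts()).reshape(grid.n_rho, grid.n_theta)
peak = np.unravel_index(votes.argmax(), votes.shape)
print(f"peak accumulator cell: rho bin {peak[0]} "
      f"(rho ~ {grid.rho_values[peak[0]]:.1f}), theta index {peak[1]} "
      f"(theta = {np.degrees(grid.theta_values[peak[1]]):.0f} deg)")
print(f"peak votes: {votes[peak]:.0f} vs median cell {np.median(votes):.0f}")
# A vertical line x = 9 satisfies rho = x cos(0): the peak sits in the rho
# bin containing 9 at theta = 0 and towers over every other cell.
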