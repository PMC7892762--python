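# modlsm — modular liquid state machines with Hough-transform input synapses

`modlsm` is a toolkit for building and analysing **liquid state machines
(LSMs)**: reservoirs of spiking leaky integrate-and-fire (LIF) neurons whose
states are read out by a trained linear classifier.  Its focus is a
*modular* reservoir architecture in which the reservoir is partitioned into
internally recurrent modules aligned on a directed acyclic graph (DAG), and
in which the input synapses are wired to perform a **Hough transform** — a
fixed, biologically motivated feature map from image pixels to line and
circle parameter space.  It is written for computational-neuroscience and
reservoir-computing practitioners who want to study how reservoir topology
affects classification performance, computational cost, and robustness to
structural damage.

## The model

**Encoding.** A grayscale image is filtered with a difference-of-Gaussians
kernel (size 7, σ₁ = 1, σ₂ = 2), approximating retinal centre–surround
receptive fields, and converted to spike trains by Poisson coding: pixel *i*
spikes in each 0.4 ms step with probability *r·dt*, where *r* scales
linearly with intensity up to 160 spikes/s; a presentation lasts 1,600
steps, preceded by 50 ms of silence.

**Input synapses.** Binary synapse maps implement the Hough transforms

&nbsp;&nbsp;W<sub>(ρ,θ),(x,y)</sub> = δ(ρ − x·cos θ − y·sin θ)  (lines, 16 ρ × 12 θ = 192 cells)
&nbsp;&nbsp;W<sub>(a,b,r),(x,y)</sub> = δ(r² − (x−a)² − (y−b)²)  (circles, 6×6×6 = 216 cells)

so post-synaptic firing rates accumulate Hough votes.  Because the exact
delta condition is rarely satisfiable on an integer pixel grid, the default
quantisation assigns each pixel to the nearest parameter bin (a strict mode
is kept for oracle checks).

**Reservoir.** Four topology families at matched size: Erdős–Rényi random
(N = 1,500, p = 0.01), small-world (8-neighbour king lattice, rewiring
probability 0.35), metric (neurons on a 15×10×10 integer lattice wired with
probability C·exp(−D²/λ²), λ = 2), and the modular network: the two Hough
layers plus eight 9×15 small-world modules (1,488 neurons total) coupled by
a random DAG (edge probability 0.25) with a constant-weight fan-out of 10
per inter-module connection.

**Dynamics.** LIF membranes obey τ dV/dt = −(V − V_rest) + R·I(t) with
V_th = 15 mV, V_reset = V_rest = 13.5 mV, τ = 30 ms, refractory 5 ms
(excitatory) / 2 ms (inhibitory); synaptic weights are 20 (ex→ex), 45
(ex→in) and −17 (inhibitory pre), with conduction delays 1.5 ms (ex→ex) /
0.8 ms (otherwise).  Integration is exponential-Euler, exact for the
piecewise-constant delta-synapse currents.

**Divide and conquer.** Because inter-module connections form a DAG,
modules can be simulated one at a time in topological order, each for the
full duration, using predecessors' recorded rasters as input.
`simulate_modular` implements this and is *bit-identical* to
`simulate_monolithic` — while the dense per-iteration cost drops from
2(ΣN_m)² to Σ2N_m² plus sparse inter-module terms, less than half at 10
modules.

**Readout.** Per-neuron mean firing rates (settle phase excluded) feed a
linear SVM (C = 1, one-vs-rest).

## A worked example

```python
import numpy as np
from modlsm import (EncoderConfig, TopologyConfig, ToyShapeSpec,
                    apply_dog, assemble_reservoir, build_input_synapses,
                    count_flops, dog_kernel, make_shape_image,
                    poisson_encode, simulate_modular, simulate_monolithic)

cfg = TopologyConfig.full("modular")
net = assemble_reservoir(cfg, seed=7)
inputs = build_input_synapses(net, cfg, (28, 28), "hough", seed=7)
image = make_shape_image(ToyShapeSpec("circle", {"cx": 13, "cy": 13, "r": 6}))
raster = poisson_encode(apply_dog(image, dog_kernel(7, 1, 2)),
                        EncoderConfig(n_steps=400, settle_steps=50), seed=7)
mono = simulate_monolithic(net, inputs, raster, settle_steps=50)
mod = simulate_modular(net, inputs, raster, settle_steps=50)
print(net.n_neurons, np.array_equal(mono.spikes, mod.spikes), count_flops(net).ratio)
```

prints

```
1488 True 0.16944814045563705
```

— a 1,488-neuron, 10-module reservoir whose modular simulation reproduces
the monolithic raster exactly while costing ~17% of the dense monolithic
FLOPs per iteration.  The scripts in `examples/` walk through each
capability (encoding, Hough accumulators, classification, ablation
robustness) and print what the numbers mean.

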