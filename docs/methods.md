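# Methods

This note documents the model implemented by `modlsm`, the choices made
where the design was genuinely open, what the synthetic data emulates, and
the limits of what the tests show.

## Model and assumptions

The system is a liquid state machine: a fixed spiking reservoir transforms
an input spike stream, and only a linear readout is trained.  Three
assumptions shape the implementation:

1. **Delta synapses, piecewise-constant current.**  A presynaptic spike
   contributes its weight to the post-synaptic input current for exactly
   one time step, after a type-dependent integer conduction delay.  No
   synaptic filtering is modelled.
2. **Clock-driven integration.**  All neurons advance on a common 0.4 ms
   grid.  The membrane update uses the exponential-Euler map
   `V ← V_rest + (V − V_rest)·e^(−dt/τ) + R·I·(1 − e^(−dt/τ))`, which is
   the exact solution for constant current over a step; the zero-input
   decay therefore matches the closed form to ~1e−9 per step (a forward
   Euler scheme is available behind a flag).
3. **Acyclic inter-module structure.**  Recurrence lives inside modules;
   between modules information flows only along a DAG.  This is what makes
   divide-and-conquer simulation exact rather than approximate.

## Parameters

| parameter | default | unit | notes |
|---|---|---|---|
| V_th / V_reset / V_rest | 15 / 13.5 / 13.5 | mV | reset equals rest; implemented verbatim |
| τ_mem | 30 | ms | |
| R | 1 | — | gain absorbed by synaptic weights |
| refractory (ex / in) | 5 / 2 | ms | 13 / 5 steps at dt = 0.4 ms (ceil) |
| weights ex→ex / ex→in / inhibitory pre | 20 / 45 / −17 | mV·step | the "in–ex = 45" label is read post–pre |
| delays ex→ex / other | 1.5 / 0.8 | ms | 4 / 2 steps (ceil, after rounding the quotient to 9 decimals) |
| peak input rate | 160 | spikes/s | per-step probability 0.064 |
| presentation / settle | 1,600 / 125 | steps | 640 ms + 50 ms silence |
| DoG | size 7, σ 1 and 2 | px | each Gaussian normalised to sum 1; kernel sums to 0 |
| Hough grids | 16 ρ × 12 θ; 6×6×6 (a,b,r) | — | ρ spans ±27√2; θ on [0,π); centres span the image; radii 3–13 px |
| DAG | 10 modules, p = 0.25 | — | candidate edges j→i, i > j, head not an input module |
| inter-module wiring | fan-out 10, weight 20 | — | constant weight, type-pair delays |

## Open design points and how they were resolved

- **Threshold comparison** is `V ≥ V_th` (a strict equality is measure-zero
  in floating point).
- **Negative DoG responses** are rectified to zero before rate scaling
  (single ON channel).  A two-channel ON/OFF mode exists
  (`rectify_negatives=False`) but is off by default.
- **Hough quantisation.**  The delta conditions are almost never exactly
  satisfiable off-axis on an integer pixel grid, so by default each pixel
  votes into the bin containing its parameter value, as classical Hough
  accumulators do; `quantization="strict"` keeps the exact condition for
  oracle tests.  With the default ρ range (±27√2) a few extreme-negative ρ
  bins are unreachable by construction; the module size is still the full
  grid.
- **Excitatory fraction** is 80/20 (the convention of the metric-network
  literature); the Hough layers are all-excitatory and, by default,
  without internal recurrence — they act as feed-forward accumulator
  layers.  Both are configurable.
- **Input wiring for non-modular reservoirs** follows the audio-task
  recipe: each input pixel connects to 10 uniformly drawn reservoir
  neurons, with excitatory-pre weights/delays.
- **Current accumulation order** is canonical — per target module: input
  projections, inter-module projections sorted by source, then the
  module's own recurrent synapses, each split by ascending delay — in both
  simulators.  Together with CSR mat-vec determinism (asserted by a unit
  test) this makes modular and monolithic rasters bit-identical, which the
  suite checks at full 1,488-neuron scale.
- **FLOP accounting** uses an explicit convention (multiply-add = 2 ops,
  6 ops per neuron update, sparse mode 2 ops per alive synapse).  Absolute
  numbers depend on the convention, so only relative claims are asserted:
  at 10 modules the dense modular count is below half the monolithic one.
- **Robustness protocol.**  `robustness_sweep` trains the readout on the
  intact network and evaluates it after damage: robustness to structural
  failure means a *trained* system keeps working.  Retraining on the
  damaged network largely restores accuracy (the information is still
  there; the mapping moved) and is available via `retrain=True`.  Damage
  applies to input synapses as well as reservoir synapses by default
  (`ablate_inputs`): a network's wiring does not spare afferents when
  synapses die, and the contrast between pooled, redundant Hough maps and
  sparse random fan-ins is precisely what the damage experiment probes.
  With damage restricted to recurrent synapses, firing-rate features
  barely move in any topology (the drive is input-dominated at these
  scales) and no topology deteriorates measurably.
- **Dead synapse counts are exact** (`round(fraction · E)` drawn without
  replacement), not binomial, so quoted percentages are realised exactly.

## Synthetic data

`make_toy_dataset` generates 28×28 stroke images in four classes: vertical
lines, horizontal lines, diagonal lines, and circles.  The `jitter`
parameter scales within-class geometric variability (stroke position and
diagonal offset up to ±9 px, circle radius ±3 px, plus mild pixel
dropout/speckle); at jitter 0 every image of a class is identical.  The
classes are chosen so each Hough layer is discriminative — line classes
differ in θ, the circle class in (a,b,r) — mirroring how digit strokes
light up line- and circle-accumulator cells.

What the toy data does **not** emulate: stroke curvature and thickness
variation, overlapping strokes, intensity gradients, and the class overlap
of real handwritten digits.  Passing the scaled-down studies therefore
shows that the pipeline's mechanisms (Hough feature extraction, reservoir
expansion, modular robustness) work in the designed regime; it does not
certify benchmark accuracy on real digit data.  Full-scale replication is
supported through the IDX loaders but requires externally supplied files.

## Study sizes

The property studies in the acceptance tests use the benchmark-size
reservoirs (1,488–1,500 neurons) with a shortened presentation (400 steps
of 0.4 ms + 50-step settle), a 4-class stroke dataset at full jitter, 30
training and 10 test images per class, and 5–10 seeds.  The presentation
length is the scaled-down dimension: rate features stabilise well within
400 steps, whereas shrinking the reservoirs to a few hundred neurons
weakens the reservoir-vs-baseline effect the studies measure (small
random-projection reservoirs do not reliably out-separate a linear readout
on raw pixel rates).  `TopologyConfig.small()` still provides ~730-neuron
configurations for quick exploration, and trials are simulated in chunks
of 40 to bound memory.

## Known limitations

- On the stroke dataset the reservoir-over-baseline benefit is specific to
  the Hough-structured modular network: in the suite's benefit study the
  random-input reservoirs (small-world, metric, random) average a few
  points *below* the linear SVM on encoded pixel rates, and the gap does
  not close with more training data.  The stroke classes are close to
  linearly separable from filtered pixels, so a random fan-in expansion
  mostly discards spatial precision; conclusions about random-input
  reservoirs on harder data cannot be drawn from this fixture.
- The modular/monolithic equality contract assumes both simulators run on
  the same platform and scipy build; it is a statement about scheduling,
  not about cross-platform float reproducibility.
- `LinearSVC` duplication invariance holds only up to solver tolerance.
- The small-world out-degree of a boundary-exact 9×15 king lattice is
  940/135 ≈ 6.96 before rewiring; reported mean degrees for such lattices
  elsewhere (e.g. 7.2) depend on unstated boundary handling, so no exact
  target is asserted for it.
- Plasticity (STDP, pruning), conductance-based neurons, event-driven
  simulation, and audio preprocessing are out of scope.
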