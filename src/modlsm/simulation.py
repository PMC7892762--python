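"""LIF network simulation: monolithic and divide-and-conquer modular.

The membrane equation ``tau_mem dV/dt = -(V - V_rest) + R I(t)`` is
integrated with the exponential-Euler scheme (exact for the
piecewise-constant currents produced by delta synapses):

    V <- V_rest + (V - V_rest) e^(-dt/tau) + R I (1 - e^(-dt/tau))

A neuron whose voltage reaches threshold spikes, resets, and is clamped
(no integration) for its type's refractory period.  ``I(t)`` is the sum of
delayed, weighted presynaptic spikes, ``W_in x S_in + W_res x S_res``.

Two simulators are provided.  :func:`simulate_monolithic` steps the whole
network clock-synchronously.  :func:`simulate_modular` exploits the acyclic
module graph: modules are simulated one at a time in topological order,
each for the full duration, using the recorded spike rasters of its
predecessor modules as exogenous input.  Because no information ever flows
against the DAG, the two schedules produce *bit-identical* rasters — the
correctness contract of the divide-and-conquer method.  To make the
equality exact rather than approximate, both simulators accumulate synaptic
current in the same canonical order (input projections, then inter-module
projections by source, then the module's own recurrent synapses, each
split by ascending delay) so floating-point summation order coincides.

Both simulators accept a single input raster or a batch (trials are
independent, so batching is pure vectorisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .params import LIFParams
from .raster import SpikeRaster
from .synapses import SynapseSet
from .topology import Network

__all__ = [
    "NetworkState",
    "SimulationResult",
    "lif_step",
    "simulate_monolithic",
    "simulate_modular",
    "extract_features",
]


@dataclass
class NetworkState:
    """Evolving per-neuron state: voltage and remaining refractory steps."""

    v: np.ndarray
    refractory: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.refractory = np.asarray(self.refractory, dtype=np.int64)
        if (self.refractory < 0).any():
            raise ValueError("refractory counters must be non-negative")


@dataclass
class SimulationResult:
    """Spike output of a simulation run.

    ``spikes`` has shape (n_trials, n_neurons, settle_steps + n_steps);
    for single-raster input ``n_trials`` is 1 and :attr:`raster` gives the
    squeezed :class:`SpikeRaster`.
    """

    spikes: np.ndarray
    dt: float
    settle_steps: int
    module_slices: dict[int, slice]
    single: bool = True
    voltages: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[2] - self.settle_steps

    @property
    def raster(self) -> SpikeRaster:
        return SpikeRaster(self.spikes[0], dt=self.dt, meta=dict(self.meta))

    def module_raster(self, module: int, trial: int = 0) -> SpikeRaster:
        return SpikeRaster(
            self.spikes[trial, self.module_slices[module]], dt=self.dt
        )


def _decay(params: LIFParams, dt: float, integration: str) -> tuple[float, float]:
    """(decay factor on V - V_rest, gain on R*I) for one step."""
    if integration == "exponential":
        alpha = float(np.exp(-dt / params.tau_mem))
        return alpha, 1.0 - alpha
    if integration == "forward":
        return 1.0 - dt / params.tau_mem, dt / params.tau_mem
    raise ValueError("integration must be 'exponential' or 'forward'")


def _lif_update(v, refractory, current, refr_steps, params, alpha, gain):
    """One LIF step on arrays; identical arithmetic in every simulator."""
    v_new = params.v_rest + (v - params.v_rest) * alpha + params.r * current * gain
    v = np.where(refractory > 0, v, v_new)
    spikes = (refractory == 0) & (v >= params.v_th)
    v = np.where(spikes, params.v_reset, v)
    refractory = np.where(spikes, refr_steps, np.maximum(refractory - 1, 0))
    return v, refractory, spikes


def lif_step(
    state: NetworkState,
    input_current: np.ndarray,
    params: LIFParams,
    dt: float,
    excitatory: np.ndarray | None = None,
    integration: str = "exponential",
) -> tuple[NetworkState, np.ndarray]:
    """Advance a population of LIF neurons by one step.

    Refractory neurons do not integrate; neurons reaching ``v_th`` emit a
    spike, reset to ``v_reset`` and enter their type's refractory period
    (all neurons excitatory when ``excitatory`` is omitted).
    """
    current = np.asarray(input_current, dtype=np.float64)
    if not np.isfinite(current).all():
        raise ValueError("input current must be finite")
    if excitatory is None:
        excitatory = np.ones(state.v.shape, dtype=bool)
    refr_steps = params.refractory_steps(excitatory, dt)
    alpha, gain = _decay(params, dt, integration)
    v, refractory, spikes = _lif_update(
        state.v, state.refractory, current, refr_steps, params, alpha, gain
    )
    return NetworkState(v, refractory, state.step + 1), spikes


# ---------------------------------------------------------------------------
# Projection compilation
# ---------------------------------------------------------------------------
def _module_of(pop: str) -> int:
    if not pop.startswith("m"):
        raise ValueError(f"population {pop!r} is not a module ('m<id>')")
    return int(pop[1:])


class _Compiled:
    """A projection lowered to per-delay CSR matrices plus routing info."""

    __slots__ = ("post_module", "kind", "pre_module", "order", "groups")

    def __init__(self, syn: SynapseSet, order: int):
        self.post_module = _module_of(syn.post_pop)
        if syn.pre_pop == "input":
            self.kind, self.pre_module = 0, -1
        elif syn.pre_pop == syn.post_pop:
            self.kind, self.pre_module = 2, self.post_module
        else:
            self.kind, self.pre_module = 1, _module_of(syn.pre_pop)
        self.order = order
        self.groups = syn.delay_groups()

    def sort_key(self):
        return (self.post_module, self.kind, self.pre_module, self.order)


def _compile(network: Network, input_synapses: list[SynapseSet]) -> list[_Compiled]:
    compiled = [_Compiled(s, k) for k, s in enumerate(input_synapses)]
    compiled += [_Compiled(s, k) for k, s in enumerate(network.projections)]
    compiled.sort(key=_Compiled.sort_key)
    return compiled


def _prepare_input(input_raster, dt):
    """Normalise input to (n_trials, n_pix, n_steps) float and report dt."""
    if isinstance(input_raster, SpikeRaster):
        return input_raster.spikes[None].astype(np.float64), input_raster.dt, True
    arr = np.asarray(input_raster, dtype=np.float64)
    if arr.ndim == 2:
        return arr[None], dt, True
    if arr.ndim == 3:
        return arr, dt, False
    raise ValueError("input raster must be 2-D or 3-D")


def _check_wiring(network: Network, input_synapses, n_pix: int) -> None:
    sizes = network.module_sizes
    for s in input_synapses:
        if s.pre_pop != "input":
            raise ValueError("input synapse sets must have pre_pop 'input'")
        if s.n_pre != n_pix:
            raise ValueError(
                f"input raster has {n_pix} channels but synapses expect {s.n_pre}"
            )
        if sizes.get(_module_of(s.post_pop)) != s.n_post:
            raise ValueError(f"input projection targets unknown module {s.post_pop}")
    for s in network.projections:
        if sizes.get(_module_of(s.pre_pop)) != s.n_pre or sizes.get(
            _module_of(s.post_pop)
        ) != s.n_post:
            raise ValueError("projection inconsistent with module sizes")


def simulate_monolithic(
    network: Network,
    input_synapses: list[SynapseSet],
    input_raster,
    params: LIFParams | None = None,
    settle_steps: int = 125,
    dt: float = 0.4,
    integration: str = "exponential",
    record_v: bool = False,
) -> SimulationResult:
    """Clock-synchronous simulation of the whole network.

    A silent settle phase of ``settle_steps`` (50 ms at the default step)
    precedes the input so all membranes sit at rest; the returned raster
    covers settle + presentation.  The dynamics are fully deterministic
    given the input raster — the only randomness in the pipeline lives in
    encoding and topology generation.
    """
    params = params or LIFParams()
    x, dt, single = _prepare_input(input_raster, dt)
    n_trials, n_pix, n_steps = x.shape
    _check_wiring(network, input_synapses, n_pix)
    compiled = _compile(network, input_synapses)
    offsets = network.offsets()
    n = network.n_neurons
    total = settle_steps + n_steps

    h_in = np.zeros((total, n_pix, n_trials))
    h_in[settle_steps:] = x.transpose(2, 1, 0)
    h_res = np.zeros((total, n, n_trials))
    out = np.zeros((n_trials, n, total), dtype=np.uint8)
    volt = np.zeros((n_trials, n, total)) if record_v else None

    v = np.full((n, n_trials), params.v_rest)
    refractory = np.zeros((n, n_trials), dtype=np.int64)
    refr_steps = params.refractory_steps(network.meta.excitatory, dt)[:, None]
    alpha, gain = _decay(params, dt, integration)

    for t in range(total):
        current = np.zeros((n, n_trials))
        for cp in compiled:
            off = offsets[cp.post_module]
            size = network.module_sizes[cp.post_module]
            for d, w in cp.groups:
                ts = t - d
                if ts < 0:
                    continue
                if cp.kind == 0:
                    src = h_in[ts]
                else:
                    o = offsets[cp.pre_module]
                    src = h_res[ts, o : o + network.module_sizes[cp.pre_module]]
                current[off : off + size] += w @ src
        v, refractory, spikes = _lif_update(
            v, refractory, current, refr_steps, params, alpha, gain
        )
        h_res[t] = spikes
        out[:, :, t] = spikes.T
        if record_v:
            volt[:, :, t] = v.T

    slices = {m: network.module_slice(m) for m in network.module_ids}
    return SimulationResult(
        out, dt, settle_steps, slices, single, volt,
        meta={"mode": "monolithic", "integration": integration},
    )


def simulate_modular(
    network: Network,
    input_synapses: list[SynapseSet],
    input_raster,
    params: LIFParams | None = None,
    settle_steps: int = 125,
    dt: float = 0.4,
    integration: str = "exponential",
) -> SimulationResult:
    """Divide-and-conquer simulation over the module DAG.

    Modules are processed in topological order (a breadth-first schedule by
    depth is valid too; modules of equal depth are independent).  For each
    module the exogenous drive — input synapses plus the recorded rasters
    of predecessor modules — is computed for the whole duration up front,
    and only the module's own recurrent synapses participate in its
    step-by-step loop.  The concatenated rasters are exactly equal to
    :func:`simulate_monolithic` on the identical flattened network.

    Raises if the module graph contains a cycle (the offending edge is
    named).
    """
    params = params or LIFParams()
    x, dt, single = _prepare_input(input_raster, dt)
    n_trials, n_pix, n_steps = x.shape
    _check_wiring(network, input_synapses, n_pix)
    order = network.graph.topological_order()  # raises on cycles
    compiled = _compile(network, input_synapses)
    n = network.n_neurons
    total = settle_steps + n_steps

    h_in = np.zeros((total, n_pix, n_trials))
    h_in[settle_steps:] = x.transpose(2, 1, 0)
    rasters: dict[int, np.ndarray] = {}  # module -> (total, n_m, n_trials) float
    alpha, gain = _decay(params, dt, integration)

    for m in order:
        n_m = network.module_sizes[m]
        incoming = [cp for cp in compiled if cp.post_module == m]
        exo = np.zeros((total, n_m, n_trials))
        recurrent: list[tuple[int, sp.csr_matrix]] = []
        for cp in incoming:
            if cp.kind == 2:
                recurrent.extend(cp.groups)
                continue
            h_pre = h_in if cp.kind == 0 else rasters[cp.pre_module]
            n_pre = h_pre.shape[1]
            for d, w in cp.groups:
                if total - d <= 0:
                    continue
                src = h_pre[: total - d].transpose(1, 0, 2).reshape(n_pre, -1)
                contrib = (w @ src).reshape(n_m, total - d, n_trials)
                exo[d:] += contrib.transpose(1, 0, 2)

        v = np.full((n_m, n_trials), params.v_rest)
        refractory = np.zeros((n_m, n_trials), dtype=np.int64)
        refr_steps = params.refractory_steps(network.module_types(m), dt)[:, None]
        h_m = np.zeros((total, n_m, n_trials))
        for t in range(total):
            current = exo[t].copy()
            for d, w in recurrent:
                if t - d >= 0:
                    current += w @ h_m[t - d]
            v, refractory, spikes = _lif_update(
                v, refractory, current, refr_steps, params, alpha, gain
            )
            h_m[t] = spikes
        rasters[m] = h_m

    out = np.zeros((n_trials, n, total), dtype=np.uint8)
    for m in network.module_ids:
        out[:, network.module_slice(m), :] = rasters[m].transpose(2, 1, 0)
    slices = {m: network.module_slice(m) for m in network.module_ids}
    return SimulationResult(
        out, dt, settle_steps, slices, single,
        meta={
            "mode": "modular",
            "integration": integration,
            "depths": network.graph.depths(),
        },
    )


def extract_features(result: SimulationResult) -> np.ndarray:
    """Per-neuron mean firing rates in spikes/s, settle phase excluded.

    Returns shape (n_neurons,) for single-trial results, else
    (n_trials, n_neurons).
    """
    counts = result.spikes[:, :, result.settle_steps :].sum(axis=2)
    duration_s = result.n_steps * result.dt / 1000.0
    rates = counts / duration_s
    return rates[0] if result.single else rates
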