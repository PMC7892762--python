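import numpy as np
import pytest

from modlsm import (
    ModuleGraph,
    Network,
    NeuronMeta,
    SynapseParams,
    connect_modules,
    generate_small_world,
)


def make_chain_network(n_modules=3, rows=3, cols=3, seed=0, fan_out=3,
                       exc_fraction=0.8, dt=0.4):
    """Small DAG-of-modules fixture: a chain m1 -> m2 -> ... -> mk of
    rewired-lattice modules with typed weights/delays."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_modules + 1)
    rng = np.random.default_rng(children[0])
    n = rows * cols
    syn_params = SynapseParams()
    sizes = {m: n for m in range(1, n_modules + 1)}
    types = {m: rng.random(n) < exc_fraction for m in sizes}
    projections = []
    for k, m in enumerate(sizes):
        syn = generate_small_world(rows, cols, 8, 0.35, seed=children[1 + k], pop=f"m{m}")
        syn.weight = syn_params.weights(types[m][syn.pre], types[m][syn.post])
        syn.delay_steps = syn_params.delays(types[m][syn.pre], types[m][syn.post], dt)
        projections.append(syn)
    edges = [(m, m + 1) for m in range(1, n_modules)]
    for k, (a, b) in enumerate(edges):
        syn = connect_modules(n, n, fan_out, weight=20.0,
                              seed=children[1 + n_modules + k],
                              pre_pop=f"m{a}", post_pop=f"m{b}")
        syn.delay_steps = syn_params.delays(types[a][syn.pre], types[b][syn.post], dt)
        projections.append(syn)
    graph = ModuleGraph(list(sizes), dict(sizes), edges, input_modules=(1,))
    excitatory = np.concatenate([types[m] for m in sizes])
    module_id = np.concatenate([np.full(n, m) for m in sizes])
    return Network(NeuronMeta(excitatory, module_id), sizes, projections, graph,
                   kind="chain")


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
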