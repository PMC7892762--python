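"""Connection structures for modular liquid state machines.

This module builds every synapse map the model needs:

* **Hough input synapses** — a fixed binary map from image pixels to a
  parameter-space accumulator grid.  A line cell ``(rho, theta)`` receives a
  synapse from pixel ``(x, y)`` iff ``rho = x cos(theta) + y sin(theta)``
  (a circle cell ``(a, b, r)`` iff ``r^2 = (x-a)^2 + (y-b)^2``), so the
  post-synaptic firing rates realise the Hough transform of the input.
  Because the exact (Kronecker-delta) condition is rarely satisfiable on an
  integer pixel grid, the default quantisation assigns each pixel to the
  accumulator bin containing its parameter value ("nearest"); the exact
  condition is kept as the "strict" mode.
* **Reservoir generators** — random (Erdos-Renyi), small-world (8-neighbour
  king lattice with probabilistic rewiring), and metric (distance-dependent
  connectivity on a 3-D integer lattice).
* **Module DAG** — a random directed acyclic graph over modules: every
  candidate edge ``j -> i`` with ``i > j`` whose head is not an input module
  is included independently with probability ``p``.
* **Inter-module wiring** — each presynaptic neuron connects to a fixed
  number of uniformly drawn targets in the post-synaptic module, at a
  constant weight.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .params import SynapseParams
from .synapses import SynapseSet

__all__ = [
    "HoughLineGrid",
    "HoughCircleGrid",
    "build_line_hough",
    "build_circle_hough",
    "generate_small_world",
    "generate_metric",
    "metric_connection_probability",
    "generate_random",
    "generate_dag",
    "connect_modules",
    "ModuleGraph",
    "NeuronMeta",
    "Network",
    "TopologyConfig",
    "DEFAULT_C_MAP",
    "assemble_reservoir",
    "build_input_synapses",
]

DEFAULT_C_MAP = {
    ("ex", "ex"): 0.3,
    ("ex", "in"): 0.2,
    ("in", "ex"): 0.4,
    ("in", "in"): 0.1,
}


# ---------------------------------------------------------------------------
# Hough accumulator grids
# ---------------------------------------------------------------------------
def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    """Bin edges with boundaries midway between consecutive centers."""
    centers = np.asarray(centers, dtype=np.float64)
    if centers.size == 1:
        return np.array([centers[0] - 0.5, centers[0] + 0.5])
    mid = (centers[:-1] + centers[1:]) / 2.0
    first = centers[0] - (mid[0] - centers[0])
    last = centers[-1] + (centers[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


@dataclass
class HoughLineGrid:
    """Accumulator grid for line detection in (rho, theta) space.

    Defaults: 12 theta values evenly spaced on [0, pi) and 16 rho bins
    spanning the full signed-offset range of a 28x28 image,
    [-27*sqrt(2), 27*sqrt(2)] — 192 post-synaptic neurons, the size of the
    line-detection input module.
    """

    rho_values: np.ndarray = field(
        default_factory=lambda: (lambda e: (e[:-1] + e[1:]) / 2.0)(
            np.linspace(-27 * np.sqrt(2), 27 * np.sqrt(2), 17)
        )
    )
    theta_values: np.ndarray = field(
        default_factory=lambda: np.arange(12) * np.pi / 12.0
    )
    quantization: str = "nearest"

    def __post_init__(self) -> None:
        self.rho_values = np.asarray(self.rho_values, dtype=np.float64)
        self.theta_values = np.asarray(self.theta_values, dtype=np.float64)
        if self.rho_values.size == 0 or self.theta_values.size == 0:
            raise ValueError("empty Hough grid")
        if (np.diff(self.theta_values) <= 0).any() or (
            self.theta_values.min() < 0 or self.theta_values.max() >= np.pi
        ):
            raise ValueError("theta values must be strictly increasing within [0, pi)")
        if self.quantization not in ("nearest", "strict"):
            raise ValueError("quantization must be 'nearest' or 'strict'")

    @property
    def n_rho(self) -> int:
        return self.rho_values.size

    @property
    def n_theta(self) -> int:
        return self.theta_values.size

    @property
    def n_cells(self) -> int:
        return self.n_rho * self.n_theta

    def cell_index(self, i_rho: np.ndarray, i_theta: np.ndarray) -> np.ndarray:
        return i_rho * self.n_theta + i_theta


@dataclass
class HoughCircleGrid:
    """Accumulator grid for circle detection in (a, b, r) space.

    Defaults: 6 centre coordinates evenly spaced across the image in each
    axis and 6 radii from 3 to 13 px — 216 post-synaptic neurons, the size
    of the circle-detection input module.
    """

    a_values: np.ndarray = field(default_factory=lambda: np.linspace(0, 27, 6))
    b_values: np.ndarray = field(default_factory=lambda: np.linspace(0, 27, 6))
    r_values: np.ndarray = field(default_factory=lambda: np.linspace(3, 13, 6))
    quantization: str = "nearest"

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=np.float64)
        self.b_values = np.asarray(self.b_values, dtype=np.float64)
        self.r_values = np.asarray(self.r_values, dtype=np.float64)
        if min(self.a_values.size, self.b_values.size, self.r_values.size) == 0:
            raise ValueError("empty Hough grid")
        if self.quantization not in ("nearest", "strict"):
            raise ValueError("quantization must be 'nearest' or 'strict'")

    @property
    def n_cells(self) -> int:
        return self.a_values.size * self.b_values.size * self.r_values.size

    def cell_index(self, i_a, i_b, i_r) -> np.ndarray:
        return (i_a * self.b_values.size + i_b) * self.r_values.size + i_r


def build_line_hough(
    grid: HoughLineGrid,
    image_dims: tuple[int, int] = (28, 28),
    weight: float = 1.0,
    delay_steps: int = 1,
    post_pop: str = "m1",
) -> SynapseSet:
    """Input synapses realising the line Hough transform.

    Pixel ``(x, y)`` (x = column) connects to cell ``(rho_i, theta_j)`` iff
    ``x cos(theta_j) + y sin(theta_j)`` falls in rho bin *i* ("nearest"
    mode) or equals ``rho_i`` exactly ("strict" mode).  All synapses share
    one weight (the input gain) and delay.
    """
    h, w = image_dims
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx.ravel().astype(np.float64)
    y = yy.ravel().astype(np.float64)
    pix = (yy * w + xx).ravel()
    edges = _edges_from_centers(grid.rho_values)
    pre_list, post_list = [], []
    for j, theta in enumerate(grid.theta_values):
        rho = x * np.cos(theta) + y * np.sin(theta)
        if grid.quantization == "nearest":
            i_rho = np.searchsorted(edges, rho, side="right") - 1
            ok = (i_rho >= 0) & (i_rho < grid.n_rho)
        else:
            diff = np.abs(rho[:, None] - grid.rho_values[None, :])
            i_rho = diff.argmin(axis=1)
            ok = diff.min(axis=1) < 1e-9
        pre_list.append(pix[ok])
        post_list.append(grid.cell_index(i_rho[ok], j))
    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)
    return SynapseSet(
        pre, post, weight, delay_steps, h * w, grid.n_cells, "input", post_pop,
        meta={"hough": "line"},
    )


def build_circle_hough(
    grid: HoughCircleGrid,
    image_dims: tuple[int, int] = (28, 28),
    weight: float = 1.0,
    delay_steps: int = 1,
    post_pop: str = "m2",
) -> SynapseSet:
    """Input synapses realising the circle Hough transform.

    Pixel ``(x, y)`` connects to cell ``(a, b, r)`` iff its Euclidean
    distance to centre ``(a, b)`` falls in radius bin *r* ("nearest") or
    satisfies ``r^2 = (x-a)^2 + (y-b)^2`` exactly ("strict").
    """
    h, w = image_dims
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx.ravel().astype(np.float64)
    y = yy.ravel().astype(np.float64)
    pix = (yy * w + xx).ravel()
    r_edges = _edges_from_centers(grid.r_values)
    pre_list, post_list = [], []
    for i_a, a in enumerate(grid.a_values):
        for i_b, b in enumerate(grid.b_values):
            d2 = (x - a) ** 2 + (y - b) ** 2
            if grid.quantization == "nearest":
                d = np.sqrt(d2)
                i_r = np.searchsorted(r_edges, d, side="right") - 1
                ok = (i_r >= 0) & (i_r < grid.r_values.size)
            else:
                diff = np.abs(d2[:, None] - grid.r_values[None, :] ** 2)
                i_r = diff.argmin(axis=1)
                ok = diff.min(axis=1) < 1e-9
            pre_list.append(pix[ok])
            post_list.append(grid.cell_index(i_a, i_b, i_r[ok]))
    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)
    return SynapseSet(
        pre, post, weight, delay_steps, h * w, grid.n_cells, "input", post_pop,
        meta={"hough": "circle"},
    )


# ---------------------------------------------------------------------------
# Reservoir generators
# ---------------------------------------------------------------------------
_KING_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN_OFFSETS = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def generate_small_world(
    rows: int,
    cols: int,
    n_neighbors: int = 8,
    p_rewire: float = 0.35,
    seed: int | None = None,
    pop: str = "res",
) -> SynapseSet:
    """Small-world network by rewiring a 2-D lattice (no wraparound).

    Starts from the king (Moore) lattice in which each neuron is connected
    to its 8 in-bounds neighbours in both directions; each directed edge is
    independently rewired with probability ``p_rewire`` to a uniformly
    drawn destination, resampling until the target is neither the source
    nor a duplicate.  Rewiring moves targets only, so every neuron's
    out-degree is preserved exactly.

    Weights and delays are left at 1; callers assign type-dependent values
    afterwards.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must lie in [0, 1]")
    if n_neighbors == 8:
        offsets = _KING_OFFSETS
    elif n_neighbors == 4:
        offsets = _VON_NEUMANN_OFFSETS
    else:
        raise ValueError("n_neighbors must be 4 or 8")
    n = rows * cols
    sources, targets_arr = [], []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    sources.append(u)
                    targets_arr.append(rr * cols + cc)
    sources = np.array(sources, dtype=np.int64)
    targets_arr = np.array(targets_arr, dtype=np.int64)
    rng = np.random.default_rng(seed)
    if p_rewire > 0 and n > 1:
        target_sets: list[set[int]] = [set() for _ in range(n)]
        for u, v in zip(sources, targets_arr):
            target_sets[u].add(int(v))
        for k in range(sources.size):
            if rng.random() < p_rewire:
                u, v = int(sources[k]), int(targets_arr[k])
                target_sets[u].discard(v)
                while True:
                    w = int(rng.integers(n))
                    if w != u and w not in target_sets[u]:
                        break
                target_sets[u].add(w)
                targets_arr[k] = w
    return SynapseSet(
        sources, targets_arr, 1.0, 1, n, n, pop, pop,
        meta={"generator": "small_world", "rows": rows, "cols": cols},
    )


def metric_connection_probability(
    pre_exc: bool, post_exc: bool, distance: float, lam: float = 2.0, c_map=None
) -> float:
    """Distance-dependent connection probability C * exp(-D^2 / lambda^2)."""
    c_map = c_map or DEFAULT_C_MAP
    key = ("ex" if pre_exc else "in", "ex" if post_exc else "in")
    if key not in c_map:
        raise KeyError(f"unknown type pair in C map: {key}")
    return c_map[key] * float(np.exp(-(distance**2) / lam**2))


def generate_metric(
    dims: tuple[int, int, int] = (15, 10, 10),
    lam: float = 2.0,
    c_map: dict | None = None,
    excitatory: np.ndarray | None = None,
    exc_fraction: float = 0.8,
    seed: int | None = None,
    pop: str = "res",
) -> SynapseSet:
    """Metric network: neurons on a 3-D integer lattice, local connectivity.

    Every ordered pair ``a != b`` is connected independently with
    probability ``C(type_a -> type_b) * exp(-D(a,b)^2 / lambda^2)`` with
    Euclidean ``D``.  If ``excitatory`` is not given, types are drawn
    first (fraction ``exc_fraction`` excitatory) from the same seed; the
    drawn types are stored in ``meta['excitatory']``.
    """
    c_map = dict(c_map) if c_map is not None else dict(DEFAULT_C_MAP)
    for key in [("ex", "ex"), ("ex", "in"), ("in", "ex"), ("in", "in")]:
        if key not in c_map:
            raise KeyError(f"C map missing type pair {key}")
    n = int(np.prod(dims))
    rng = np.random.default_rng(seed)
    if excitatory is None:
        excitatory = rng.random(n) < exc_fraction
    excitatory = np.asarray(excitatory, dtype=bool)
    coords = np.indices(dims).reshape(len(dims), -1).T.astype(np.float64)
    d2 = cdist(coords, coords, "sqeuclidean")
    c_pre_ex = np.where(excitatory, c_map[("ex", "ex")], c_map[("in", "ex")])
    c_pre_in = np.where(excitatory, c_map[("ex", "in")], c_map[("in", "in")])
    # C[i, j] is the coefficient for synapse j -> i (rows = post)
    c = np.where(excitatory[:, None], c_pre_ex[None, :], c_pre_in[None, :])
    prob = c * np.exp(-d2 / lam**2)
    np.fill_diagonal(prob, 0.0)
    adj = rng.random((n, n)) < prob  # adj[post, pre]
    post, pre = np.nonzero(adj)
    return SynapseSet(
        pre, post, 1.0, 1, n, n, pop, pop,
        meta={"generator": "metric", "dims": dims, "excitatory": excitatory,
              "coords": coords},
    )


def generate_random(
    n: int = 1500, p: float = 0.01, seed: int | None = None, pop: str = "res"
) -> SynapseSet:
    """Erdos-Renyi digraph: each ordered pair connected with probability p."""
    if n < 2:
        raise ValueError("need at least two neurons")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    post, pre = np.nonzero(adj.T)  # iterate in (post, pre) order for determinism
    return SynapseSet(pre, post, 1.0, 1, n, n, pop, pop, meta={"generator": "random"})


# ---------------------------------------------------------------------------
# Module graph
# ---------------------------------------------------------------------------
@dataclass
class ModuleGraph:
    """Directed acyclic graph of reservoir modules.

    Modules are labelled 1..n in topological order; ``input_modules`` are
    the modules wired to the input layer and never receive inter-module
    edges.
    """

    module_ids: list[int]
    sizes: dict[int, int] = field(default_factory=dict)
    edges: list[tuple[int, int]] = field(default_factory=list)
    input_modules: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        self.module_ids = sorted(int(m) for m in self.module_ids)
        self.edges = [(int(a), int(b)) for a, b in self.edges]
        ids = set(self.module_ids)
        for a, b in self.edges:
            if a not in ids or b not in ids:
                raise ValueError(f"edge ({a}, {b}) references unknown module")
            if b in self.input_modules:
                raise ValueError(f"input module {b} cannot receive edge ({a}, {b})")
        self.topological_order()  # raises on cycles

    def predecessors(self, module: int) -> list[int]:
        return sorted(a for a, b in self.edges if b == module)

    def topological_order(self) -> list[int]:
        """Kahn's algorithm; raises on a cycle naming an offending edge."""
        indeg = {m: 0 for m in self.module_ids}
        for _, b in self.edges:
            indeg[b] += 1
        ready = sorted(m for m, d in indeg.items() if d == 0)
        order = []
        while ready:
            m = ready.pop(0)
            order.append(m)
            for a, b in self.edges:
                if a == m:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        ready.append(b)
            ready.sort()
        if len(order) != len(self.module_ids):
            stuck = [m for m in self.module_ids if m not in order]
            bad = next((a, b) for a, b in self.edges if a in stuck and b in stuck)
            raise ValueError(f"module graph has a cycle through edge {bad}")
        return order

    def depths(self) -> dict[int, int]:
        """Schedule depth per module: 0 for source modules, else
        1 + max(depth of predecessors)."""
        depth: dict[int, int] = {}
        for m in self.topological_order():
            preds = self.predecessors(m)
            depth[m] = 0 if not preds else 1 + max(depth[a] for a in preds)
        return depth


def generate_dag(
    n_modules: int = 10,
    p: float = 0.25,
    input_modules: tuple[int, ...] = (1, 2),
    seed: int | None = None,
) -> ModuleGraph:
    """Random module DAG: candidate edges are all (j -> i) with i > j whose
    head i is not an input module; each is included with probability p.

    Acyclic by construction since edges only run from lower to higher
    labels.  Input modules must be the first labels (1..k).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    input_modules = tuple(sorted(int(m) for m in input_modules))
    if input_modules != tuple(range(1, len(input_modules) + 1)):
        raise ValueError("input modules must be labelled first (1..k)")
    if n_modules < len(input_modules):
        raise ValueError("fewer modules than input modules")
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(1, n_modules + 1):
        if i in input_modules:
            continue
        for j in range(1, i):
            if rng.random() < p:
                edges.append((j, i))
    return ModuleGraph(list(range(1, n_modules + 1)), {}, edges, input_modules)


def connect_modules(
    n_pre: int,
    n_post: int,
    fan_out: int = 10,
    weight: float = 1.0,
    seed: int | None = None,
    pre_pop: str = "pre",
    post_pop: str = "post",
    delay_steps: int = 1,
) -> SynapseSet:
    """Random inter-module wiring at constant weight.

    Every presynaptic neuron gets exactly ``min(fan_out, n_post)`` distinct
    targets sampled uniformly without replacement.
    """
    if pre_pop == post_pop:
        raise ValueError("inter-module wiring requires disjoint modules")
    rng = np.random.default_rng(seed)
    k = min(fan_out, n_post)
    pre = np.repeat(np.arange(n_pre), k)
    post = np.concatenate([rng.choice(n_post, size=k, replace=False) for _ in range(n_pre)])
    return SynapseSet(pre, post, weight, delay_steps, n_pre, n_post, pre_pop, post_pop)


# ---------------------------------------------------------------------------
# Assembled networks
# ---------------------------------------------------------------------------
@dataclass
class NeuronMeta:
    """Per-neuron annotations: type, module membership, optional coords."""

    excitatory: np.ndarray
    module_id: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.excitatory = np.asarray(self.excitatory, dtype=bool)
        self.module_id = np.asarray(self.module_id, dtype=np.int64)
        if self.excitatory.shape != self.module_id.shape:
            raise ValueError("type and module vectors must align")


@dataclass
class Network:
    """An assembled reservoir: modules, typed neurons, and synapse sets.

    ``projections`` holds every reservoir-internal synapse set (intra- and
    inter-module), with population names ``"m<id>"``; indices are local to
    each module.  ``graph`` drives modular scheduling.
    """

    meta: NeuronMeta
    module_sizes: dict[int, int]
    projections: list[SynapseSet]
    graph: ModuleGraph
    kind: str = "custom"

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.module_sizes)

    @property
    def n_neurons(self) -> int:
        return int(sum(self.module_sizes.values()))

    def offsets(self) -> dict[int, int]:
        off, total = {}, 0
        for m in self.module_ids:
            off[m] = total
            total += self.module_sizes[m]
        return off

    def module_slice(self, module: int) -> slice:
        off = self.offsets()[module]
        return slice(off, off + self.module_sizes[module])

    def module_types(self, module: int) -> np.ndarray:
        return self.meta.excitatory[self.module_slice(module)]

    def n_synapses(self, alive_only: bool = False) -> int:
        return int(
            sum(s.n_alive if alive_only else s.n_synapses for s in self.projections)
        )


@dataclass
class TopologyConfig:
    """Reservoir configuration for the four benchmark topologies.

    Defaults reproduce the reference configurations: random (N=1,500,
    p=0.01), small-world (1,500 neurons, 8-neighbour lattice, rewiring
    0.35), metric (15x10x10 lattice, lambda=2), and modular (10 modules:
    one 16x12 line-Hough layer, one 6x6x6 circle-Hough layer, eight 9x15
    small-world modules, DAG edge probability 0.25, inter-module fan-out
    10 at constant weight).
    """

    kind: str = "modular"
    exc_fraction: float = 0.8
    # random
    n: int = 1500
    p: float = 0.01
    # small-world (single-module reservoir and modular sub-modules)
    sw_rows: int = 30
    sw_cols: int = 50
    n_neighbors: int = 8
    p_rewire: float = 0.35
    # metric
    metric_dims: tuple[int, int, int] = (15, 10, 10)
    lam: float = 2.0
    c_map: dict = field(default_factory=lambda: dict(DEFAULT_C_MAP))
    # modular
    n_modules: int = 10
    dag_p: float = 0.25
    module_rows: int = 9
    module_cols: int = 15
    fan_out: int = 10
    inter_module_weight: float = 20.0
    line_grid: HoughLineGrid = field(default_factory=HoughLineGrid)
    circle_grid: HoughCircleGrid = field(default_factory=HoughCircleGrid)
    hough_module_recurrence: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("random", "small_world", "metric", "modular"):
            raise ValueError(f"unknown topology kind {self.kind!r}")
        for prob in (self.p, self.p_rewire, self.dag_p, self.exc_fraction):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def full(cls, kind: str) -> "TopologyConfig":
        """Benchmark-scale configuration (Table-1 sizes)."""
        return cls(kind=kind)

    @classmethod
    def small(cls, kind: str) -> "TopologyConfig":
        """Desk-scale configuration (~730 neurons) for property studies.

        Modular: full-size Hough layers (they are cheap, feed-forward) plus
        four 9x9 small-world modules; the single-reservoir comparisons are
        matched at 729 neurons with comparable mean degree.
        """
        if kind == "modular":
            return cls(kind="modular", n_modules=6, module_rows=9, module_cols=9)
        if kind == "small_world":
            return cls(kind="small_world", sw_rows=27, sw_cols=27)
        if kind == "random":
            return cls(kind="random", n=729, p=0.011)
        if kind == "metric":
            return cls(kind="metric", metric_dims=(9, 9, 9))
        raise ValueError(f"unknown topology kind {kind!r}")


def _typed(syn: SynapseSet, pre_exc, post_exc, params: SynapseParams, dt: float) -> SynapseSet:
    """Assign type-dependent weights and delays to a unit synapse set."""
    syn.weight = params.weights(pre_exc[syn.pre], post_exc[syn.post])
    syn.delay_steps = params.delays(pre_exc[syn.pre], post_exc[syn.post], dt)
    return syn


def assemble_reservoir(
    config: TopologyConfig,
    seed: int | None = None,
    dt: float = 0.4,
    syn_params: SynapseParams | None = None,
) -> Network:
    """Build a complete typed reservoir for any of the four topologies.

    For ``"modular"``: module 1 is the line-Hough layer, module 2 the
    circle-Hough layer (both all-excitatory and, by default, without
    internal recurrence — they act as feed-forward encoding layers),
    modules 3..n are small-world lattices with an 80/20
    excitatory/inhibitory split; inter-module synapses realise a freshly
    generated module DAG at constant weight.  The other kinds yield a
    single-module reservoir whose input module is module 1.
    """
    syn_params = syn_params or SynapseParams()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(config.n_modules + 64)
    rng_types = np.random.default_rng(children[0])

    if config.kind == "modular":
        sizes: dict[int, int] = {1: config.line_grid.n_cells, 2: config.circle_grid.n_cells}
        sw_size = config.module_rows * config.module_cols
        for m in range(3, config.n_modules + 1):
            sizes[m] = sw_size
        types: dict[int, np.ndarray] = {
            1: np.ones(sizes[1], dtype=bool),
            2: np.ones(sizes[2], dtype=bool),
        }
        for m in range(3, config.n_modules + 1):
            types[m] = rng_types.random(sizes[m]) < config.exc_fraction
        projections: list[SynapseSet] = []
        for idx, m in enumerate(range(3, config.n_modules + 1)):
            syn = generate_small_world(
                config.module_rows,
                config.module_cols,
                config.n_neighbors,
                config.p_rewire,
                seed=children[1 + idx],
                pop=f"m{m}",
            )
            projections.append(_typed(syn, types[m], types[m], syn_params, dt))
        graph = generate_dag(
            config.n_modules, config.dag_p, (1, 2), seed=children[config.n_modules + 1]
        )
        graph.sizes = dict(sizes)
        for k, (a, b) in enumerate(sorted(graph.edges)):
            syn = connect_modules(
                sizes[a],
                sizes[b],
                config.fan_out,
                weight=config.inter_module_weight,
                seed=children[config.n_modules + 2 + k],
                pre_pop=f"m{a}",
                post_pop=f"m{b}",
            )
            # constant weight, type-pair conduction delays
            syn.delay_steps = syn_params.delays(
                types[a][syn.pre], types[b][syn.post], dt
            )
            projections.append(syn)
        excitatory = np.concatenate([types[m] for m in sorted(sizes)])
        module_id = np.concatenate(
            [np.full(sizes[m], m, dtype=np.int64) for m in sorted(sizes)]
        )
        meta = NeuronMeta(excitatory, module_id)
        return Network(meta, sizes, projections, graph, kind="modular")

    # single-module reservoirs
    if config.kind == "small_world":
        n = config.sw_rows * config.sw_cols
        types1 = rng_types.random(n) < config.exc_fraction
        syn = generate_small_world(
            config.sw_rows, config.sw_cols, config.n_neighbors, config.p_rewire,
            seed=children[1], pop="m1",
        )
        syn = _typed(syn, types1, types1, syn_params, dt)
        coords = None
    elif config.kind == "random":
        n = config.n
        types1 = rng_types.random(n) < config.exc_fraction
        syn = generate_random(n, config.p, seed=children[1], pop="m1")
        syn = _typed(syn, types1, types1, syn_params, dt)
        coords = None
    elif config.kind == "metric":
        n = int(np.prod(config.metric_dims))
        types1 = rng_types.random(n) < config.exc_fraction
        syn = generate_metric(
            config.metric_dims, config.lam, config.c_map,
            excitatory=types1, seed=children[1], pop="m1",
        )
        coords = syn.meta.get("coords")
        syn = _typed(syn, types1, types1, syn_params, dt)
    else:  # pragma: no cover - guarded in config
        raise ValueError(config.kind)
    meta = NeuronMeta(types1, np.ones(n, dtype=np.int64), coords)
    graph = ModuleGraph([1], {1: n}, [], input_modules=(1,))
    return Network(meta, {1: n}, [syn], graph, kind=config.kind)


def build_input_synapses(
    network: Network,
    config: TopologyConfig,
    image_dims: tuple[int, int] = (28, 28),
    mode: str = "hough",
    seed: int | None = None,
    dt: float = 0.4,
    syn_params: SynapseParams | None = None,
) -> list[SynapseSet]:
    """Wire the input layer (pixels) to the network's input modules.

    ``mode="hough"`` (modular networks): the line grid feeds module 1 and
    the circle grid module 2, with the excitatory->excitatory weight as
    input gain.  ``mode="random"``: every pixel connects to ``fan_out``
    uniformly drawn neurons in each input module.  Input fibres are
    treated as excitatory for weight and delay purposes.
    """
    syn_params = syn_params or SynapseParams()
    h, w = image_dims
    n_pix = h * w
    gain = syn_params.w_exc_exc
    sets: list[SynapseSet] = []
    if mode == "hough":
        if network.kind != "modular":
            raise ValueError("Hough input wiring requires a modular network")
        for grid, m, builder in (
            (config.line_grid, 1, build_line_hough),
            (config.circle_grid, 2, build_circle_hough),
        ):
            syn = builder(grid, image_dims, weight=gain, post_pop=f"m{m}")
            post_exc = network.module_types(m)
            syn.delay_steps = syn_params.delays(
                np.ones(syn.n_synapses, dtype=bool), post_exc[syn.post], dt
            )
            sets.append(syn)
        return sets
    if mode != "random":
        raise ValueError("mode must be 'hough' or 'random'")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(network.graph.input_modules))
    for k, m in enumerate(network.graph.input_modules):
        syn = connect_modules(
            n_pix,
            network.module_sizes[m],
            config.fan_out,
            weight=1.0,
            seed=children[k],
            pre_pop="input",
            post_pop=f"m{m}",
        )
        post_exc = network.module_types(m)
        syn.weight = syn_params.weights(
            np.ones(syn.n_synapses, dtype=bool), post_exc[syn.post]
        )
        syn.delay_steps = syn_params.delays(
            np.ones(syn.n_synapses, dtype=bool), post_exc[syn.post], dt
        )
        sets.append(syn)
    return sets
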