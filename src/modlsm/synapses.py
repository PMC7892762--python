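"""Sparse, typed, delayed synapse sets.

A :class:`SynapseSet` is a triplet table ``(pre, post, weight)`` with an
integer conduction delay (in simulation steps) and an ``alive`` flag per
synapse.  Pre- and post-synaptic indices are local to the named populations,
which keeps module-by-module simulation natural; simulators translate to a
global index space where needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["SynapseSet", "save_synapses", "load_synapses"]


@dataclass
class SynapseSet:
    """Directed weighted synapses between two neuron populations.

    Invariants: no self-connections when the populations coincide, no
    duplicate ``(pre, post)`` pairs, finite weights, delays >= 1 step.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_steps: np.ndarray
    n_pre: int
    n_post: int
    pre_pop: str = "pre"
    post_pop: str = "post"
    alive: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        n = self.pre.size
        self.weight = np.broadcast_to(np.asarray(self.weight, dtype=np.float64), (n,)).copy()
        self.delay_steps = np.broadcast_to(
            np.asarray(self.delay_steps, dtype=np.int64), (n,)
        ).copy()
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        else:
            self.alive = np.asarray(self.alive, dtype=bool).copy()
        self._validate()

    def _validate(self) -> None:
        n = self.pre.size
        if not (self.post.size == self.weight.size == self.delay_steps.size == n):
            raise ValueError("pre/post/weight/delay arrays must have equal length")
        if n and (self.pre.min() < 0 or self.pre.max() >= self.n_pre):
            raise ValueError("presynaptic index out of range")
        if n and (self.post.min() < 0 or self.post.max() >= self.n_post):
            raise ValueError("post-synaptic index out of range")
        if not np.isfinite(self.weight).all():
            raise ValueError("synaptic weights must be finite")
        if n and self.delay_steps.min() < 1:
            raise ValueError("delays must be at least one step")
        if self.pre_pop == self.post_pop and n and (self.pre == self.post).any():
            raise ValueError("self-connections are not allowed")
        key = self.pre * self.n_post + self.post
        if np.unique(key).size != n:
            raise ValueError("duplicate (pre, post) pairs")

    # -- basic queries -----------------------------------------------------
    @property
    def n_synapses(self) -> int:
        return self.pre.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def out_degrees(self) -> np.ndarray:
        """Out-degree (alive synapses) per presynaptic neuron."""
        return np.bincount(self.pre[self.alive], minlength=self.n_pre)

    # -- matrices ----------------------------------------------------------
    def matrix(self) -> sp.csr_matrix:
        """Alive synapses as a CSR weight matrix of shape (n_post, n_pre)."""
        m = self.alive
        w = sp.coo_matrix(
            (self.weight[m], (self.post[m], self.pre[m])),
            shape=(self.n_post, self.n_pre),
        ).tocsr()
        w.sort_indices()
        return w

    def delay_groups(self) -> list[tuple[int, sp.csr_matrix]]:
        """Alive synapses split by delay, as (delay, CSR matrix) pairs.

        Sorted by ascending delay: the accumulation order simulators rely on.
        """
        groups = []
        for d in np.unique(self.delay_steps[self.alive]):
            m = self.alive & (self.delay_steps == d)
            w = sp.coo_matrix(
                (self.weight[m], (self.post[m], self.pre[m])),
                shape=(self.n_post, self.n_pre),
            ).tocsr()
            w.sort_indices()
            groups.append((int(d), w))
        return groups

    def copy(self) -> "SynapseSet":
        return SynapseSet(
            self.pre.copy(),
            self.post.copy(),
            self.weight.copy(),
            self.delay_steps.copy(),
            self.n_pre,
            self.n_post,
            self.pre_pop,
            self.post_pop,
            self.alive.copy(),
            dict(self.meta),
        )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.weight,
                "delay_steps": self.delay_steps,
                "alive": self.alive,
            }
        )


def save_synapses(syn: SynapseSet, prefix: str | Path) -> None:
    """Write a synapse set: Matrix Market weights + CSV sidecar + JSON meta.

    ``<prefix>.mtx`` holds the (n_post, n_pre) weight matrix of alive
    synapses; ``<prefix>.csv`` the full triplet table including delays and
    alive flags; ``<prefix>.json`` the population names and sizes.
    """
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), syn.matrix())
    syn.table().to_csv(prefix.with_suffix(".csv"), index=False)
    prefix.with_suffix(".json").write_text(
        json.dumps(
            {
                "n_pre": syn.n_pre,
                "n_post": syn.n_post,
                "pre_pop": syn.pre_pop,
                "post_pop": syn.post_pop,
                "meta": {k: v for k, v in syn.meta.items() if isinstance(v, (int, float, str))},
            },
            indent=1,
        )
    )


def load_synapses(prefix: str | Path) -> SynapseSet:
    prefix = Path(prefix)
    info = json.loads(prefix.with_suffix(".json").read_text())
    tab = pd.read_csv(prefix.with_suffix(".csv"))
    return SynapseSet(
        tab["pre"].to_numpy(),
        tab["post"].to_numpy(),
        tab["weight"].to_numpy(),
        tab["delay_steps"].to_numpy(),
        info["n_pre"],
        info["n_post"],
        info["pre_pop"],
        info["post_pop"],
        tab["alive"].to_numpy(),
        info.get("meta", {}),
    )
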