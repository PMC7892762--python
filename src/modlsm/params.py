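"""Membrane and synapse constants for the LIF reservoir.

Values follow the classical liquid-state-machine parameterisation: threshold
15 mV, reset = rest = 13.5 mV, membrane time constant 30 ms, refractory
periods 5 ms (excitatory) / 2 ms (inhibitory); synaptic weights 20 for
excitatory->excitatory, 45 for excitatory->inhibitory and -17 for any
inhibitory presynaptic neuron, with conduction delays of 1.5 ms for
excitatory->excitatory pairs and 0.8 ms otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LIFParams", "SynapseParams", "ms_to_steps"]


def ms_to_steps(delay_ms: float, dt: float) -> int:
    """Convert a delay/period in ms to simulation steps (ceil, min 1).

    The quotient is rounded to 9 decimals first so that exact multiples of
    dt are not pushed up by floating-point representation error
    (1.5/0.4 -> 4 steps, 0.8/0.4 -> 2, 5/0.4 -> 13, 2/0.4 -> 5).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return max(1, math.ceil(round(delay_ms / dt, 9)))


@dataclass
class LIFParams:
    """Leaky integrate-and-fire constants (voltages in mV, times in ms).

    The membrane obeys ``tau_mem dV/dt = -(V - V_rest) + R I(t)`` and a
    neuron reaching ``v_th`` spikes, resets to ``v_reset`` and stays
    refractory for its type's period.  ``r`` is a dimensionless input gain
    (the synaptic weights absorb physical scaling).
    """

    v_th: float = 15.0
    v_reset: float = 13.5
    v_rest: float = 13.5
    tau_mem: float = 30.0
    r: float = 1.0
    refractory_ex_ms: float = 5.0
    refractory_in_ms: float = 2.0

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_th:
            raise ValueError("v_reset must lie below v_th")
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")

    def refractory_steps(self, excitatory: np.ndarray, dt: float) -> np.ndarray:
        """Per-neuron refractory period in steps given a type vector."""
        ex = ms_to_steps(self.refractory_ex_ms, dt)
        inh = ms_to_steps(self.refractory_in_ms, dt)
        return np.where(np.asarray(excitatory, dtype=bool), ex, inh).astype(np.int64)


@dataclass
class SynapseParams:
    """Type-dependent synaptic weights and conduction delays.

    Weights by (pre -> post) type: excitatory->excitatory ``w_exc_exc``,
    excitatory->inhibitory ``w_exc_inh``, and ``w_inh`` whenever the
    presynaptic neuron is inhibitory.  Delays: ``delay_exc_exc_ms`` for
    excitatory->excitatory pairs, ``delay_other_ms`` otherwise.
    """

    w_exc_exc: float = 20.0
    w_exc_inh: float = 45.0
    w_inh: float = -17.0
    delay_exc_exc_ms: float = 1.5
    delay_other_ms: float = 0.8

    def weights(self, pre_exc: np.ndarray, post_exc: np.ndarray) -> np.ndarray:
        pre_exc = np.asarray(pre_exc, dtype=bool)
        post_exc = np.asarray(post_exc, dtype=bool)
        return np.where(
            pre_exc, np.where(post_exc, self.w_exc_exc, self.w_exc_inh), self.w_inh
        ).astype(np.float64)

    def delays(self, pre_exc: np.ndarray, post_exc: np.ndarray, dt: float) -> np.ndarray:
        pre_exc = np.asarray(pre_exc, dtype=bool)
        post_exc = np.asarray(post_exc, dtype=bool)
        d_ee = ms_to_steps(self.delay_exc_exc_ms, dt)
        d_other = ms_to_steps(self.delay_other_ms, dt)
        return np.where(pre_exc & post_exc, d_ee, d_other).astype(np.int64)
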