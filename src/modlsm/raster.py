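"""Spike rasters: the binary neuron x time matrices exchanged between stages.

A :class:`SpikeRaster` is the lingua franca of the pipeline: the Poisson
encoder produces one per image, the reservoir simulators consume and emit
them, and the readout consumes per-neuron rates derived from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "save_raster", "load_raster"]


@dataclass
class SpikeRaster:
    """Binary spike matrix with a fixed time step.

    Parameters
    ----------
    spikes : ndarray of shape (n_neurons, n_steps)
        Entries in {0, 1}; stored as uint8.
    dt : float
        Time step in milliseconds.
    meta : dict
        Free-form provenance (seed, encoder settings, ...).
    """

    spikes: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be 2-D (n_neurons, n_steps)")
        uniq = np.unique(self.spikes)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.spikes = self.spikes.astype(np.uint8)
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return self.spikes.sum(axis=1)

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron in spikes/s."""
        return self.counts() / (self.duration_ms / 1000.0)

    def events(self) -> pd.DataFrame:
        """Event list with columns ``neuron_id, time_step``."""
        nid, t = np.nonzero(self.spikes)
        return pd.DataFrame({"neuron_id": nid, "time_step": t})


def save_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Write a raster as a CSV event list plus a JSON sidecar.

    The sidecar (``<path>.json``) records dt, the matrix shape and any
    metadata, so the CSV round-trips losslessly.
    """
    path = Path(path)
    raster.events().to_csv(path, index=False)
    sidecar = {
        "dt": raster.dt,
        "n_neurons": raster.n_neurons,
        "n_steps": raster.n_steps,
        "meta": raster.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    events = pd.read_csv(path)
    spikes = np.zeros((sidecar["n_neurons"], sidecar["n_steps"]), dtype=np.uint8)
    if len(events):
        spikes[events["neuron_id"].to_numpy(), events["time_step"].to_numpy()] = 1
    return SpikeRaster(spikes, dt=sidecar["dt"], meta=sidecar.get("meta", {}))
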