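"""System-noise experiments: synapse ablation and robustness sweeps.

Structural damage is modelled by marking an exact fraction of synapses
dead (weight treated as zero).  :func:`ablate_synapses` damages the
reservoir (intra- and inter-module synapses); :func:`robustness_sweep`
additionally damages the input synapses at the same fraction by default,
since a network's wiring does not distinguish afferent from recurrent
fibres when synapses die — pooled, redundant input maps (the Hough layers)
then degrade gracefully while sparse random fan-ins lose information.

The sweep trains the readout on the *intact* network and evaluates it on
the damaged one: robustness to system damage means a trained system keeps
working after synapses die.  (Retraining on the damaged network largely
restores accuracy and is available as an option.)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synapses import SynapseSet
from .topology import Network

__all__ = [
    "AblationSpec",
    "ablate_synapses",
    "ablate_input_synapses",
    "robustness_sweep",
    "summarize_sweep",
]


@dataclass
class AblationSpec:
    """Which fraction of which reservoir synapses to disable.

    fraction : in [0, 1]; the number of dead synapses is exactly
        ``round(fraction * n_eligible)`` (not binomial), so a quoted
        percentage is realised exactly.
    scope : "all" (every reservoir-internal and inter-module synapse),
        "intra" or "inter".
    """

    fraction: float
    scope: str = "all"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("ablation fraction must lie in [0, 1]")
        if self.scope not in ("all", "intra", "inter"):
            raise ValueError("scope must be 'all', 'intra' or 'inter'")


def ablate_synapses(network: Network, spec: AblationSpec) -> Network:
    """Return a copy of the network with dead synapses marked.

    Exactly ``round(fraction * E)`` eligible synapses are drawn uniformly
    without replacement across the eligible sets.  The original network is
    untouched (copy-on-write).  Idempotent for a fixed seed, and ablating
    0% then f% equals ablating f% directly.
    """
    projections = [s.copy() for s in network.projections]
    if spec.scope == "all":
        eligible = list(range(len(projections)))
    elif spec.scope == "intra":
        eligible = [k for k, s in enumerate(projections) if s.pre_pop == s.post_pop]
    else:
        eligible = [k for k, s in enumerate(projections) if s.pre_pop != s.post_pop]
    counts = [projections[k].n_synapses for k in eligible]
    total = int(sum(counts))
    n_dead = int(round(spec.fraction * total))
    if n_dead > 0:
        rng = np.random.default_rng(spec.seed)
        chosen = rng.choice(total, size=n_dead, replace=False)
        bounds = np.cumsum([0] + counts)
        for j, k in enumerate(eligible):
            local = chosen[(chosen >= bounds[j]) & (chosen < bounds[j + 1])] - bounds[j]
            projections[k].alive[local] = False
    return replace(network, projections=projections)


def ablate_input_synapses(
    input_synapses: list[SynapseSet], fraction: float, seed: int | None = None
) -> list[SynapseSet]:
    """Disable an exact fraction of the input (afferent) synapses.

    The fraction applies to the pooled set, drawn uniformly without
    replacement; originals are untouched.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("ablation fraction must lie in [0, 1]")
    copies = [s.copy() for s in input_synapses]
    counts = [s.n_synapses for s in copies]
    total = int(sum(counts))
    n_dead = int(round(fraction * total))
    if n_dead > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(total, size=n_dead, replace=False)
        bounds = np.cumsum([0] + counts)
        for j, s in enumerate(copies):
            local = chosen[(chosen >= bounds[j]) & (chosen < bounds[j + 1])] - bounds[j]
            s.alive[local] = False
    return copies


def robustness_sweep(
    fractions=(0.0, 0.05, 0.1, 0.2),
    seeds=(0, 1, 2, 3, 4),
    topologies=("modular", "small_world"),
    config=None,
    ablate_inputs: bool = True,
    retrain: bool = False,
) -> pd.DataFrame:
    """Damage sweep: accuracy of each topology under dead synapses.

    For each (seed, topology): a fresh dataset is drawn and encoded
    (shared across topologies and fractions within the seed) and the
    reservoir is built; for each fraction the given percentage of synapses
    (reservoir, and input synapses too unless ``ablate_inputs=False``) is
    disabled and the readout — trained on the intact network, or on the
    damaged one if ``retrain=True`` — is evaluated on the damaged
    network's features.  Fraction-0 rows reproduce the unperturbed
    accuracies exactly.

    Returns a tidy table (topology, fraction, seed, accuracy, n_dead).
    """
    from .experiment import (
        ExperimentConfig,
        derive_seeds,
        encode_dataset,
        reservoir_features,
    )
    from .datasets import make_toy_dataset
    from .readout import evaluate, train_readout
    from .topology import assemble_reservoir, build_input_synapses

    config = config or ExperimentConfig(topologies=tuple(topologies))
    enc = config.encoder
    rows = []
    for seed in seeds:
        (s_train, s_test, s_enc_tr, s_enc_te, s_topo, s_read, s_abl) = derive_seeds(seed, 7)
        train_imgs, train_labels = make_toy_dataset(
            config.n_classes, config.n_train_per_class, config.jitter, seed=s_train
        )
        test_imgs, test_labels = make_toy_dataset(
            config.n_classes, config.n_test_per_class, config.jitter, seed=s_test
        )
        enc_train = encode_dataset(train_imgs, enc, s_enc_tr, config.noise_level)
        enc_test = encode_dataset(test_imgs, enc, s_enc_te, config.noise_level)
        for kind in topologies:
            tcfg = config.topology_config(kind)
            network = assemble_reservoir(tcfg, seed=s_topo, dt=enc.dt, syn_params=config.syn)
            input_mode = "hough" if kind == "modular" else "random"
            input_syn = build_input_synapses(
                network, tcfg, train_imgs.shape[1:], input_mode,
                seed=s_topo, dt=enc.dt, syn_params=config.syn,
            )
            model = None
            if not retrain:
                ftrain = reservoir_features(network, input_syn, enc_train, config.lif,
                                            enc.settle_steps, enc.dt, chunk_size=config.chunk_size)
                model = train_readout(ftrain, train_labels, config.readout, seed=s_read)
            for fraction in fractions:
                damaged = ablate_synapses(network, AblationSpec(fraction, seed=s_abl))
                inputs = (
                    ablate_input_synapses(input_syn, fraction, seed=s_abl)
                    if ablate_inputs
                    else input_syn
                )
                if retrain:
                    ftrain = reservoir_features(damaged, inputs, enc_train, config.lif,
                                                enc.settle_steps, enc.dt,
                                                chunk_size=config.chunk_size)
                    model = train_readout(ftrain, train_labels, config.readout, seed=s_read)
                ftest = reservoir_features(damaged, inputs, enc_test, config.lif,
                                           enc.settle_steps, enc.dt,
                                           chunk_size=config.chunk_size)
                report = evaluate(model, ftest, test_labels)
                n_dead = damaged.n_synapses() - damaged.n_synapses(alive_only=True)
                n_dead += sum(s.n_synapses - s.n_alive for s in inputs)
                rows.append({
                    "topology": kind,
                    "fraction": fraction,
                    "seed": seed,
                    "accuracy": report.accuracy,
                    "n_dead": n_dead,
                })
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd accuracy per (topology, fraction), sorted."""
    return (
        table.groupby(["topology", "fraction"])["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy=lambda a: float(np.std(a, ddof=0)))
        .reset_index()
        .sort_values(["topology", "fraction"], kind="stable")
        .reset_index(drop=True)
    )
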