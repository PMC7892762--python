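"""End-to-end experiment orchestration.

Ties the stages together — build topology, encode images, simulate,
extract rate features, train and evaluate the readout — across topologies,
training-set sizes and seeds, and aggregates learning curves.  Every
result row carries the derived seeds and a configuration hash for full
provenance; reruns with identical configuration and seeds are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EncoderConfig, add_input_noise, apply_dog, dog_kernel, poisson_encode
from .params import LIFParams, SynapseParams
from .readout import EvalReport, ReadoutConfig, evaluate, train_readout
from .simulation import extract_features, simulate_modular, simulate_monolithic
from .synapses import SynapseSet
from .topology import Network, TopologyConfig, assemble_reservoir, build_input_synapses

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "derive_seeds",
    "encode_dataset",
    "reservoir_features",
    "baseline_features",
    "run_experiment",
    "learning_curve",
]


def derive_seeds(seed: int, n: int) -> list[int]:
    """n stable sub-seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class ExperimentConfig:
    """One experiment: dataset, topologies, parameter blocks, seeds.

    Defaults describe the desk-scale study: a 4-class stroke dataset with
    full geometric jitter (stroke positions and radii vary over their whole
    range, so classes are far from linearly separable in pixel space),
    benchmark-size reservoirs (``scale="full"``), and a shortened 400-step
    / 0.4 ms presentation with a 50-step settle phase — the presentation
    length, not the network, is the scaled-down dimension.
    ``scale="small"`` switches to ~730-neuron reservoirs for quick runs.
    """

    n_classes: int = 4
    n_train_per_class: int = 30
    n_test_per_class: int = 10
    jitter: float = 1.0
    noise_level: float = 0.0
    topologies: tuple[str, ...] = ("modular", "small_world", "metric", "random")
    scale: str = "full"
    chunk_size: int = 40
    train_sizes: tuple[int, ...] | None = None
    seeds: tuple[int, ...] = (0,)
    include_baseline: bool = True
    dog_size: int = 7
    dog_sigma1: float = 1.0
    dog_sigma2: float = 2.0
    encoder: EncoderConfig = field(
        default_factory=lambda: EncoderConfig(n_steps=400, settle_steps=50)
    )
    lif: LIFParams = field(default_factory=LIFParams)
    syn: SynapseParams = field(default_factory=SynapseParams)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("small", "full"):
            raise ValueError("scale must be 'small' or 'full'")
        if self.n_train_per_class < 1 or self.n_test_per_class < 1:
            raise ValueError("need at least one train and test sample per class")
        n_train = self.n_classes * self.n_train_per_class
        if self.train_sizes is None:
            self.train_sizes = (n_train,)
        if any(t <= 0 or t > n_train for t in self.train_sizes):
            raise ValueError("train sizes must lie in 1..n_train")

    def topology_config(self, kind: str) -> TopologyConfig:
        return TopologyConfig.small(kind) if self.scale == "small" else TopologyConfig.full(kind)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    confusions: dict
    config_hash: str


def encode_dataset(
    images: np.ndarray,
    encoder: EncoderConfig,
    seed: int,
    noise_level: float = 0.0,
    dog_size: int = 7,
    dog_sigma1: float = 1.0,
    dog_sigma2: float = 2.0,
) -> np.ndarray:
    """Noise -> DoG -> Poisson for a stack of images.

    Returns a uint8 batch of shape (n_samples, n_pixels, n_steps); each
    image gets its own derived sub-seed so the batch is reproducible and
    samples are independent.
    """
    kernel = dog_kernel(dog_size, dog_sigma1, dog_sigma2)
    sub = derive_seeds(seed, 2 * len(images))
    batch = np.empty((len(images), images.shape[1] * images.shape[2], encoder.n_steps),
                     dtype=np.uint8)
    for k, img in enumerate(images):
        if noise_level > 0:
            img = add_input_noise(img, noise_level, seed=sub[2 * k])
        filtered = apply_dog(img, kernel)
        batch[k] = poisson_encode(filtered, encoder, seed=sub[2 * k + 1]).spikes
    return batch


def reservoir_features(
    network: Network,
    input_synapses: list[SynapseSet],
    encoded: np.ndarray,
    lif: LIFParams | None = None,
    settle_steps: int = 50,
    dt: float = 0.4,
    mode: str = "modular",
    chunk_size: int = 40,
) -> np.ndarray:
    """Per-neuron mean rates (n_samples, n_neurons) for an encoded batch.

    Samples are independent trials, so the batch is simulated in chunks of
    ``chunk_size`` to bound memory without changing any result.
    """
    sim = simulate_modular if mode == "modular" else simulate_monolithic
    chunks = []
    for i in range(0, len(encoded), chunk_size):
        result = sim(network, input_synapses, encoded[i : i + chunk_size].astype(np.float64),
                     params=lif, settle_steps=settle_steps, dt=dt)
        chunks.append(extract_features(result))
    return np.vstack(chunks)


def baseline_features(encoded: np.ndarray, dt: float = 0.4) -> np.ndarray:
    """SVM-only control: per-pixel mean firing rates of the encoded input.

    The fairest "without the reservoir" comparison — the readout sees the
    same spiking input statistics, just not the reservoir expansion.
    """
    n_steps = encoded.shape[2]
    return encoded.sum(axis=2) / (n_steps * dt / 1000.0)


def _stratified_order(labels: np.ndarray) -> np.ndarray:
    """Class-interleaved sample order so any prefix is near-balanced."""
    order = []
    classes = np.unique(labels)
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    longest = max(len(ix) for ix in idx_by_class)
    for k in range(longest):
        for ix in idx_by_class:
            if k < len(ix):
                order.append(ix[k])
    return np.array(order)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full grid: (topology x train size x seed) -> accuracy.

    Per seed, a fresh train and test dataset is drawn and encoded once;
    each topology is built once and its features reused across
    training-set sizes.  The SVM-only baseline is evaluated on the encoded
    input rates.  Emits a tidy records table and, per (topology, seed),
    the confusion report at the largest training size.
    """
    from .datasets import make_toy_dataset

    chash = config.config_hash()
    rows = []
    confusions: dict = {}
    enc = config.encoder
    for seed in config.seeds:
        (s_train, s_test, s_enc_tr, s_enc_te, s_topo, s_read) = derive_seeds(seed, 6)
        train_imgs, train_labels = make_toy_dataset(
            config.n_classes, config.n_train_per_class, config.jitter, seed=s_train
        )
        test_imgs, test_labels = make_toy_dataset(
            config.n_classes, config.n_test_per_class, config.jitter, seed=s_test
        )
        enc_train = encode_dataset(train_imgs, enc, s_enc_tr, config.noise_level,
                                   config.dog_size, config.dog_sigma1, config.dog_sigma2)
        enc_test = encode_dataset(test_imgs, enc, s_enc_te, config.noise_level,
                                  config.dog_size, config.dog_sigma1, config.dog_sigma2)
        order = _stratified_order(train_labels)

        feature_sets = {}
        if config.include_baseline:
            feature_sets["svm_only"] = (
                baseline_features(enc_train, enc.dt),
                baseline_features(enc_test, enc.dt),
            )
        for kind in config.topologies:
            tcfg = config.topology_config(kind)
            network = assemble_reservoir(tcfg, seed=s_topo, dt=enc.dt, syn_params=config.syn)
            input_mode = "hough" if kind == "modular" else "random"
            input_syn = build_input_synapses(
                network, tcfg, train_imgs.shape[1:], input_mode,
                seed=s_topo, dt=enc.dt, syn_params=config.syn,
            )
            feature_sets[kind] = (
                reservoir_features(network, input_syn, enc_train, config.lif,
                                   enc.settle_steps, enc.dt, chunk_size=config.chunk_size),
                reservoir_features(network, input_syn, enc_test, config.lif,
                                   enc.settle_steps, enc.dt, chunk_size=config.chunk_size),
            )
        for name, (ftrain, ftest) in feature_sets.items():
            for size in config.train_sizes:
                sel = order[:size]
                if np.unique(train_labels[sel]).size < 2:
                    raise ValueError(f"train size {size} covers fewer than two classes")
                model = train_readout(ftrain[sel], train_labels[sel],
                                      config.readout, seed=s_read)
                report = evaluate(model, ftest, test_labels)
                rows.append({
                    "topology": name,
                    "train_size": size,
                    "seed": seed,
                    "accuracy": report.accuracy,
                    "n_test": report.n_samples,
                    "topology_seed": s_topo,
                    "encode_seed": s_enc_tr,
                    "readout_seed": s_read,
                    "config_hash": chash,
                })
                if size == max(config.train_sizes):
                    confusions[(name, seed)] = report
    records = pd.DataFrame(rows).sort_values(
        ["topology", "train_size", "seed"], kind="stable"
    ).reset_index(drop=True)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False)
        learning_curve(records).to_csv(out / "learning_curve.csv", index=False)
    return ExperimentResult(records, confusions, chash)


def learning_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd accuracy per (topology, train size).

    The sd is the population standard deviation over seeds (zero for a
    single seed); rows are sorted by (topology, train_size).
    """
    if records["train_size"].nunique() < 1:
        raise ValueError("no learning-curve points")
    grouped = (
        records.groupby(["topology", "train_size"])["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy=lambda a: float(np.std(a, ddof=0)),
             n_seeds="count")
        .reset_index()
        .sort_values(["topology", "train_size"], kind="stable")
        .reset_index(drop=True)
    )
    return grouped
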