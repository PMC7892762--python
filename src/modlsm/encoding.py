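"""Image-to-spike encoding: DoG filtering, Poisson rate coding, input noise.

The front end mimics early vision: a difference-of-Gaussians (DoG) filter
approximates the centre-surround receptive fields of retinal ganglion
cells, and each pixel of the filtered image drives an independent Poisson
spike train whose rate is proportional to intensity.  By default the
brightest pixel fires at 160 spikes/s and a presentation lasts 1,600 steps
of 0.4 ms (640 ms), preceded during simulation by a 50 ms silent settle
phase.

Images are H x W float arrays with intensities in [0, 1]; pixel ``(x, y)``
(x = column, y = row, 0-based, origin top-left) maps to input neuron
``y * W + x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .raster import SpikeRaster

__all__ = [
    "EncoderConfig",
    "dog_kernel",
    "apply_dog",
    "poisson_encode",
    "add_input_noise",
    "pixel_index",
]


@dataclass
class EncoderConfig:
    """Poisson-coding parameters.

    max_rate : peak firing rate in spikes/s assigned to the brightest pixel.
    n_steps  : presentation length in time steps.
    dt       : step length in ms; ``max_rate * dt`` must be a valid
               per-step spike probability (default 160 * 0.0004 = 0.064).
    settle_steps : silent steps prepended by the simulators (50 ms / dt).
    rectify_negatives : clip negative (OFF-surround) DoG responses to zero
               before rate scaling; if False, a two-channel ON/OFF raster
               is produced (ON rows first, then OFF rows).
    """

    max_rate: float = 160.0
    n_steps: int = 1600
    dt: float = 0.4
    settle_steps: int = 125
    rectify_negatives: bool = True

    def __post_init__(self) -> None:
        if self.max_rate < 0 or self.n_steps <= 0 or self.dt <= 0:
            raise ValueError("max_rate, n_steps and dt must be positive")
        if self.max_rate * self.dt / 1000.0 >= 1.0:
            raise ValueError("max_rate*dt must stay below 1 (a probability)")

    @property
    def p_max(self) -> float:
        """Per-step spike probability of a maximal-intensity pixel."""
        return self.max_rate * self.dt / 1000.0


def pixel_index(x: np.ndarray, y: np.ndarray, width: int) -> np.ndarray:
    """Input-neuron index of pixel (x=column, y=row) under row-major order."""
    return y * width + x


def dog_kernel(size: int, sigma1: float, sigma2: float) -> np.ndarray:
    """Difference-of-Gaussians kernel: G(sigma1) - G(sigma2).

    Each Gaussian is evaluated on the centred ``size x size`` integer grid
    and individually normalised to sum 1, so the DoG entries sum to zero
    and a constant image yields zero response.

    ``size`` must be odd and positive and ``0 < sigma1 < sigma2`` (the
    centre is excitatory, the surround inhibitory).
    """
    if size <= 0 or size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    if not (0 < sigma1 < sigma2):
        raise ValueError("need 0 < sigma1 < sigma2 (identical sigmas cancel)")
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = xx**2 + yy**2
    g1 = np.exp(-r2 / (2.0 * sigma1**2))
    g2 = np.exp(-r2 / (2.0 * sigma2**2))
    return g1 / g1.sum() - g2 / g2.sum()


def apply_dog(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D correlation of an image with a DoG kernel, zero-padded borders.

    Output shape equals input shape.  The border mode is plain zero
    padding; responses within ``size//2`` pixels of the border therefore
    see the (zero) padding.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if image.ndim != 2 or kernel.ndim != 2:
        raise ValueError("image and kernel must be 2-D")
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError("kernel larger than image")
    return scipy.ndimage.correlate(image, kernel, mode="constant", cval=0.0)


def _intensity_to_prob(values: np.ndarray, config: EncoderConfig) -> np.ndarray:
    """Linear intensity->rate map: the image maximum fires at max_rate."""
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        return np.zeros_like(values)
    return (values / vmax) * config.p_max


def poisson_encode(
    image: np.ndarray, config: EncoderConfig | None = None, seed: int | None = None
) -> SpikeRaster:
    """Convert an intensity image to an independent-Bernoulli spike raster.

    Pixel *i* spikes in each step with probability ``rate_i * dt`` where
    ``rate_i = max_rate * intensity_i / max intensity``.  Negative values
    (DoG OFF responses) are clipped to zero by default; with
    ``rectify_negatives=False`` the raster carries an ON block followed by
    an OFF block encoding ``max(v, 0)`` and ``max(-v, 0)`` respectively.

    Deterministic for a fixed seed.  An all-zero image yields an all-zero
    raster (valid, not an error).
    """
    config = config or EncoderConfig()
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image intensities must be finite")
    if config.rectify_negatives:
        values = np.clip(image, 0.0, None).ravel()
    else:
        values = np.concatenate(
            [np.clip(image, 0.0, None).ravel(), np.clip(-image, 0.0, None).ravel()]
        )
    p = _intensity_to_prob(values, config)
    rng = np.random.default_rng(seed)
    spikes = rng.random((values.size, config.n_steps)) < p[:, None]
    return SpikeRaster(
        spikes.astype(np.uint8),
        dt=config.dt,
        meta={"seed": seed, "max_rate": config.max_rate, "shape": image.shape},
    )


def add_input_noise(
    image: np.ndarray, noise_level: float, seed: int | None = None
) -> np.ndarray:
    """Add white noise to an image and clip the result to [0, 1].

    ``noise_level`` is the noise-to-signal amplitude ratio: the Gaussian
    noise has standard deviation ``noise_level * std(image)`` (so 0.2 means
    "20% white noise").  Deterministic for a fixed seed.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    image = np.asarray(image, dtype=np.float64)
    if noise_level == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    sigma = noise_level * image.std()
    return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)
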