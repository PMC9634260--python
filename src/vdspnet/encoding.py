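"""Grayscale-image-to-drive encoders for the input layer.

Rate coding is achieved implicitly: each pixel drives one input LIF neuron
with a constant current proportional to its intensity, so the neuron's
firing frequency grows with pixel value.  A black pixel contributes zero
drive; together with the input layer's positive bias it leaves the neuron at
a positive sub-threshold potential, which is what lets VDSP depress
background synapses.  Alternatively the drive can be delivered as a Poisson
spike raster (rate proportional to intensity), and zero-mean Gaussian noise
can be injected into constant-current drive to emulate noisy analog front
ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import ConfigurationError

__all__ = [
    "EncoderConfig",
    "EncodedSample",
    "encode_constant_current",
    "encode_poisson",
    "inject_gaussian_noise",
]


@dataclass(frozen=True)
class EncoderConfig:
    """How pixel intensities map onto input-neuron drive.

    ``current_scale`` is the constant current delivered at full-scale pixel
    intensity (``pixel_max``); the input neuron's bias is added inside the
    neuron model, not here.  In Poisson mode the firing rate at full scale
    is ``poisson_max_rate`` Hz.
    """

    pixel_max: float = 255.0
    current_scale: float = 1.0
    mode: str = "constant_current"
    poisson_max_rate: float = 60.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_max <= 0 or self.current_scale <= 0:
            raise ConfigurationError("pixel_max and current_scale must be positive")
        if self.poisson_max_rate <= 0:
            raise ConfigurationError("poisson_max_rate must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if self.mode not in ("constant_current", "poisson"):
            raise ConfigurationError(f"unknown encoder mode {self.mode!r}")


@dataclass
class EncodedSample:
    """Per-input-neuron drive for one stimulus presentation.

    ``drive`` is either a constant-current vector of length ``n_in``, a
    ``(n_steps, n_in)`` time-varying drive matrix (noisy constant current),
    or a boolean ``(n_steps, n_in)`` spike raster (Poisson mode).
    """

    drive: np.ndarray
    label: int
    duration: float

    @property
    def is_raster(self) -> bool:
        return self.drive.dtype == np.bool_

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("sample duration must be positive")


def encode_constant_current(
    pixels: np.ndarray,
    cfg: EncoderConfig,
    label: int = -1,
    duration: float = 350.0,
) -> EncodedSample:
    """Encode pixel intensities as constant input currents,
    ``drive_i = current_scale * pixels_i / pixel_max``."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if np.any(pixels < 0):
        raise ValueError("pixel intensities must be non-negative")
    drive = cfg.current_scale * pixels / cfg.pixel_max
    return EncodedSample(drive=drive, label=label, duration=duration)


def encode_poisson(
    pixels: np.ndarray,
    duration: float,
    dt: float,
    cfg: EncoderConfig,
    rng: np.random.Generator | int | None = None,
) -> EncodedSample:
    """Encode pixel intensities as independent Bernoulli spike trains with
    per-step probability ``rate_i * dt``, ``rate_i`` proportional to
    intensity (``poisson_max_rate`` at full scale)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ConfigurationError("duration must be a multiple of dt")
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if np.any(pixels < 0):
        raise ValueError("pixel intensities must be non-negative")
    rates_hz = cfg.poisson_max_rate * pixels / cfg.pixel_max
    p = rates_hz * dt * 1e-3  # dt is in ms
    if np.any(p > 1.0):
        raise ConfigurationError(
            "rate * dt exceeds 1 spike per step; decrease dt or the rate"
        )
    if rng is None:
        rng = cfg.seed
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    raster = rng.random((n_steps, pixels.size)) < p[None, :]
    return EncodedSample(drive=raster, label=-1, duration=duration)


def inject_gaussian_noise(
    drive: np.ndarray,
    noise_sigma: float,
    rng: np.random.Generator | int,
    n_steps: int | None = None,
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise per neuron per step.

    A 1-D constant-current drive is broadcast to ``(n_steps, n_in)`` first
    (``n_steps`` required in that case); the expectation of the drive is
    unchanged.
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be non-negative")
    drive = np.asarray(drive, dtype=np.float64)
    if drive.ndim == 1:
        if n_steps is None:
            raise ConfigurationError("n_steps required to add noise to constant drive")
        drive = np.broadcast_to(drive, (n_steps, drive.size)).copy()
    if noise_sigma == 0:
        return drive
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return drive + rng.normal(0.0, noise_sigma, size=drive.shape)
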