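"""Measurement-noise model for simulated FRF magnitudes.

Noise emulates moderate experimental variability in amplitude measurements:
zero-mean Gaussian perturbations applied independently per (DOF, frequency)
cell, scaled relative to the local response magnitude.  Phase and the
underlying complex responses are left untouched — only the magnitude
channel, the observable used for inverse fitting and classification, is
corrupted.

Two scalings are provided:

* ``relative`` (default): m -> m * (1 + sigma * eps), i.e. the perturbation
  standard deviation is sigma times the local magnitude;
* ``additive``: m -> m + sigma * mean(m) * eps, a strictly additive
  perturbation with amplitude set by the band-mean magnitude per DOF.

Corrupted magnitudes are clamped below at a small positive floor so they
remain valid amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frf import FRFResult

__all__ = ["NoiseSpec", "add_magnitude_noise"]

_MODES = ("relative", "additive")


@dataclass(frozen=True)
class NoiseSpec:
    """Magnitude-noise parameters.

    Parameters
    ----------
    relative_sigma : float
        Noise standard deviation as a fraction of the local (or band-mean)
        magnitude.  Default 0.02 (2 %), a moderate experimental level.
    seed : int
        Seed for the dedicated random generator; same seed, same noise.
    floor : float
        Lower clamp keeping corrupted magnitudes positive.
    mode : str
        ``"relative"`` or ``"additive"`` (see module docstring).
    """

    relative_sigma: float = 0.02
    seed: int = 0
    floor: float = 1e-12
    mode: str = "relative"

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")


def add_magnitude_noise(
    result: FRFResult, spec: NoiseSpec, rng: np.random.Generator | None = None
) -> FRFResult:
    """Return a copy of ``result`` with noisy magnitudes.

    Each magnitude cell receives an independent Gaussian perturbation;
    draws are deterministic given ``spec.seed`` (or the supplied ``rng``,
    which takes precedence — used by the cohort generator to stream one
    seed sequence across many realizations).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mag = result.magnitude
    if np.any(mag <= 0):
        raise ValueError("magnitudes must be > 0 before noise injection")
    eps = rng.standard_normal(mag.shape)
    if spec.mode == "relative":
        noisy = mag * (1.0 + spec.relative_sigma * eps)
    else:
        band_mean = mag.mean(axis=1, keepdims=True)
        noisy = mag + spec.relative_sigma * band_mean * eps
    noisy = np.maximum(noisy, spec.floor)
    return result.with_magnitude(noisy)
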