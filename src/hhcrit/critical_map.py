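"""Synthetic trajectories with known critical exponents.

The one-dimensional intermittency map

    phi[n+1] = phi[n] + u * phi[n]**z + eps

has a marginally stable fixed point at 0; trajectories crawl through
its neighbourhood (laminar phases) and are reinjected uniformly into
[0, 1) once they exceed 1.  The laminar lengths follow a power law with
exponent p = z/(z-1), which makes the map the ground-truth generator
for validating the MCF exponent recovery.  ``eps`` models finite-size
noise: one-sided uniform on (0, w) by default, so the fixed point is
approached only via reinjection; symmetric noise is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k

__all__ = ["CriticalMapConfig", "iterate_map", "gaussian_series"]


_NOISE_LAWS = {"gaussian": 0, "uniform": 1, "uniform_two_sided": 2}


@dataclass(frozen=True)
class CriticalMapConfig:
    """Map parameters.

    ``noise_law``: 'gaussian' (default; sd = noise_width, reflected at
    the fixed point), 'uniform' (one-sided on (0, w)), or
    'uniform_two_sided'.  Gaussian noise is the natural finite-size
    law -- the aggregate of many microscopic contributions -- and its
    soft cutoff of the longest laminar phases is exactly the
    exponential correction the fit model carries.
    """
    u: float = 30.0
    z: float = 2.0
    noise_width: float = 1e-6
    n: int = 1_000_000
    seed: int = 0
    phi_init: float = 0.5
    noise_law: str = "gaussian"

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("coupling u must be positive")
        if self.z <= 1:
            raise ValueError("nonlinearity z must exceed 1")
        if self.noise_width < 0:
            raise ValueError("noise_width must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.noise_law not in _NOISE_LAWS:
            raise ValueError(f"unknown noise law {self.noise_law!r}")


def iterate_map(config: CriticalMapConfig) -> np.ndarray:
    """Seeded trajectory of the map, confined to [0, 1]."""
    seed = config.seed % (2 ** 31 - 1)
    return _k.critical_map_kernel(config.n, config.u, config.z,
                                  config.noise_width, config.phi_init,
                                  seed, _NOISE_LAWS[config.noise_law])


def gaussian_series(n: int, sd: float, seed: int = 0) -> np.ndarray:
    """i.i.d. zero-mean Gaussian series (the memoryless null of MCF)."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return np.random.default_rng(seed).normal(0.0, sd, size=n)
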