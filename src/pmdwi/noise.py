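"""Rician magnitude noise for simulated MRI signals."""

from __future__ import annotations

from typing import Union

import numpy as np

__all__ = ["add_rician_noise"]


def add_rician_noise(
    signals: np.ndarray,
    sigma: float,
    n_averages: int = 1,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise), averaged over repeats.

    Each of ``n_averages`` acquisitions receives independent complex Gaussian
    noise of standard deviation ``sigma`` per channel before the magnitude is
    taken; the averages are then combined.  sigma = 0 returns the input
    unchanged.  Deterministic given ``seed``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0 (got {sigma})")
    if n_averages < 1:
        raise ValueError(f"n_averages must be >= 1 (got {n_averages})")
    s = np.asarray(signals, float)
    if sigma == 0:
        return s.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    re = s[None, ...] + rng.normal(0.0, sigma, (n_averages,) + s.shape)
    im = rng.normal(0.0, sigma, (n_averages,) + s.shape)
    return np.hypot(re, im).mean(axis=0)
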