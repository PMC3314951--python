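"""Diffusion gradient direction schemes.

Direction sets are generated by electrostatic-repulsion optimization on the
sphere with antipodal symmetry (each direction interacts with both the point
charges and their antipodes), the standard construction for isotropically
distributed diffusion-encoding schemes.  Schemes are read and written in the
3-row bvec / 1-row bval whitespace-separated dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DirectionScheme",
    "generate_directions",
    "pairwise_min_angle",
    "electrostatic_energy",
    "write_bvecs_bvals",
    "read_bvecs_bvals",
]


@dataclass(frozen=True)
class DirectionScheme:
    """Unit diffusion-encoding directions plus a count of low-b measurements.

    ``vectors`` has one row per diffusion-weighted measurement; the scheme
    additionally carries ``n_lowb`` low-b volumes (conventionally stored
    before the weighted ones in bvec/bval tables).
    """

    vectors: np.ndarray
    n_lowb: int = 0

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, float))
        object.__setattr__(self, "vectors", v)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vectors must be (n, 3) (got shape {v.shape})")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("direction vectors must be unit norm (tolerance 1e-9)")
        if self.n_lowb < 0:
            raise ValueError(f"n_lowb must be >= 0 (got {self.n_lowb})")
        if len(v) <= 64 and len(v) >= 2:
            if pairwise_min_angle(v) <= 5.0:
                raise ValueError(
                    "minimum pairwise angle (mod antipodal symmetry) must "
                    "exceed 5 degrees for n <= 64"
                )

    @property
    def n(self) -> int:
        return len(self.vectors)


def pairwise_min_angle(vectors: np.ndarray) -> float:
    """Minimum pairwise angle in degrees, modulo antipodal symmetry."""
    v = np.asarray(vectors, float)
    dots = np.abs(v @ v.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1, 1))))


def electrostatic_energy(vectors: np.ndarray) -> float:
    """Antipodal Coulomb energy sum_{i<j} 1/|vi-vj| + 1/|vi+vj|."""
    v = np.asarray(vectors, float)
    n = len(v)
    iu = np.triu_indices(n, 1)
    dm = np.linalg.norm(v[iu[0]] - v[iu[1]], axis=1)
    dp = np.linalg.norm(v[iu[0]] + v[iu[1]], axis=1)
    return float(np.sum(1.0 / dm) + np.sum(1.0 / dp))


def _energy_grad(angles: np.ndarray, n: int):
    th, ph = angles[:n], angles[n:]
    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    v = np.stack([st * cp, st * sp, ct], axis=1)
    diff = v[:, None, :] - v[None, :, :]
    summ = v[:, None, :] + v[None, :, :]
    dm = np.linalg.norm(diff, axis=2)
    dp = np.linalg.norm(summ, axis=2)
    np.fill_diagonal(dm, np.inf)
    np.fill_diagonal(dp, np.inf)
    E = 0.5 * (np.sum(1.0 / dm) + np.sum(1.0 / dp))
    # dE/dv_i
    gv = -np.sum(diff / dm[:, :, None] ** 3, axis=1) - np.sum(summ / dp[:, :, None] ** 3, axis=1)
    dv_dth = np.stack([ct * cp, ct * sp, -st], axis=1)
    dv_dph = np.stack([-st * sp, st * cp, np.zeros(n)], axis=1)
    return E, np.concatenate([np.sum(gv * dv_dth, 1), np.sum(gv * dv_dph, 1)])


def generate_directions(
    n: int,
    seed: int = 0,
    n_lowb: int = 0,
    n_restarts: int = 4,
    maxiter: int = 400,
) -> DirectionScheme:
    """Electrostatic-repulsion direction scheme; deterministic given seed.

    The best of ``n_restarts`` seeded random initializations, each refined by
    L-BFGS on spherical coordinates with analytic gradients.
    """
    if n < 6:
        raise ValueError(f"need n >= 6 directions for a determined fit (got {n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        v0 = rng.standard_normal((n, 3))
        v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
        th = np.arccos(np.clip(v0[:, 2], -1, 1))
        ph = np.arctan2(v0[:, 1], v0[:, 0])
        res = minimize(
            _energy_grad, np.concatenate([th, ph]), args=(n,), jac=True,
            method="L-BFGS-B", options={"maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    th, ph = best.x[:n], best.x[n:]
    v = np.stack([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=1)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # canonical hemisphere + stable ordering for reproducibility
    flip = v[:, 2] < 0
    v[flip] *= -1
    v = v[np.lexsort((v[:, 1], v[:, 0], v[:, 2]))]
    return DirectionScheme(vectors=v, n_lowb=n_lowb)


def write_bvecs_bvals(
    scheme: DirectionScheme,
    bvec_path: Union[str, Path],
    bval_path: Union[str, Path],
    b_high: float,
    b_low: float = 0.0,
) -> None:
    """Write the scheme as 3-row bvec / 1-row bval tables (low-b first)."""
    zeros = np.zeros((scheme.n_lowb, 3))
    vecs = np.vstack([zeros, scheme.vectors])
    bvals = np.concatenate([np.full(scheme.n_lowb, b_low), np.full(scheme.n, b_high)])
    np.savetxt(bvec_path, vecs.T, fmt="%.10f")
    np.savetxt(bval_path, bvals[None, :], fmt="%g")


def read_bvecs_bvals(
    bvec_path: Union[str, Path], bval_path: Union[str, Path],
    b_low_threshold: float = 100.0,
) -> Tuple[DirectionScheme, np.ndarray]:
    """Read a 3-row bvec / 1-row bval pair; returns (scheme, bvals).

    Volumes with b below ``b_low_threshold`` are counted as low-b and removed
    from the direction list.
    """
    vecs = np.loadtxt(bvec_path)
    if vecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows (got {vecs.shape[0]})")
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if vecs.shape[1] != len(bvals):
        raise ValueError("bvec/bval column counts differ")
    low = bvals < b_low_threshold
    v = vecs.T[~low]
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return DirectionScheme(vectors=v, n_lowb=int(low.sum())), bvals
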