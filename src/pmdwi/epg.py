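"""Extended-phase-graph steady-state simulator for DW-SSFP.

Independent numerical oracle for the closed-form solver in ``signals``: the
same sequence physics (constant-phase RF, one rectangular gradient lobe per
TR, per-order diffusion attenuation) is iterated TR by TR with the standard
complex EPG operators until the echo amplitude converges, rather than solved
directly.  Agreement between the two routes validates both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import q_rad_per_mm
from .params import SSFPProtocol, TissueParams

__all__ = ["EPGState", "epg_steady_state", "EPGConvergenceError"]


class EPGConvergenceError(RuntimeError):
    """Raised when the power iteration fails to reach a steady state."""


@dataclass
class EPGState:
    """Configuration-state amplitudes F_k (transverse) and Z_k (longitudinal).

    Arrays are indexed k = -K .. K (index k + K); amplitudes are fractions of
    M0.
    """

    F: np.ndarray
    Z: np.ndarray

    @property
    def max_order(self) -> int:
        return (len(self.F) - 1) // 2


def epg_steady_state(
    protocol: SSFPProtocol,
    tissue: TissueParams,
    max_order: int = 100,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    initial: str = "equilibrium",
    return_state: bool = False,
):
    """Steady-state DW-SSFP echo amplitude by EPG power iteration.

    Each TR applies: RF rotation (flip alpha about x, constant phase), then
    the gradient lobe (duration delta: relaxation, per-order diffusion
    attenuation, order shift +1), then free evolution (TR - delta).  The echo
    is the F_0 amplitude just before the next pulse.  Convergence is declared
    on the echo amplitude once five consecutive TRs change it by less than
    ``tol`` (relative); the result must additionally leave the boundary
    orders unpopulated (otherwise ``max_order`` is too small).
    """
    if max_order < 10:
        raise ValueError(f"max_order must be >= 10 (got {max_order})")
    if tol <= 0:
        raise ValueError(f"tol must be > 0 (got {tol})")
    if initial not in ("equilibrium", "saturated"):
        raise ValueError(f"initial must be 'equilibrium' or 'saturated' (got {initial!r})")

    TR, alpha, delta, G = protocol.TR, protocol.alpha, protocol.delta, protocol.G
    T1, T2, D = tissue.T1, tissue.T2, tissue.D
    a = np.radians(alpha)
    q = q_rad_per_mm(G, delta)
    K = max_order
    i0 = K
    ks = np.arange(-K, K + 1)

    att_lobe_T = np.exp(-D * q * q * (delta * 1e-3) * (ks**2 + ks + 1.0 / 3.0))
    att_lobe_L = np.exp(-D * q * q * (delta * 1e-3) * ks**2)
    att_free = np.exp(-D * q * q * ((TR - delta) * 1e-3) * ks**2)
    E1l, E2l = np.exp(-delta / T1), np.exp(-delta / T2)
    E1f, E2f = np.exp(-(TR - delta) / T1), np.exp(-(TR - delta) / T2)
    c2, s2, sa, ca = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2, np.sin(a), np.cos(a)

    F = np.zeros(2 * K + 1, complex)
    Z = np.zeros(2 * K + 1, complex)
    if initial == "equilibrium":
        Z[i0] = 1.0

    prev = None
    streak = 0
    for _ in range(max_iter):
        # RF mixing of (F_k, conj(F_-k), Z_k)
        Fm = np.conj(F[::-1])
        F, Z = (c2 * F + s2 * Fm - 1j * sa * Z,
                -0.5j * sa * F + 0.5j * sa * Fm + ca * Z)
        # gradient lobe: relax + attenuate + recover, then shift orders +1
        F *= E2l * att_lobe_T
        Z *= E1l * att_lobe_L
        Z[i0] += 1 - E1l
        F = np.roll(F, 1)
        F[0] = 0.0
        # free period
        F *= E2f * att_free
        Z *= E1f * att_free
        Z[i0] += 1 - E1f
        echo = abs(F[i0])
        if prev is not None and abs(echo - prev) <= tol * max(echo, 1e-30):
            streak += 1
            if streak >= 5:
                break
        else:
            streak = 0
        prev = echo
    else:
        raise EPGConvergenceError(
            f"echo amplitude not converged to tol={tol} within {max_iter} TRs"
        )

    boundary = max(abs(F[1]), abs(F[-1]), abs(Z[1]), abs(Z[-1]))
    if boundary > 1e-8:
        raise EPGConvergenceError(
            f"boundary configuration amplitude {boundary:.2e} > 1e-8: "
            f"max_order={max_order} too small"
        )
    if return_state:
        return float(echo), EPGState(F=F, Z=Z)
    return float(echo)
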