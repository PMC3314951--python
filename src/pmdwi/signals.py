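"""Closed-form steady-state signals for DW-SE and DW-SSFP.

DW-SE
-----
The spin-echo signal is separable: a longitudinal recovery factor over the
recovery period TR - TE (the refocusing pulses are assumed to destroy
longitudinal recovery until the echo), the transverse decay exp(-TE/T2), and
optionally the Stejskal-Tanner diffusion attenuation exp(-b*D).

DW-SSFP
-------
The diffusion-weighted SSFP steady state follows the Buxton sequence model:
one rectangular diffusion-gradient lobe of moment q = gamma*G*delta per TR,
constant RF phase, measurement of the echo pathway (the coherence that
refocuses just before the next RF pulse).  Decomposing the magnetization into
configuration states F_k / Z_k, the steady state satisfies a linear recursion
in the dephasing order k; ``dwssfp_signal`` solves that recursion *exactly*
by a direct linear solve, with per-order diffusion attenuation:

* transverse state passing from order k to k+1 through the lobe:
  exp(-D q^2 [delta (k^2 + k + 1/3) + (TR - delta)(k+1)^2])
* longitudinal state of order k over one TR: exp(-D q^2 k^2 TR)

At D = 0 the recursion has the classic scalar solution (Freeman-Hill /
Ernst-Anderson SSFP echo), implemented in ``ssfp_echo_ideal`` and used as an
analytic cross-check and fast path for the non-diffusion-weighted amplitude.

The effective b-value of a DW-SSFP protocol is defined as the DW-SE b-value
giving the same fractional attenuation for the stated tissue:
b_eff = -(1/D) ln[S(D)/S(D=0)].
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import q_rad_per_mm
from .params import SEProtocol, SSFPProtocol, TissueParams

__all__ = [
    "ernst_angle",
    "dwse_signal",
    "min_te_dwse",
    "dwssfp_signal",
    "ssfp_echo_ideal",
    "ssfp_echo",
    "beff",
    "DEFAULT_TE_ANCHORS",
]


def ernst_angle(recovery_time: float, T1: float) -> float:
    """Flip angle (degrees) maximizing the spoiled steady-state signal.

    cos(alpha_E) = exp(-recovery_time/T1).  At this angle the longitudinal
    steady-state factor equals sqrt((1-E1)/(1+E1)).
    """
    if recovery_time <= 0:
        raise ValueError(f"recovery_time must be > 0 (got {recovery_time})")
    if T1 <= 0:
        raise ValueError(f"T1 must be > 0 (got {T1})")
    return float(np.degrees(np.arccos(np.exp(-recovery_time / T1))))


def _longitudinal_factor(
    recovery: float, T1: float, alpha: Union[float, str], model: str
) -> float:
    E1 = np.exp(-recovery / T1)
    if model == "saturation":
        return 1.0 - E1
    if model != "ernst":
        raise ValueError(f"recovery_model must be 'ernst' or 'saturation' (got {model!r})")
    if isinstance(alpha, str):  # "optimal" -> Ernst angle
        return float(np.sqrt((1 - E1) / (1 + E1)))
    a = np.radians(alpha)
    return float(np.sin(a) * (1 - E1) / (1 - np.cos(a) * E1))


def dwse_signal(
    protocol: SEProtocol,
    tissue: TissueParams,
    include_diffusion_attenuation: bool = False,
    recovery_model: str = "ernst",
) -> float:
    """Steady-state DW-SE signal as a fraction of M0.

    The recovery period is TR - TE.  ``recovery_model="ernst"`` uses the
    spoiled-GRE steady state sin(a)(1-E1)/(1-cos(a)E1) (with a the Ernst angle
    when the protocol requests ``alpha="optimal"``); ``"saturation"`` uses
    1 - E1.  The diffusion factor exp(-b*D) is excluded by default, matching
    the raw-signal convention used in the sequence-efficiency comparison.
    """
    L = _longitudinal_factor(protocol.TR - protocol.TE, tissue.T1, protocol.alpha, recovery_model)
    s = L * np.exp(-protocol.TE / tissue.T2)
    if include_diffusion_attenuation:
        s *= np.exp(-protocol.b * tissue.D)
    return float(s)


#: Minimum achievable DW-SE echo time on the reference scanner (5/8 partial
#: Fourier, twice-refocused preparation): printed endpoints plus the
#: implemented b = 4500 s/mm^2 protocol.
DEFAULT_TE_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (1000.0, 91.0),
    (4500.0, 122.0),
    (10000.0, 148.0),
)


def min_te_dwse(
    b: float,
    anchors: Optional[Sequence[Tuple[float, float]]] = None,
    allow_extrapolation: bool = False,
) -> float:
    """Minimum DW-SE echo time (ms) at b (s/mm^2) by monotone interpolation.

    Shape-preserving (PCHIP) interpolation on b^(1/3): the diffusion gradient
    duration, and hence the echo time penalty, grows sublinearly with b at
    fixed gradient amplitude.
    """
    anc = sorted(anchors if anchors is not None else DEFAULT_TE_ANCHORS)
    bs = np.array([a[0] for a in anc], float)
    tes = np.array([a[1] for a in anc], float)
    if len(bs) < 2:
        raise ValueError("need at least two (b, TE) anchors")
    if not allow_extrapolation and not (bs[0] <= b <= bs[-1]):
        raise ValueError(
            f"b={b} outside anchored range [{bs[0]}, {bs[-1]}]; "
            "pass allow_extrapolation=True to override"
        )
    interp = PchipInterpolator(np.cbrt(bs), tes, extrapolate=True)
    return float(interp(np.cbrt(b)))


# ---------------------------------------------------------------------------
# DW-SSFP steady state
# ---------------------------------------------------------------------------


def ssfp_echo_ideal(TR: float, alpha: float, T1: float, T2: float) -> float:
    """Non-diffusion-weighted SSFP echo amplitude (fraction of M0).

    Classic closed form for the gradient-spoiled steady state with constant RF
    phase, obtained from the configuration recursion at D = 0: the bounded
    tail solution is the decaying eigenvector of the two-state transfer
    matrix, whose eigenvalue carries the characteristic square root.
    """
    a = np.radians(alpha)
    E1, E2 = np.exp(-TR / T1), np.exp(-TR / T2)
    sa, ca = np.sin(a), np.cos(a)
    c2, s2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    bet = sa * E1 / (2 * (1 - ca * E1))
    gam = (1 - E1) / (1 - ca * E1)
    A = E2 * (c2 - sa * bet)
    B = E2 * (s2 + sa * bet)
    h = E2 * sa * gam
    tau = A + (1 - B * B) / A
    # transfer matrix has det 1: eigenvalues lam, 1/lam; keep |lam| < 1,
    # computed through the large root for stability as A -> 0
    with np.errstate(over="ignore", divide="ignore"):
        r_big = (abs(tau) + np.sqrt(tau * tau - 4.0)) / 2.0
        lam = np.sign(tau) / r_big
    P = (A * (A - lam) - B * B) / B
    g1 = -h / (1.0 - (A - B) * P)
    return float(abs(P * g1))


def _ssfp_solve(
    TR: float,
    alpha: float,
    delta: float,
    G: float,
    T1: float,
    T2: float,
    D: float,
    max_order: int,
) -> Tuple[float, float]:
    """Direct solve of the configuration recursion; returns (echo, tail).

    ``tail`` is the boundary amplitude relative to the echo, used to verify
    that ``max_order`` retained enough configuration states.
    """
    a = np.radians(alpha)
    q = q_rad_per_mm(G, delta)
    E1, E2 = np.exp(-TR / T1), np.exp(-TR / T2)
    K = max_order
    ks = np.arange(-K, K + 1)
    # per-order diffusion attenuation (times converted ms -> s)
    At = E2 * np.exp(
        -D * q * q * 1e-3 * (delta * (ks**2 + ks + 1.0 / 3.0) + (TR - delta) * (ks + 1) ** 2)
    )
    Lam = np.exp(-D * q * q * TR * 1e-3 * ks**2)
    sa, ca = np.sin(a), np.cos(a)
    c2, s2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    bet = sa * E1 * Lam / (2 * (1 - ca * E1 * Lam))
    gam = (1 - E1) / (1 - ca * E1)

    n = 2 * K + 1
    M = np.zeros((n, n))
    rhs = np.zeros(n)
    rows = np.arange(1, n)  # equation for g_{k+1}, k = -K .. K-1
    np.add.at(M, (rows, rows), 1.0)
    np.add.at(M, (rows, rows - 1), -At[:-1] * (c2 - sa * bet[:-1]))
    np.add.at(M, (rows, n - rows), At[:-1] * (s2 + sa * bet[:-1]))
    M[0, 0] = 1.0  # truncation: g_{-K} = 0
    rhs[K + 1] = -At[K] * sa * gam
    g = np.linalg.solve(M, rhs)
    echo = abs(g[K])
    tail = max(abs(g[1]), abs(g[-1])) / max(echo, 1e-300)
    return float(echo), float(tail)


def ssfp_echo(
    TR: float,
    alpha: float,
    delta: float,
    G: float,
    T1: float,
    T2: float,
    D: float,
    max_order: int = 48,
) -> float:
    """DW-SSFP echo amplitude (fraction of M0) for explicit parameters.

    Exact steady state of the Buxton sequence model; the configuration order
    truncation is grown automatically until the boundary amplitude is
    negligible.
    """
    if D == 0:
        return ssfp_echo_ideal(TR, alpha, T1, T2)
    K = max_order
    while True:
        echo, tail = _ssfp_solve(TR, alpha, delta, G, T1, T2, D, K)
        if tail < 1e-10 or K >= 384:
            return echo
        K *= 2


def dwssfp_signal(
    protocol: SSFPProtocol,
    tissue: TissueParams,
    include_diffusion_attenuation: bool = True,
    max_order: int = 48,
) -> float:
    """Steady-state DW-SSFP echo amplitude as a fraction of M0.

    With ``include_diffusion_attenuation=False`` (or D = 0) this reduces to
    the classic non-diffusion-weighted SSFP echo closed form.
    """
    if protocol.delta / protocol.TR > 0.9:
        warnings.warn(
            f"delta/TR = {protocol.delta / protocol.TR:.2f} > 0.9: readout infeasible",
            stacklevel=2,
        )
    D = tissue.D if include_diffusion_attenuation else 0.0
    return ssfp_echo(
        protocol.TR, protocol.alpha, protocol.delta, protocol.G,
        tissue.T1, tissue.T2, D, max_order=max_order,
    )


def beff(
    protocol: SSFPProtocol,
    tissue: TissueParams,
    max_order: int = 48,
) -> float:
    """Effective b-value (s/mm^2) of a DW-SSFP protocol for the given tissue.

    b_eff = -(1/D) ln[S(D)/S(D=0)]: the DW-SE b-value that would produce the
    same fractional attenuation.  Independent of M0 and of the readout; only
    weakly dependent on D itself.
    """
    if tissue.D == 0:
        raise ValueError(
            "b_eff is undefined at D = 0 (division by zero); compare the "
            "attenuation ratio S(D)/S(0) directly instead"
        )
    s_dw = dwssfp_signal(protocol, tissue, True, max_order=max_order)
    s0 = dwssfp_signal(protocol, tissue, False, max_order=max_order)
    return float(-np.log(s_dw / s0) / tissue.D)
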