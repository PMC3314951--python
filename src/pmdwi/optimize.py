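"""SNR-efficiency computation and constrained protocol optimization.

The figure of merit is the SNR efficiency eta = S[%] * sqrt(rho): the raw
(non-diffusion-weighted) steady-state amplitude in percent of M0 times the
square root of the readout efficiency rho = T_acq/TR.  Optimizing eta subject
to an effective-b-value constraint is equivalent to optimizing the
diffusion-weighted SNR efficiency, since on the constraint manifold the two
differ by the constant factor exp(-b_eff * D).

DW-SSFP optimization searches (TR, delta, alpha): for each candidate
(TR, alpha) the gradient duration delta is solved by bisection so that the
protocol achieves the target b_eff (b_eff is strictly increasing in delta),
then eta is maximized over alpha (bounded scalar search) and TR (coarse grid
plus local refinement; ties broken toward shorter TR).  DW-SE optimization
fixes T_acq = 30 ms and the minimum echo time TE(b), and searches TR with the
excitation at the Ernst angle of the recovery period.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .params import FIXED_TISSUE, OptimizationResult, SEProtocol, SSFPProtocol, TissueParams
from .signals import (
    dwse_signal,
    dwssfp_signal,
    beff as beff_of,
    min_te_dwse,
    ssfp_echo,
    ssfp_echo_ideal,
)

__all__ = [
    "snr_efficiency",
    "evaluate_ssfp_protocol",
    "optimize_dwssfp",
    "optimize_dwse",
    "required_tr_2d",
    "match_te_equal_efficiency",
    "efficiency_landscape",
]

_G_DEFAULT = 38.0


def snr_efficiency(S: float, T_acq: float, TR: float) -> float:
    """eta = S[%] * sqrt(T_acq/TR) for a signal S given as a fraction of M0."""
    if not (0 < T_acq <= TR):
        raise ValueError(f"need 0 < T_acq <= TR (got T_acq={T_acq}, TR={TR})")
    return 100.0 * S * float(np.sqrt(T_acq / TR))


def _beff_fast(TR, alpha, delta, G, tissue, max_order=48):
    s_dw = ssfp_echo(TR, alpha, delta, G, tissue.T1, tissue.T2, tissue.D, max_order)
    s0 = ssfp_echo_ideal(TR, alpha, tissue.T1, tissue.T2)
    return -np.log(s_dw / s0) / tissue.D


def _delta_for_beff(TR, alpha, target, tissue, G, T_dead, delta_min=0.05):
    """Solve b_eff(delta) = target at fixed (TR, alpha); None if unreachable."""
    delta_max = TR - T_dead - 1e-3
    if delta_max <= delta_min:
        return None
    f = lambda d: _beff_fast(TR, alpha, d, G, tissue) - target
    if f(delta_max) < 0:
        return None
    if f(delta_min) > 0:
        return None
    return brentq(f, delta_min, delta_max, xtol=1e-4)


def evaluate_ssfp_protocol(
    TR: float,
    delta: float,
    tissue: TissueParams = FIXED_TISSUE,
    alpha="optimal",
    G: float = _G_DEFAULT,
    T_dead: float = 5.0,
    T_acq_cap: float = 30.0,
) -> OptimizationResult:
    """Figures of merit of one DW-SSFP (TR, delta) configuration.

    With ``alpha="optimal"`` the flip angle maximizing the
    diffusion-weighted signal at the fixed timing is found by bounded scalar
    search (the readout efficiency is fixed, so this maximizes the physical
    DW SNR); eta is then reported on the raw-amplitude convention.
    """
    T_acq = TR - delta - T_dead
    if T_acq <= 0:
        raise ValueError(
            f"infeasible timing: T_acq = TR - delta - T_dead = {T_acq:.3f} <= 0"
        )
    if alpha == "optimal":
        r = minimize_scalar(
            lambda a: -ssfp_echo(TR, a, delta, G, tissue.T1, tissue.T2, tissue.D),
            bounds=(1.0, 90.0), method="bounded", options={"xatol": 1e-3},
        )
        alpha = float(r.x)
    proto = SSFPProtocol(TR=TR, alpha=alpha, delta=delta, G=G,
                         T_dead=T_dead, T_acq_cap=T_acq_cap)
    S = ssfp_echo_ideal(TR, alpha, tissue.T1, tissue.T2)
    S_dw = dwssfp_signal(proto, tissue)
    rho = proto.T_acq_effective / TR
    eta = snr_efficiency(S, proto.T_acq_effective, TR)
    b = beff_of(proto, tissue) if tissue.D > 0 else 0.0
    return OptimizationResult(protocol=proto, S=S, rho=rho, eta=eta,
                              b_achieved=b, S_dw=S_dw)


def _eta_ssfp_at(TR, alpha, target, tissue, G, T_dead, T_acq_cap):
    """(eta, delta) at fixed (TR, alpha) subject to the b_eff constraint."""
    d = _delta_for_beff(TR, alpha, target, tissue, G, T_dead)
    if d is None:
        return -np.inf, None
    T_acq = TR - d - T_dead
    if T_acq <= 0:
        return -np.inf, None
    S = ssfp_echo_ideal(TR, alpha, tissue.T1, tissue.T2)
    return snr_efficiency(S, min(T_acq, T_acq_cap), TR), d


def optimize_dwssfp(
    beff_target: float,
    tissue: TissueParams = FIXED_TISSUE,
    TR_range: Tuple[float, float] = (10.0, 200.0),
    TR_step: float = 0.5,
    G: float = _G_DEFAULT,
    T_dead: float = 5.0,
    T_acq_cap: float = 30.0,
    alpha_bounds: Tuple[float, float] = (1.0, 90.0),
    keep_trace: bool = False,
) -> OptimizationResult:
    """Maximize DW-SSFP SNR efficiency subject to b_eff = ``beff_target``.

    Deterministic grid-then-refine search; the returned protocol achieves the
    target effective b-value to <= 1e-3 relative.
    """
    if beff_target <= 0:
        raise ValueError(f"beff_target must be > 0 (got {beff_target})")

    def neg_eta(TR, a):
        eta, _ = _eta_ssfp_at(TR, a, beff_target, tissue, G, T_dead, T_acq_cap)
        return -eta if np.isfinite(eta) else 1e12  # finite penalty for the solver

    def eval_tr(TR, xatol=0.02):
        r = minimize_scalar(
            lambda a: neg_eta(TR, a),
            bounds=alpha_bounds, method="bounded", options={"xatol": xatol},
        )
        eta, d = _eta_ssfp_at(TR, r.x, beff_target, tissue, G, T_dead, T_acq_cap)
        return eta, float(r.x), d

    trs = np.arange(TR_range[0], TR_range[1] + 1e-9, TR_step)
    rows = []
    best = (-np.inf, None, None, None)  # eta, TR, alpha, delta
    for TR in trs:
        eta, a, d = eval_tr(TR)
        rows.append((TR, a, d, eta))
        if eta > best[0]:  # strict: ties keep the shorter TR
            best = (eta, TR, a, d)
    if best[1] is None or not np.isfinite(best[0]):
        raise ValueError(
            f"b_eff target {beff_target} s/mm^2 unreachable within TR range "
            f"{TR_range} with G = {G} mT/m and T_dead = {T_dead} ms"
        )
    # local refinement around the best coarse TR
    lo = max(TR_range[0], best[1] - TR_step)
    hi = min(TR_range[1], best[1] + TR_step)
    for TR in np.arange(lo, hi + 1e-9, TR_step / 5.0):
        eta, a, d = eval_tr(TR, xatol=5e-3)
        rows.append((TR, a, d, eta))
        if eta > best[0]:
            best = (eta, TR, a, d)

    eta, TR, alpha, delta = best
    proto = SSFPProtocol(TR=TR, alpha=alpha, delta=delta, G=G,
                         T_dead=T_dead, T_acq_cap=T_acq_cap)
    b_ach = beff_of(proto, tissue)
    converged = abs(b_ach - beff_target) / beff_target <= 1e-3
    S = ssfp_echo_ideal(TR, alpha, tissue.T1, tissue.T2)
    trace = None
    if keep_trace:
        trace = pd.DataFrame(rows, columns=["TR_ms", "alpha_deg", "delta_ms", "eta"])
    return OptimizationResult(
        protocol=proto, S=S, rho=proto.T_acq_effective / TR, eta=eta,
        b_achieved=b_ach, converged=converged,
        S_dw=dwssfp_signal(proto, tissue), search_trace=trace,
    )


def _eta_se(TR, TE, b, tissue, T_acq, T_dead, recovery_model, include_diff):
    min_tr = TE + T_acq / 2 + T_dead
    if TR < min_tr:
        return -np.inf
    proto = SEProtocol(TR=TR, TE=TE, alpha="optimal", T_acq=T_acq, T_dead=T_dead, b=b)
    S = dwse_signal(proto, tissue, include_diff, recovery_model)
    return snr_efficiency(S, T_acq, TR)


def optimize_dwse(
    b: float,
    tissue: TissueParams = FIXED_TISSUE,
    TE: Optional[float] = None,
    TR_range: Tuple[float, float] = (150.0, 3000.0),
    T_acq: float = 30.0,
    T_dead: float = 5.0,
    recovery_model: str = "ernst",
    include_diffusion_attenuation: bool = False,
    te_anchors=None,
) -> OptimizationResult:
    """Maximize DW-SE SNR efficiency over TR at fixed b.

    TE defaults to the minimum achievable echo time for this b from the anchor
    table; the flip angle is the Ernst angle of the recovery period TR - TE.
    """
    if TE is None:
        TE = min_te_dwse(b, anchors=te_anchors)
    tr_lo = max(TR_range[0], TE + T_acq / 2 + T_dead + 1e-6)
    tr_hi = TR_range[1]
    if tr_lo >= tr_hi:
        raise ValueError(
            f"TR range {TR_range} infeasible for TE={TE} (need TR >= "
            f"{TE + T_acq / 2 + T_dead})"
        )
    def obj(TR):
        eta = _eta_se(TR, TE, b, tissue, T_acq, T_dead,
                      recovery_model, include_diffusion_attenuation)
        return -eta if np.isfinite(eta) else 1e12
    # coarse bracket then bounded refinement (eta(TR) is unimodal)
    grid = np.linspace(tr_lo, tr_hi, 200)
    vals = [obj(tr) for tr in grid]
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    r = minimize_scalar(obj, bounds=(blo, bhi), method="bounded",
                        options={"xatol": 1e-4})
    TR = float(r.x) if -r.fun >= -min(vals) else float(grid[i])
    proto = SEProtocol(TR=TR, TE=TE, alpha="optimal", T_acq=T_acq, T_dead=T_dead, b=b)
    S = dwse_signal(proto, tissue, include_diffusion_attenuation, recovery_model)
    return OptimizationResult(
        protocol=proto, S=S, rho=T_acq / TR, eta=snr_efficiency(S, T_acq, TR),
        b_achieved=b, S_dw=S * float(np.exp(-b * tissue.D)),
    )


def required_tr_2d(n_slices: int, TE: float, T_acq: float = 30.0, T_dead: float = 5.0) -> float:
    """TR (ms) a 2D multi-slice DW-SE sequence needs for ``n_slices`` slices.

    Each slice occupies one excitation block of TE + T_acq/2 + T_dead.
    """
    if n_slices <= 0:
        raise ValueError(f"n_slices must be >= 1 (got {n_slices})")
    if TE <= 0 or T_acq <= 0 or T_dead <= 0:
        raise ValueError("TE, T_acq and T_dead must all be > 0")
    return n_slices * (TE + T_acq / 2 + T_dead)


def match_te_equal_efficiency(
    b: float,
    tissue: TissueParams = FIXED_TISSUE,
    te_bounds: Tuple[float, float] = (15.0, 300.0),
    ssfp_result: Optional[OptimizationResult] = None,
    **ssfp_kwargs,
) -> float:
    """Echo time at which TR-reoptimized DW-SE matches the DW-SSFP optimum.

    Root-finds TE such that ``optimize_dwse`` (TE overridden) equals the
    optimal DW-SSFP eta at the same b.  A pre-computed DW-SSFP optimum can be
    passed to avoid repeating the search.
    """
    if ssfp_result is None:
        ssfp_result = optimize_dwssfp(b, tissue, **ssfp_kwargs)
    eta_target = ssfp_result.eta

    def f(TE):
        return optimize_dwse(b, tissue, TE=TE).eta - eta_target

    lo, hi = te_bounds
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no TE in ({lo}, {hi}) ms matches the DW-SSFP efficiency "
            f"{eta_target:.3f} at b={b}"
        )
    return float(brentq(f, lo, hi, xtol=1e-3))


def efficiency_landscape(
    b_list: Sequence[float],
    T1_list: Sequence[float],
    T2_list: Sequence[float],
    D: float = 0.08e-3,
    ssfp_TR_step: float = 2.0,
    **kwargs,
) -> pd.DataFrame:
    """Optimized eta for both sequences over a (b, T1, T2) grid.

    Returns one row per cell with columns eta_se, eta_ssfp and their ratio.
    The DW-SSFP search uses a coarser TR grid than the single-protocol
    optimizer (the optimum is broad); pass ``ssfp_TR_step`` to refine.
    """
    rows = []
    for T1 in T1_list:
        for T2 in T2_list:
            tissue = TissueParams(T1=T1, T2=T2, D=D)
            for b in b_list:
                r_se = optimize_dwse(b, tissue)
                r_fp = optimize_dwssfp(b, tissue, TR_step=ssfp_TR_step, **kwargs)
                rows.append({
                    "b_s_mm2": b, "T1_ms": T1, "T2_ms": T2,
                    "eta_se": r_se.eta, "eta_ssfp": r_fp.eta,
                    "ratio_ssfp_se": r_fp.eta / r_se.eta,
                })
    return pd.DataFrame(rows)
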