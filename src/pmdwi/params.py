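"""Tissue parameters, sequence protocols and optimization results.

Pure data containers; constructors validate physical invariants and raise
``ValueError`` naming the violated bound.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Union

import numpy as np
import pandas as pd

from .constants import q_rad_per_mm

__all__ = [
    "TissueParams",
    "FIXED_TISSUE",
    "SEProtocol",
    "SSFPProtocol",
    "OptimizationResult",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and diffusion description of a voxel.

    T1, T2 in ms; D is the apparent diffusion coefficient in mm^2/s.
    The default preset is formalin-fixed white matter at room temperature,
    whose T2 (~45 ms), T1 (~400 ms) and ADC (~0.08e-3 mm^2/s) are all
    markedly reduced relative to in-vivo tissue.
    """

    T1: float = 400.0
    T2: float = 45.0
    D: float = 0.08e-3

    def __post_init__(self) -> None:
        if self.T1 <= 0:
            raise ValueError(f"T1 must be > 0 (got T1={self.T1})")
        if self.T2 <= 0:
            raise ValueError(f"T2 must be > 0 (got T2={self.T2})")
        if self.D < 0:
            raise ValueError(f"D must be >= 0 (got D={self.D})")
        if self.T2 > self.T1:
            raise ValueError(
                f"T2 must not exceed T1 (got T2={self.T2} > T1={self.T1})"
            )


#: Default fixed-tissue preset (T1/T2 = 400/45 ms, D = 0.08e-3 mm^2/s).
FIXED_TISSUE = TissueParams()


@dataclass(frozen=True)
class SEProtocol:
    """One diffusion-weighted spin-echo configuration.

    TR, TE, T_acq, T_dead in ms; alpha (excitation flip) in degrees or the
    string ``"optimal"`` for the Ernst angle of the recovery period; b is the
    nominal b-value in s/mm^2.
    """

    TR: float
    TE: float
    alpha: Union[float, str] = "optimal"
    T_acq: float = 30.0
    T_dead: float = 5.0
    b: float = 0.0
    T_acq_cap: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.TE < self.TR):
            raise ValueError(
                f"need 0 < TE < TR (got TE={self.TE}, TR={self.TR})"
            )
        if isinstance(self.alpha, str):
            if self.alpha != "optimal":
                raise ValueError(f"alpha must be degrees or 'optimal' (got {self.alpha!r})")
        elif not (0 < self.alpha <= 90):
            raise ValueError(f"need 0 < alpha <= 90 degrees (got alpha={self.alpha})")
        if self.b < 0:
            raise ValueError(f"b must be >= 0 (got b={self.b})")
        if self.T_acq <= 0 or self.T_acq > self.T_acq_cap:
            raise ValueError(
                f"need 0 < T_acq <= {self.T_acq_cap} ms cap (got T_acq={self.T_acq})"
            )
        min_tr = self.TE + self.T_acq / 2 + self.T_dead
        if self.TR < min_tr:
            raise ValueError(
                "TR below feasibility bound TE + T_acq/2 + T_dead "
                f"(TR={self.TR} < {min_tr})"
            )


@dataclass(frozen=True)
class SSFPProtocol:
    """One diffusion-weighted SSFP configuration.

    A single rectangular diffusion gradient lobe of duration ``delta`` (ms) and
    amplitude ``G`` (mT/m) is played every TR; the readout fills the remaining
    time, T_acq = TR - delta - T_dead.  The dephasing moment q = gamma*G*delta
    is always recomputed from the stored fields, never cached.
    """

    TR: float
    alpha: float
    delta: float
    G: float
    T_dead: float = 5.0
    T_acq_cap: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.TR):
            raise ValueError(
                f"need 0 < delta < TR (got delta={self.delta}, TR={self.TR})"
            )
        if not (0 < self.alpha <= 180):
            raise ValueError(f"need 0 < alpha <= 180 degrees (got alpha={self.alpha})")
        if self.G < 0:
            raise ValueError(f"G must be >= 0 (got G={self.G})")
        if self.T_dead < 0:
            raise ValueError(f"T_dead must be >= 0 (got T_dead={self.T_dead})")
        if self.T_acq <= 0:
            raise ValueError(
                "readout infeasible: T_acq = TR - delta - T_dead must be > 0 "
                f"(got {self.T_acq:.3f} ms)"
            )

    @property
    def T_acq(self) -> float:
        """Derived readout duration, ms (uncapped)."""
        return self.TR - self.delta - self.T_dead

    @property
    def T_acq_effective(self) -> float:
        """Readout duration actually usable, ms (capped at T_acq_cap)."""
        return min(self.T_acq, self.T_acq_cap)

    @property
    def q(self) -> float:
        """Lobe dephasing moment gamma*G*delta, rad/mm."""
        return q_rad_per_mm(self.G, self.delta)


@dataclass
class OptimizationResult:
    """A protocol together with its figures of merit.

    S is the steady-state signal as a *fraction* of M0 (the raw,
    non-diffusion-weighted amplitude used in the efficiency comparison;
    ``S_dw`` carries the diffusion-attenuated amplitude).  rho is the readout
    efficiency T_acq/TR; eta = 100*S*sqrt(rho) is the SNR efficiency on the
    percent-M0 scale; b_achieved is the (effective) b-value of the protocol.
    """

    protocol: Union[SEProtocol, SSFPProtocol]
    S: float
    rho: float
    eta: float
    b_achieved: float
    converged: bool = True
    S_dw: Optional[float] = None
    search_trace: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1] (got rho={self.rho})")
        expected = 100.0 * self.S * np.sqrt(self.rho)
        if self.eta > 0 and abs(self.eta - expected) > 1e-9 * max(self.eta, 1.0):
            raise ValueError(
                f"eta must equal S[%]*sqrt(rho) (eta={self.eta}, S*sqrt(rho)={expected})"
            )

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "search_trace"}
        d["protocol"] = asdict(self.protocol)
        d["sequence"] = "DW-SSFP" if isinstance(self.protocol, SSFPProtocol) else "DW-SE"
        return d
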