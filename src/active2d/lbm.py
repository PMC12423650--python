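"""D2Q9 lattice-Boltzmann solver for the (weakly compressible) flow.

BGK collision with a single relaxation time tau = 3 eta/rho + 1/2 and the
second-order Guo forcing scheme; the divergence of the passive+active
nematic stress enters as the body force.  The scheme realises the
Navier-Stokes momentum balance rho (d_t v + v.grad v) = d_j sigma_ij with
kinematic viscosity nu = eta/rho and speed of sound c_s = 1/sqrt(3);
incompressibility is approximate, so configurations should stay at small
Mach number (|v| << c_s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .core import StressFields
from .params import ModelParams

CX = kernels.CX
CY = kernels.CY
W = kernels.W
CS2 = kernels.CS2


@dataclass
class FlowState:
    """Distribution functions plus derived density and velocity fields.

    ``Fx``/``Fy`` hold the body force applied during the last collision;
    the velocity moment includes its half-step correction, as required by
    the forcing scheme.
    """

    f: np.ndarray
    rho_field: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray

    @classmethod
    def quiescent(cls, L: int, rho: float = 40.0) -> "FlowState":
        rho_field = np.full((L, L), float(rho))
        zero = np.zeros((L, L))
        f = kernels.equilibrium(rho_field, zero, zero)
        return cls(f, rho_field, zero.copy(), zero.copy(),
                   zero.copy(), zero.copy())

    @property
    def mass(self) -> float:
        return float(self.f.sum())

    def refresh_moments(self) -> None:
        self.rho_field, self.vx, self.vy = kernels.moments(
            self.f, self.Fx, self.Fy)


def equilibrium(rho_field: np.ndarray, vx: np.ndarray, vy: np.ndarray
                ) -> np.ndarray:
    """Second-order D2Q9 equilibrium, shape (9, L, L).

    Its moments reproduce rho, rho v and the ideal-gas momentum flux
    rho c_s^2 delta + rho v v exactly.
    """
    rho_field = np.ascontiguousarray(rho_field, dtype=np.float64)
    return kernels.equilibrium(
        rho_field,
        np.ascontiguousarray(vx, dtype=np.float64),
        np.ascontiguousarray(vy, dtype=np.float64))


def force_from_stress(sigma: StressFields):
    """Body force F_i = d_j sigma_ij by central differences."""
    return kernels.force_from_stress(
        sigma.sigma_xx, sigma.sigma_xy, sigma.sigma_yx, sigma.sigma_yy)


def lbm_step(state: FlowState, Fx: np.ndarray, Fy: np.ndarray,
             params: ModelParams) -> FlowState:
    """One BGK collision + streaming step under the given body force.

    The input state's moments are recomputed with the *new* force so that
    collision, source term and output velocity are mutually consistent
    (Guo scheme); one step from rest under constant F therefore changes
    the velocity by exactly F/rho per unit time.
    """
    tau = params.tau
    if tau <= 0.5:
        raise ValueError("relaxation time must exceed 1/2")
    Fx = np.ascontiguousarray(Fx, dtype=np.float64)
    Fy = np.ascontiguousarray(Fy, dtype=np.float64)
    rho, vx, vy = kernels.moments(state.f, Fx, Fy)
    if (rho <= 0).any():
        raise FloatingPointError("non-positive density in LB state")
    f = kernels.collide_stream(state.f, rho, vx, vy, Fx, Fy, tau)
    if not np.isfinite(f).all():
        raise FloatingPointError("LB update produced NaN/Inf")
    new = FlowState(f, rho, vx, vy, Fx, Fy)
    new.refresh_moments()
    return new
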