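"""Field containers and nemato-dynamic operations.

The tensor order parameter of a 2D nematic, Q_ij = 2q(n_i n_j - delta_ij/2),
is symmetric and traceless and therefore fully described by its two
independent components (Qxx, Qxy); tracelessness is exact by representation.
The operations here evaluate the free energy, the molecular field, the
co-rotation coupling to the flow, the polarity assignment that selects one
of the two director directions, the passive+active stress, and one explicit
step of the order-tensor evolution

    dQ/dt + (v + V0 p) . grad Q = Gamma H + S.

All spatial derivatives are second-order central differences on the
periodic lattice except the advection term, which is first-order upwind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .params import ModelParams


@dataclass
class NematicField:
    """Tensor order parameter: independent components on an (L, L) lattice."""

    Qxx: np.ndarray
    Qxy: np.ndarray

    def __post_init__(self) -> None:
        self.Qxx = np.ascontiguousarray(self.Qxx, dtype=np.float64)
        self.Qxy = np.ascontiguousarray(self.Qxy, dtype=np.float64)
        if self.Qxx.shape != self.Qxy.shape or self.Qxx.ndim != 2:
            raise ValueError("Qxx and Qxy must be 2D arrays of equal shape")

    @property
    def shape(self):
        return self.Qxx.shape

    def copy(self) -> "NematicField":
        return NematicField(self.Qxx.copy(), self.Qxy.copy())

    @classmethod
    def aligned(cls, L: int, q: float = 1.0, theta: float = 0.0
                ) -> "NematicField":
        """Uniform state with order magnitude q and director angle theta."""
        Qxx = np.full((L, L), q * np.cos(2 * theta))
        Qxy = np.full((L, L), q * np.sin(2 * theta))
        return cls(Qxx, Qxy)

    @classmethod
    def from_director(cls, q: np.ndarray, theta: np.ndarray) -> "NematicField":
        return cls(q * np.cos(2 * theta), q * np.sin(2 * theta))


@dataclass
class PolarityField:
    """Per-site unit vector equal to +n or -n (the flow-chosen direction)."""

    px: np.ndarray
    py: np.ndarray

    def __post_init__(self) -> None:
        self.px = np.ascontiguousarray(self.px, dtype=np.float64)
        self.py = np.ascontiguousarray(self.py, dtype=np.float64)


@dataclass
class StressFields:
    """Sum of passive and active stress (viscous stress lives in the LB)."""

    sigma_xx: np.ndarray
    sigma_xy: np.ndarray
    sigma_yx: np.ndarray
    sigma_yy: np.ndarray


def decompose(Q: NematicField):
    """Order magnitude q = sqrt(Qxx^2 + Qxy^2) and director angle theta.

    theta = atan2(Qxy, Qxx)/2, defined modulo pi; sites with q = 0 get
    theta = 0 by convention.  The inverse map is Qxx = q cos 2theta,
    Qxy = q sin 2theta.
    """
    if not (np.isfinite(Q.Qxx).all() and np.isfinite(Q.Qxy).all()):
        raise ValueError("non-finite order tensor")
    return kernels.qtheta(Q.Qxx, Q.Qxy)


def elastic_energy_density(Q: NematicField, K: float) -> np.ndarray:
    """Frank elastic energy density E = K/2 (d_k Q_ij)^2 (full ij sum)."""
    return kernels.elastic_energy(Q.Qxx, Q.Qxy, K)


def molecular_field(Q: NematicField, K: float, A: float) -> NematicField:
    """H = K lap Q + 4A(1 - Q:Q) Q, the negative variational derivative of

    F = int [ K/2 (d_k Q_ij)^2 + A (1 - Q_ij Q_ji)^2 ]

    restricted to symmetric traceless variations.  The bulk part vanishes
    at Q:Q = 1, i.e. order magnitude q = 1/sqrt(2).
    """
    Hxx, Hxy = kernels.molecular_field(Q.Qxx, Q.Qxy, K, A)
    return NematicField(Hxx, Hxy)


def corotation(Q: NematicField, vx: np.ndarray, vy: np.ndarray,
               lam: float) -> NematicField:
    """Co-rotational term S(Q, grad v); see :func:`kernels.corotation`."""
    Sxx, Sxy = kernels.corotation(
        Q.Qxx, Q.Qxy,
        np.ascontiguousarray(vx, dtype=np.float64),
        np.ascontiguousarray(vy, dtype=np.float64), lam)
    return NematicField(Sxx, Sxy)


def assign_polarity(Q: NematicField, vx: np.ndarray, vy: np.ndarray,
                    p_prev: PolarityField) -> PolarityField:
    """Polarity rule: p = sign(v . n) n, ties keep the previous sign."""
    px, py = kernels.assign_polarity(
        Q.Qxx, Q.Qxy,
        np.ascontiguousarray(vx, dtype=np.float64),
        np.ascontiguousarray(vy, dtype=np.float64),
        p_prev.px, p_prev.py)
    return PolarityField(px, py)


def initial_polarity(Q: NematicField) -> PolarityField:
    """+n of the given field (the convention for the first step)."""
    q, theta = kernels.qtheta(Q.Qxx, Q.Qxy)
    return PolarityField(np.cos(theta), np.sin(theta))


def assemble_stress(Q: NematicField, H: NematicField, lam: float,
                    zeta: float, K: float) -> StressFields:
    """Passive + active stress.

    The isotropic pressure -P delta_ij is *not* included: the LB equation
    of state carries it, and adding both would double-count.  The
    antisymmetric part (QH - HQ) and the Ericksen term
    -K d_iQ_kl d_jQ_kl are included; the active part is -zeta Q.
    """
    sxx, sxy, syx, syy = kernels.stress(
        Q.Qxx, Q.Qxy, H.Qxx, H.Qxy, K, lam, zeta)
    return StressFields(sxx, sxy, syx, syy)


def beris_edwards_step(Q: NematicField, vx: np.ndarray, vy: np.ndarray,
                       p: PolarityField, params: ModelParams,
                       dt: float | None = None) -> NematicField:
    """One explicit Euler step of the order-tensor evolution.

    Raises on NaN/Inf in the result (blow-up detection).  The advecting
    velocity v + V0 p should satisfy (max|v| + V0) dt < 1.
    """
    if dt is None:
        dt = params.dt
    Qxx, Qxy = kernels.be_step(
        Q.Qxx, Q.Qxy,
        np.ascontiguousarray(vx, dtype=np.float64),
        np.ascontiguousarray(vy, dtype=np.float64),
        p.px, p.py, params.Gamma, params.K, params.A, params.lam,
        params.V0, dt)
    if not (np.isfinite(Qxx).all() and np.isfinite(Qxy).all()):
        raise FloatingPointError("order-tensor update produced NaN/Inf")
    return NematicField(Qxx, Qxy)
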