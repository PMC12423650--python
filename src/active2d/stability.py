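"""Linear stability of the aligned nematic state.

The coupled equations are linearised about the uniform state
(Qxx, Qxy, omega) = (1, 0, 0) with polarity p = (+1, 0), for perturbations
exp(i q (n x + m y)) with q = 2 pi / L the shortest wavevector of the box.
Incompressibility ties the velocity to the vorticity, so the dynamical
variables reduce to (dQxx, dQxy, domega) and the linearised dynamics is a
3x3 complex Jacobian per mode.  The self-advection contributes the purely
propagative term -i kx V0 to both tensor rows; V0 stabilises the system by
de-phasing the order tensor from the flow response it generates.

With the bulk coefficient A = 0 the aligned state is an exact steady state
for any order magnitude, and the (1,0)-mode eigenvalues reduce to the
classical active-nematic dispersion relation extended by self-propulsion:

    Lambda_10 = q/2 [ -q(Gamma K + eta/rho) - i V0
                      +- sqrt( q^2(Gamma K - eta/rho)^2
                               + 2 i q V0 (Gamma K - eta/rho) - V0^2
                               + 2(2+lam)/rho (zeta - q^2 K (2+lam)) ) ].

With A > 0 the same base state is linearised verbatim (it is then not a
stationary point of the free energy; the Jacobian is the mathematical
derivative of the right-hand side) and the closed forms below carry the
corresponding bulk contributions, reducing to the expression above at A=0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams


@dataclass(frozen=True)
class ModeSpec:
    """Perturbation mode indices (n, m) on the periodic box."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n == 0 and self.m == 0:
            raise ValueError("(0, 0) is not a perturbation mode")

    def wavevector(self, L: int):
        q = 2.0 * np.pi / L
        return q * self.n, q * self.m


@dataclass
class StabilityResult:
    eigenvalues: np.ndarray
    max_growth_rate: float
    stable: bool
    V0_star: float | None = None


def jacobian(mode: ModeSpec, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian on (dQxx, dQxy, domega) for the given mode."""
    kx, ky = mode.wavevector(params.L)
    k2 = kx * kx + ky * ky
    K, A, lam, zeta = params.K, params.A, params.lam, params.zeta
    Gamma, rho, V0 = params.Gamma, params.rho, params.V0
    nu = params.nu

    J = np.zeros((3, 3), dtype=complex)
    adv = -1j * kx * V0
    # order-tensor rows: self-advection + relaxation + flow coupling
    J[0, 0] = adv - Gamma * (K * k2 + 20.0 * A)
    J[0, 2] = 3.0 * lam * kx * ky / k2
    J[1, 1] = adv - Gamma * (K * k2 + 4.0 * A)
    J[1, 2] = 0.5 * lam * (kx * kx - ky * ky) / k2 + 1.0
    # vorticity row: curl of the stress divergence plus viscous diffusion
    c_xx = -lam * (3.0 * K * k2 + 92.0 * A) - zeta   # sym sigma_xx per dQxx
    c_xy = lam * K * k2 - 12.0 * lam * A - zeta      # sym sigma_xy per dQxy
    c_anti = -2.0 * K * k2                           # antisym part per dQxy
    J[2, 0] = 2.0 * kx * ky * c_xx / rho
    J[2, 1] = (-(kx * kx - ky * ky) * c_xy + k2 * c_anti) / rho
    J[2, 2] = -nu * k2
    return J


def eigenvalues(mode: ModeSpec, params: ModelParams) -> np.ndarray:
    return np.linalg.eigvals(jacobian(mode, params))


def analyze_mode(mode: ModeSpec, params: ModelParams) -> StabilityResult:
    ev = eigenvalues(mode, params)
    rate = float(ev.real.max())
    return StabilityResult(ev, rate, rate < 0.0)


def lambda_10(params: ModelParams) -> np.ndarray:
    """Closed-form eigenvalue pair of the coupled (dQxy, domega) block at
    mode (1, 0); matches the Jacobian eigenvalues to rounding error and
    reduces to the classical dispersion relation at A = 0."""
    q = params.q_min
    q2 = q * q
    K, A, lam, zeta = params.K, params.A, params.lam, params.zeta
    j11 = -1j * q * params.V0 - params.Gamma * (K * q2 + 4.0 * A)
    j12 = 0.5 * (2.0 + lam)
    j21 = (q2 / params.rho) * (zeta + 12.0 * lam * A - (2.0 + lam) * K * q2)
    j22 = -params.nu * q2
    half_tr = 0.5 * (j11 + j22)
    disc = 0.25 * (j11 - j22) ** 2 + j12 * j21
    root = np.sqrt(disc + 0j)
    return np.array([half_tr + root, half_tr - root])


def critical_v0_closed_form(params: ModelParams) -> float:
    """Printed closed form of the suppression threshold (A = 0):

    V0* = (Gamma K + eta/rho) sqrt( (2+lam)(zeta - q^2 K (2+lam))
                                    / (2 Gamma K eta) - q^2 ).

    Returns 0 when the bracket is non-positive (already stable at V0=0).
    """
    q2 = params.q_min ** 2
    GK = params.Gamma * params.K
    bracket = ((2.0 + params.lam)
               * (params.zeta - q2 * params.K * (2.0 + params.lam))
               / (2.0 * GK * params.eta)) - q2
    if bracket <= 0.0:
        return 0.0
    return (GK + params.nu) * float(np.sqrt(bracket))


def _max_growth_10(params: ModelParams, V0: float) -> float:
    p = params.replace(V0=V0)
    return float(eigenvalues(ModeSpec(1, 0), p).real.max())


def critical_v0(params: ModelParams, v_max: float = 1.0,
                tol: float = 1e-10) -> float:
    """Self-propulsion threshold V0* of the (1, 0) mode.

    Root of max Re(eig(J_10))(V0) = 0 by bisection on [0, v_max]; returns 0
    when the mode is already stable at V0 = 0 and raises if no root exists
    in the bracket.
    """
    if _max_growth_10(params, 0.0) <= 0.0:
        return 0.0
    if _max_growth_10(params, v_max) >= 0.0:
        raise ValueError(f"no stability crossing in [0, {v_max}]")
    lo, hi = 0.0, v_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _max_growth_10(params, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def all_modes(max_index: int = 2):
    out = []
    for n in range(-max_index, max_index + 1):
        for m in range(-max_index, max_index + 1):
            if (n, m) != (0, 0):
                out.append(ModeSpec(n, m))
    return out


def is_stable(params: ModelParams, max_index: int = 2) -> bool:
    return all(analyze_mode(mode, params).stable
               for mode in all_modes(max_index))


def max_growth_rate(params: ModelParams, max_index: int = 2):
    """(rate, mode) of the fastest-growing mode among |n|,|m| <= max_index."""
    best = None
    for mode in all_modes(max_index):
        r = analyze_mode(mode, params).max_growth_rate
        if best is None or r > best[0]:
            best = (r, mode)
    return best


def phase_diagram(v0_grid, zeta_grid, params: ModelParams,
                  max_index: int = 2):
    """Stability map over a (V0, zeta) grid plus the V0*(zeta) curve.

    Returns a pandas DataFrame with columns (V0, zeta, re_lambda_max,
    stable) and a dict zeta -> V0*.
    """
    import pandas as pd

    rows = []
    for zeta in zeta_grid:
        for v0 in v0_grid:
            p = params.replace(V0=float(v0), zeta=float(zeta))
            rate, _ = max_growth_rate(p, max_index)
            rows.append({"V0": float(v0), "zeta": float(zeta),
                         "re_lambda_max": rate, "stable": rate < 0.0})
    curve = {float(z): critical_v0(params.replace(zeta=float(z)))
             for z in zeta_grid}
    return pd.DataFrame(rows), curve


def timescales(params: ModelParams):
    """(tau_Q, tau_v) = (Gamma K / V0^2, eta / zeta)."""
    if params.V0 == 0.0 or params.zeta == 0.0:
        raise ZeroDivisionError("timescales need V0 > 0 and zeta > 0")
    return (params.Gamma * params.K / params.V0 ** 2,
            params.eta / params.zeta)


# -- independent numerical linearisation ----------------------------------


def _spectral_rhs(Qxx, Qxy, omega, params: ModelParams):
    """Nonlinear continuum right-hand side, pseudo-spectrally, on the
    periodic box of physical size params.L.

    Independent of the lattice solver: derivatives are exact Fourier
    derivatives and the flow is exactly incompressible (velocity recovered
    from the vorticity through the streamfunction).  The polarity is taken
    on the +n branch, the branch the aligned-state analysis lives on.
    """
    N = Qxx.shape[0]
    Lbox = params.L
    k1 = 2.0 * np.pi * np.fft.fftfreq(N, d=Lbox / N)
    kx = k1[:, None]
    ky = k1[None, :]
    k2 = kx ** 2 + ky ** 2
    k2_safe = np.where(k2 == 0.0, 1.0, k2)

    def dx(f):
        return np.real(np.fft.ifft2(1j * kx * np.fft.fft2(f)))

    def dy(f):
        return np.real(np.fft.ifft2(1j * ky * np.fft.fft2(f)))

    def lap(f):
        return np.real(np.fft.ifft2(-k2 * np.fft.fft2(f)))

    # velocity from vorticity: omega = -lap(psi), v = (dy psi, -dx psi)
    what = np.fft.fft2(omega)
    psih = np.where(k2 == 0.0, 0.0, what / k2_safe)
    vx = np.real(np.fft.ifft2(1j * ky * psih))
    vy = np.real(np.fft.ifft2(-1j * kx * psih))

    K, A, lam, zeta = params.K, params.A, params.lam, params.zeta

    trq2 = 2.0 * (Qxx ** 2 + Qxy ** 2)
    Hxx = K * lap(Qxx) + 4.0 * A * (1.0 - trq2) * Qxx
    Hxy = K * lap(Qxy) + 4.0 * A * (1.0 - trq2) * Qxy

    dxvx, dyvx = dx(vx), dy(vx)
    dxvy, dyvy = dx(vy), dy(vy)
    exx = dxvx
    exy = 0.5 * (dxvy + dyvx)
    om_t = 0.5 * (dyvx - dxvy)  # vorticity tensor xy component
    g = Qxx * (dxvx - dyvy) + Qxy * (dxvy + dyvx)

    txx = Qxx + 0.5
    tyy = -Qxx + 0.5
    txy = Qxy
    m1xx, m1yy = lam * exx, lam * dyvy
    m1xy, m1yx = lam * exy + om_t, lam * exy - om_t
    m2xy, m2yx = lam * exy - om_t, lam * exy + om_t
    sxx = m1xx * txx + m1xy * txy + txx * m1xx + txy * m2yx \
        - 2.0 * lam * txx * g
    syy = m1yx * txy + m1yy * tyy + txy * m2xy + tyy * m1yy \
        - 2.0 * lam * tyy * g
    sxy = m1xx * txy + m1xy * tyy + txx * m2xy + txy * m1yy \
        - 2.0 * lam * txy * g
    S_xx = 0.5 * (sxx - syy)
    S_xy = sxy

    theta = 0.5 * np.arctan2(Qxy, Qxx)
    pxn = np.cos(theta)
    pyn = np.sin(theta)
    ax = vx + params.V0 * pxn
    ay = vy + params.V0 * pyn
    rhs_Qxx = -(ax * dx(Qxx) + ay * dy(Qxx)) + params.Gamma * Hxx + S_xx
    rhs_Qxy = -(ax * dx(Qxy) + ay * dy(Qxy)) + params.Gamma * Hxy + S_xy

    qh = 2.0 * (Qxx * Hxx + Qxy * Hxy)
    dxQxx, dyQxx = dx(Qxx), dy(Qxx)
    dxQxy, dyQxy = dx(Qxy), dy(Qxy)
    sig_xx = 2.0 * lam * qh * Qxx - lam * Hxx \
        - 2.0 * K * (dxQxx ** 2 + dxQxy ** 2) - zeta * Qxx
    sig_yy = -2.0 * lam * qh * Qxx + lam * Hxx \
        - 2.0 * K * (dyQxx ** 2 + dyQxy ** 2) + zeta * Qxx
    sym_xy = 2.0 * lam * qh * Qxy - lam * Hxy \
        - 2.0 * K * (dxQxx * dyQxx + dxQxy * dyQxy) - zeta * Qxy
    anti = 2.0 * (Qxx * Hxy - Qxy * Hxx)
    sig_xy = sym_xy + anti
    sig_yx = sym_xy - anti

    div_x = dx(sig_xx) + dy(sig_xy)
    div_y = dx(sig_yx) + dy(sig_yy)
    rhs_omega = (dx(div_y) - dy(div_x)) / params.rho \
        - (vx * dx(omega) + vy * dy(omega)) + params.nu * lap(omega)
    return rhs_Qxx, rhs_Qxy, rhs_omega


def numerical_jacobian(mode: ModeSpec, params: ModelParams, N: int = 16,
                       eps: float = 1e-5) -> np.ndarray:
    """Directional-derivative linearisation of the nonlinear right-hand
    side about the aligned state, as an independent check of
    :func:`jacobian`.

    Each column perturbs one of (Qxx, Qxy, omega) by eps*cos(k.x) on an
    N x N collocation grid, evaluates the full nonlinear right-hand side
    pseudo-spectrally, central-differences in eps, and projects the result
    back on the mode.
    """
    n_idx = mode.n % N
    m_idx = mode.m % N
    x = np.arange(N) * (params.L / N)
    X, Y = np.meshgrid(x, x, indexing="ij")
    q = 2.0 * np.pi / params.L
    wave = np.cos(q * (mode.n * X + mode.m * Y))

    base = (np.ones((N, N)), np.zeros((N, N)), np.zeros((N, N)))
    J = np.zeros((3, 3), dtype=complex)
    for col in range(3):
        plus = [b.copy() for b in base]
        minus = [b.copy() for b in base]
        plus[col] += eps * wave
        minus[col] -= eps * wave
        rp = _spectral_rhs(*plus, params)
        rm = _spectral_rhs(*minus, params)
        for row in range(3):
            diff = (rp[row] - rm[row]) / (2.0 * eps)
            J[row, col] = np.fft.fft2(diff)[n_idx, m_idx] * 2.0 / N ** 2
    return J
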