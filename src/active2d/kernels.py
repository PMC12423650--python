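"""Numba-compiled stencil kernels shared by the field operations and the driver.

Every kernel works on C-contiguous float64 arrays of shape (L, L) indexed
``[x, y]`` with fully periodic wrap-around.  Spatial derivatives are
second-order central differences; the advection of the order tensor is
first-order upwind (the hyperbolic part dominates stability at the speeds
used here).  The public modules :mod:`active2d.core` and :mod:`active2d.lbm`
wrap these kernels with validation and documentation; the simulation driver
calls them directly so that the tested operations and the production loop
are the same code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# D2Q9 velocity set and weights.  Index order: rest, +x, +y, -x, -y,
# (+x,+y), (-x,+y), (-x,-y), (+x,-y).
CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
W = np.array(
    [4.0 / 9.0] + [1.0 / 9.0] * 4 + [1.0 / 36.0] * 4, dtype=np.float64
)

CS2 = 1.0 / 3.0  # lattice speed of sound squared

# Tie tolerance for the polarity rule: |v.n| below TIE_EPS*|v| (or |v| below
# TIE_EPS) keeps the previous polarity sign.
TIE_EPS = 1e-12


@njit(cache=True)
def qtheta(Qxx, Qxy):
    """Order magnitude q and director angle theta (mod pi) per site."""
    L0, L1 = Qxx.shape
    q = np.empty_like(Qxx)
    theta = np.empty_like(Qxx)
    for i in range(L0):
        for j in range(L1):
            q[i, j] = np.sqrt(Qxx[i, j] ** 2 + Qxy[i, j] ** 2)
            if q[i, j] == 0.0:
                theta[i, j] = 0.0
            else:
                theta[i, j] = 0.5 * np.arctan2(Qxy[i, j], Qxx[i, j])
    return q, theta


@njit(cache=True)
def molecular_field(Qxx, Qxy, K, A):
    """H_ij = K lap(Q_ij) + 4A(1 - Q:Q) Q_ij with Q:Q = 2(Qxx^2 + Qxy^2)."""
    L0, L1 = Qxx.shape
    Hxx = np.empty_like(Qxx)
    Hxy = np.empty_like(Qxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            lap_xx = (Qxx[ip, j] + Qxx[im, j] + Qxx[i, jp] + Qxx[i, jm]
                      - 4.0 * Qxx[i, j])
            lap_xy = (Qxy[ip, j] + Qxy[im, j] + Qxy[i, jp] + Qxy[i, jm]
                      - 4.0 * Qxy[i, j])
            trq2 = 2.0 * (Qxx[i, j] ** 2 + Qxy[i, j] ** 2)
            bulk = 4.0 * A * (1.0 - trq2)
            Hxx[i, j] = K * lap_xx + bulk * Qxx[i, j]
            Hxy[i, j] = K * lap_xy + bulk * Qxy[i, j]
    return Hxx, Hxy


@njit(cache=True)
def elastic_energy(Qxx, Qxy, K):
    """E = K/2 (d_k Q_ij)^2 summed over i,j,k (Qyy=-Qxx, Qyx=Qxy implied)."""
    L0, L1 = Qxx.shape
    E = np.empty_like(Qxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            dxQxx = 0.5 * (Qxx[ip, j] - Qxx[im, j])
            dyQxx = 0.5 * (Qxx[i, jp] - Qxx[i, jm])
            dxQxy = 0.5 * (Qxy[ip, j] - Qxy[im, j])
            dyQxy = 0.5 * (Qxy[i, jp] - Qxy[i, jm])
            # xx and yy components each contribute (dQxx)^2, xy and yx each
            # (dQxy)^2, so K/2 * 2 * (...) = K * (...).
            E[i, j] = K * (dxQxx ** 2 + dyQxx ** 2 + dxQxy ** 2 + dyQxy ** 2)
    return E


@njit(cache=True)
def corotation(Qxx, Qxy, vx, vy, lam):
    """Co-rotational coupling S of the order tensor to the flow gradients.

    S = (lam*E + Om)(Q + I/2) + (Q + I/2)(lam*E - Om)
        - 2*lam*(Q + I/2) * (Q_kl d_k v_l)

    with E the strain rate and Om_ij = (d_j v_i - d_i v_j)/2.  Returns the
    traceless-symmetric components (Sxx, Sxy), i.e. (S_xx - S_yy)/2 and
    (S_xy + S_yx)/2; the discrete trace (lam * div v) is projected out so
    the updated tensor stays exactly traceless.
    """
    L0, L1 = Qxx.shape
    Sxx = np.empty_like(Qxx)
    Sxy = np.empty_like(Qxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            dxvx = 0.5 * (vx[ip, j] - vx[im, j])
            dyvx = 0.5 * (vx[i, jp] - vx[i, jm])
            dxvy = 0.5 * (vy[ip, j] - vy[im, j])
            dyvy = 0.5 * (vy[i, jp] - vy[i, jm])

            exx = dxvx
            eyy = dyvy
            exy = 0.5 * (dxvy + dyvx)
            om = 0.5 * (dyvx - dxvy)  # Om_xy

            a = Qxx[i, j]
            b = Qxy[i, j]
            # Qtilde = Q + I/2
            txx = a + 0.5
            tyy = -a + 0.5
            txy = b

            # M1 = lam*E + Om, M2 = lam*E - Om
            m1xx = lam * exx
            m1yy = lam * eyy
            m1xy = lam * exy + om
            m1yx = lam * exy - om
            m2xx = lam * exx
            m2yy = lam * eyy
            m2xy = lam * exy - om
            m2yx = lam * exy + om

            g = a * (dxvx - dyvy) + b * (dxvy + dyvx)  # Q_kl d_k v_l

            sxx = (m1xx * txx + m1xy * txy + txx * m2xx + txy * m2yx
                   - 2.0 * lam * txx * g)
            syy = (m1yx * txy + m1yy * tyy + txy * m2xy + tyy * m2yy
                   - 2.0 * lam * tyy * g)
            sxy = (m1xx * txy + m1xy * tyy + txx * m2xy + txy * m2yy
                   - 2.0 * lam * txy * g)
            Sxx[i, j] = 0.5 * (sxx - syy)
            Sxy[i, j] = sxy
    return Sxx, Sxy


@njit(cache=True)
def assign_polarity(Qxx, Qxy, vx, vy, px_prev, py_prev):
    """Pick the director direction closest to the local flow.

    p = +n if v.n > 0, -n if v.n < 0.  Ties (|v.n| below tolerance, or
    vanishing flow) keep the sign of the previous polarity projected on n,
    which avoids sign chattering where the flow is perpendicular to the
    director or the site sits at a defect core.
    """
    L0, L1 = Qxx.shape
    px = np.empty_like(Qxx)
    py = np.empty_like(Qxx)
    for i in range(L0):
        for j in range(L1):
            q = np.sqrt(Qxx[i, j] ** 2 + Qxy[i, j] ** 2)
            if q == 0.0:
                th = 0.0
            else:
                th = 0.5 * np.arctan2(Qxy[i, j], Qxx[i, j])
            nx = np.cos(th)
            ny = np.sin(th)
            vdotn = vx[i, j] * nx + vy[i, j] * ny
            vnorm = np.sqrt(vx[i, j] ** 2 + vy[i, j] ** 2)
            if vnorm < TIE_EPS or np.abs(vdotn) < TIE_EPS * vnorm:
                s = px_prev[i, j] * nx + py_prev[i, j] * ny
                sign = 1.0 if s >= 0.0 else -1.0
            else:
                sign = 1.0 if vdotn > 0.0 else -1.0
            px[i, j] = sign * nx
            py[i, j] = sign * ny
    return px, py


@njit(cache=True)
def stress(Qxx, Qxy, Hxx, Hxy, K, lam, zeta):
    """Passive + active stress (pressure excluded; viscous lives in the LB).

    sigma = 2*lam*(Q:H)*Q - lam*H                (flow-alignment part; the
                                                  isotropic pieces of the
                                                  printed expression cancel
                                                  exactly in 2D)
            - K * d_i Q_kl d_j Q_kl              (Ericksen/elastic)
            + (QH - HQ)                          (antisymmetric torque)
            - zeta * Q                           (dipolar activity)
    """
    L0, L1 = Qxx.shape
    sxx = np.empty_like(Qxx)
    sxy = np.empty_like(Qxx)
    syx = np.empty_like(Qxx)
    syy = np.empty_like(Qxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            a = Qxx[i, j]
            b = Qxy[i, j]
            h = Hxx[i, j]
            g = Hxy[i, j]
            qh = 2.0 * (a * h + b * g)  # Q:H

            dxQxx = 0.5 * (Qxx[ip, j] - Qxx[im, j])
            dyQxx = 0.5 * (Qxx[i, jp] - Qxx[i, jm])
            dxQxy = 0.5 * (Qxy[ip, j] - Qxy[im, j])
            dyQxy = 0.5 * (Qxy[i, jp] - Qxy[i, jm])

            # Ericksen term: -K d_iQ_kl d_jQ_kl; the kl sum doubles both
            # independent components.
            e_xx = -2.0 * K * (dxQxx * dxQxx + dxQxy * dxQxy)
            e_yy = -2.0 * K * (dyQxx * dyQxx + dyQxy * dyQxy)
            e_xy = -2.0 * K * (dxQxx * dyQxx + dxQxy * dyQxy)

            anti = 2.0 * (a * g - b * h)  # (QH - HQ)_xy

            sxx[i, j] = 2.0 * lam * qh * a - lam * h + e_xx - zeta * a
            syy[i, j] = -2.0 * lam * qh * a + lam * h + e_yy + zeta * a
            sym_xy = 2.0 * lam * qh * b - lam * g + e_xy - zeta * b
            sxy[i, j] = sym_xy + anti
            syx[i, j] = sym_xy - anti
    return sxx, sxy, syx, syy


@njit(cache=True)
def force_from_stress(sxx, sxy, syx, syy):
    """Body force F_i = d_j sigma_ij by central differences."""
    L0, L1 = sxx.shape
    Fx = np.empty_like(sxx)
    Fy = np.empty_like(sxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            Fx[i, j] = (0.5 * (sxx[ip, j] - sxx[im, j])
                        + 0.5 * (sxy[i, jp] - sxy[i, jm]))
            Fy[i, j] = (0.5 * (syx[ip, j] - syx[im, j])
                        + 0.5 * (syy[i, jp] - syy[i, jm]))
    return Fx, Fy


@njit(cache=True)
def be_step(Qxx, Qxy, vx, vy, px, py, Gamma, K, A, lam, V0, dt):
    """One explicit Euler step of the order-tensor evolution.

    dQ/dt = -(v + V0 p) . grad Q + Gamma*H + S, with first-order upwind
    advection and central differences in H and S.
    """
    Hxx, Hxy = molecular_field(Qxx, Qxy, K, A)
    Sxx, Sxy = corotation(Qxx, Qxy, vx, vy, lam)
    L0, L1 = Qxx.shape
    Qxx_new = np.empty_like(Qxx)
    Qxy_new = np.empty_like(Qxx)
    for i in range(L0):
        ip = i + 1 if i + 1 < L0 else 0
        im = i - 1 if i - 1 >= 0 else L0 - 1
        for j in range(L1):
            jp = j + 1 if j + 1 < L1 else 0
            jm = j - 1 if j - 1 >= 0 else L1 - 1
            ax = vx[i, j] + V0 * px[i, j]
            ay = vy[i, j] + V0 * py[i, j]
            if ax > 0.0:
                dxQxx = Qxx[i, j] - Qxx[im, j]
                dxQxy = Qxy[i, j] - Qxy[im, j]
            else:
                dxQxx = Qxx[ip, j] - Qxx[i, j]
                dxQxy = Qxy[ip, j] - Qxy[i, j]
            if ay > 0.0:
                dyQxx = Qxx[i, j] - Qxx[i, jm]
                dyQxy = Qxy[i, j] - Qxy[i, jm]
            else:
                dyQxx = Qxx[i, jp] - Qxx[i, j]
                dyQxy = Qxy[i, jp] - Qxy[i, j]
            adv_xx = ax * dxQxx + ay * dyQxx
            adv_xy = ax * dxQxy + ay * dyQxy
            Qxx_new[i, j] = Qxx[i, j] + dt * (
                -adv_xx + Gamma * Hxx[i, j] + Sxx[i, j])
            Qxy_new[i, j] = Qxy[i, j] + dt * (
                -adv_xy + Gamma * Hxy[i, j] + Sxy[i, j])
    return Qxx_new, Qxy_new


@njit(cache=True)
def equilibrium(rho, vx, vy):
    """Second-order D2Q9 equilibrium distributions, shape (9, L, L)."""
    L0, L1 = rho.shape
    feq = np.empty((9, L0, L1))
    for k in range(9):
        cx = CX[k]
        cy = CY[k]
        w = W[k]
        for i in range(L0):
            for j in range(L1):
                cu = cx * vx[i, j] + cy * vy[i, j]
                usq = vx[i, j] ** 2 + vy[i, j] ** 2
                feq[k, i, j] = w * rho[i, j] * (
                    1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
    return feq


@njit(cache=True)
def moments(f, Fx, Fy):
    """Density and force-corrected velocity: rho*v = sum_k f_k c_k + F/2."""
    L0, L1 = f.shape[1], f.shape[2]
    rho = np.zeros((L0, L1))
    vx = np.zeros((L0, L1))
    vy = np.zeros((L0, L1))
    for k in range(9):
        cx = float(CX[k])
        cy = float(CY[k])
        for i in range(L0):
            for j in range(L1):
                rho[i, j] += f[k, i, j]
                vx[i, j] += cx * f[k, i, j]
                vy[i, j] += cy * f[k, i, j]
    for i in range(L0):
        for j in range(L1):
            vx[i, j] = (vx[i, j] + 0.5 * Fx[i, j]) / rho[i, j]
            vy[i, j] = (vy[i, j] + 0.5 * Fy[i, j]) / rho[i, j]
    return rho, vx, vy


@njit(cache=True)
def collide_stream(f, rho, vx, vy, Fx, Fy, tau):
    """BGK collision with Guo forcing followed by periodic streaming.

    The velocity passed in must already contain the half-force correction
    (see :func:`moments`); the forcing source term then reproduces the
    macroscopic body force to second order.
    """
    L0, L1 = f.shape[1], f.shape[2]
    fnew = np.empty_like(f)
    pref = 1.0 - 0.5 / tau
    for k in range(9):
        cx = float(CX[k])
        cy = float(CY[k])
        w = W[k]
        icx = CX[k]
        icy = CY[k]
        for i in range(L0):
            for j in range(L1):
                u_x = vx[i, j]
                u_y = vy[i, j]
                cu = cx * u_x + cy * u_y
                usq = u_x * u_x + u_y * u_y
                feq = w * rho[i, j] * (1.0 + 3.0 * cu + 4.5 * cu * cu
                                       - 1.5 * usq)
                # Guo source: w_k [3(c-u) + 9(c.u)c] . F
                sx = 3.0 * (cx - u_x) + 9.0 * cu * cx
                sy = 3.0 * (cy - u_y) + 9.0 * cu * cy
                src = pref * w * (sx * Fx[i, j] + sy * Fy[i, j])
                post = f[k, i, j] - (f[k, i, j] - feq) / tau + src
                ii = i + icx
                if ii >= L0:
                    ii -= L0
                elif ii < 0:
                    ii += L0
                jj = j + icy
                if jj >= L1:
                    jj -= L1
                elif jj < 0:
                    jj += L1
                fnew[k, ii, jj] = post
    return fnew


@njit(cache=True)
def coupled_step(f, Qxx, Qxy, px, py, Fx, Fy,
                 rho0, eta, lam, Gamma, K, A, zeta, V0, dt):
    """One full step of the hybrid solver.  Order per step:

    1. moments of f (velocity uses the force applied at the previous step),
    2. polarity assignment from the current (Q, v),
    3. order-tensor update,
    4. molecular field and stress of the updated tensor, new body force,
    5. LB collision + streaming driven by that force.

    Returns the updated (f, Qxx, Qxy, px, py, Fx, Fy, rho, vx, vy).
    """
    tau = 3.0 * eta / rho0 + 0.5
    rho, vx, vy = moments(f, Fx, Fy)
    px, py = assign_polarity(Qxx, Qxy, vx, vy, px, py)
    Qxx, Qxy = be_step(Qxx, Qxy, vx, vy, px, py, Gamma, K, A, lam, V0, dt)
    Hxx, Hxy = molecular_field(Qxx, Qxy, K, A)
    sxx, sxy, syx, syy = stress(Qxx, Qxy, Hxx, Hxy, K, lam, zeta)
    FxN, FyN = force_from_stress(sxx, sxy, syx, syy)
    # The collision's velocity must carry the half correction of the force
    # applied in *this* collision; vx/vy above carried the previous one.
    L0, L1 = rho.shape
    vxc = np.empty_like(rho)
    vyc = np.empty_like(rho)
    for i in range(L0):
        for j in range(L1):
            vxc[i, j] = vx[i, j] + 0.5 * (FxN[i, j] - Fx[i, j]) / rho[i, j]
            vyc[i, j] = vy[i, j] + 0.5 * (FyN[i, j] - Fy[i, j]) / rho[i, j]
    f = collide_stream(f, rho, vxc, vyc, FxN, FyN, tau)
    return f, Qxx, Qxy, px, py, FxN, FyN, rho, vx, vy
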