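"""Deterministic synthetic generators for tests and examples.

Three families: nematic textures with prescribed +-1/2 defects, point
processes with known hyperuniformity class (for the structure-factor and
number-variance estimators), and divergence-free velocity fields with
prescribed spectra or anisotropy (for the spectral estimators).  All
generators are bit-reproducible from their arguments and seed.
"""

from __future__ import annotations

import numpy as np

from .core import NematicField

Q_BULK = 1.0 / np.sqrt(2.0)


# -- defect textures -------------------------------------------------------


def make_defect_texture(kind: str, L: int, separation: float = 20.0,
                        q_bulk: float = Q_BULK) -> NematicField:
    """Nematic texture with prescribed defects on an L x L patch.

    kind='single_plus' / 'single_minus': one +-1/2 defect at the centre
    (net charge: open-boundary patch, detect with periodic=False).
    kind='pair': a +1/2 and a -1/2 defect a distance ``separation`` apart
    along x, centred in the box (charge-neutral, periodic-safe away from
    the branch cut, detect with periodic=False to be safe near edges).

    The director angle is theta = sum_k s_k atan2(y - y_k, x - x_k) with
    s_k = +-1/2; the order magnitude is tapered to zero at each core over
    about two sites, q(r) = q_bulk tanh(r/2).
    """
    if kind == "pair" and separation <= 0:
        raise ValueError("pair separation must be positive")
    if kind == "pair" and separation >= L / 2:
        raise ValueError("pair separation must be below L/2")
    x, y = np.meshgrid(np.arange(L, dtype=float),
                       np.arange(L, dtype=float), indexing="ij")
    c = (L - 1) / 2.0
    if kind in ("single_plus", "single_minus"):
        s = 0.5 if kind == "single_plus" else -0.5
        cores = [((c, c), s)]
    elif kind == "pair":
        cores = [((c - separation / 2.0, c), 0.5),
                 ((c + separation / 2.0, c), -0.5)]
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    theta = np.zeros((L, L))
    q = np.full((L, L), q_bulk)
    for (x0, y0), s in cores:
        theta += s * np.arctan2(y - y0, x - x0)
        r = np.hypot(x - x0, y - y0)
        q *= np.tanh(r / 2.0)
    return NematicField.from_director(q, theta)


# -- point processes -------------------------------------------------------


def _symmetric_stable(alpha: float, size, rng) -> np.ndarray:
    """Symmetric alpha-stable samples (Chambers-Mallows-Stuck)."""
    U = rng.uniform(-np.pi / 2, np.pi / 2, size)
    Wexp = rng.exponential(1.0, size)
    if alpha == 1.0:
        return np.tan(U)
    return (np.sin(alpha * U) / np.cos(U) ** (1.0 / alpha)
            * (np.cos(U - alpha * U) / Wexp) ** ((1.0 - alpha) / alpha))


def make_point_process(kind: str, L: float, N: int = 500, seed: int = 0,
                       **kw) -> np.ndarray:
    """Point patterns with known density-fluctuation class on the torus.

    kind='poisson': N i.i.d. uniform points (S = 1, alpha = 0, beta = 1/2).
    kind='perturbed_lattice': sqrt(N)^2 grid plus i.i.d. jitter.  Gaussian
      jitter (``jitter`` in sites, default 0.2 lattice spacings) is
      strongly hyperuniform in the window probed (beta < 1/2); with
      ``stable_index`` in (0, 2) the jitter is heavy-tailed alpha-stable
      and the small-q structure factor goes as q^stable_index, giving a
      tunable hyperuniform exponent.
    kind='thomas_cluster': Poisson parents with ``mean_daughters``
      (default 10) Gaussian daughters of spread ``sigma`` (default L/40):
      clustered, giant number fluctuations in the probed window
      (beta > 1/2).
    kind='powerlaw_cox': log-Gaussian Cox process whose intensity field
      has a small-q power spectrum ~ q^alpha with ``alpha`` < 0 (default
      -0.8): anti-hyperuniform, S(q) ~ q^alpha at small q.
    """
    rng = np.random.default_rng(seed)
    if kind == "poisson":
        return rng.uniform(0.0, L, size=(N, 2))
    if kind == "perturbed_lattice":
        n_side = int(round(np.sqrt(N)))
        spacing = L / n_side
        g = (np.arange(n_side) + 0.5) * spacing
        pts = np.stack(np.meshgrid(g, g, indexing="ij"),
                       axis=-1).reshape(-1, 2)
        stable_index = kw.get("stable_index")
        jitter = kw.get("jitter", 0.2) * spacing
        if stable_index is None:
            disp = rng.normal(0.0, jitter, size=pts.shape)
        else:
            disp = jitter * _symmetric_stable(stable_index, pts.shape, rng)
        return (pts + disp) % L
    if kind == "thomas_cluster":
        mu = kw.get("mean_daughters", 10)
        sigma = kw.get("sigma", L / 40.0)
        n_parents = max(int(round(N / mu)), 1)
        parents = rng.uniform(0.0, L, size=(n_parents, 2))
        counts = rng.poisson(mu, size=n_parents)
        reps = np.repeat(np.arange(n_parents), counts)
        pts = parents[reps] + rng.normal(0.0, sigma, size=(len(reps), 2))
        return pts % L
    if kind == "powerlaw_cox":
        alpha = kw.get("alpha", -0.8)
        sigma_g = kw.get("sigma_g", 1.0)
        n_grid = kw.get("n_grid", 256)
        k1 = np.fft.fftfreq(n_grid, d=L / n_grid) * 2.0 * np.pi
        kk = np.hypot(k1[:, None], k1[None, :])
        kk[0, 0] = np.inf
        amp = kk ** (alpha / 2.0)
        amp[kk > 0.5] = 0.0  # keep the power law a small-q feature
        noise = np.fft.fft2(rng.standard_normal((n_grid, n_grid)))
        g = np.real(np.fft.ifft2(amp * noise))
        g *= sigma_g / g.std()
        lam = np.exp(g - g.var() / 2.0)
        prob = (lam / lam.sum()).ravel()
        cells = rng.choice(prob.size, size=N, p=prob)
        ci, cj = np.unravel_index(cells, (n_grid, n_grid))
        cell = L / n_grid
        return np.stack([(ci + rng.uniform(0, 1, N)) * cell,
                         (cj + rng.uniform(0, 1, N)) * cell], axis=1)
    raise ValueError(f"unknown point-process kind {kind!r}")


# -- velocity fields -------------------------------------------------------


def _divergence_free_from_psi(psih):
    """v = (Dy psi, -Dx psi) with the solver's central differences, so the
    discrete divergence Dx vx + Dy vy vanishes identically (the mixed
    stencils commute)."""
    psi = np.real(np.fft.ifft2(psih))
    vx = 0.5 * (np.roll(psi, -1, axis=1) - np.roll(psi, 1, axis=1))
    vy = -0.5 * (np.roll(psi, -1, axis=0) - np.roll(psi, 1, axis=0))
    return vx, vy


def make_velocity_field(kind: str, L: int, seed: int = 0, **kw):
    """Divergence-free 2D velocity fields with prescribed statistics.

    kind='taylor_green': v = v0 (sin kx cos ky, -cos kx sin ky) with
      ``n_cells`` periods per box: all spectral power in one shell.
    kind='powerlaw': random-phase field whose enstrophy spectrum follows
      q^b over the resolved band (``b`` default -1.0, band set by
      ``q_low``/``q_high`` in shell units, defaults 2 and L/8).
    kind='anisotropic': random-phase field with a direction-dependent
      Gaussian spectral envelope (correlation length ``l_par``, default
      16, along x; ``l_perp``, default 4, across): the flow organises
      into streamwise jets along x, so the local-frame statistics see a
      longer parallel than perpendicular correlation.

    Returns (vx, vy).
    """
    rng = np.random.default_rng(seed)
    if kind == "taylor_green":
        n_cells = kw.get("n_cells", 1)
        v0 = kw.get("v0", 1.0)
        k = 2.0 * np.pi * n_cells / L
        x, y = np.meshgrid(np.arange(L, dtype=float),
                           np.arange(L, dtype=float), indexing="ij")
        return (v0 * np.sin(k * x) * np.cos(k * y),
                -v0 * np.cos(k * x) * np.sin(k * y))
    k1 = 2.0 * np.pi * np.fft.fftfreq(L)
    kk = np.hypot(k1[:, None], k1[None, :])
    shell = kk * L / (2.0 * np.pi)  # wavevector in shell units
    # Hermitian random phases (real field, exact per-mode modulus)
    gh = np.fft.fft2(rng.standard_normal((L, L)))
    mod = np.abs(gh)
    phases = np.where(mod > 0, gh / np.where(mod > 0, mod, 1.0), 1.0)
    if kind == "powerlaw":
        b = kw.get("b", -1.0)
        q_low = kw.get("q_low", 2.0)
        q_high = kw.get("q_high", L / 8.0)
        # prescribe the *shell-summed* enstrophy spectrum exactly: each
        # ring of rounded radius s carries total power s^b, split evenly
        # over its modes; omega = curl v with the solver's central
        # differences has symbol s2 = sin^2 kx + sin^2 ky, so psi = w/s2
        ring = np.round(shell).astype(int)
        counts = np.bincount(ring.ravel())
        band = (ring >= q_low) & (ring <= q_high)
        amp = np.zeros_like(kk)
        amp[band] = np.sqrt(ring[band].astype(float) ** b
                            / counts[ring[band]])
        s2 = np.sin(k1[:, None]) ** 2 + np.sin(k1[None, :]) ** 2
        psih = np.zeros_like(amp, dtype=complex)
        nz = band & (s2 > 0)
        psih[nz] = amp[nz] * phases[nz] / s2[nz]
        return _divergence_free_from_psi(psih * L ** 2)
    if kind == "anisotropic":
        # streamwise jets: vx = f(y) with transverse correlation length
        # l_perp is exactly divergence free and stays correlated
        # indefinitely along the flow; a weak isotropic background of the
        # same short length gives the perpendicular component its decay
        l_perp = kw.get("l_perp", 4.0)
        eps = kw.get("background", 0.3)
        g1 = np.fft.fft(rng.standard_normal(L))
        env1 = np.exp(-0.5 * (k1 * l_perp) ** 2)
        env1[0] = 0.0
        f_y = np.real(np.fft.ifft(env1 * g1))
        f_y /= f_y.std()
        env = np.exp(-0.5 * (kk * l_perp) ** 2)
        env[0, 0] = 0.0
        ivx, ivy = _divergence_free_from_psi(env * phases * L ** 2)
        scale = eps / np.sqrt(ivx.var() + ivy.var())
        vx = f_y[None, :] * np.ones((L, 1)) + scale * ivx
        vy = scale * ivy
        return vx, vy
    raise ValueError(f"unknown velocity-field kind {kind!r}")
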