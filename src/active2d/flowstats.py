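"""Spectral and real-space statistics of the emergent flows and textures.

Covers the observables used to characterise the active-turbulence state:
kinetic-energy and enstrophy spectra with power-law exponent fits, the
real-space vorticity correlation and its decay exponent nu (related to the
small-q enstrophy exponent b by nu = b + 1), the normalised elastic
free-energy density rho_e, the nematic director correlation length l_c,
and the parallel/perpendicular velocity correlations that diagnose
rotational-symmetry breaking.

Wavevectors are reported in units of the smallest box wavevector 2 pi / L
(integer shell index); correlations are radially averaged over the whole
lattice via FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NematicField


@dataclass
class SpectrumResult:
    q_bins: np.ndarray        # shell index, units of 2 pi / L
    values: np.ndarray
    exponent: float | None = None
    exponent_ci: float | None = None
    fit_window: tuple | None = None


@dataclass
class CorrelationCurve:
    r: np.ndarray
    C: np.ndarray
    length: float            # e^-1 crossing distance
    crossed: bool            # False -> no crossing, length = L/2
    exponent: float | None = None
    exponent_ci: float | None = None


def vorticity(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """omega = dx vy - dy vx by central differences (periodic)."""
    return (0.5 * (np.roll(vy, -1, 0) - np.roll(vy, 1, 0))
            - 0.5 * (np.roll(vx, -1, 1) - np.roll(vx, 1, 1)))


def _ring_index(L: int) -> np.ndarray:
    n = np.fft.fftfreq(L, d=1.0 / L)
    return np.round(np.hypot(n[:, None], n[None, :])).astype(int)


def _shell_spectrum(power: np.ndarray) -> SpectrumResult:
    L = power.shape[0]
    ring = _ring_index(L)
    nbins = ring.max() + 1
    sums = np.bincount(ring.ravel(), weights=power.ravel(),
                       minlength=nbins)
    sums[0] = 0.0  # drop the mean mode
    q = np.arange(nbins)
    keep = q >= 1
    return SpectrumResult(q_bins=q[keep], values=sums[keep])


def _fit_loglog(x, y, lo, hi):
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x > lo) & (x <= hi) & (y > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in the fit window")
    res = stats.linregress(np.log(x[mask]), np.log(y[mask]))
    return float(res.slope), float(1.96 * res.stderr)


def energy_spectrum(vx: np.ndarray, vy: np.ndarray,
                    fit_window=None) -> SpectrumResult:
    """Isotropic kinetic-energy spectrum E(q) from |v(q)|^2 shell sums.

    Normalised so that sum_q E(q) equals the lattice variance of the
    velocity (Parseval, mean flow excluded).  The power-law exponent is
    fitted over normalised q in (1, L/8] unless a window is given.
    """
    L = vx.shape[0]
    power = (np.abs(np.fft.fft2(vx)) ** 2
             + np.abs(np.fft.fft2(vy)) ** 2) / L ** 4
    spec = _shell_spectrum(power)
    if fit_window is None:
        fit_window = (1.0, L / 8.0)
    try:
        spec.exponent, spec.exponent_ci = _fit_loglog(
            spec.q_bins, spec.values, *fit_window)
        spec.fit_window = fit_window
    except ValueError:
        pass
    return spec


def enstrophy_spectrum(omega: np.ndarray, fit_window=None) -> SpectrumResult:
    """Isotropic enstrophy spectrum from |omega(q)|^2 shell sums.

    The small-q exponent b (fitted over normalised q in [1, L/8] by
    default) maps to the real-space vorticity-correlation decay through
    nu = b + 1.
    """
    L = omega.shape[0]
    power = np.abs(np.fft.fft2(omega)) ** 2 / L ** 4
    spec = _shell_spectrum(power)
    if fit_window is None:
        fit_window = (0.99, L / 8.0)
    try:
        spec.exponent, spec.exponent_ci = _fit_loglog(
            spec.q_bins, spec.values, *fit_window)
        spec.fit_window = fit_window
    except ValueError:
        pass
    return spec


def _radial_profile(field2d: np.ndarray):
    """Radially average a 2D correlation map over min-image distances."""
    L = field2d.shape[0]
    idx = np.arange(L)
    sep = np.minimum(idx, L - idx)
    r = np.hypot(sep[:, None], sep[None, :])
    rbin = np.round(r).astype(int)
    nbins = rbin.max() + 1
    sums = np.bincount(rbin.ravel(), weights=field2d.ravel(),
                       minlength=nbins)
    counts = np.bincount(rbin.ravel(), minlength=nbins)
    prof = sums / counts
    rmax = L // 2
    return np.arange(rmax + 1), prof[:rmax + 1]


def _autocorr2d(field: np.ndarray) -> np.ndarray:
    fh = np.fft.fft2(field)
    return np.real(np.fft.ifft2(fh * np.conj(fh))) / field.size


def _e_crossing(r, C, L):
    """First e^-1 crossing by linear interpolation; (L/2, False) if none."""
    target = np.exp(-1.0)
    below = np.nonzero(C < target)[0]
    if len(below) == 0 or below[0] == 0:
        return L / 2.0, False
    i = below[0]
    r0, r1 = r[i - 1], r[i]
    c0, c1 = C[i - 1], C[i]
    return float(r0 + (c0 - target) / (c0 - c1) * (r1 - r0)), True


def vorticity_correlation(omega_snapshots, fit_window=None
                          ) -> CorrelationCurve:
    """Two-point vorticity correlation <omega(0) omega(r)>, radially
    averaged and snapshot averaged, with the large-distance decay exponent
    nu of C(r) ~ r^-nu fitted over r in [L/8, L/3] by default.

    The lattice mean of omega is removed per snapshot (it vanishes on a
    periodic domain up to discretisation error).
    """
    if isinstance(omega_snapshots, np.ndarray) and \
            omega_snapshots.ndim == 2:
        omega_snapshots = [omega_snapshots]
    acc = None
    n = 0
    for w in omega_snapshots:
        w = w - w.mean()
        c = _autocorr2d(w)
        acc = c if acc is None else acc + c
        n += 1
    acc /= n
    L = acc.shape[0]
    r, prof = _radial_profile(acc)
    C = prof / prof[0]
    length, crossed = _e_crossing(r, C, L)
    curve = CorrelationCurve(r=r, C=C, length=length, crossed=crossed)
    if fit_window is None:
        fit_window = (L / 8.0, L / 3.0)
    try:
        slope, ci = _fit_loglog(r[1:], C[1:], fit_window[0], fit_window[1])
        curve.exponent = -slope  # nu: C ~ r^-nu
        curve.exponent_ci = ci
    except ValueError:
        pass
    return curve


def elastic_energy_summary(Q_snapshots, K: float) -> float:
    """Normalised elastic free-energy density rho_e = <E / max(E)>.

    Per snapshot the elastic energy density is divided by its spatial
    maximum; the result is averaged over the lattice and over snapshots.
    A perfectly uniform snapshot (max E = 0) is degenerate and raises.
    """
    from .core import elastic_energy_density

    vals = []
    for Q in Q_snapshots:
        if not isinstance(Q, NematicField):
            Q = NematicField(*Q)
        E = elastic_energy_density(Q, K)
        m = E.max()
        if m == 0.0:
            raise ValueError("uniform snapshot: max elastic energy is zero")
        vals.append(float(np.mean(E / m)))
    if not vals:
        raise ValueError("no snapshots given")
    return float(np.mean(vals))


def director_correlation(Q_snapshots) -> CorrelationCurve:
    """Nematic director autocorrelation and correlation length l_c.

    Uses the sign-unambiguous tensor contraction
    C(r) = <Q(x):Q(x+r)> / <Q:Q>, which equals the order-weighted
    <cos 2(theta(x) - theta(x+r))>; l_c is the first e^-1 crossing
    (linearly interpolated), flagged and set to L/2 when no crossing
    occurs (e.g. a uniform director).
    """
    acc = None
    norm = 0.0
    n = 0
    for Q in Q_snapshots:
        if not isinstance(Q, NematicField):
            Q = NematicField(*Q)
        c = 2.0 * (_autocorr2d(Q.Qxx) + _autocorr2d(Q.Qxy))
        acc = c if acc is None else acc + c
        norm += c[0, 0]
        n += 1
    L = acc.shape[0]
    r, prof = _radial_profile(acc / n)
    C = prof / (norm / n)
    length, crossed = _e_crossing(r, C, L)
    return CorrelationCurve(r=r, C=C, length=length, crossed=crossed)


def _crosscorr2d(f, g):
    return np.real(np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(g)))
                   ) / f.size


def anisotropy_correlations(v_snapshots, n_ref: int | None = None,
                            rng=None):
    """Velocity correlations parallel and perpendicular to the local flow.

    For every reference site, the velocity field is rotated into the frame
    set by the flow direction *at that site* (angle phi); the parallel and
    perpendicular components are autocorrelated over the lattice, radially
    averaged, and the curves are averaged over reference sites and
    snapshots.  In that frame the autocorrelations are exact linear
    combinations of the three component correlation maps,

        C_par  = cos^2 phi Axx + sin^2 phi Ayy + sin 2phi Axy,
        C_perp = sin^2 phi Axx + cos^2 phi Ayy - sin 2phi Axy,

    so the average over reference sites reduces to averaging the angle
    weights; by default every lattice site is used (``n_ref`` subsamples
    with the given rng, which only adds sampling noise).  Returns
    (C_par, C_perp, l_par - l_perp) with the e^-1 correlation lengths;
    equal lengths signal a rotationally symmetric (isotropic) flow, and
    l_par > l_perp a flow that stays correlated longer along its own
    direction.
    """
    rng = np.random.default_rng(rng)
    acc_par = acc_perp = None
    n_snap = 0
    for vx, vy in v_snapshots:
        L = vx.shape[0]
        Axx = _autocorr2d(vx)
        Ayy = _autocorr2d(vy)
        Axy = 0.5 * (_crosscorr2d(vx, vy) + _crosscorr2d(vy, vx))
        phi = np.arctan2(vy, vx)
        if n_ref is not None:
            ii = rng.integers(0, L, size=n_ref)
            jj = rng.integers(0, L, size=n_ref)
            phi = phi[ii, jj]
        c2 = np.mean(np.cos(phi) ** 2)
        s2 = np.mean(np.sin(phi) ** 2)
        s2p = np.mean(np.sin(2 * phi))
        cpar = c2 * Axx + s2 * Ayy + s2p * Axy
        cperp = s2 * Axx + c2 * Ayy - s2p * Axy
        acc_par = cpar if acc_par is None else acc_par + cpar
        acc_perp = cperp if acc_perp is None else acc_perp + cperp
        n_snap += 1
    if n_snap == 0:
        raise ValueError("no snapshots given")
    r, prof_par = _radial_profile(acc_par / n_snap)
    _, prof_perp = _radial_profile(acc_perp / n_snap)
    C_par = prof_par / prof_par[0]
    C_perp = prof_perp / prof_perp[0]
    l_par, _ = _e_crossing(r, C_par, L)
    l_perp, _ = _e_crossing(r, C_perp, L)
    par = CorrelationCurve(r=r, C=C_par, length=l_par, crossed=True)
    perp = CorrelationCurve(r=r, C=C_perp, length=l_perp, crossed=True)
    return par, perp, l_par - l_perp
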