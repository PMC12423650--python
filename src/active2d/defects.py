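"""Topological defect detection and hyperuniformity statistics.

A 2D nematic admits half-integer point defects: the director winds by
+-pi around a +-1/2 core.  Detection computes the winding of the director
angle around every unit plaquette with the angle differences folded into
(-pi/2, pi/2] (nematic symmetry); defect positions are plaquette centres
(sub-pixel refinement is deliberately omitted: defect spacings of interest
are tens of sites).

The spatial statistics quantify how defect density fluctuates at large
scale: the structure factor S(q) and its small-q exponent alpha
(S ~ q^alpha; alpha = 0 Poisson-like, alpha > 0 hyperuniform, alpha < 0
anti-hyperuniform / giant number fluctuations), and the number variance in
randomly placed circular windows, whose growth exponent beta
(sigma_N ~ <N>^beta) maps to alpha through beta = (1 - alpha/d)/2, d = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NematicField, decompose


@dataclass
class DefectSet:
    positions: np.ndarray  # (n, 2) lattice coordinates
    charges: np.ndarray    # (n,), +-1/2
    step: int = 0

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.charges)


@dataclass
class StructureFactorEstimate:
    q_bins: np.ndarray
    S_values: np.ndarray
    n_modes: np.ndarray
    q_upper: float


@dataclass
class NumberVarianceCurve:
    radii: np.ndarray
    mean_N: np.ndarray
    var_N: np.ndarray
    beta: float
    beta_ci: float


def _fold_nematic(dtheta):
    """Fold director-angle differences into (-pi/2, pi/2]."""
    return dtheta - np.pi * np.round(dtheta / np.pi)


def detect_defects(Q: NematicField, periodic: bool = True,
                   step: int = 0) -> DefectSet:
    """Find +-1/2 defects from the director winding on unit plaquettes.

    Positions are plaquette centres (i + 1/2, j + 1/2).  On a periodic
    lattice the total charge vanishes identically.  With
    ``periodic=False`` the wrapping plaquettes are excluded (used for
    open-patch textures that carry net charge).
    """
    _, theta = decompose(Q)
    t00 = theta
    t10 = np.roll(theta, -1, axis=0)
    t11 = np.roll(t10, -1, axis=1)
    t01 = np.roll(theta, -1, axis=1)
    winding = (_fold_nematic(t10 - t00) + _fold_nematic(t11 - t10)
               + _fold_nematic(t01 - t11) + _fold_nematic(t00 - t01))
    charge2 = np.round(winding / np.pi)  # twice the defect charge
    if not periodic:
        charge2[-1, :] = 0
        charge2[:, -1] = 0
    ii, jj = np.nonzero(charge2)
    positions = np.stack([ii + 0.5, jj + 0.5], axis=1)
    return DefectSet(positions, 0.5 * charge2[ii, jj], step=step)


def structure_factor(points_snapshots, L: float, q_upper: float = 0.25
                     ) -> StructureFactorEstimate:
    """Structure factor S(q) = |sum_j exp(-i q.r_j)|^2 / N of point
    patterns, averaged over time (snapshots) and orientations (radial
    bins).

    Only box-commensurate wavevectors q = (2 pi / L)(n, m), q != 0,
    |q| <= q_upper are evaluated; with the 1/N normalisation an ideal
    Poisson pattern gives S = 1 at every q.
    """
    if isinstance(points_snapshots, np.ndarray):
        points_snapshots = [points_snapshots]
    n_max = int(np.floor(q_upper * L / (2.0 * np.pi)))
    if n_max < 1:
        raise ValueError("q_upper below the smallest box wavevector")
    n = np.arange(-n_max, n_max + 1)
    NN, MM = np.meshgrid(n, n, indexing="ij")
    qnorm = 2.0 * np.pi * np.hypot(NN, MM) / L
    keep = (qnorm > 0) & (qnorm <= q_upper)
    qnorm = qnorm[keep]

    S_acc = np.zeros(qnorm.size)
    n_snap = 0
    for pts in points_snapshots:
        pts = np.asarray(pts, dtype=float)
        N = len(pts)
        if N < 1:
            raise ValueError("empty point pattern")
        # separable phases: amp(n, m) = sum_j e^{-i q_n x_j} e^{-i q_m y_j}
        px = np.exp(-2j * np.pi * np.outer(n, pts[:, 0]) / L)
        py = np.exp(-2j * np.pi * np.outer(n, pts[:, 1]) / L)
        amp = px @ py.T
        S_acc += (amp.real ** 2 + amp.imag ** 2)[keep] / N
        n_snap += 1
    S_per_mode = S_acc / n_snap

    # orientational average: bin by |q| at the resolution of the q-lattice
    ring = np.round(qnorm * L / (2.0 * np.pi)).astype(int)
    n_bins = ring.max() + 1
    counts = np.bincount(ring, minlength=n_bins)
    sums = np.bincount(ring, weights=S_per_mode, minlength=n_bins)
    qsums = np.bincount(ring, weights=qnorm, minlength=n_bins)
    nz = counts > 0
    return StructureFactorEstimate(
        q_bins=qsums[nz] / counts[nz],
        S_values=sums[nz] / counts[nz],
        n_modes=counts[nz],
        q_upper=q_upper)


def fit_alpha(est: StructureFactorEstimate, fit_decade: float = 10.0):
    """Small-q exponent alpha of S(q) ~ q^alpha with a 95% CI.

    Least squares on log S vs log q over the lowest ``fit_decade``-fold
    range of retained wavevectors (at least 5 bins required).
    """
    from scipy import stats

    q = est.q_bins
    S = est.S_values
    mask = (q <= q.min() * fit_decade) & (S > 0)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 bins in the fit range")
    res = stats.linregress(np.log(q[mask]), np.log(S[mask]))
    return res.slope, 1.96 * res.stderr


def count_in_windows(points: np.ndarray, L: float, radii: np.ndarray,
                     centers: np.ndarray) -> np.ndarray:
    """Counts N(R) for every window centre and radius, with points taken
    at minimum-image distance on the torus.  Returns (n_centers, n_radii).
    """
    pts = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    centers = np.asarray(centers, dtype=float)
    out = np.empty((len(centers), len(radii)), dtype=np.int64)
    # chunk the (centers x points) distance matrix to bound memory
    chunk = max(1, int(2e7) // max(len(pts), 1))
    r2 = radii ** 2
    for lo in range(0, len(centers), chunk):
        hi = min(lo + chunk, len(centers))
        d2 = np.zeros((hi - lo, len(pts)))
        for axis in range(2):
            sep = np.abs(centers[lo:hi, axis, None] - pts[None, :, axis])
            sep = np.minimum(sep, L - sep)
            d2 += sep ** 2
        for i, rr in enumerate(r2):
            out[lo:hi, i] = (d2 <= rr).sum(axis=1)
    return out


def number_variance(points_snapshots, L: float, n_windows: int = 10_000,
                    rng=None, n_radii: int = 25,
                    radius_range=None) -> NumberVarianceCurve:
    """Moments of the count N(R) in randomly placed circular windows.

    Windows are uniform on the torus; by default 25 radii span
    [L/100, L/10].  beta is the log-log slope of the count standard
    deviation sigma_N(R) against the mean <N(R)> (so a Poisson pattern
    gives beta = 1/2 and giant number fluctuations give beta > 1/2),
    with a 95% CI from the fit.
    """
    from scipy import stats

    if isinstance(points_snapshots, np.ndarray):
        points_snapshots = [points_snapshots]
    rng = np.random.default_rng(rng)
    if radius_range is None:
        radius_range = (L / 100.0, L / 10.0)
    radii = np.geomspace(radius_range[0], radius_range[1], n_radii)

    counts = []
    for pts in points_snapshots:
        centers = rng.uniform(0.0, L, size=(n_windows, 2))
        counts.append(count_in_windows(pts, L, radii, centers))
    counts = np.concatenate(counts, axis=0).astype(float)
    mean_N = counts.mean(axis=0)
    var_N = counts.var(axis=0)

    ok = (mean_N > 0) & (var_N > 0)
    res = stats.linregress(np.log(mean_N[ok]), 0.5 * np.log(var_N[ok]))
    return NumberVarianceCurve(radii=radii, mean_N=mean_N, var_N=var_N,
                               beta=float(res.slope),
                               beta_ci=float(1.96 * res.stderr))


def fit_beta(curve: NumberVarianceCurve, tail_fraction: float = 0.0):
    """Re-fit the count-fluctuation exponent beta from a stored curve.

    ``tail_fraction`` restricts the fit to the upper part of the radius
    range (in log spacing): windows spanning only a few interparticle
    distances count nearly independent points and scale with beta = 1/2
    whatever the asymptotic class, so asymptotic-exponent estimates should
    drop the smallest radii (tail_fraction = 0.5 keeps the upper half).
    Returns (beta, 95% CI).
    """
    from scipy import stats

    r0, r1 = curve.radii[0], curve.radii[-1]
    keep = curve.radii >= r0 * (r1 / r0) ** tail_fraction
    ok = keep & (curve.mean_N > 0) & (curve.var_N > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable radii in the fit range")
    res = stats.linregress(np.log(curve.mean_N[ok]),
                           0.5 * np.log(curve.var_N[ok]))
    return float(res.slope), float(1.96 * res.stderr)


def beta_from_alpha(alpha: float, d: int = 2) -> float:
    """Exponent map beta = (1 - alpha/d)/2 between the structure-factor
    exponent and the number-fluctuation exponent."""
    return 0.5 * (1.0 - alpha / d)


def defects_to_frame(defect_sets):
    """Defect lists as a DataFrame with columns (t, x, y, charge)."""
    import pandas as pd

    rows = []
    for ds in defect_sets:
        for (x, y), c in zip(ds.positions, ds.charges):
            rows.append({"t": ds.step, "x": x, "y": y, "charge": c})
    return pd.DataFrame(rows, columns=["t", "x", "y", "charge"])
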