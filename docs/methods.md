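# Methods

## Model

`active2d` solves the two-dimensional hydrodynamics of an active nematic
whose constituents also self-propel. The orientational state is the
symmetric traceless tensor Q_ij = 2q(n_i n_j − δ_ij/2), carried on an
L×L periodic lattice as its two independent components (Qxx, Qxy), which
makes tracelessness and symmetry exact by representation. The order
tensor evolves by

    ∂t Q + (v + V0 p)·∇Q = Γ H + S(Q, ∇v),

where H = −δF/δQ is the molecular field of the free energy

    F = ∫ [ K/2 (∂_k Q_ij)² + A (1 − Q_ij Q_ji)² ],

S is the co-rotation term with flow-alignment parameter λ, and the flow
obeys the Navier–Stokes momentum balance driven by the divergence of the
passive (elastic) and active (−ζQ, extensile for ζ>0) stresses.

The distinctive ingredient is the polar self-advection V0 p·∇Q: every
particle moves at speed V0 along its polarity p, which is the director
direction (n or −n) closest to the local flow, re-assigned every step.
Ties (|v·n| below 10⁻¹² of |v|, or vanishing flow) keep the previous
polarity sign; the initial polarity is +n. This persistence rule avoids
sign chattering where the flow runs perpendicular to the director and at
defect cores, where the advection term is O(q) and insensitive to the
choice.

## Numerics

* Flow: D2Q9 lattice Boltzmann, BGK collision, τ = 3η/ρ + ½ (defaults
  give τ = 2), Guo second-order forcing with the half-force velocity
  shift. The body force is the central-difference divergence of the
  passive+active stress. The isotropic pressure −Pδ is *not* added to
  the stress: the LB equation of state supplies it, and adding both
  would double-count. Incompressibility is approximate (weakly
  compressible); runs are kept at Mach ≪ 1 and the driver aborts when
  max|v| exceeds 0.3.
* Order tensor: explicit Euler with dt = 1 (the LB step), second-order
  central differences for all gradients and Laplacians, first-order
  upwind for the advection by v + V0 p. Upwind is chosen for stability
  of the hyperbolic part; its numerical diffusion (≈ |a|/2 per unit
  time) is the price. Consequences that the tests document: a localized
  structure advected at V0 keeps its centroid speed and integral exactly
  but spreads; an advected linear mode feels an extra damping of order
  (V0/2)k².
* Update order per step (fixed, because it affects results at floating
  point level): (1) LB moments, with the velocity carrying the half
  correction of the force applied at the previous collision; (2)
  polarity assignment from (Q, v); (3) Q update; (4) molecular field,
  stress and new force from the updated Q; (5) LB collision/streaming
  under the new force (whose half correction enters that collision's
  velocity). Runs are bitwise reproducible given a configuration and
  seed, and restarting from a checkpoint reproduces an uninterrupted
  run.
* In 2D the flow-alignment part of the passive stress simplifies
  exactly: 2λ(Q+δ/2)(Q:H) − λ[H(Q+δ/2) + (Q+δ/2)H] = 2λ(Q:H)Q − λH,
  the isotropic pieces cancelling; the code uses this reduced form.
  The Ericksen term −K ∂_iQ_kl ∂_jQ_kl and the antisymmetric torque
  QH − HQ are kept in full.

Default coefficients (lattice units): ρ=40, η=20, λ=0.2, Γ=0.1, K=0.05,
A=0.1, ζ=0.05. The bulk term is minimised at q = 1/√2; aligned initial
states start there (at q=1 when A=0, where every uniform magnitude is
stationary) plus uniform noise of amplitude 0.01.

## Linear stability

Perturbations δφ = (δQxx, δQxy, δω) e^{iq(nx+my)} about the aligned
state (Qxx, Qxy, ω) = (1, 0, 0) with polarity (1, 0) obey ∂t φ = J_{nm}φ
with an analytic 3×3 Jacobian assembled in `stability.jacobian`. The
self-advection enters as the purely propagative −i kx V0 in the tensor
rows; stabilisation arises because this drift de-phases the order
perturbation from the shear flow it generates. For the longitudinal mode
(1,0) the δQxx row decouples and the coupled 2×2 block has the closed
form implemented in `lambda_10`; at A=0 it reduces to

    Λ10 = q/2 [ −q(ΓK + η/ρ) − iV0
                ± sqrt( q²(ΓK − η/ρ)² + 2iqV0(ΓK − η/ρ) − V0²
                        + 2(2+λ)/ρ (ζ − q²K(2+λ)) ) ],

and Re Λ10 = 0 yields the suppression threshold

    V0* = (ΓK + η/ρ) sqrt( (2+λ)(ζ − q²K(2+λ))/(2ΓKη) − q² ),

which grows as √ζ at large activity (the balance τ_Q = τ_v of the
self-propulsion time ΓK/V0² against the active-viscous time η/ζ gives
the same square-root relation). `critical_v0` treats the bracketed
root-finding on the Jacobian eigenvalues as authoritative and the
printed expression as a cross-check.

Two deliberate choices here:

* With A > 0 the state q=1 is not a stationary point of the free
  energy; the Jacobian is then simply the mathematical derivative of
  the right-hand side at that point, and the closed forms carry the
  corresponding bulk contributions (they reduce to the expressions
  above at A = 0). Threshold comparisons against simulation are run at
  A = 0, where the aligned base state is exact.
* The independent oracle for the Jacobian is a pseudo-spectral
  evaluation of the full nonlinear continuum right-hand side on a 16×16
  collocation grid (exact Fourier derivatives, exactly incompressible
  velocity from the vorticity), linearised by central directional
  differences and projected back on the mode. It shares no code with
  the solver stencils or the analytic Jacobian; agreement is at the
  10⁻¹² level.

### Stability probe

The simulation-side classifier seeds δQxy = 10⁻⁴ cos(qx) on the aligned
state and fits the growth of the lattice-mean δQxy² over steps
[500, 5000]. One subtlety is essential: the linear analysis assumes the
flow keeps a positive component along the director, so that p = +n
coherently. In a probe started from rest, the infinitesimal flow of the
longitudinal mode is transverse and alternates in sign across the
pattern; the polarity then splits 50/50 between ±n and the coherent
self-advection averages out — a physically different (incoherent)
scenario in which V0 does not suppress the mode. The probe therefore
imposes a small uniform background flow vx = 10⁻³. A uniform flow only
adds a rigid Doppler shift −i kx vx to every eigenvalue (it advects all
perturbation fields equally and has no gradients), so growth rates and
classifications are untouched, while v·n > 0 holds everywhere and the
coherent-polarity branch of the dynamics is realised. With this probe
the measured rates track Re Λ10 to within a few tens of percent near
threshold and the stable/unstable classification matches the theory on
the tested (V0, ζ) grid.

## Statistics suite

* Defects: ±1/2 charges from the director winding around unit
  plaquettes, angle differences folded into (−π/2, π/2]; positions at
  plaquette centres (defect spacings of interest are tens of sites, so
  no sub-pixel refinement). Charge neutrality on the periodic domain is
  an exact invariant of the winding construction.
* Structure factor: S(q) = |Σ e^{−iq·r}|²/N on box-commensurate modes
  with |q| ≤ 1/4, evaluated by a separable phase matrix product,
  orientationally averaged over rings and over snapshots; Poisson
  patterns give S = 1 exactly in expectation. The small-q exponent α is
  a log-log fit over the lowest retained decade.
* Number variance: counts in circular windows placed uniformly on the
  torus (minimum-image distances), 25 radii in [L/100, L/10], 10⁴
  windows per radius by default. The growth exponent β is the log–log
  slope of the count standard deviation against the mean, the
  convention in which a Poisson gas has β = 1/2 exactly and giant
  number fluctuations give β > 1/2; it maps to the structure-factor
  exponent as β = (1 − α/2)/2. Windows that span only a few
  interparticle spacings count nearly independent points and scale with
  β = 1/2 for *any* class, so asymptotic-exponent estimates
  (`fit_beta`) can drop the lower half of the radius range; the
  exponent-map consistency check does this for all pattern classes
  symmetrically.
* Spectra: kinetic energy and enstrophy as ring-binned |v̂|², |ω̂|²,
  normalised so the spectrum sums to the lattice variance (Parseval,
  mean mode excluded); wavevectors in units of 2π/L. Power-law
  exponents by log-log fits over normalised q ∈ (1, L/8] by default.
* Vorticity correlation: FFT autocorrelation, radially averaged,
  snapshot averaged, mean removed. The decay exponent ν relates to the
  small-q enstrophy exponent b by ν = b + 1 (Fourier pair); the
  relation is validated on constructed fields with exact ring spectra.
  In a periodic box the real-space power law survives only at r well
  below L/(2π) — the default fit window [L/8, L/3] follows the
  convention used for large-box data, while the validation fixtures fit
  at r ∈ [4, 20] on L = 1024 fields, inside the window where the
  construction actually scales; the relation holds there to ±0.05 for
  b < 1/2 (it breaks down for b ≥ 1/2, where the transform is
  ultraviolet-dominated).
* Director correlation: C(r) = ⟨Q(x):Q(x+r)⟩/⟨Q:Q⟩ — the only
  sign-unambiguous nematic estimator (equals the order-weighted
  ⟨cos 2Δθ⟩); l_c is the interpolated e⁻¹ crossing, flagged at L/2 when
  no crossing exists.
* Rotational-symmetry diagnostic: for each reference site the velocity
  field is rotated into the frame of the local flow direction and the
  parallel/perpendicular components are autocorrelated. In that frame
  the two autocorrelations are exact linear combinations (weights
  cos²φ, sin²φ, sin 2φ) of the three component correlation maps, so the
  site average reduces to averaging the angle weights and every lattice
  site can be used at no extra cost. Equal e⁻¹ lengths signal an
  isotropic flow; l_par − l_perp > 0 a flow correlated longer along its
  own direction.

## Synthetic fixtures

The generators exist to give the estimators inputs with *known* answers;
all are bit-reproducible from (arguments, seed).

* Defect textures: θ = Σ s_k atan2(y−y_k, x−x_k), order tapered as
  q_bulk·tanh(r/2) over ~2 sites at each core.
* Point processes: Poisson (uniform null); perturbed lattices with
  Gaussian jitter (strongly hyperuniform) or symmetric α-stable jitter
  (S(q) ~ q^a with a the stable index — tunable hyperuniform exponent;
  sampled by the Chambers–Mallows–Stuck formula); Thomas clusters
  (giant fluctuations in the probed window); log-Gaussian Cox processes
  whose intensity has a prescribed small-q power spectrum
  (anti-hyperuniform, S ~ q^α with α < 0).
* Velocity fields: Taylor–Green cells (single spectral shell);
  random-phase fields whose *shell-summed* enstrophy spectrum follows
  the prescribed power law exactly (Hermitian phases, per-ring
  normalisation, streamfunction differentiated with the solver's own
  central stencils so the discrete divergence vanishes identically);
  streamwise-jet fields (vx = f(y) plus a weak short-range isotropic
  background) for the anisotropy diagnostic.

What the fixtures do not emulate: genuine active-turbulence statistics
(the solver provides those), defect motion, and the +1/2/−1/2 core
asymmetry.

## Problem sizes and what the desk-scale runs show

The study-condition coefficients above are kept throughout; lattice
sizes are scaled to a single CPU. The threshold grid runs at L = 256
(3×3 cells, 5000 steps each); steady-turbulence defect statistics at
L = 128 (15000 warm-up steps, 20 snapshots 500 steps apart, ~50
defects); the order-enhancement comparison at L = 256 (random initial
texture, 5000 warm-up steps, 30 snapshots). At these sizes the V0 = 0
state reproduces the uniform (β ≈ 1/2) defect gas, and V0 = 0.06 shows
the order enhancement directly: the director correlation length grows
from ≈6 to ≈90 sites.

A finite-size limitation must be stated plainly: at L = 256 the
V0 = 0.06 ordering is so strong that the emergent correlation length
reaches the box scale and the defect gas largely annihilates (counts
fall from ~190 to a handful). Giant number fluctuations of defects are
a property of a defect *ensemble* that survives at scale; with the gas
collapsed the measured β shifts upward only by ~0.05 rather than the
≳0.1 expected of the full-scale anti-hyperuniform regime, and the test
asserting that shift is expected to fail at these sizes. The l_c
signature of the same physics is robust. Full-scale (L = 1024) sweeps are
supported by the same code path but are long-running.

## Known limitations

* Weakly compressible flow: density fluctuations O(Ma²) leak into the
  stress balance; quantitative spectra need Mach ≪ 1.
* First-order upwind advection diffuses sharp Q structures (see above);
  a sub-cycling knob (smaller dt for the order tensor) exists for runs
  that need it.
* The linear theory addresses the coherent-polarity branch; the
  incoherent branch (polarity anti-aligned over half the pattern) is
  physically accessible from noisy initial data and is *less*
  stabilised by V0 than the dispersion relation suggests.
* Exponent estimates from single boxes carry finite-window biases
  discussed above; confidence intervals from independent replicate
  groups are the honest uncertainty.
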