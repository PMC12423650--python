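"""Model and run-control parameters.

All quantities are in lattice units (grid spacing = LB time step = 1).
The defaults are the working point of the study this package implements:
rho=40, eta=20, lam=0.2, Gamma=0.1, K=0.05, A=0.1, zeta=0.05, and a
1024-site box (desk-scale runs use smaller L).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of the coupled nemato-hydrodynamic model.

    Attributes
    ----------
    rho : fluid density.
    eta : dynamic viscosity (kinematic viscosity is eta/rho).
    lam : flow-alignment coefficient of the co-rotation term.
    Gamma : rotational mobility of the order tensor.
    K : Frank elastic constant (one-constant approximation).
    A : bulk free-energy coefficient; the bulk term A(1 - Q:Q)^2 is
        minimised at order magnitude q = 1/sqrt(2).
    zeta : dipolar activity (extensile for zeta > 0).
    V0 : self-propulsion speed multiplying the polar self-advection term.
    L : lattice side length (sites).
    dt : time step of the order-tensor update (LB step is always 1).
    seed : RNG seed used for initial noise.
    """

    rho: float = 40.0
    eta: float = 20.0
    lam: float = 0.2
    Gamma: float = 0.1
    K: float = 0.05
    A: float = 0.1
    zeta: float = 0.05
    V0: float = 0.0
    L: int = 1024
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eta <= 0 or self.Gamma <= 0 or self.K <= 0:
            raise ValueError("rho, eta, Gamma and K must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.L < 8:
            raise ValueError("lattice must have at least 8 sites per side")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity eta/rho."""
        return self.eta / self.rho

    @property
    def tau(self) -> float:
        """BGK relaxation time, tau = 3 nu + 1/2 in lattice units."""
        return 3.0 * self.nu + 0.5

    @property
    def q_min(self) -> float:
        """Shortest wavevector of the periodic box, 2 pi / L."""
        import math

        return 2.0 * math.pi / self.L

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SimulationConfig:
    """Run control wrapped around :class:`ModelParams`."""

    params: ModelParams = ModelParams()
    n_steps: int = 1000
    snapshot_interval: int = 100
    warmup_steps: int = 0
    init: str = "aligned"  # "aligned" or "random"
    noise: float = 0.01
    diag_interval: int = 10

    def __post_init__(self) -> None:
        if self.snapshot_interval > self.n_steps:
            raise ValueError("snapshot_interval must not exceed n_steps")
        if self.init not in ("aligned", "random"):
            raise ValueError("init must be 'aligned' or 'random'")


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_RUN_KEYS = {
    f.name for f in dataclasses.fields(SimulationConfig)
} - {"params"}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a TOML configuration.

    Model keys are named exactly after the model symbols (rho, eta, lam,
    Gamma, K, A, zeta, V0, L, dt, seed); run-control keys (n_steps,
    snapshot_interval, warmup_steps, init, noise, diag_interval) may appear
    at top level or under a ``[run]`` table.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run_tbl = raw.pop("run", {})
    model_kw = {k: v for k, v in raw.items() if k in _MODEL_KEYS}
    run_kw = {k: v for k, v in raw.items() if k in _RUN_KEYS}
    run_kw.update({k: v for k, v in run_tbl.items() if k in _RUN_KEYS})
    unknown = set(raw) - _MODEL_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return SimulationConfig(params=ModelParams(**model_kw), **run_kw)
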