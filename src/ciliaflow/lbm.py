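"""D2Q9 BGK lattice-Boltzmann solver for the depth-averaged mucus flow.

The mucus layer is modeled as a 2D incompressible Newtonian film driven by a
body force ``f_n = f_v + f_c``: a periciliary-layer (PCL) friction
``f_v = -kappa*U`` acting everywhere, and a constant-magnitude ciliary
propulsion ``f_c`` acting on the nodes of ciliated elements along the
element's beat angle.  The governing momentum equation is solved on a fully
periodic Cartesian grid with the BGK collision operator and Guo's
second-order external-forcing scheme.

Non-dimensional control parameters and their lattice mapping:

* ``Re = rho_m * D * U0 / mu_m`` — Reynolds number (``U0 = |f_c|/kappa``).
* ``lambda = sqrt(mu_m/kappa) / D`` — hydrodynamic interaction length, the
  screening length of one element's forcing in units of the hexagon side D.
* lattice units: ``dx = dt = rho0 = 1``; ``D = resolution`` nodes,
  ``U0 = target_mach * c_s``, ``nu = U0*D/Re``, ``tau = 3*nu + 1/2``,
  ``kappa = rho0*nu/(lambda*D)**2``, ``|f_c| = kappa*U0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import EpitheliumMap

__all__ = [
    "LatticeMapping",
    "SimulationParams",
    "LatticeState",
    "map_to_lattice",
    "element_forces",
    "compute_body_force",
    "lbm_step",
    "solve_frozen_orientations",
    "DEFAULT_MACH",
    "TAU_MIN",
    "TAU_MAX",
]

#: default lattice Mach number; gives U0 = 0.01 in lattice units, so that with
#: Omega = U0/D and resolution 5 the alignment threshold 2*Omega*dt = 0.004 rad
DEFAULT_MACH = np.sqrt(3.0) / 100.0

TAU_MIN, TAU_MAX = 0.55, 2.5


@dataclass(frozen=True)
class LatticeMapping:
    """Derived lattice-unit parameter block (dx = dt = rho0 = 1)."""

    U0: float
    nu: float
    tau: float
    kappa: float
    fc: float
    D: int
    mach: float
    rho0: float = 1.0
    cs: float = float(np.sqrt(_kernels.CS2))


@dataclass(frozen=True)
class SimulationParams:
    """Non-dimensional control set plus its lattice mapping."""

    phi: float
    lambda_: float
    Re: float
    lattice: LatticeMapping
    In: float = 0.0
    domain_elements: tuple[int, int] = (40, 40)
    resolution: int = 5
    seed_geometry: int = 0
    seed_orientation: int = 1
    seed_noise: int = 2
    backend: str = "numba"

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


def map_to_lattice(
    phi: float,
    lambda_: float,
    Re: float = 0.1,
    resolution: int = 5,
    target_mach: float = DEFAULT_MACH,
    **kw,
) -> SimulationParams:
    """Map (phi, lambda, Re) to lattice units and validate the BGK stability window.

    Extra keyword arguments (``In``, ``domain_elements``, seeds, ``backend``)
    are forwarded to :class:`SimulationParams`.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if lambda_ <= 0 or Re <= 0:
        raise ValueError("lambda and Re must be positive")
    if not 0.0 < target_mach <= 0.1:
        raise ValueError("target_mach must lie in (0, 0.1]")
    cs = float(np.sqrt(_kernels.CS2))
    rho0 = 1.0
    D = int(resolution)
    U0 = target_mach * cs
    nu = U0 * D / Re
    tau = 3.0 * nu + 0.5
    if not TAU_MIN < tau < TAU_MAX:
        raise ValueError(
            f"BGK relaxation time tau={tau:.3f} outside the stability window "
            f"({TAU_MIN}, {TAU_MAX}); lower target_mach or the resolution "
            f"(tau = 3*target_mach*c_s*resolution/Re + 1/2)"
        )
    kappa = rho0 * nu / (lambda_ * D) ** 2
    fc = kappa * U0
    # round-trip identities (defining relations must hold simultaneously)
    assert abs(np.sqrt(nu * rho0 / kappa) / D - lambda_) < 1e-12 * max(1, lambda_)
    assert abs(rho0 * D * U0 / (rho0 * nu) - Re) < 1e-12 * max(1, Re)
    assert abs(fc / kappa - U0) < 1e-15
    lat = LatticeMapping(U0=U0, nu=nu, tau=tau, kappa=kappa, fc=fc, D=D, mach=target_mach)
    return SimulationParams(
        phi=phi, lambda_=lambda_, Re=Re, lattice=lat, resolution=D, **kw
    )


@dataclass
class LatticeState:
    """D2Q9 populations and derived macroscopic fields on the periodic grid."""

    f: np.ndarray  # (Nx, Ny, 9) populations
    ux: np.ndarray
    uy: np.ndarray
    rho: np.ndarray
    _scratch: np.ndarray = field(default=None, repr=False)

    @classmethod
    def rest(cls, grid_shape: tuple[int, int], rho0: float = 1.0) -> "LatticeState":
        nx, ny = grid_shape
        f = np.empty((nx, ny, 9))
        f[:, :] = _kernels.W * rho0
        return cls(
            f=f,
            ux=np.zeros((nx, ny)),
            uy=np.zeros((nx, ny)),
            rho=np.full((nx, ny), rho0),
        )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.f.shape[:2]

    def momentum(self) -> np.ndarray:
        """Global bare momentum (sum over nodes of first population moment)."""
        ex = _kernels.EX.astype(float)
        ey = _kernels.EY.astype(float)
        return np.array([(self.f @ ex).sum(), (self.f @ ey).sum()])

    def pressure(self, rho0: float = 1.0) -> np.ndarray:
        """Weakly compressible pressure c_s^2 * (rho - rho0)."""
        return _kernels.CS2 * (self.rho - rho0)


def element_forces(emap: EpitheliumMap, params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-element ciliary force components (zero on passive elements)."""
    n = emap.tiling.n_elements
    fx = np.zeros(n)
    fy = np.zeros(n)
    cil = emap.is_ciliated
    fx[cil] = params.lattice.fc * np.cos(emap.theta_c[cil])
    fy[cil] = params.lattice.fc * np.sin(emap.theta_c[cil])
    return fx, fy


def compute_body_force(
    state: LatticeState, emap: EpitheliumMap, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Total per-node body force f_n = f_v + f_c for the current velocity.

    Friction ``-kappa*U`` acts at every node (the PCL underlies the whole
    mucus film); the ciliary term acts only on nodes owned by ciliated
    elements, with identical magnitude ``|f_c|`` everywhere it acts.
    """
    if state.grid_shape != emap.node_owner.shape:
        raise ValueError("state and epithelium map use different grids")
    fccx, fccy = element_forces(emap, params)
    owner = emap.node_owner
    k = params.lattice.kappa
    return fccx[owner] - k * state.ux, fccy[owner] - k * state.uy


def lbm_step(
    state: LatticeState,
    emap: EpitheliumMap,
    params: SimulationParams,
    element_force: tuple[np.ndarray, np.ndarray] | None = None,
    elem_sums: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """One collide-stream cycle with Guo forcing; updates ``state`` in place.

    Returns the squared L2 change and squared L2 norm of the velocity field,
    for convergence monitoring.  ``elem_sums`` optionally receives per-element
    velocity sums computed in the same pass.  Raises on numerical blow-up.
    """
    if element_force is None:
        element_force = element_forces(emap, params)
    fccx, fccy = element_force
    if state._scratch is None:
        state._scratch = np.empty_like(state.f)
    diff2, norm2 = _kernels.step(
        state.f,
        state._scratch,
        state.ux,
        state.uy,
        state.rho,
        fccx,
        fccy,
        emap.node_owner,
        params.lattice.kappa,
        1.0 / params.lattice.tau,
        backend=params.backend,
        elem_sums=elem_sums,
    )
    state.f, state._scratch = state._scratch, state.f
    if not np.isfinite(diff2):
        mach = float(np.hypot(state.ux, state.uy).max()) / params.lattice.cs
        raise FloatingPointError(
            f"LBM populations diverged (max Mach {mach:.3g}, tau "
            f"{params.lattice.tau:.3f})"
        )
    return diff2, norm2


def solve_frozen_orientations(
    emap: EpitheliumMap,
    params: SimulationParams,
    tolerance: float = 1e-9,
    max_steps: int = 200_000,
    state: LatticeState | None = None,
) -> LatticeState:
    """Iterate the flow to steady state with the beat angles held fixed.

    Convergence is declared when the relative L2 velocity change per step
    drops below ``tolerance``.  Used for solver validation and for
    two-element / single-element screening configurations.
    """
    if state is None:
        state = LatticeState.rest(emap.node_owner.shape, params.lattice.rho0)
    force = element_forces(emap, params)
    history: list[float] = []
    for it in range(max_steps):
        diff2, norm2 = lbm_step(state, emap, params, force)
        if norm2 > 0:
            res = np.sqrt(diff2 / norm2)
            history.append(res)
            if it > 10 and res < tolerance:
                return state
    raise RuntimeError(
        f"frozen-orientation solve did not converge in {max_steps} steps; "
        f"last residuals {history[-5:]}"
    )
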