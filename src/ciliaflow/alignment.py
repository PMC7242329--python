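"""Streamwise-alignment dynamics of the ciliary-beat angles.

Each ciliated element carries a beat angle ``theta_c``.  At every update the
flow velocity is averaged over the element's nodes; if the wrapped angle
difference ``dtheta = theta_f - theta_c`` to the local flow direction
exceeds a small threshold ``theta_0``, the beat angle rotates toward the flow
at fixed angular speed ``Omega`` (sign of ``dtheta``), plus an optional
Gaussian rotational-noise term ``In * eta * dt``.  Within the threshold only
the noise acts, which lets noise-free systems reach exactly steady states.

Defaults follow the flow solver's non-dimensionalization: ``Omega = U0/D``
and ``theta_0 = 2*Omega*dt`` (0.004 rad at the default lattice mapping).
``Omega`` only shapes the transient; steady noise-free organizations do not
depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EpitheliumMap
from .lbm import LatticeState, SimulationParams, element_forces, lbm_step

__all__ = [
    "AlignmentParams",
    "ElementFlowSummary",
    "RunResult",
    "wrap_angle",
    "box_muller",
    "summarize_element_flow",
    "update_orientations",
    "run_to_steady",
    "default_alignment_params",
]

#: fraction of U0 below which an element-averaged flow has no defined angle
EPS_SPEED_FACTOR = 1e-6


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    w = -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)
    return w if np.ndim(a) else float(w)


def box_muller(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standard-normal draws via the Box-Muller transform.

    The basic transform is the primitive used for the rotational noise, so it
    is implemented explicitly rather than through a library normal sampler.
    """
    m = (n + 1) // 2
    u1 = 1.0 - rng.random(m)  # in (0, 1], keeps log finite
    u2 = rng.random(m)
    r = np.sqrt(-2.0 * np.log(u1))
    z = np.concatenate([r * np.cos(2.0 * np.pi * u2), r * np.sin(2.0 * np.pi * u2)])
    return z[:n]


@dataclass(frozen=True)
class AlignmentParams:
    """Parameters of the orientation update law.

    ``dt`` is the orientation time step (in flow-solver steps);
    ``update_stride`` is the number of LBM steps between orientation updates.
    """

    Omega: float
    theta_0: float
    In: float = 0.0
    dt: float = 1.0
    update_stride: int = 1
    eps_speed: float = 0.0  # absolute speed threshold; set from U0 by factory

    def __post_init__(self):
        if self.Omega <= 0 or self.dt <= 0 or self.theta_0 < 0:
            raise ValueError("Omega, dt must be positive; theta_0 non-negative")


def default_alignment_params(
    params: SimulationParams,
    In: float | None = None,
    update_stride: int = 1,
    omega_factor: float = 1.0,
) -> AlignmentParams:
    """Alignment parameters: Omega = omega_factor * U0/D, theta_0 = 2*Omega*dt.

    ``omega_factor`` rescales the (transient-only) alignment angular speed;
    noise-free steady organizations do not depend on it, so ensemble drivers
    may raise it to shorten transients.
    """
    dt = float(update_stride)
    omega = omega_factor * params.lattice.U0 / params.lattice.D
    return AlignmentParams(
        Omega=omega,
        theta_0=2.0 * omega * dt,
        In=params.In if In is None else In,
        dt=dt,
        update_stride=update_stride,
        eps_speed=EPS_SPEED_FACTOR * params.lattice.U0,
    )


@dataclass(frozen=True)
class ElementFlowSummary:
    """Element-averaged flow and its angular offset from the beat directions.

    Quantities are defined on ciliated elements only, in ciliated-index order
    (``emap.ciliated_indices``).
    """

    mean_velocity: np.ndarray  # (n_ciliated, 2)
    theta_f: np.ndarray  # flow angle, NaN where undefined
    delta_theta: np.ndarray  # wrapped theta_f - theta_c, NaN where undefined
    defined: np.ndarray  # |mean_velocity| >= eps_speed


def summary_from_sums(
    sx: np.ndarray,
    sy: np.ndarray,
    counts: np.ndarray,
    emap: EpitheliumMap,
    eps_speed: float = 0.0,
) -> ElementFlowSummary:
    """Build the flow summary from per-element velocity sums and node counts."""
    cil = emap.ciliated_indices
    mean_v = np.column_stack([sx[cil] / counts[cil], sy[cil] / counts[cil]])
    speed = np.hypot(mean_v[:, 0], mean_v[:, 1])
    defined = speed >= eps_speed
    with np.errstate(invalid="ignore"):
        theta_f = np.where(defined, np.arctan2(mean_v[:, 1], mean_v[:, 0]), np.nan)
        dtheta = np.where(defined, wrap_angle(theta_f - emap.theta_c[cil]), np.nan)
    return ElementFlowSummary(mean_v, theta_f, dtheta, defined)


def summarize_element_flow(
    state: LatticeState, emap: EpitheliumMap, eps_speed: float = 0.0
) -> ElementFlowSummary:
    """Average the node velocities over each ciliated element.

    The flow angle is taken from the mean vector (never a mean of angles);
    elements whose mean speed falls below ``eps_speed`` are flagged undefined.
    """
    owner = emap.node_owner.ravel()
    n = emap.tiling.n_elements
    counts = emap.tiling.nodes_per_element()
    sx = np.bincount(owner, weights=state.ux.ravel(), minlength=n)
    sy = np.bincount(owner, weights=state.uy.ravel(), minlength=n)
    return summary_from_sums(sx, sy, counts, emap, eps_speed)


def update_orientations(
    emap: EpitheliumMap,
    summary: ElementFlowSummary,
    ap: AlignmentParams,
    noise_rng: np.random.Generator,
) -> EpitheliumMap:
    """Apply one orientation update; returns a map with the new beat angles.

    Elements with ``|dtheta| > theta_0`` rotate by ``Omega*dt`` toward the
    flow direction (clamped onto ``theta_f`` if the step would overshoot);
    others keep their angle.  Gaussian rotational noise ``In*eta*dt`` is added
    to every ciliated element, including undefined-flow ones.  An exact
    head-on difference ``dtheta = pi`` rotates in a seeded random direction.
    """
    cil = emap.ciliated_indices
    theta = emap.theta_c.copy()
    th = theta[cil].copy()
    d = summary.delta_theta
    with np.errstate(invalid="ignore"):
        move = summary.defined & (np.abs(d) > ap.theta_0)
    if move.any():
        dm = d[move]
        sign = np.sign(dm)
        ties = dm == np.pi  # wrap convention makes -pi unreachable
        if ties.any():
            sign[ties] = np.where(noise_rng.random(int(ties.sum())) < 0.5, -1.0, 1.0)
        step = sign * ap.Omega * ap.dt
        # clamp overshoot onto the flow angle
        step = np.where(np.abs(step) > np.abs(dm), dm, step)
        th[move] = th[move] + step
    changed = move
    if ap.In > 0.0:
        th = th + ap.In * ap.dt * box_muller(noise_rng, th.size)
        changed = np.full_like(move, True)
    # rewrap only what moved, so frozen elements stay bit-identical
    theta[cil] = np.where(changed, wrap_angle(th), theta[cil])
    return emap.with_angles(theta)


@dataclass
class RunResult:
    """Outcome of a coupled flow-orientation run.

    ``mode`` records how the run terminated: ``"steady"`` (strict per-element
    criterion), ``"stationary"`` (order parameters flat over a long window),
    or ``"max_updates"``.
    """

    emap: EpitheliumMap
    state: LatticeState
    params: SimulationParams
    ap: AlignmentParams
    converged: bool
    n_updates: int
    mode: str = "max_updates"
    trace: "pd.DataFrame | None" = None  # type: ignore[name-defined]  # noqa: F821
    polarization_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_to_steady(
    emap: EpitheliumMap,
    params: SimulationParams,
    ap: AlignmentParams | None = None,
    max_updates: int = 60_000,
    K_quiet: int = 50,
    tol_flow: float = 1e-8,
    stat_stride: int = 50,
    stat_window: int = 2_000,
    stat_tol: float = 2e-3,
    moving_tol: float = 0.02,
    state: LatticeState | None = None,
    noise_rng: np.random.Generator | None = None,
) -> RunResult:
    """Alternate flow stepping and orientation updates until steady state.

    Two noise-free termination rules are applied:

    * strict steadiness — for ``K_quiet`` consecutive orientation updates,
      every defined ``|dtheta|`` stays within ``theta_0`` and the relative L2
      velocity-field change per update stays below ``tol_flow``;
    * stationarity window — near threshold the organization can keep creeping
      indefinitely with a handful of elements hovering at ``|dtheta| ~
      theta_0``, so the run is also declared converged when, over the last
      ``stat_window`` updates (sampled every ``stat_stride``), the
      polarization span is below ``stat_tol``, the kinetic energy varies by
      less than ``stat_tol`` relatively, and the mean fraction of still-moving
      elements stays below ``moving_tol``.

    With ``In > 0`` there is no strict steady state; the loop runs to
    ``max_updates`` and reports the final (statistically stationary) window.
    """
    import pandas as pd

    if ap is None:
        ap = default_alignment_params(params)
    if state is None:
        state = LatticeState.rest(emap.node_owner.shape, params.lattice.rho0)
    if noise_rng is None:
        noise_rng = np.random.default_rng(params.seed_noise)
    from .statistics import polarization

    quiet = 0
    converged = False
    mode = "max_updates"
    rows = []
    p_hist = []
    n_window = max(2, stat_window // stat_stride)
    force = element_forces(emap, params)
    n_elem = emap.tiling.n_elements
    counts = emap.tiling.nodes_per_element()
    elem_sums = (np.empty(n_elem), np.empty(n_elem))
    for it in range(1, max_updates + 1):
        diff2 = norm2 = 0.0
        for _ in range(ap.update_stride):
            diff2, norm2 = lbm_step(state, emap, params, force, elem_sums=elem_sums)
        summary = summary_from_sums(elem_sums[0], elem_sums[1], counts, emap, ap.eps_speed)
        emap = update_orientations(emap, summary, ap, noise_rng)
        force = element_forces(emap, params)

        with np.errstate(invalid="ignore"):
            abs_d = np.abs(summary.delta_theta)
            max_d = float(np.nanmax(abs_d)) if summary.defined.any() else 0.0
            mean_d = float(np.nanmean(abs_d)) if summary.defined.any() else 0.0
            moving_frac = float(np.mean(abs_d > ap.theta_0)) if abs_d.size else 0.0
        flow_res = np.sqrt(diff2 / norm2) if norm2 > 0 else np.inf
        if max_d <= ap.theta_0 and flow_res < tol_flow:
            quiet += 1
        else:
            quiet = 0
        if it % stat_stride == 0 or quiet >= K_quiet or it == max_updates:
            p = polarization(state.ux, state.uy, eps_speed=ap.eps_speed)
            p_hist.append(p)
            rows.append(
                {
                    "update": it,
                    "polarization": p,
                    "max_abs_dtheta": max_d,
                    "mean_abs_dtheta": mean_d,
                    "moving_fraction": moving_frac,
                    "flow_residual": flow_res,
                    "kinetic_energy": 0.5 * norm2,
                }
            )
        if ap.In == 0.0:
            if quiet >= K_quiet:
                converged = True
                mode = "steady"
                break
            if len(rows) >= n_window and it % stat_stride == 0:
                win = rows[-n_window:]
                ps = [r["polarization"] for r in win]
                kes = [r["kinetic_energy"] for r in win]
                mvs = [r["moving_fraction"] for r in win]
                ke_mean = np.mean(kes)
                if (
                    max(ps) - min(ps) < stat_tol
                    and (max(kes) - min(kes)) < stat_tol * max(ke_mean, 1e-300)
                    and np.mean(mvs) < moving_tol
                ):
                    converged = True
                    mode = "stationary"
                    break

    trace = pd.DataFrame(rows)
    return RunResult(
        emap=emap,
        state=state,
        params=params,
        ap=ap,
        converged=converged,
        n_updates=it,
        mode=mode,
        trace=trace,
        polarization_history=np.asarray(p_hist),
    )
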