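"""Numerical campaigns and physiological back-of-envelope calculators.

Drivers for the study protocols: the regime phase diagram over (phi, lambda),
swirl-size ensembles with the sparse-occurrence discard rule and the
``Lambda' = lambda^alpha * phi`` scaling fit, the rectangular
"virtual bronchus" alignment series, and the dimensional estimates linking
the model parameters to airway physiology (single-cilium force, PCL
viscosity/thickness, mucus viscosity).

Domain presets: the full square campaign domain holds ~1e4 elements
(100 x 100); a reduced 40 x 40 preset (~1.6e3 elements) is used for
desk-scale runs and tests.  Swirls larger than about a third of the box are
flagged as confined by the statistics layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignment import RunResult, default_alignment_params, run_to_steady
from .geometry import assign_ciliated, build_tiling, initialize_orientations
from .lbm import map_to_lattice
from .statistics import (
    CorrelationProfile,
    RegimeRecord,
    SwirlSize,
    autocorrelation,
    classify_regime,
    integral_length,
    polarization,
    swirl_size,
    vorticity_field,
)

__all__ = [
    "PRESETS",
    "SweepSpec",
    "PhysiologyParams",
    "ScalingFit",
    "spawn_run_seeds",
    "simulate_run",
    "phase_diagram",
    "swirl_ensemble",
    "fit_scaling",
    "bronchus_alignment",
    "mean_velocity_prediction",
    "physiological_lambda",
    "physiological_forcing",
]

#: named domain presets (element counts); "full" is the ~1e4-element square
PRESETS: dict[str, tuple[int, int]] = {"full": (100, 100), "reduced": (40, 40)}


def spawn_run_seeds(master_seed: int, run_index: int) -> tuple[int, int, int]:
    """Counter-based (geometry, orientation, noise) seed triple for one run."""
    ss = np.random.SeedSequence([int(master_seed), int(run_index)])
    g, o, n = ss.generate_state(3) % np.uint32(2**31)
    return int(g), int(o), int(n)


def simulate_run(
    phi: float,
    lambda_: float,
    domain_elements: tuple[int, int] = PRESETS["reduced"],
    seeds: tuple[int, int, int] = (0, 1, 2),
    Re: float = 0.1,
    In: float = 0.0,
    resolution: int = 5,
    max_updates: int = 60_000,
    update_stride: int = 1,
    omega_factor: float = 1.0,
    backend: str = "numba",
) -> tuple[RunResult, RegimeRecord, CorrelationProfile | None]:
    """One fully coupled run: geometry, random init, run to steady, classify.

    Returns the raw run result, its regime record, and the vorticity
    autocorrelation profile (None for a strictly uniform flow).
    ``omega_factor`` rescales the transient-only alignment speed Omega.
    """
    sg, so, sn = seeds
    params = map_to_lattice(
        phi,
        lambda_,
        Re,
        resolution=resolution,
        In=In,
        domain_elements=tuple(domain_elements),
        seed_geometry=sg,
        seed_orientation=so,
        seed_noise=sn,
        backend=backend,
    )
    tiling = build_tiling(*domain_elements, resolution=resolution)
    emap = initialize_orientations(assign_ciliated(tiling, phi, sg), so)
    ap = default_alignment_params(
        params, update_stride=update_stride, omega_factor=omega_factor
    )
    result = run_to_steady(emap, params, ap, max_updates=max_updates)

    lat = params.lattice
    p = polarization(result.state.ux, result.state.uy, eps_speed=ap.eps_speed)
    omega = vorticity_field(result.state.ux, result.state.uy, lat.D, lat.U0)
    if float(np.mean(omega**2)) > 0.0:
        profile = autocorrelation(omega)
        lam_int, mode = integral_length(profile, lambda_, lat.D)
    else:
        profile, lam_int, mode = None, 0.0, "zero_vorticity"
    record = RegimeRecord(
        phi=phi,
        lambda_=lambda_,
        polarization=p,
        integral_length=lam_int,
        label=classify_regime(p, lam_int),
        converged=result.converged,
        n_updates=result.n_updates,
        seed_geometry=sg,
        seed_orientation=so,
        seed_noise=sn,
        truncation=mode,
    )
    return result, record, profile


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for the phase-diagram sweep."""

    phi_values: tuple[float, ...]
    lambda_values: tuple[float, ...]
    Re: float = 0.1
    In: float = 0.0
    repeats: int = 10
    domain_elements: tuple[int, int] = PRESETS["reduced"]
    master_seed: int = 0
    max_updates: int = 60_000
    omega_factor: float = 1.0

    def __post_init__(self):
        if self.repeats < 1 or not self.phi_values or not self.lambda_values:
            raise ValueError("repeats >= 1 and non-empty phi/lambda grids required")


def phase_diagram(spec: SweepSpec) -> pd.DataFrame:
    """Most-frequent regime (and its occurrence frequency) per (phi, lambda).

    ``repeats`` randomly initialized runs are tallied at each grid point;
    non-converged runs are counted separately and excluded from the tally.
    """
    rows = []
    run_idx = 0
    for lam in spec.lambda_values:
        for phi in spec.phi_values:
            labels = []
            n_unconverged = 0
            for _ in range(spec.repeats):
                seeds = spawn_run_seeds(spec.master_seed, run_idx)
                run_idx += 1
                _, rec, _ = simulate_run(
                    phi,
                    lam,
                    domain_elements=spec.domain_elements,
                    seeds=seeds,
                    Re=spec.Re,
                    In=spec.In,
                    max_updates=spec.max_updates,
                    omega_factor=spec.omega_factor,
                )
                if rec.converged or spec.In > 0:
                    labels.append(rec.label)
                else:
                    n_unconverged += 1
            if labels:
                modal, count = Counter(labels).most_common(1)[0]
                freq = count / len(labels)
            else:
                modal, freq = "unconverged", np.nan
            rows.append(
                {
                    "phi": phi,
                    "lambda": lam,
                    "modal_label": modal,
                    "frequency": freq,
                    "n_tallied": len(labels),
                    "n_unconverged": n_unconverged,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnsembleSwirl:
    """Swirl-size measurement over a seeded ensemble at one (phi, lambda)."""

    phi: float
    lambda_: float
    swirl: SwirlSize | None
    n_selected: int
    n_runs: int
    discarded: bool
    records: tuple[RegimeRecord, ...] = field(default=(), repr=False)


def swirl_ensemble(
    phi: float,
    lambda_: float,
    n_runs: int = 25,
    min_swirly: int = 10,
    domain_elements: tuple[int, int] = (60, 60),
    master_seed: int = 0,
    require_swirly: bool = True,
    max_updates: int = 60_000,
    Re: float = 0.1,
    resolution: int = 5,
    omega_factor: float = 1.0,
) -> EnsembleSwirl:
    """Ensemble swirl size Lambda' from randomly initialized runs.

    With ``require_swirly`` (the campaign protocol) only swirly-classified
    runs enter the average, and the point is discarded when fewer than
    ``min_swirly`` occur.  With ``require_swirly=False`` all converged runs
    contribute — the measurement applied to the localized recirculations of
    the poorly organized state at low density.
    """
    if n_runs < min_swirly:
        raise ValueError("n_runs must be at least min_swirly")
    profiles, records = [], []
    for i in range(n_runs):
        seeds = spawn_run_seeds(master_seed, i)
        _, rec, prof = simulate_run(
            phi,
            lambda_,
            domain_elements=domain_elements,
            seeds=seeds,
            Re=Re,
            resolution=resolution,
            max_updates=max_updates,
            omega_factor=omega_factor,
        )
        records.append(rec)
        if prof is None:
            continue
        if (not require_swirly) or rec.label == "swirly":
            profiles.append(prof)
    if require_swirly and len(profiles) < min_swirly:
        return EnsembleSwirl(phi, lambda_, None, len(profiles), n_runs, True, tuple(records))
    sz = swirl_size(profiles, D=resolution)
    return EnsembleSwirl(phi, lambda_, sz, len(profiles), n_runs, False, tuple(records))


@dataclass(frozen=True)
class ScalingFit:
    """Result of fitting Lambda' = lambda^alpha * phi over ensemble points."""

    alpha: float
    residual: float
    slope: float
    fit_points: tuple[tuple[float, float, float], ...]


def _collapse_residual(alpha: float, phi: np.ndarray, lam: np.ndarray, lp: np.ndarray):
    y = lp / lam**alpha
    slope = float((phi * y).sum() / (phi * phi).sum())
    return float(np.sqrt(np.mean((y - slope * phi) ** 2))), slope


def fit_scaling(triples: list[tuple[float, float, float]]) -> ScalingFit:
    """Exponent alpha minimizing the RMS deviation of Lambda'/lambda^alpha
    from a single line through the origin in phi.

    The 1D objective is minimized by bounded golden-section/Brent search over
    alpha in [0, 4].  Requires at least three distinct lambda values, or the
    exponent is unidentifiable.
    """
    pts = [(float(p), float(l), float(s)) for p, l, s in triples]
    phi = np.array([p for p, _, _ in pts])
    lam = np.array([l for _, l, _ in pts])
    lp = np.array([s for _, _, s in pts])
    if np.unique(lam).size < 3:
        raise ValueError("exponent unidentifiable: need >= 3 distinct lambda values")
    res = minimize_scalar(
        lambda a: _collapse_residual(a, phi, lam, lp)[0],
        bounds=(0.0, 4.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rms, slope = _collapse_residual(res.x, phi, lam, lp)
    return ScalingFit(alpha=float(res.x), residual=rms, slope=slope, fit_points=tuple(pts))


def bronchus_alignment(
    aspect_ratios: tuple[float, ...] = (1.0, 2.0, 3.0),
    n_runs: int = 32,
    phi: float = 0.4,
    lambda_: float = 5.0,
    Ly_elements: int = 29,
    master_seed: int = 0,
    max_updates: int = 60_000,
    omega_factor: float = 1.0,
) -> pd.DataFrame:
    """Virtual-bronchus series: mean-flow angles in rectangular periodic boxes.

    ``Ly_elements = 29`` rows give Ly/D ~ 50; the x extent is scaled to each
    aspect ratio (hexagon columns rounded to the nearest even count).  The
    summary per ratio is the fraction of runs whose space-averaged flow
    direction lies within +/-45 deg of the long (x) axis; the raw angle census
    (with each run's regime label) is returned so other summaries can be
    derived.
    """
    rows = []
    run_idx = 0
    for ratio in aspect_ratios:
        if ratio < 1:
            raise ValueError("aspect ratios must be >= 1 (long axis along x)")
        nx = 2 * round(ratio * Ly_elements * np.sqrt(3.0) / 3.0)
        for _ in range(n_runs):
            seeds = spawn_run_seeds(master_seed, run_idx)
            run_idx += 1
            result, rec, _ = simulate_run(
                phi,
                lambda_,
                domain_elements=(nx, Ly_elements),
                seeds=seeds,
                max_updates=max_updates,
                omega_factor=omega_factor,
            )
            angle = float(np.arctan2(result.state.uy.mean(), result.state.ux.mean()))
            along_x = min(abs(angle), np.pi - abs(angle)) <= np.pi / 4.0
            rows.append(
                {
                    "aspect_ratio": ratio,
                    "nx_elements": nx,
                    "ny_elements": Ly_elements,
                    "mean_flow_angle": angle,
                    "within_45deg_of_x": along_x,
                    "label": rec.label,
                    "converged": rec.converged,
                    "seed_geometry": rec.seed_geometry,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# physiological calculators
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysiologyParams:
    """Dimensional airway parameters for the back-of-envelope estimates.

    Defaults: single-cilium force F = 6e-11 N, n_c = 250 cilia per ciliated
    cell of radius 2.5e-6 m, PCL viscosity ~1e-3 Pa s (water-like) and
    thickness ~1e-5 m, element (ciliary patch) size D = 2e-5 m, mucus
    viscosity 1e-2 Pa s (lower end of the reported range).
    """

    F: float = 6e-11
    n_c: int = 250
    R_cell: float = 2.5e-6
    mu_p: float = 1e-3
    delta_p: float = 1e-5
    mu_m: float = 1e-2
    D_patch: float = 2e-5

    def __post_init__(self):
        vals = (self.F, self.n_c, self.R_cell, self.mu_p, self.delta_p, self.mu_m, self.D_patch)
        if any(v <= 0 for v in vals):
            raise ValueError("all physiological parameters must be positive")


def physiological_lambda(pp: PhysiologyParams = PhysiologyParams()) -> float:
    """Interaction length estimate lambda = (delta_p / D) * sqrt(mu_m / mu_p)."""
    return (pp.delta_p / pp.D_patch) * np.sqrt(pp.mu_m / pp.mu_p)


def physiological_forcing(pp: PhysiologyParams = PhysiologyParams()) -> tuple[float, float, float]:
    """Ciliary force density, PCL friction coefficient and velocity scale.

    ``|f_c| = F*n_c/(2*pi*R^2)`` (the time-averaged propulsion of one cilium
    is F/2 — force is transmitted only during the power stroke — spread over
    the cell area pi*R^2); ``kappa = mu_p/delta_p^2``; ``U0 = |f_c|/kappa``.
    """
    fc = pp.F * pp.n_c / (2.0 * np.pi * pp.R_cell**2)
    kappa = pp.mu_p / pp.delta_p**2
    return fc, kappa, fc / kappa


def mean_velocity_prediction(fc_magnitude: float, kappa: float, phi: float) -> float:
    """Uniform-regime mean transport speed |U| = (|f_c|/kappa) * phi.

    Follows from the global momentum balance between the ciliary forcing on
    the ciliated fraction phi and the PCL friction over the whole surface.
    """
    if fc_magnitude <= 0 or kappa <= 0:
        raise ValueError("force magnitude and friction must be positive")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return fc_magnitude / kappa * phi
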