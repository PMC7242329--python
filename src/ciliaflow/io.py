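"""Configuration files, HDF5 snapshots and deterministic test fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

import h5py
import numpy as np
import yaml

from .geometry import EpitheliumMap, HexTiling, build_tiling
from .lbm import DEFAULT_MACH, LatticeState, SimulationParams, map_to_lattice
from .statistics import CorrelationProfile

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "write_snapshot",
    "read_snapshot",
    "element_table",
    "SNAPSHOT_SCHEMA_VERSION",
]

SNAPSHOT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Validated, serializable description of one simulation run."""

    phi: float = 0.4
    lambda_: float = 2.0
    Re: float = 0.1
    In: float = 0.0
    domain_elements: tuple[int, int] = (40, 40)
    resolution: int = 5
    target_mach: float = float(DEFAULT_MACH)
    seed_geometry: int = 0
    seed_orientation: int = 1
    seed_noise: int = 2
    update_stride: int = 1
    max_updates: int = 20_000
    K_quiet: int = 50
    tol_flow: float = 1e-8
    verbosity: str = "info"

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.Re <= 0:
            raise ValueError("Re must be positive")
        if self.In < 0:
            raise ValueError("noise intensity In must be non-negative")
        if len(self.domain_elements) != 2 or min(self.domain_elements) < 2:
            raise ValueError("domain_elements must be a pair of counts >= 2")
        if self.resolution < 3:
            raise ValueError("resolution must be >= 3")
        if self.update_stride < 1 or self.max_updates < 1 or self.K_quiet < 1:
            raise ValueError("strides and counters must be positive")

    def to_params(self) -> SimulationParams:
        return map_to_lattice(
            self.phi,
            self.lambda_,
            self.Re,
            resolution=self.resolution,
            target_mach=self.target_mach,
            In=self.In,
            domain_elements=tuple(self.domain_elements),
            seed_geometry=self.seed_geometry,
            seed_orientation=self.seed_orientation,
            seed_noise=self.seed_noise,
        )


def save_config(cfg: RunConfig, path) -> None:
    d = asdict(cfg)
    d["domain_elements"] = list(d["domain_elements"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "domain_elements" in raw:
        raw["domain_elements"] = tuple(raw["domain_elements"])
    return RunConfig(**raw)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def _map_with_elements(
    tiling: HexTiling, indices: np.ndarray, angles: np.ndarray
) -> EpitheliumMap:
    is_cil = np.zeros(tiling.n_elements, dtype=bool)
    is_cil[indices] = True
    theta = np.full(tiling.n_elements, np.nan)
    theta[indices] = angles
    return EpitheliumMap(tiling, is_cil, theta, phi_realized=len(indices) / tiling.n_elements)


def make_fixture(name: str, **kw):
    """Deterministic small geometries plus closed-form oracle fields.

    Fixtures
    --------
    ``two_element``
        Two ciliated elements three element-columns apart in a small periodic
        box, frozen beat angles 3*pi/4 and pi/4; used with the frozen-angle
        solver to probe the screening role of lambda.
    ``uniform_forcing``
        Every element ciliated at a common angle; steady solution is the
        uniform flow U0 in that direction.
    ``single_element``
        One ciliated element at the domain center; probes the screened
        (Brinkman-type) radial decay of an isolated element's flow.
    ``taylor_green``
        No geometry; returns an analytic doubly periodic velocity field and
        its exact curl as discretization oracles.
    ``synthetic_swirl_profile``
        Damped-cosine correlation profile with a constructed first zero.

    Returns ``(EpitheliumMap | None, oracle dict)``.
    """
    if name == "two_element":
        nx = kw.get("nx_elements", 12)
        ny = kw.get("ny_elements", 8)
        resolution = kw.get("resolution", 5)
        angles = np.asarray(kw.get("angles", (3 * np.pi / 4, np.pi / 4)), dtype=float)
        tiling = build_tiling(nx, ny, resolution)
        row = ny // 2
        # same row, four columns apart (center distance 6D along x): far
        # enough that at lambda = 1 each element's own forcing dominates
        want = [(nx // 2 - 3, row), (nx // 2 + 1, row)]
        ax = tiling.element_axial_index
        idx = np.array(
            [np.flatnonzero((ax[:, 0] == c) & (ax[:, 1] == r))[0] for c, r in want]
        )
        emap = _map_with_elements(tiling, idx, angles)
        return emap, {"element_indices": idx, "angles": angles}
    if name == "uniform_forcing":
        nx = kw.get("nx_elements", 8)
        ny = kw.get("ny_elements", 8)
        resolution = kw.get("resolution", 5)
        angle = kw.get("angle", 0.0)
        tiling = build_tiling(nx, ny, resolution)
        idx = np.arange(tiling.n_elements)
        emap = _map_with_elements(tiling, idx, np.full(tiling.n_elements, angle))
        return emap, {"angle": angle}
    if name == "single_element":
        nx = kw.get("nx_elements", 24)
        ny = kw.get("ny_elements", 24)
        resolution = kw.get("resolution", 5)
        angle = kw.get("angle", 0.0)
        tiling = build_tiling(nx, ny, resolution)
        center = np.array(tiling.grid_shape, dtype=float) / 2.0
        d = tiling.element_centers - center
        idx = np.array([int(np.argmin((d**2).sum(axis=1)))])
        emap = _map_with_elements(tiling, idx, np.array([angle]))
        return emap, {"element_index": int(idx[0]), "center": tiling.element_centers[idx[0]]}
    if name == "taylor_green":
        n = kw.get("n", 128)
        amp = kw.get("amplitude", 0.01)
        k = 2.0 * np.pi / n
        x = np.arange(n)[:, None]
        y = np.arange(n)[None, :]
        ux = amp * np.sin(k * x) * np.cos(k * y)
        uy = -amp * np.cos(k * x) * np.sin(k * y)
        curl = 2.0 * amp * k * np.sin(k * x) * np.sin(k * y)
        return None, {"ux": ux, "uy": uy, "curl": curl, "wavenumber": k}
    if name == "synthetic_swirl_profile":
        zero_at_D = kw.get("zero_at", 20.0)
        D = kw.get("D", 5)
        n_lags = kw.get("n_lags", int(8 * zero_at_D * D))
        lags = np.arange(n_lags, dtype=float)
        r = np.cos(np.pi * lags / (2.0 * zero_at_D * D)) * np.exp(-lags / (100.0 * D))
        profile = CorrelationProfile(lags=lags, Rx=r.copy(), Ry=r.copy())
        return None, {"profile": profile, "first_zero_D": zero_at_D, "D": D}
    raise ValueError(f"unknown fixture name: {name!r}")


def element_table(emap: EpitheliumMap):
    """Per-element inspection table (centers in units of D, labels, angles)."""
    import pandas as pd

    t = emap.tiling
    return pd.DataFrame(
        {
            "element": np.arange(t.n_elements),
            "col": t.element_axial_index[:, 0],
            "row": t.element_axial_index[:, 1],
            "x_D": t.element_centers[:, 0] / t.side_nodes,
            "y_D": t.element_centers[:, 1] / t.side_nodes,
            "is_ciliated": emap.is_ciliated,
            "theta_c": emap.theta_c,
            "n_nodes": t.nodes_per_element(),
        }
    )


# --------------------------------------------------------------------------
# snapshots
# --------------------------------------------------------------------------


def write_snapshot(path, state: LatticeState, emap: EpitheliumMap, params: SimulationParams) -> None:
    """Lossless HDF5 snapshot of populations, fields, geometry and parameters."""
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SNAPSHOT_SCHEMA_VERSION
        h5.attrs["params_json"] = json.dumps(
            {
                "phi": params.phi,
                "lambda_": params.lambda_,
                "Re": params.Re,
                "In": params.In,
                "domain_elements": list(params.domain_elements),
                "resolution": params.resolution,
                "target_mach": params.lattice.mach,
                "seed_geometry": params.seed_geometry,
                "seed_orientation": params.seed_orientation,
                "seed_noise": params.seed_noise,
                "backend": params.backend,
            }
        )
        h5.attrs["tiling_elements"] = [emap.tiling.nx_elements, emap.tiling.ny_elements]
        h5.attrs["tiling_resolution"] = emap.tiling.side_nodes
        h5.create_dataset("populations", data=state.f)
        h5.create_dataset("ux", data=state.ux)
        h5.create_dataset("uy", data=state.uy)
        h5.create_dataset("rho", data=state.rho)
        h5.create_dataset("theta_c", data=emap.theta_c)
        h5.create_dataset("is_ciliated", data=emap.is_ciliated)
        h5.create_dataset("element_centers", data=emap.tiling.element_centers)


def read_snapshot(path) -> tuple[LatticeState, EpitheliumMap, SimulationParams]:
    """Rebuild a run's state, epithelium map and parameters from a snapshot."""
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs["schema_version"])
        if version != SNAPSHOT_SCHEMA_VERSION:
            raise ValueError(
                f"snapshot schema version {version} not supported "
                f"(expected {SNAPSHOT_SCHEMA_VERSION}); no migration available"
            )
        meta = json.loads(h5.attrs["params_json"])
        til_nx, til_ny = (int(v) for v in h5.attrs["tiling_elements"])
        til_res = int(h5.attrs["tiling_resolution"])
        f = h5["populations"][...]
        ux = h5["ux"][...]
        uy = h5["uy"][...]
        rho = h5["rho"][...]
        theta = h5["theta_c"][...]
        is_cil = h5["is_ciliated"][...]
    params = map_to_lattice(
        meta["phi"],
        meta["lambda_"],
        meta["Re"],
        resolution=meta["resolution"],
        target_mach=meta["target_mach"],
        In=meta["In"],
        domain_elements=tuple(meta["domain_elements"]),
        seed_geometry=meta["seed_geometry"],
        seed_orientation=meta["seed_orientation"],
        seed_noise=meta["seed_noise"],
        backend=meta["backend"],
    )
    tiling = build_tiling(til_nx, til_ny, resolution=til_res)
    if tiling.grid_shape != f.shape[:2]:
        raise ValueError("snapshot fields inconsistent with stored tiling geometry")
    emap = EpitheliumMap(
        tiling, is_cil, theta, phi_realized=float(is_cil.sum()) / tiling.n_elements
    )
    state = LatticeState(f=f, ux=ux, uy=uy, rho=rho)
    return state, emap, params
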