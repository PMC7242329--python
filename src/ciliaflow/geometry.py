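"""Periodic hexagonal epithelium geometry.

The epithelial surface is discretized into flat-top hexagonal unit elements of
side length ``D``; each element represents a multi-ciliated cell or a small
group of cells with a joint beating direction, or a passive (club/goblet)
cell.  Elements are rasterized onto the uniform Cartesian flow grid (spacing
``dn = D/resolution``) by periodic nearest-center (Voronoi) assignment, so the
tiling is exactly space-filling: every fluid node belongs to one element.

All lengths inside this module are expressed in lattice units (one grid
spacing = 1), with ``side_nodes = resolution`` playing the role of ``D``.

Because the vertical hexagon pitch ``sqrt(3)*D`` is irrational in grid units,
the domain height is rounded to the nearest integer node count and the row
pitch stretched accordingly (relative distortion < 1% for the domain sizes
used here); the Voronoi rasterization keeps the partition exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "HexTiling",
    "EpitheliumMap",
    "build_tiling",
    "assign_ciliated",
    "initialize_orientations",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class HexTiling:
    """Periodic flat-top hexagonal tiling rasterized on a Cartesian grid.

    Attributes
    ----------
    element_centers : (n_elements, 2) float array, lattice units.
    element_axial_index : (n_elements, 2) int array, (column, row) index.
    side_nodes : hexagon side length D in grid spacings (= resolution).
    grid_shape : (Nx, Ny) node counts of the underlying Cartesian grid.
    nx_elements, ny_elements : element counts along x (columns) and y (rows).
    node_owner : (Nx, Ny) int32 array, owning element index per grid node.
    """

    element_centers: np.ndarray
    element_axial_index: np.ndarray
    side_nodes: int
    grid_shape: tuple[int, int]
    nx_elements: int
    ny_elements: int
    node_owner: np.ndarray = field(repr=False)

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    @property
    def domain_extent_D(self) -> tuple[float, float]:
        """Domain size (Lx, Ly) in units of the hexagon side D."""
        return (
            self.grid_shape[0] / self.side_nodes,
            self.grid_shape[1] / self.side_nodes,
        )

    def nodes_per_element(self) -> np.ndarray:
        """Owned-node count per element (sums to the total node count)."""
        return np.bincount(self.node_owner.ravel(), minlength=self.n_elements)


@dataclass(frozen=True)
class EpitheliumMap:
    """Ciliated/passive labelling and beat angles on a :class:`HexTiling`.

    ``theta_c`` holds the ciliary-beat angle (radians, wrapped to (-pi, pi])
    for ciliated elements and NaN for passive ones.
    """

    tiling: HexTiling
    is_ciliated: np.ndarray
    theta_c: np.ndarray
    phi_realized: float

    @property
    def node_owner(self) -> np.ndarray:
        return self.tiling.node_owner

    @property
    def n_ciliated(self) -> int:
        return int(self.is_ciliated.sum())

    @property
    def ciliated_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_ciliated)

    def with_angles(self, theta_c: np.ndarray) -> "EpitheliumMap":
        """Copy of the map with replaced beat angles."""
        theta = np.asarray(theta_c, dtype=float)
        if theta.shape != self.theta_c.shape:
            raise ValueError("theta_c shape mismatch")
        return EpitheliumMap(self.tiling, self.is_ciliated, theta, self.phi_realized)


def build_tiling(nx_elements: int, ny_elements: int, resolution: int = 5) -> HexTiling:
    """Build a periodic hexagonal tiling and rasterize it on the flow grid.

    Parameters
    ----------
    nx_elements, ny_elements
        Number of hexagon columns / rows.  ``nx_elements`` must be even so
        that the alternating column offset wraps seamlessly.
    resolution
        Grid nodes per hexagon side (``dn = D/resolution``); the default 5
        gives ~65 fluid nodes per element.
    """
    if nx_elements < 2 or ny_elements < 2:
        raise ValueError("need at least 2x2 elements for a periodic tiling")
    if resolution < 3:
        raise ValueError("resolution must be >= 3 nodes per hexagon side")
    if nx_elements % 2 != 0:
        raise ValueError(
            "nx_elements must be even: flat-top hexagon columns alternate a "
            "half-pitch vertical offset, so an odd column count cannot wrap "
            "periodically"
        )
    d = int(resolution)
    # column pitch 1.5*D; total width 1.5*D*nx is integer because nx is even
    nx_nodes = (3 * d * nx_elements) // 2
    # row pitch sqrt(3)*D, rounded to the nearest commensurate node count
    ny_nodes = int(round(_SQRT3 * d * ny_elements))
    row_pitch = ny_nodes / ny_elements

    cols = np.arange(nx_elements)
    rows = np.arange(ny_elements)
    ci, ri = np.meshgrid(cols, rows, indexing="ij")
    ci = ci.ravel()
    ri = ri.ravel()
    cx = 1.5 * d * ci
    cy = row_pitch * (ri + 0.5 * (ci % 2))
    centers = np.column_stack([cx, cy])
    axial = np.column_stack([ci, ri]).astype(np.int64)

    node_owner = _rasterize(centers, nx_nodes, ny_nodes)
    return HexTiling(
        element_centers=centers,
        element_axial_index=axial,
        side_nodes=d,
        grid_shape=(nx_nodes, ny_nodes),
        nx_elements=nx_elements,
        ny_elements=ny_elements,
        node_owner=node_owner,
    )


def _rasterize(centers: np.ndarray, nx: int, ny: int) -> np.ndarray:
    """Periodic nearest-center assignment; ties go to the lowest element index."""
    tree = cKDTree(centers, boxsize=(nx, ny))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([ix.ravel(), iy.ravel()]).astype(float)
    k = min(4, centers.shape[0])
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        owner = idx
    else:
        # deterministic tie-break: among centers equidistant to the nearest
        # (within 1e-9), keep the lowest element index
        tied = dist <= dist[:, :1] + 1e-9
        masked = np.where(tied, idx, centers.shape[0])
        owner = masked.min(axis=1)
    return owner.reshape(nx, ny).astype(np.int32)


def assign_ciliated(tiling: HexTiling, phi: float, seed: int) -> EpitheliumMap:
    """Flag ``round(phi * n_elements)`` elements as ciliated, uniformly at random.

    The realized ciliated-area fraction equals the element-count fraction by
    space-filling of the tiling, and differs from the request by at most one
    element.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"ciliary density phi must lie in [0, 1], got {phi}")
    n = tiling.n_elements
    n_cil = int(round(phi * n))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_cil, replace=False)
    is_cil = np.zeros(n, dtype=bool)
    is_cil[chosen] = True
    theta = np.full(n, np.nan)
    return EpitheliumMap(tiling, is_cil, theta, phi_realized=n_cil / n)


def initialize_orientations(emap: EpitheliumMap, seed: int) -> EpitheliumMap:
    """Draw independent uniform beat angles on (-pi, pi] for ciliated elements."""
    if emap.n_ciliated < 1:
        raise ValueError("map has no ciliated elements to orient")
    rng = np.random.default_rng(seed)
    theta = np.full(emap.tiling.n_elements, np.nan)
    # uniform on (-pi, pi]: pi - U*2*pi with U in [0, 1)
    theta[emap.is_ciliated] = np.pi - rng.random(emap.n_ciliated) * (2.0 * np.pi)
    return emap.with_angles(theta)
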