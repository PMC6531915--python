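"""Regular hexahedral tissue grids: labels, fibers, layers, conductivities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LABEL_BZ, LABEL_FIBROSIS, LABEL_SCAR, VoxelVolume

LAYER_ENDO = 0
LAYER_M = 1
LAYER_EPI = 2

DEFAULT_LAYER_FRACTIONS = (0.17, 0.41, 0.42)


@dataclass
class TissueGrid:
    """A regular hexahedral grid of cardiac tissue.

    Elements (cells) carry the tissue label, fiber unit vector, transmural
    layer and the conductivity pair (sigma_l, sigma_t, in S/m).  Nodes are
    the element corners; element (i, j, k) spans
    ``origin + dx*[i, i+1] x [j, j+1] x [k, k+1]``.
    """

    shape: tuple[int, int, int]  # elements per axis
    dx: float  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: np.ndarray = field(default=None)
    fiber: np.ndarray = field(default=None)  # (nx, ny, nz, 3)
    layer: np.ndarray = field(default=None)
    sigma_l: np.ndarray = field(default=None)
    sigma_t: np.ndarray = field(default=None)

    def __post_init__(self):
        nx, ny, nz = self.shape
        if self.dx <= 0:
            raise ValueError("element edge length must be positive")
        if self.label is None:
            self.label = np.zeros(self.shape, dtype=np.int8)
        if self.fiber is None:
            f = np.zeros(self.shape + (3,))
            f[..., 0] = 1.0
            self.fiber = f
        if self.layer is None:
            self.layer = np.full(self.shape, LAYER_EPI, dtype=np.int8)
        if self.sigma_l is None:
            self.sigma_l = np.zeros(self.shape)
        if self.sigma_t is None:
            self.sigma_t = np.zeros(self.shape)

    @property
    def n_elements(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def node_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        return (nx + 1, ny + 1, nz + 1)

    @property
    def n_nodes(self) -> int:
        a, b, c = self.node_shape
        return a * b * c

    def element_centroids(self) -> np.ndarray:
        """(n_elements, 3) centroid coordinates in mm (C order)."""
        nx, ny, nz = self.shape
        ox, oy, oz = self.origin
        x = ox + (np.arange(nx) + 0.5) * self.dx
        y = oy + (np.arange(ny) + 0.5) * self.dx
        z = oz + (np.arange(nz) + 0.5) * self.dx
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 3) node coordinates in mm (C order over (i, j, k))."""
        a, b, c = self.node_shape
        ox, oy, oz = self.origin
        x = ox + np.arange(a) * self.dx
        y = oy + np.arange(b) * self.dx
        z = oz + np.arange(c) * self.dx
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def conducting(self) -> np.ndarray:
        """Boolean element mask of the conducting domain (non-scar)."""
        return self.label != LABEL_SCAR

    def validate(self):
        cond = self.conducting()
        norms = np.linalg.norm(self.fiber[cond], axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fiber vectors on conducting elements must be unit norm")
        if np.any(self.sigma_t[cond] <= 0) or np.any(
            self.sigma_l[cond] < self.sigma_t[cond] - 1e-12
        ):
            raise ValueError("conducting elements need sigma_l >= sigma_t > 0")


def map_voxel_values(volume: VoxelVolume, grid: TissueGrid, values: np.ndarray | None = None) -> np.ndarray:
    """Sample a voxel volume at element centroids (containing-voxel rule).

    Each element receives the value of the voxel that contains its
    centroid.  ``values`` defaults to the volume's intensity data; pass a
    label volume to transfer labels.  Raises if any centroid falls outside
    the volume.
    """
    data = volume.data if values is None else np.asarray(values)
    cent = grid.element_centroids() - np.asarray(volume.origin)
    idx = np.floor(cent / volume.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(data.shape)):
        raise ValueError("element centroid outside the voxel volume")
    out = data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out.reshape(grid.shape)


def apply_label_volume(volume: VoxelVolume, labels: np.ndarray, grid: TissueGrid) -> TissueGrid:
    """Assign voxel labels to grid elements by centroid containment."""
    grid.label = map_voxel_values(volume, grid, values=labels).astype(np.int8)
    return grid


def assign_fibrosis(grid: TissueGrid, intensities: np.ndarray, level_pct: float) -> TissueGrid:
    """Relabel the brightest ``level_pct`` % of BZ elements as fibrosis.

    Exactly ``round(level_pct/100 * N_BZ)`` border-zone elements are
    selected in descending mapped intensity (ties broken by ascending
    element linear index), deterministically.
    """
    if not 0.0 <= level_pct <= 100.0:
        raise ValueError("fibrosis level must be in [0, 100] %")
    intens = np.asarray(intensities).reshape(-1)
    lab = grid.label.reshape(-1)
    bz_idx = np.nonzero(lab == LABEL_BZ)[0]
    n_sel = int(round(level_pct / 100.0 * bz_idx.size))
    if n_sel > 0:
        # stable sort on (-intensity, index): mergesort keeps index order on ties
        order = np.argsort(-intens[bz_idx], kind="stable")
        chosen = bz_idx[order[:n_sel]]
        lab[chosen] = LABEL_FIBROSIS
    grid.label = lab.reshape(grid.shape)
    return grid


def assign_transmural_layers(
    grid: TissueGrid,
    fractions: tuple[float, float, float] = DEFAULT_LAYER_FRACTIONS,
    depth_axis: int = 2,
) -> TissueGrid:
    """Partition the wall into endo/M/epi layers by normalized depth.

    ``fractions`` are the endo/M/epi thickness fractions (defaults
    17/41/42 % of wall thickness); depth runs from 0 (endocardium) to 1
    (epicardium) along ``depth_axis``.
    """
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError("layer fractions must sum to 1")
    n = grid.shape[depth_axis]
    if n == 0:
        raise ValueError("zero-thickness wall")
    depth = (np.arange(n) + 0.5) / n
    cut1, cut2 = fractions[0], fractions[0] + fractions[1]
    layer_line = np.full(n, LAYER_EPI, dtype=np.int8)
    layer_line[depth < cut2] = LAYER_M
    layer_line[depth < cut1] = LAYER_ENDO
    shape = [1, 1, 1]
    shape[depth_axis] = n
    grid.layer = np.broadcast_to(layer_line.reshape(shape), grid.shape).copy()
    return grid


def assign_fibers(
    grid: TissueGrid,
    helix_deg: tuple[float, float] = (60.0, -60.0),
    transverse_deg: float = 0.0,
    smoothing_sigma_mm: float = 0.0,
    depth_axis: int = 2,
    circumferential_axis: int = 0,
) -> TissueGrid:
    """Rule-based fiber field: helix angle linear in transmural depth.

    The helix angle rotates the fiber from the circumferential axis toward
    the longitudinal axis, varying linearly from ``helix_deg[0]`` at the
    endocardium to ``helix_deg[1]`` at the epicardium; ``transverse_deg``
    tilts the fiber out of the wall-tangent plane.  Optional 3-D Gaussian
    smoothing (sigma in mm) is applied componentwise and re-normalized.
    """
    n = grid.shape[depth_axis]
    if n == 0:
        raise ValueError("zero-thickness wall")
    axes = [0, 1, 2]
    if circumferential_axis == depth_axis:
        raise ValueError("circumferential axis cannot equal the depth axis")
    axes.remove(depth_axis)
    axes.remove(circumferential_axis)
    long_axis = axes[0]

    depth = (np.arange(n) + 0.5) / n
    a0, a1 = np.deg2rad(helix_deg[0]), np.deg2rad(helix_deg[1])
    helix = a0 + depth * (a1 - a0)
    at = np.deg2rad(transverse_deg)

    fib_line = np.zeros((n, 3))
    fib_line[:, circumferential_axis] = np.cos(helix) * np.cos(at)
    fib_line[:, long_axis] = np.sin(helix) * np.cos(at)
    fib_line[:, depth_axis] = np.sin(at)

    shape = [1, 1, 1]
    shape[depth_axis] = n
    fiber = np.empty(grid.shape + (3,))
    for c in range(3):
        fiber[..., c] = np.broadcast_to(fib_line[:, c].reshape(shape), grid.shape)

    if smoothing_sigma_mm > 0:
        sig = smoothing_sigma_mm / grid.dx
        for c in range(3):
            fiber[..., c] = ndimage.gaussian_filter(fiber[..., c], sig)
        norms = np.linalg.norm(fiber, axis=-1, keepdims=True)
        fiber = fiber / np.maximum(norms, 1e-300)

    grid.fiber = fiber
    return grid
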