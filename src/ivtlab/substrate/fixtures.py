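"""Tissue-grid fixtures: strand, slab and scar-with-isthmus sheet.

The strand is a thin pseudo-1D bar used for conduction-velocity
measurement; the slab is the 20 x 20 x 6 mm block used for conductivity
calibration; the isthmus sheet is a thin 2-D sheet containing two scar
blocks separated by a border-zone channel (the slow conducting channel)
whose lower mouth is narrower than the upper one — the substrate geometry
that supports reentry through the channel.
"""

from __future__ import annotations

import numpy as np

from .grid import LAYER_EPI, TissueGrid
from .volume import LABEL_BZ, LABEL_HEALTHY, LABEL_SCAR


def strand(
    length: float = 30.0,
    cross: float = 1.6,
    dx: float = 0.4,
    fiber_direction=(1.0, 0.0, 0.0),
) -> TissueGrid:
    """A thin bar along x with a uniform fiber field.

    Set ``fiber_direction`` to a transverse vector to measure cross-fiber
    conduction along the bar.
    """
    shape = _dims((length, cross, cross), dx)
    grid = TissueGrid(shape=shape, dx=dx)
    f = np.asarray(fiber_direction, dtype=float)
    n = np.linalg.norm(f)
    if n == 0:
        raise ValueError("fiber direction must be nonzero")
    grid.fiber[...] = f / n
    grid.layer[...] = LAYER_EPI
    return grid


def slab(lx: float = 20.0, ly: float = 20.0, lz: float = 6.0, dx: float = 0.4) -> TissueGrid:
    """The calibration slab (fibers along x, epicardial membrane)."""
    grid = TissueGrid(shape=_dims((lx, ly, lz), dx), dx=dx)
    grid.layer[...] = LAYER_EPI
    return grid


def isthmus_sheet(
    width: float = 32.0,
    height: float = 32.0,
    dx: float = 0.4,
    scar_x: tuple[float, float] = (6.0, 26.0),
    scar_y: tuple[float, float] = (6.0, 26.0),
    channel_center_x: float = 16.0,
    channel_w_lower: float = 1.2,
    channel_w_upper: float = 4.0,
    rim_mm: float = 1.2,
    corridor_bz: bool = True,
):
    """A one-element-thick sheet with two scar blocks and a BZ channel.

    The channel runs vertically (along y) between the scar blocks and
    tapers linearly from ``channel_w_lower`` at the lower mouth to
    ``channel_w_upper`` at the upper one.  A BZ rim of ``rim_mm``
    surrounds the scar; with ``corridor_bz`` the lateral corridors between
    the scar blocks and the sheet edges are border zone as well, so the
    outer reentry pathway is slow-conducting.  Returns ``(grid,
    landmarks)`` where landmarks (mm coordinates) mark the channel mouths,
    a pacing site below the lower mouth, a lateral pacing site and a
    reference probe opposite the scar.
    """
    if channel_w_lower < 0 or channel_w_upper < 0:
        raise ValueError("channel mouth widths cannot be negative (0 closes the channel)")
    nx, ny, nz = _dims((width, height, dx), dx)
    grid = TissueGrid(shape=(nx, ny, nz), dx=dx)
    grid.layer[...] = LAYER_EPI
    # fibers run along the channel axis (y): the channel and the lateral
    # corridors conduct longitudinally, as in a channel carved along the
    # prevailing fiber direction
    grid.fiber[...] = 0.0
    grid.fiber[..., 1] = 1.0

    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    x0, x1 = scar_x
    y0, y1 = scar_y
    in_block = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
    frac = np.clip((Y - y0) / max(y1 - y0, 1e-12), 0.0, 1.0)
    w = channel_w_lower + frac * (channel_w_upper - channel_w_lower)
    in_channel = in_block & (np.abs(X - channel_center_x) <= w / 2.0)
    scar = in_block & ~in_channel

    # rim: within rim_mm of the scar (Chebyshev distance on the sheet plane)
    rim = np.zeros_like(scar)
    r = int(np.ceil(rim_mm / dx))
    from scipy import ndimage

    if r > 0:
        rim = ndimage.binary_dilation(scar, iterations=r) & ~scar

    label2d = np.full((nx, ny), LABEL_HEALTHY, dtype=np.int8)
    if corridor_bz:
        corridor = ((X < x0) | (X > x1)) & (Y >= y0) & (Y <= y1)
        label2d[corridor] = LABEL_BZ
    label2d[rim] = LABEL_BZ
    label2d[in_channel] = LABEL_BZ
    label2d[scar] = LABEL_SCAR

    grid.label = np.repeat(label2d[:, :, None], nz, axis=2)

    landmarks = {
        "mouth_lower": (channel_center_x, y0 - dx, 0.0),
        "mouth_upper": (channel_center_x, y1 + dx, 0.0),
        "channel_low": (channel_center_x, y0 + 1.0, 0.0),
        "channel_mid": (channel_center_x, 0.5 * (y0 + y1), 0.0),
        "channel_high": (channel_center_x, y1 - 1.0, 0.0),
        "pacing_lower": (channel_center_x, max(y0 - 4.0, dx), 0.0),
        "pacing_lateral": (max(x0 - 4.0, dx), 0.5 * (y0 + y1), 0.0),
        "probe_top": (channel_center_x, min(y1 + 4.0, height - dx), 0.0),
    }
    return grid, landmarks


def synthetic_bz_intensity(grid, seed: int = 0, corr_mm: float = 1.5) -> np.ndarray:
    """A spatially correlated pseudo-enhancement field over grid elements.

    Used to rank border-zone elements for patchy-fibrosis selection on
    fixtures that were not built from an intensity volume: correlated
    Gaussian noise (clustered patches) plus a mild gradient toward the
    scar, emulating the brightest BZ voxels sitting near the scar core.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    sig = corr_mm / grid.dx
    noise = ndimage.gaussian_filter(noise, sig)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    scar = grid.label == LABEL_SCAR
    if scar.any():
        dist = ndimage.distance_transform_edt(~scar, sampling=grid.dx)
        grad = np.exp(-dist / 4.0)
    else:
        grad = np.zeros(grid.shape)
    return noise + 1.5 * grad


def build_fixture(kind: str, **params):
    """Dispatch on fixture kind ('strand', 'slab', 'isthmus_sheet')."""
    if kind == "strand":
        return strand(**params)
    if kind == "slab":
        return slab(**params)
    if kind == "isthmus_sheet":
        return isthmus_sheet(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _dims(lengths, dx):
    dims = []
    for L in lengths:
        n = L / dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"extent {L} mm is not divisible by dx = {dx} mm")
        dims.append(max(int(round(n)), 1))
    return tuple(dims)
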