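"""DE-MRI-like intensity volumes and SD-method scar/border-zone classification.

The synthetic generator emulates a delayed-enhancement acquisition of a
chronically infarcted slab of myocardium: remote tissue with Normally
distributed intensity, a hyper-enhanced scar core, an intermediate-intensity
border-zone (BZ) rim whose brightest voxels cluster into patches (spatially
correlated noise), and a lower-intensity channel crossing the scar (the
isthmus).  The SD method then labels voxels inside the infarct region of
interest as scar (intensity >= remote mean + 3 SD), BZ (between mean + 2 SD
and mean + 3 SD) or healthy, with remote statistics taken per slice or
globally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

LABEL_HEALTHY = 0
LABEL_SCAR = 1
LABEL_BZ = 2
LABEL_FIBROSIS = 3


@dataclass
class VoxelVolume:
    """A 3-D scalar intensity volume with isotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: float = 1.4
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("intensity volume must be 3-D")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    def to_nifti(self, path):
        import nibabel as nib

        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), aff), str(path))

    @classmethod
    def from_nifti(cls, path):
        import nibabel as nib

        img = nib.load(str(path))
        spacing = float(img.header.get_zooms()[0])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(data=np.asarray(img.dataobj, dtype=float), spacing=spacing, origin=origin)


@dataclass
class RegionMasks:
    """Myocardium, remote and infarct regions of interest (boolean volumes)."""

    myocardium: np.ndarray
    remote: np.ndarray
    infarct: np.ndarray

    def __post_init__(self):
        for name in ("myocardium", "remote", "infarct"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if np.any(self.remote & self.infarct):
            raise ValueError("remote and infarct ROIs must be disjoint")
        if np.any(self.remote & ~self.myocardium) or np.any(self.infarct & ~self.myocardium):
            raise ValueError("ROIs must lie within the myocardium mask")


@dataclass
class SyntheticInfarctSpec:
    """Parameters of the synthetic DE-MRI volume.

    Intensities are in arbitrary units; plateau levels are expressed in
    multiples of the remote SD ``s_r`` above the remote mean ``mu_r`` so
    that they line up with the SD-method thresholds.  ``noise_sd_rel``
    scales the spatially correlated noise in units of ``s_r`` (1.0 makes
    the measured remote SD match the nominal one).
    """

    shape: tuple[int, int, int] = (40, 40, 12)
    spacing: float = 1.4
    mu_r: float = 100.0
    s_r: float = 10.0
    scar_plateau_sd: float = 5.0
    scar_semiaxes: tuple[float, float, float] = (12.0, 8.0, 5.0)  # mm
    bz_rim_mm: float = 3.0
    channel_width_mm: float = 3.0
    channel_axis: int = 1  # channel runs along this axis through the scar
    corr_len_mm: float = 2.8
    noise_sd_rel: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scar_plateau_sd < 3.0:
            raise ValueError("scar plateau must be at least 3 remote SDs above the mean")


def generate_synthetic_infarct(spec: SyntheticInfarctSpec):
    """Generate a synthetic DE-MRI volume, its ROI masks and ground truth.

    Returns ``(VoxelVolume, RegionMasks, truth)`` where ``truth`` is an
    int8 label volume (0 healthy, 1 scar, 2 BZ) recording the intended
    tissue class of each voxel.  Deterministic for a fixed seed.
    """
    nx, ny, nz = spec.shape
    sp = spec.spacing
    rx, ry, rz = spec.scar_semiaxes
    has_scar = min(rx, ry, rz) > 0
    if has_scar and spec.channel_width_mm >= 2.0 * min(rx, ry, rz):
        raise ValueError("channel is wider than the scar")

    x = (np.arange(nx) + 0.5) * sp
    y = (np.arange(ny) + 0.5) * sp
    z = (np.arange(nz) + 0.5) * sp
    cx, cy, cz = nx * sp / 2, ny * sp / 2, nz * sp / 2
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    if has_scar:
        r2 = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2
        scar_body = r2 <= 1.0
    else:
        scar_body = np.zeros(spec.shape, dtype=bool)

    # through-scar channel: a slab of surviving tissue crossing the scar
    axes = [0, 1, 2]
    axes.remove(spec.channel_axis)
    perp = axes[0]  # width measured along the first remaining axis
    coord = (X, Y, Z)[perp]
    center = (cx, cy, cz)[perp]
    channel = scar_body & (np.abs(coord - center) <= spec.channel_width_mm / 2.0)
    scar = scar_body & ~channel

    dist = ndimage.distance_transform_edt(~scar, sampling=sp)
    rim = (~scar) & (dist <= spec.bz_rim_mm) & ~channel

    truth = np.zeros(spec.shape, dtype=np.int8)
    truth[scar] = LABEL_SCAR
    truth[rim | channel] = LABEL_BZ

    base = np.full(spec.shape, spec.mu_r, dtype=float)
    base[scar] = spec.mu_r + spec.scar_plateau_sd * spec.s_r
    # BZ rim: intensity decays linearly from just under mean+3SD at the scar
    # edge to mean+2SD at the outer rim edge
    base[rim] = spec.mu_r + spec.s_r * (2.0 + 0.98 * (1.0 - dist[rim] / spec.bz_rim_mm))
    base[channel] = spec.mu_r + 2.5 * spec.s_r

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape)
    sigma_vox = spec.corr_len_mm / sp
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        noise -= noise.mean()
        noise /= noise.std()
    vol = VoxelVolume(data=base + spec.noise_sd_rel * spec.s_r * noise, spacing=sp)

    myocardium = np.ones(spec.shape, dtype=bool)
    infarct_extent = scar_body | rim
    infarct = ndimage.binary_dilation(infarct_extent, iterations=1)
    remote = ~ndimage.binary_dilation(infarct_extent, iterations=3)
    masks = RegionMasks(myocardium=myocardium, remote=remote, infarct=infarct)
    return vol, masks, truth


def sd_classify(volume: VoxelVolume, masks: RegionMasks, mode: str = "per-slice") -> np.ndarray:
    """SD-method tissue classification inside the infarct ROI.

    Thresholds come from remote-ROI statistics: scar if intensity >=
    mean + 3 SD, BZ if mean + 2 SD <= intensity < mean + 3 SD, healthy
    below; voxels outside the infarct ROI are healthy.  ``mode``
    'per-slice' computes remote statistics per z-slice (slices indexed on
    the last axis), 'global' uses the whole remote ROI.
    """
    if mode not in ("per-slice", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    data = volume.data
    labels = np.zeros(data.shape, dtype=np.int8)

    if mode == "global":
        if not masks.remote.any():
            raise ValueError("empty remote ROI")
        vals = data[masks.remote]
        _classify_into(labels, data, masks.infarct, vals.mean(), vals.std())
        return labels

    for k in range(data.shape[2]):
        inf_sl = masks.infarct[:, :, k]
        if not inf_sl.any():
            continue
        rem_sl = masks.remote[:, :, k]
        if not rem_sl.any():
            raise ValueError(f"slice {k}: infarct ROI present but remote ROI is empty")
        vals = data[:, :, k][rem_sl]
        sub = np.zeros(inf_sl.shape, dtype=np.int8)
        _classify_into(sub, data[:, :, k], inf_sl, vals.mean(), vals.std())
        labels[:, :, k] = sub
    return labels


def _classify_into(labels, data, infarct_mask, mu, sd):
    region = data[infarct_mask]
    lab = np.full(region.shape, LABEL_HEALTHY, dtype=np.int8)
    if sd == 0.0:
        # degenerate remote statistics: only clear hyper-enhancement is scar
        lab[region > mu] = LABEL_SCAR
    else:
        hi = mu + 3.0 * sd
        lo = mu + 2.0 * sd
        lab[region >= hi] = LABEL_SCAR
        lab[(region >= lo) & (region < hi)] = LABEL_BZ
    labels[infarct_mask] = lab
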