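"""Confocal-like rendering of a simulated cell sheet.

Produces a two-channel stack emulating simultaneous cell-wall staining
(channel "wall": bright voxels along every cell boundary, including the
top/bottom faces of the sheet) and S-phase nuclear labelling (channel
"edu": a bright sphere at the centroid of every EdU-positive cell),
optionally blurred by an isotropic Gaussian PSF and corrupted by Gaussian
or Poisson noise. The ground-truth label image is the full partition of
the tissue slab: every voxel whose centre falls inside a cell's polygon
(and within the z slab) carries that cell's id.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import find_boundaries

from .images import LabelImage, VoxelImage
from .tissue import TissueSnapshot

DEFAULT_VOXEL = (0.5, 0.25, 0.25)  # (z, y, x) um


@dataclass
class RenderParams:
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL
    psf_sigma: float = 0.0           # um, isotropic Gaussian PSF
    wall_intensity: float = 1.0
    nucleus_intensity: float = 1.0
    nucleus_radius: float = 2.5      # um
    noise_model: str = "none"        # none | gaussian | poisson
    noise_scale: float = 0.0
    pad: float = 2.0                 # um of empty space around the tissue
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _rasterize_sheet(snapshot: TissueSnapshot, params: RenderParams
                     ) -> tuple[np.ndarray, tuple, tuple]:
    """2D label raster of the polygonal sheet plus grid geometry."""
    vz, vy, vx = params.voxel_size
    all_v = np.vstack([c.verts for c in snapshot.cells])
    xmin, ymin = all_v.min(axis=0) - params.pad
    xmax, ymax = all_v.max(axis=0) + params.pad
    nx = int(np.ceil((xmax - xmin) / vx))
    ny = int(np.ceil((ymax - ymin) / vy))
    labels2d = np.zeros((ny, nx), dtype=np.int32)
    for c in snapshot.cells:
        rr, cc = draw_polygon((c.verts[:, 1] - ymin) / vy - 0.5,
                              (c.verts[:, 0] - xmin) / vx - 0.5,
                              shape=labels2d.shape)
        labels2d[rr, cc] = c.id
    # fill sub-voxel rasterisation gaps between adjacent cells with the
    # nearest assigned label (gaps are at most one voxel wide)
    mask = labels2d > 0
    filled = ndimage.binary_fill_holes(mask)
    holes = filled & ~mask
    if holes.any():
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~mask, return_indices=True, sampling=(vy, vx))
        labels2d[holes] = labels2d[iy[holes], ix[holes]]
    return labels2d, (xmin, ymin), (ny, nx)


def render_stack(snapshot: TissueSnapshot, params: RenderParams
                 ) -> tuple[VoxelImage, LabelImage]:
    """Render one snapshot to a (wall, edu) stack plus ground-truth labels.

    With ``noise_model="none"`` and ``psf_sigma=0`` the intensity stack is
    the exact rasterisation: the wall channel is nonzero only on boundary
    voxels and the label image partitions the tissue slab.
    """
    if not snapshot.cells:
        raise ValueError("cannot render an empty snapshot")
    vz, vy, vx = params.voxel_size
    thickness = snapshot.cells[0].thickness
    min_diam = 2.0 * np.sqrt(min(c.volume / c.thickness
                                 for c in snapshot.cells) / np.pi)
    if max(params.voxel_size) > min(min_diam, thickness):
        warnings.warn("voxel size exceeds the smallest cell diameter; "
                      "segmentation will be unreliable")

    labels2d, (xmin, ymin), (ny, nx) = _rasterize_sheet(snapshot, params)
    z0 = int(round(params.pad / vz))
    n_slab = max(1, int(round(thickness / vz)))
    nz = n_slab + 2 * z0
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    labels[z0:z0 + n_slab] = labels2d[None]

    # wall channel: every voxel within half a voxel of a cell boundary,
    # i.e. one voxel layer on each side of lateral walls, the tissue
    # outline and the top/bottom faces of the sheet. The symmetric double
    # layer matters: the watershed crest then falls on the true boundary,
    # so basins split wall voxels the same way the ground-truth partition
    # does.
    walls2d = find_boundaries(labels2d, mode="thick")
    tissue2d = labels2d > 0
    wall = np.zeros((nz, ny, nx), dtype=np.float32)
    wall[z0:z0 + n_slab][:, walls2d] = params.wall_intensity
    for face in (z0 - 1, z0, z0 + n_slab - 1, z0 + n_slab):
        if 0 <= face < nz:
            wall[face][tissue2d] = params.wall_intensity

    # nuclear channel: spheres at EdU-positive centroids
    edu = np.zeros_like(wall)
    zc_um = params.pad + thickness / 2.0
    zz = (np.arange(nz) + 0.5) * vz
    yy = (np.arange(ny) + 0.5) * vy
    xx = (np.arange(nx) + 0.5) * vx
    for c in snapshot.cells:
        if not c.edu_positive:
            continue
        cx, cy = c.centroid
        r = params.nucleus_radius
        iz = np.flatnonzero(np.abs(zz - zc_um) <= r)
        iy = np.flatnonzero(np.abs(yy - (cy - ymin)) <= r)
        ix = np.flatnonzero(np.abs(xx - (cx - xmin)) <= r)
        if not (len(iz) and len(iy) and len(ix)):
            continue
        dz = (zz[iz] - zc_um)[:, None, None]
        dy = (yy[iy] - (cy - ymin))[None, :, None]
        dx = (xx[ix] - (cx - xmin))[None, None, :]
        ball = dz ** 2 + dy ** 2 + dx ** 2 <= r ** 2
        sub = edu[np.ix_(iz, iy, ix)]
        sub[ball] = params.nucleus_intensity
        edu[np.ix_(iz, iy, ix)] = sub

    data = np.stack([wall, edu])
    if params.psf_sigma > 0:
        sig = [params.psf_sigma / v for v in params.voxel_size]
        for ch in range(2):
            data[ch] = ndimage.gaussian_filter(data[ch], sigma=sig)
    if params.noise_model != "none" and params.noise_scale > 0:
        rng = np.random.default_rng(params.rng_seed)
        if params.noise_model == "gaussian":
            data = data + rng.normal(0.0, params.noise_scale, data.shape)
        else:  # poisson: noise_scale = intensity quantum per photon
            data = rng.poisson(np.clip(data, 0, None)
                               / params.noise_scale) * params.noise_scale
        data = data.astype(np.float32)

    # voxel (0,0,0) centre in world coordinates; z=0 is pad below the sheet
    origin = (0.5 * vz - params.pad + 0.0,
              ymin + 0.5 * vy, xmin + 0.5 * vx)
    img = VoxelImage(data=data, voxel_size=params.voxel_size,
                     channel_names=["wall", "edu"], origin=origin)
    lab = LabelImage(labels=labels, voxel_size=params.voxel_size,
                     origin=origin)
    return img, lab
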