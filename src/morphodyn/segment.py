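"""Seeded 3D watershed segmentation and voxel volumetry.

The wall channel is smoothed and treated as a landscape whose basins are
cell interiors: h-minima suppression yields one seed per cell (plus the
surrounding background), the watershed assigns every voxel to a basin,
border-touching low-intensity basins are relabelled as background, and
cells are measured by voxel counting (volume = voxel count x voxel
volume). EdU positivity is scored per cell from the mean nuclear-channel
intensity inside an eroded copy of the cell mask (erosion keeps
wall-adjacent bleed-through out of the average).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_minima
from skimage.segmentation import watershed as _watershed

from .images import LabelImage, VoxelImage


class NoSeedsError(ValueError):
    """The wall channel contains no basins to seed (e.g. constant image)."""


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 0.3          # um
    h_depth: float = 0.2                  # intensity units (h-minima depth)
    background_threshold: float = 0.3     # basin mean intensity below which a
                                          # border-touching basin is background
    min_volume: float = 20.0              # um^3
    max_volume: float = 2000.0            # um^3
    #: dissolve interfaces between adjacent labels whose mean (smoothed)
    #: wall intensity falls below this -- false splits cross dark interior,
    #: real walls are bright. 0 disables merging.
    merge_boundary_threshold: float = 0.4
    edu_threshold_method: str = "otsu"    # otsu | fixed
    edu_fixed_threshold: float = 0.5      # intensity units
    erosion_radius: float = 0.75          # um

    def __post_init__(self) -> None:
        if self.min_volume >= self.max_volume:
            raise ValueError("min_volume must be < max_volume")
        if self.smoothing_sigma < 0 or self.h_depth <= 0:
            raise ValueError("need smoothing_sigma >= 0 and h_depth > 0")
        if self.edu_threshold_method not in ("otsu", "fixed"):
            raise ValueError("edu_threshold_method must be otsu or fixed")


def _smoothed(wall: VoxelImage, params: SegmentationParams) -> np.ndarray:
    data = wall.data
    if data.ndim != 3:
        raise ValueError("expected a single-channel wall stack")
    if params.smoothing_sigma > 0:
        sig = [params.smoothing_sigma / v for v in wall.voxel_size]
        return ndimage.gaussian_filter(data.astype(np.float64), sigma=sig)
    return data.astype(np.float64)


def detect_seeds(wall: VoxelImage, params: SegmentationParams | None = None
                 ) -> LabelImage:
    """Seed detection: smooth, treat interiors as basins, suppress shallow
    minima at depth ``h_depth`` and label what remains."""
    params = params or SegmentationParams()
    sm = _smoothed(wall, params)
    if np.ptp(sm) <= params.h_depth:
        raise NoSeedsError("no basins deeper than h_depth "
                           "(constant or near-constant image)")
    minima = h_minima(sm, params.h_depth)
    seeds, n = ndimage.label(minima)
    if n == 0:
        raise NoSeedsError("h-minima suppression removed all basins")
    return LabelImage(labels=seeds.astype(np.int32),
                      voxel_size=wall.voxel_size, origin=wall.origin)


def watershed_segment(wall: VoxelImage, seeds: LabelImage,
                      params: SegmentationParams | None = None) -> LabelImage:
    """Flood the smoothed wall landscape from the seeds and relabel
    border-touching low-intensity basins as background (0). Foreground
    labels are renumbered consecutively in seed order."""
    params = params or SegmentationParams()
    if seeds.labels.max() == 0:
        raise ValueError("no seeds given")
    if seeds.labels.shape != wall.data.shape:
        raise ValueError("seeds and wall stack shapes differ")
    sm = _smoothed(wall, params)
    basins = _watershed(sm, markers=seeds.labels)
    if params.merge_boundary_threshold > 0:
        basins = _merge_weak_boundaries(basins, sm,
                                        params.merge_boundary_threshold)
    ids = np.unique(basins)
    ids = ids[ids > 0]
    means = ndimage.mean(sm, labels=basins, index=ids)
    border = np.zeros(basins.shape, bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    touches = np.isin(ids, np.unique(basins[border]))
    is_bg = touches & (np.asarray(means) < params.background_threshold)
    out = np.zeros_like(basins, dtype=np.int32)
    next_id = 1
    for lab, bg in zip(ids, is_bg):
        if not bg:
            out[basins == lab] = next_id
            next_id += 1
    return LabelImage(labels=out, voxel_size=wall.voxel_size,
                      origin=wall.origin)


def _interface_means(labels: np.ndarray, intensity: np.ndarray
                     ) -> dict[tuple[int, int], float]:
    """Mean intensity over the voxel-pair interface of each adjacent
    label pair (both labels > 0)."""
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)
        v = np.moveaxis(intensity, axis, 0)
        la, lb = a[:-1], a[1:]
        mask = (la != lb) & (la > 0) & (lb > 0)
        if not mask.any():
            continue
        pa, pb = la[mask], lb[mask]
        vals = 0.5 * (v[:-1][mask] + v[1:][mask])
        lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
        for key, val in zip(zip(lo.tolist(), hi.tolist()), vals.tolist()):
            sums[key] = sums.get(key, 0.0) + val
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def _merge_weak_boundaries(basins: np.ndarray, sm: np.ndarray,
                           threshold: float) -> np.ndarray:
    """Union labels across interfaces with mean intensity < threshold."""
    for _ in range(4):  # merged regions expose new interfaces; iterate
        means = _interface_means(basins, sm)
        weak = [k for k, v in means.items() if v < threshold]
        if not weak:
            break
        parent = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        for a, b in weak:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        lut = np.arange(int(basins.max()) + 1)
        for lab in np.unique(basins):
            if lab > 0:
                lut[lab] = find(int(lab))
        basins = lut[basins]
    return basins


def filter_labels(labels: LabelImage,
                  params: SegmentationParams | None = None) -> LabelImage:
    """Drop labels whose voxel volume lies outside [min_volume,
    max_volume]; survivors are renumbered consecutively in label order."""
    params = params or SegmentationParams()
    ids = labels.ids
    if len(ids) == 0:
        return labels
    counts = ndimage.sum_labels(np.ones_like(labels.labels), labels.labels,
                                index=ids)
    vols = np.asarray(counts) * labels.voxel_volume
    keep = ids[(vols >= params.min_volume) & (vols <= params.max_volume)]
    lut = np.zeros(int(labels.labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    return LabelImage(labels=lut[labels.labels],
                      voxel_size=labels.voxel_size, origin=labels.origin)


def measure_cells(labels: LabelImage) -> pd.DataFrame:
    """Voxel-count volumetry: per cell, volume = voxel count x voxel
    volume, centroid = mean voxel position in world um."""
    ids = labels.ids
    if len(ids) == 0:
        return pd.DataFrame(columns=["cell_id", "cx", "cy", "cz",
                                     "volume_um3", "voxel_count"])
    counts = np.asarray(ndimage.sum_labels(
        np.ones_like(labels.labels), labels.labels, index=ids))
    com = np.asarray(ndimage.center_of_mass(
        np.ones_like(labels.labels), labels.labels, index=ids))
    vz, vy, vx = labels.voxel_size
    oz, oy, ox = labels.origin
    return pd.DataFrame({
        "cell_id": ids.astype(int),
        "cx": ox + com[:, 2] * vx,
        "cy": oy + com[:, 1] * vy,
        "cz": oz + com[:, 0] * vz,
        "volume_um3": counts * labels.voxel_volume,
        "voxel_count": counts.astype(int),
    })


def classify_edu(labels: LabelImage, nuclear: VoxelImage,
                 params: SegmentationParams | None = None) -> pd.DataFrame:
    """Measure cells and flag EdU positivity from the nuclear channel.

    The per-cell mean is taken inside the label eroded by
    ``erosion_radius`` (a box min/max filter); cells erased by erosion
    fall back to their full mask. Thresholding is Otsu over the per-cell
    means, or a fixed cutoff; a degenerate intensity distribution (all
    means equal, e.g. an all-zero channel) yields all-negative flags.
    """
    params = params or SegmentationParams()
    if nuclear.data.ndim != 3:
        raise ValueError("expected a single-channel nuclear stack")
    if nuclear.data.shape != labels.labels.shape:
        raise ValueError("nuclear stack and labels shapes differ")
    table = measure_cells(labels)
    if table.empty:
        table["mean_nuclear_intensity"] = []
        table["edu"] = []
        return table
    lab = labels.labels
    size = [max(1, 2 * int(round(params.erosion_radius / v)) + 1)
            for v in labels.voxel_size]
    eroded = np.where(
        (ndimage.minimum_filter(lab, size=size)
         == ndimage.maximum_filter(lab, size=size)), lab, 0)
    ids = table["cell_id"].to_numpy()
    present = np.isin(ids, np.unique(eroded))
    means = np.zeros(len(ids))
    means[present] = ndimage.mean(nuclear.data, labels=eroded,
                                  index=ids[present])
    if not present.all():  # fully eroded cells: use the whole mask
        means[~present] = ndimage.mean(nuclear.data, labels=lab,
                                       index=ids[~present])
    if params.edu_threshold_method == "fixed":
        flags = means > params.edu_fixed_threshold
    else:
        if np.ptp(means) <= 1e-12:
            flags = np.zeros(len(means), dtype=bool)
        else:
            flags = means > threshold_otsu(np.asarray(means))
    table["mean_nuclear_intensity"] = means
    table["edu"] = flags
    return table


def segment_stack(image: VoxelImage,
                  params: SegmentationParams | None = None
                  ) -> tuple[LabelImage, pd.DataFrame]:
    """Full pipeline on a (wall, edu) stack: seeds, watershed, volume
    filter, voxel volumetry and EdU classification."""
    params = params or SegmentationParams()
    wall = image.channel("wall") if image.data.ndim == 4 else image
    seeds = detect_seeds(wall, params)
    labels = watershed_segment(wall, seeds, params)
    labels = filter_labels(labels, params)
    if image.data.ndim == 4 and "edu" in image.channel_names:
        table = classify_edu(labels, image.channel("edu"), params)
    else:
        table = measure_cells(labels)
    return labels, table


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def match_labels(truth: LabelImage, pred: LabelImage) -> pd.DataFrame:
    """One-to-one matching of predicted to ground-truth cells by maximal
    voxel overlap; reports the Jaccard index per ground-truth cell.

    Each predicted label is assigned to the truth label it overlaps most;
    a truth cell's match is the predicted label assigning it the largest
    intersection. Truth cells with no overlapping prediction get
    jaccard 0.
    """
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    both = (t > 0) | (p > 0)
    t, p = t[both], p[both]
    pair, counts = np.unique(np.stack([t, p]), axis=1, return_counts=True)
    t_sizes = dict(zip(*np.unique(t, return_counts=True)))
    p_sizes = dict(zip(*np.unique(p, return_counts=True)))
    best: dict[int, tuple[int, int]] = {}
    order = np.argsort(-counts)
    used_pred: set[int] = set()
    for k in order:
        ti, pi = int(pair[0, k]), int(pair[1, k])
        if ti == 0 or pi == 0 or ti in best or pi in used_pred:
            continue
        best[ti] = (pi, int(counts[k]))
        used_pred.add(pi)
    rows = []
    for ti in np.unique(t[t > 0]):
        ti = int(ti)
        if ti in best:
            pi, inter = best[ti]
            union = t_sizes[ti] + p_sizes[pi] - inter
            rows.append((ti, pi, inter / union))
        else:
            rows.append((ti, 0, 0.0))
    return pd.DataFrame(rows, columns=["truth_id", "pred_id", "jaccard"])
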