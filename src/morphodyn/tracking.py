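"""Cell tracking across timepoints and clonal sector analysis.

Consecutive snapshots of a growing tissue are related by an (unknown)
rigid motion plus, in a uniformly expanding tissue, a global scale. The
registration here is a similarity Procrustes fit on matched cell
centroids: matches come either from user anchors or from mutual nearest
neighbours after normalising both clouds. Cells at the later timepoint are
then assigned to the nearest transformed earlier-timepoint centroid
(daughters of a division share a parent), clones are grown from founder
sectors, and per-sector growth metrics are reported.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """x1 ~ scale * R @ x0 + t."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)
    scale: float
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T \
            + self.translation


@dataclass
class SectorDefinition:
    founder_ids: frozenset[int]
    name: str = "sector"

    def __post_init__(self) -> None:
        object.__setattr__(self, "founder_ids", frozenset(self.founder_ids))
        if not self.founder_ids:
            raise ValueError("sector must contain at least one founder")


def _umeyama(p0: np.ndarray, p1: np.ndarray, with_scale: bool
             ) -> RigidTransform:
    """Least-squares similarity transform between matched point sets."""
    mu0, mu1 = p0.mean(axis=0), p1.mean(axis=0)
    q0, q1 = p0 - mu0, p1 - mu1
    cov = q1.T @ q0 / len(p0)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    if with_scale:
        var0 = (q0 ** 2).sum() / len(p0)
        scale = float(np.trace(np.diag(s) @ diag) / var0)
    else:
        scale = 1.0
    t = mu1 - scale * rot @ mu0
    resid = p1 - (scale * p0 @ rot.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=t, scale=scale,
                          residual_rms=rms)


def _centroids(table: pd.DataFrame) -> np.ndarray:
    return table[["cx", "cy", "cz"]].to_numpy(dtype=float)


def register_timepoints(cells_t0: pd.DataFrame, cells_t1: pd.DataFrame,
                        anchors: Optional[Sequence[tuple[int, int]]] = None,
                        with_scale: bool = True) -> RigidTransform:
    """Similarity (Procrustes) registration between two cell tables.

    With ``anchors`` (pairs of cell ids, >= 3 and non-collinear) the fit is
    computed on those correspondences. Without anchors, both centroid
    clouds are normalised (centred, unit RMS radius) and mutual nearest
    neighbours in normalised space provide the correspondences; this is
    robust to the global dilation between snapshots of a growing tissue.
    """
    if len(cells_t0) == 0 or len(cells_t1) == 0:
        raise ValueError("both cell tables must be non-empty")
    c0, c1 = _centroids(cells_t0), _centroids(cells_t1)
    if anchors is not None:
        if len(anchors) < 3:
            raise ValueError("need >= 3 anchor pairs")
        i0 = {int(v): k for k, v in enumerate(cells_t0["cell_id"])}
        i1 = {int(v): k for k, v in enumerate(cells_t1["cell_id"])}
        p0 = np.array([c0[i0[a]] for a, _ in anchors])
        p1 = np.array([c1[i1[b]] for _, b in anchors])
        if np.linalg.matrix_rank(p0 - p0.mean(axis=0)) < 2:
            raise ValueError("anchor points are collinear")
    else:
        p0, p1 = _mutual_nearest_pairs(c0, c1)
        if len(p0) < 3:
            raise ValueError("too few mutual-nearest centroid pairs")
    return _umeyama(p0, p1, with_scale)


def _mutual_nearest_pairs(c0: np.ndarray, c1: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    def normalise(c):
        mu = c.mean(axis=0)
        q = c - mu
        rms = np.sqrt((q ** 2).sum(axis=1).mean())
        return q / max(rms, 1e-12)

    n0, n1 = normalise(c0), normalise(c1)
    _, fwd = cKDTree(n1).query(n0)
    _, bwd = cKDTree(n0).query(n1)
    keep = [i for i in range(len(n0)) if bwd[fwd[i]] == i]
    return c0[keep], c1[np.array([fwd[i] for i in keep])]


@dataclass
class AffineTransform:
    """x1 ~ A @ x0 + t; the general-linear refinement of a similarity fit,
    needed when growth is strongly anisotropic."""

    matrix: np.ndarray        # (3, 3)
    translation: np.ndarray   # (3,)
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + self.translation


def register_affine(cells_t0: pd.DataFrame, cells_t1: pd.DataFrame,
                    n_iter: int = 8, trim: float = 0.8) -> AffineTransform:
    """Full-affine registration by iterated matching.

    Starts from the similarity (Procrustes) fit, then alternates
    mutual-nearest matching in the transformed frame with a trimmed
    least-squares 3D affine fit (the worst ``1 - trim`` fraction of
    matches is discarded each round, which lets the fit escape early
    mismatches). Use for transitions of anisotropically growing tissue,
    where no similarity transform can align the centroid clouds.
    """
    c0, c1 = _centroids(cells_t0), _centroids(cells_t1)
    mu0, mu1 = c0.mean(axis=0), c1.mean(axis=0)

    def _sqrtm_spd(C):
        w, v = np.linalg.eigh(C)
        w = np.clip(w, 1e-12, None)
        return v @ np.diag(np.sqrt(w)) @ v.T

    # moment-based initialisation: match the cloud covariances,
    # C1 = A C0 A^T, up to the rotation left free by whitening (taken from
    # the similarity fit). Exact when the clouds differ by an affine map.
    try:
        U = register_timepoints(cells_t0, cells_t1).rotation
    except ValueError:
        U = np.eye(3)
    C0 = np.cov(c0.T) + 1e-9 * np.eye(3)
    C1 = np.cov(c1.T) + 1e-9 * np.eye(3)
    A = _sqrtm_spd(C1) @ U @ np.linalg.inv(_sqrtm_spd(C0))
    t = mu1 - A @ mu0
    rms = float(np.sqrt(np.mean(np.sum((c1.mean(axis=0) - c1) ** 2, axis=1))))
    for _ in range(n_iter):
        moved = c0 @ A.T + t
        _, fwd = cKDTree(c1).query(moved)
        _, bwd = cKDTree(moved).query(c1)
        keep = np.array([i for i in range(len(c0)) if bwd[fwd[i]] == i])
        if len(keep) < 6:
            break
        p0 = c0[keep]
        p1 = c1[fwd[keep]]
        err = np.linalg.norm(p0 @ A.T + t - p1, axis=1)
        good = err <= np.quantile(err, trim)
        if good.sum() < 4:
            good[:] = True
        design = np.column_stack([p0[good], np.ones(int(good.sum()))])
        coef, *_ = np.linalg.lstsq(design, p1[good], rcond=None)
        A, t = coef[:3].T, coef[3]
        resid = p1 - (p0 @ A.T + t)
        rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AffineTransform(matrix=A, translation=t, residual_rms=rms)


def track_cells(cells_t0: pd.DataFrame, cells_t1: pd.DataFrame,
                transform: "RigidTransform | AffineTransform",
                max_distance: float = np.inf,
                children_cap: int = 2) -> dict[int, Optional[int]]:
    """Assign each t1 cell the t0 parent with the nearest transformed
    centroid; assignments beyond ``max_distance`` become None. Parents with
    more than ``children_cap`` children are logged as warnings (the default
    cap matches one division per 24 h transition)."""
    c0 = transform.apply(_centroids(cells_t0))
    c1 = _centroids(cells_t1)
    ids0 = cells_t0["cell_id"].to_numpy()
    ids1 = cells_t1["cell_id"].to_numpy()
    dist, idx = cKDTree(c0).query(c1)
    lineage: dict[int, Optional[int]] = {}
    for k in range(len(ids1)):
        lineage[int(ids1[k])] = (int(ids0[idx[k]])
                                 if dist[k] <= max_distance else None)
    counts = pd.Series([v for v in lineage.values() if v is not None]
                       ).value_counts()
    for parent, n in counts.items():
        if n > children_cap:
            logger.warning("parent %s assigned %d children (cap %d)",
                           parent, n, children_cap)
    return lineage


def build_clones(sector: SectorDefinition,
                 lineages: Sequence[dict[int, Optional[int]]],
                 cell_tables: Sequence[pd.DataFrame]
                 ) -> dict[int, list[set[int]]]:
    """Clone membership per timepoint for each founder of a sector.

    ``lineages[k]`` maps cell ids at timepoint k+1 to parents at timepoint
    k. Returns founder -> list of member-id sets, one per timepoint;
    clones are disjoint and their union is the sector's descendants.
    """
    t0_ids = set(cell_tables[0]["cell_id"].astype(int))
    missing = set(sector.founder_ids) - t0_ids
    if missing:
        raise ValueError(f"founders absent from the first timepoint: "
                         f"{sorted(missing)}")
    clones = {f: [({f})] for f in sorted(sector.founder_ids)}
    for lineage in lineages:
        for f in clones:
            prev = clones[f][-1]
            clones[f].append({child for child, parent in lineage.items()
                              if parent in prev})
    return clones


def sector_metrics(clones: dict[int, list[set[int]]],
                   cell_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-timepoint sector growth metrics.

    Columns mirror the classic clonal-analysis readouts: cell count, mean
    and sample SD of member cell volume, total sector volume, CV of cell
    volumes and CV of per-clone total volumes.
    """
    rows = []
    for k, table in enumerate(cell_tables):
        vol = dict(zip(table["cell_id"].astype(int),
                       table["volume_um3"].astype(float)))
        members = sorted(set().union(*(c[k] for c in clones.values())))
        if not members:
            raise ValueError(f"sector lost at timepoint index {k}")
        v = np.array([vol[m] for m in members])
        clone_totals = np.array([sum(vol[m] for m in c[k])
                                 for c in clones.values() if c[k]])
        rows.append({
            "t_hr": float(table["t_hr"].iloc[0]),
            "n_cells": len(members),
            "mean_volume": v.mean(),
            "sd_volume": v.std(ddof=1) if len(v) > 1 else 0.0,
            "total_volume": v.sum(),
            "cv_cell_volume": (v.std(ddof=1) / v.mean()) if len(v) > 1 else 0.0,
            "cv_clone_volume": (clone_totals.std(ddof=1) / clone_totals.mean()
                                if len(clone_totals) > 1 else 0.0),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lineage JSON round trip
# ---------------------------------------------------------------------------

def write_lineage_json(lineages: Sequence[dict[int, Optional[int]]],
                       times: Sequence[float], path: str | Path) -> None:
    transitions = []
    for k, lineage in enumerate(lineages):
        pairs = sorted((int(c), int(p)) for c, p in lineage.items()
                       if p is not None)
        transitions.append({"t0": float(times[k]), "t1": float(times[k + 1]),
                            "pairs": [[c, p] for c, p in pairs]})
    Path(path).write_text(json.dumps({"transitions": transitions}, indent=1))


def read_lineage_json(path: str | Path
                      ) -> tuple[list[dict[int, int]], list[float]]:
    data = json.loads(Path(path).read_text())
    lineages, times = [], []
    for tr in data["transitions"]:
        if not times:
            times.append(float(tr["t0"]))
        times.append(float(tr["t1"]))
        lineages.append({int(c): int(p) for c, p in tr["pairs"]})
    return lineages, times
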