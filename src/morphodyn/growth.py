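"""Growth-tensor isotropy of tracked sectors.

A sector followed between two timepoints is summarised by a 2x2 linear map
estimated on matched landmarks after projecting each point set onto its
least-squares plane. The singular values of the
map are the principal stretches (s_max >= s_min); growth isotropy is their
ratio s_min / s_max (1 = uniform expansion, -> 0 = strongly oriented
growth). A rate-ratio variant, (s_min - 1) / (s_max - 1), ratios relative
expansions instead of stretch factors.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DegenerateGeometryError(ValueError):
    """Points are collinear/rank-deficient for the requested fit."""


@dataclass
class PlaneFrame:
    """Least-squares plane through a 3D point cloud.

    ``basis`` rows are two orthonormal in-plane directions; ``normal`` is
    the minimum-variance principal direction.
    """

    origin: np.ndarray        # (3,)
    basis: np.ndarray         # (2, 3)
    normal: np.ndarray        # (3,)


@dataclass
class GrowthResult:
    linear_map: np.ndarray    # (2, 2)
    stretches: tuple[float, float]   # (s_max, s_min)
    isotropy: float
    mode: str                 # stretch_ratio | rate_ratio
    residual_rms: float = 0.0
    degenerate_zero_growth: bool = False


def fit_plane(points: Sequence) -> PlaneFrame:
    """Plane through the centroid minimising the sum of squared
    point-plane distances (total least squares via SVD)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need >= 3 points of dimension 3")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear")
    return PlaneFrame(origin=origin, basis=vt[:2], normal=vt[2])


def project(points: Sequence, frame: PlaneFrame) -> np.ndarray:
    """In-plane coordinates of the orthogonal projections onto the frame."""
    pts = np.asarray(points, dtype=float)
    return (pts - frame.origin) @ frame.basis.T


def estimate_affine2d(p0: Sequence, p1: Sequence
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares affine fit p1 ~ A @ p0 + b on matched 2D landmarks.

    Returns ``(A, b, residual_rms)``; exact (zero residual) when the point
    sets are related by an affine map.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if p0.shape != p1.shape or p0.ndim != 2 or p0.shape[1] != 2:
        raise ValueError("p0 and p1 must be matched (n, 2) arrays")
    if len(p0) < 3:
        raise DegenerateGeometryError("need >= 3 landmark pairs")
    design = np.column_stack([p0, np.ones(len(p0))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("landmarks are collinear")
    coef, *_ = np.linalg.lstsq(design, p1, rcond=None)
    A = coef[:2].T
    b = coef[2]
    resid = p1 - (p0 @ A.T + b)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return A, b, rms


def isotropy(linear_map: np.ndarray, mode: str = "stretch_ratio",
             residual_rms: float = 0.0, zero_growth_tol: float = 1e-6
             ) -> GrowthResult:
    """Growth isotropy of a 2x2 linear map.

    stretch_ratio: s_min / s_max of the singular values. rate_ratio:
    (s_min - 1) / (s_max - 1), clamped to [0, 1], defined for s_max > 1.
    A map with both stretches within ``zero_growth_tol`` of 1 is flagged as
    zero-growth degenerate and reported as isotropy 1.
    """
    A = np.asarray(linear_map, dtype=float)
    s = np.linalg.svd(A, compute_uv=False)
    s_max, s_min = float(s[0]), float(s[1])
    if s_min <= 1e-12:
        raise DegenerateGeometryError("singular linear map")
    if mode not in ("stretch_ratio", "rate_ratio"):
        raise ValueError(f"unknown isotropy mode {mode!r}")
    degenerate = abs(s_max - 1) < zero_growth_tol and abs(s_min - 1) < zero_growth_tol
    if degenerate:
        iso = 1.0
    elif mode == "stretch_ratio":
        iso = s_min / s_max
    else:
        if s_max <= 1:
            raise ValueError("rate_ratio mode undefined for s_max <= 1 "
                             "(no growth along the maximal axis)")
        iso = float(np.clip((s_min - 1) / (s_max - 1), 0.0, 1.0))
    return GrowthResult(linear_map=A, stretches=(s_max, s_min), isotropy=iso,
                        mode=mode, residual_rms=residual_rms,
                        degenerate_zero_growth=degenerate)


def interval_growth(points_t0: Sequence, points_t1: Sequence,
                    mode: str = "stretch_ratio") -> GrowthResult:
    """Growth tensor of one interval from matched 3D landmarks.

    Each timepoint is projected onto its own least-squares plane before
    the 2D affine fit. For a sector that stays in one plane this equals
    projecting both onto the earlier plane; fitting per timepoint keeps
    the principal stretches correct when a rigid motion tilts the sector
    between acquisitions (the frame change only contributes a rotation,
    which the singular values ignore).
    """
    q0 = project(points_t0, fit_plane(points_t0))
    q1 = project(points_t1, fit_plane(points_t1))
    A, _, rms = estimate_affine2d(q0, q1)
    return isotropy(A, mode=mode, residual_rms=rms)


def sector_growth_series(landmarks: Sequence, mode: str = "stretch_ratio"
                         ) -> list[GrowthResult]:
    """Isotropy per consecutive interval of a landmark time series.

    ``landmarks`` is a sequence of (n, 3) arrays, one per timepoint, with
    row-wise correspondence between consecutive timepoints.
    """
    if len(landmarks) < 2:
        raise ValueError("need landmarks at >= 2 timepoints")
    return [interval_growth(landmarks[i], landmarks[i + 1], mode=mode)
            for i in range(len(landmarks) - 1)]
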