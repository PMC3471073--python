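"""Coordination between cell volume and S-phase entry.

The core comparison pairs each S-phase-labelled (EdU+) cell with its
nearest unlabelled neighbour and tests whether the paired volume
differences are centred on zero with a Wilcoxon signed-rank test. Small
samples get an exact p-value (computed under the permutation null over
sign assignments, conditional on the observed ranks, so ties are handled
exactly); larger samples fall back to the tie-corrected normal
approximation with continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, norm, rankdata

EXACT_N_MAX = 25  # exact null enumeration up to this many nonzero pairs


class InsufficientControlsError(ValueError):
    """No unlabelled neighbour cells available for pairing."""


class DegenerateDataError(ValueError):
    """All paired differences are zero."""


@dataclass
class WilcoxonResult:
    n_pairs: int
    n_nonzero: int
    statistic: float          # W = sum of ranks of positive differences
    p_two_sided: float
    method: str               # exact | normal_approx
    p_one_sided_greater: Optional[float] = None


@dataclass
class BoxplotSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def select_controls(cells: pd.DataFrame) -> pd.DataFrame:
    """Pair each EdU+ cell with its nearest unpaired EdU- neighbour.

    Candidate pairs are taken in increasing centroid-distance order
    (greedy, without replacement), so a contested control goes to the
    closer labelled cell. Returns a PairSet DataFrame with columns
    (edu_cell_id, control_cell_id, volume_edu, volume_control, distance);
    unmatched EdU+ cells are simply not part of the pairing.
    """
    pos = cells[cells["edu"].astype(bool)]
    neg = cells[~cells["edu"].astype(bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise InsufficientControlsError(
            "pairing needs at least one EdU+ and one EdU- cell")
    ppos = pos[["cx", "cy", "cz"]].to_numpy()
    pneg = neg[["cx", "cy", "cz"]].to_numpy()
    k = min(len(neg), len(pos) + 5)  # enough neighbours to resolve contention
    dist, idx = cKDTree(pneg).query(ppos, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    candidates = sorted(
        (dist[i, j], i, idx[i, j])
        for i in range(len(pos)) for j in range(dist.shape[1]))
    used_pos: set[int] = set()
    used_neg: set[int] = set()
    rows = []
    for d, i, j in candidates:
        if i in used_pos or j in used_neg:
            continue
        used_pos.add(i)
        used_neg.add(j)
        rows.append((int(pos.iloc[i]["cell_id"]), int(neg.iloc[j]["cell_id"]),
                     float(pos.iloc[i]["volume_um3"]),
                     float(neg.iloc[j]["volume_um3"]), float(d)))
    return pd.DataFrame(rows, columns=["edu_cell_id", "control_cell_id",
                                       "volume_edu", "volume_control",
                                       "distance"])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample null
# ---------------------------------------------------------------------------

def _exact_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W over all sign assignments.

    Works on doubled ranks (mid-ranks from ties become integers) with a
    shift-convolution over the 2^n equally likely sign vectors; returns the
    support (on the doubled scale) and probabilities.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:len(pmf) - r]
        pmf = 0.5 * (pmf + shifted)
    return np.arange(total + 1), pmf


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Signed-rank test on paired differences (e.g. EdU+ minus control).

    Zero differences are dropped; ties among |differences| receive
    mid-ranks; W is the sum of ranks of positive differences. The
    two-sided p doubles the smaller tail (capped at 1); the exact method is
    used whenever the number of nonzero differences is <= 25.
    """
    if isinstance(differences, pd.DataFrame):
        differences = (differences["volume_edu"]
                       - differences["volume_control"]).to_numpy()
    d = np.asarray(differences, dtype=float)
    n_pairs = len(d)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_N_MAX:
        support, pmf = _exact_null_pmf(ranks)
        w2 = int(round(2 * w))
        p_low = float(pmf[support <= w2].sum())
        p_high = float(pmf[support >= w2].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        p_greater = p_high
        method = "exact"
    else:
        # tie-corrected variance; continuity correction of 0.5
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu - 0.5 * np.sign(w - mu)) / sigma
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        p_greater = float(norm.sf((w - mu - 0.5) / sigma))
        method = "normal_approx"
    return WilcoxonResult(n_pairs=n_pairs, n_nonzero=n, statistic=w,
                          p_two_sided=p, method=method,
                          p_one_sided_greater=p_greater)


def boxplot_summary(volumes) -> BoxplotSummary:
    """Five-number summary; quartiles by linear interpolation of order
    statistics (numpy's default convention)."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return BoxplotSummary(minimum=float(v.min()), q1=float(q1),
                          median=float(med), q3=float(q3),
                          maximum=float(v.max()), n=int(v.size))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class CoordinationReport:
    pairs: pd.DataFrame
    wilcoxon: WilcoxonResult
    summary_edu: BoxplotSummary
    summary_control: BoxplotSummary
    median_difference: float
    alpha: float
    coordinated: bool
    mannwhitney_p: Optional[float] = None


def coordination_report(cells: pd.DataFrame, alpha: float = 0.05,
                        paired: bool = True) -> CoordinationReport:
    """Full volume/S-phase coordination analysis of one cell table.

    ``coordinated`` is True when the (two-sided) test rejects at ``alpha``
    and the EdU+ median volume exceeds the control median — the signature
    of a volume checkpoint gating S-phase entry. An unpaired Mann-Whitney
    p-value is included for sensitivity analysis.
    """
    pairs = select_controls(cells)
    wres = wilcoxon_signed_rank(pairs)
    se = boxplot_summary(pairs["volume_edu"])
    sc = boxplot_summary(pairs["volume_control"])
    med_diff = float(np.median(pairs["volume_edu"] - pairs["volume_control"]))
    pos = cells[cells["edu"].astype(bool)]["volume_um3"]
    neg = cells[~cells["edu"].astype(bool)]["volume_um3"]
    mw_p = float(mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    p = wres.p_two_sided if paired else mw_p
    coordinated = bool(p < alpha and se.median > sc.median)
    return CoordinationReport(pairs=pairs, wilcoxon=wres, summary_edu=se,
                              summary_control=sc, median_difference=med_diff,
                              alpha=alpha, coordinated=coordinated,
                              mannwhitney_p=mw_p)


def heterogeneity_trend(cell_tables: list[pd.DataFrame]
                        ) -> tuple[np.ndarray, bool]:
    """CV of cell volumes per timepoint and a strict-increase flag."""
    if len(cell_tables) < 2:
        raise ValueError("need >= 2 timepoints")
    cvs = []
    for tab in cell_tables:
        v = tab["volume_um3"].to_numpy(dtype=float)
        m = v.mean()
        cvs.append(0.0 if m == 0 or len(v) < 2 else float(v.std(ddof=1) / m))
    cvs = np.array(cvs)
    return cvs, bool(np.all(np.diff(cvs) > 0))
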