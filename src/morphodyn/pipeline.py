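"""End-to-end orchestration: simulate -> render -> segment -> track ->
growth tensor -> coordination statistics.

A run is described by a :class:`RunConfig` (round-trippable to YAML) and
produces a :class:`RunReport` plus a directory of intermediate files:
per-timepoint cell tables (CSV), lineage JSON, sector metrics CSV, a
report JSON and a config echo. With ``use_segmentation=True`` each
snapshot is rendered to a confocal-like stack and re-measured through the
watershed pipeline; otherwise the simulator's ground-truth tables are
analysed directly. All randomness derives from the two seeds in the
config, and outputs are byte-reproducible for a fixed config.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import growth, segment, stats, tissue, tracking
from .render import RenderParams, render_stack
from .segment import SegmentationParams


@dataclass
class RunConfig:
    preset: str = "meristem"
    hours: float = 48.0
    seed: int = 1
    render_seed: int = 0
    n_cells: int = tissue.DEFAULT_N_CELLS
    domain_radius: float = tissue.DEFAULT_RADIUS
    thickness: float = tissue.DEFAULT_THICKNESS
    dt: float = 0.5
    snapshot_times: Optional[list[float]] = None
    use_segmentation: bool = True
    save_stacks: bool = False
    tracking_max_distance: float = 8.0   # um gate on parent assignment
    isotropy_mode: str = "stretch_ratio"
    alpha: float = 0.05
    render: RenderParams = field(default_factory=RenderParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["render"]["voxel_size"] = list(self.render.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "render" in d and isinstance(d["render"], dict):
            r = dict(d["render"])
            if "voxel_size" in r:
                r["voxel_size"] = tuple(r["voxel_size"])
            d["render"] = RenderParams(**r)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    config: dict
    timepoints: list[float]
    n_cells: list[int]
    sector_metrics: pd.DataFrame
    growth_results: list[growth.GrowthResult]
    coordination: stats.CoordinationReport
    cv_series: np.ndarray
    cv_increasing: bool
    tracking_accuracy_vs_truth: Optional[float] = None

    @property
    def isotropy_per_interval(self) -> list[float]:
        return [g.isotropy for g in self.growth_results]

    def summary(self) -> dict:
        w = self.coordination.wilcoxon
        return {
            "preset": self.config["preset"],
            "timepoints_hr": self.timepoints,
            "n_cells": self.n_cells,
            "n_cells_fold_change": self.n_cells[-1] / self.n_cells[0],
            "mean_volume_first_um3": float(
                self.sector_metrics["mean_volume"].iloc[0]),
            "mean_volume_last_um3": float(
                self.sector_metrics["mean_volume"].iloc[-1]),
            "cv_cell_volume": [float(c) for c in self.cv_series],
            "cv_increasing": self.cv_increasing,
            "isotropy_per_interval": self.isotropy_per_interval,
            "wilcoxon_W": w.statistic,
            "wilcoxon_p": w.p_two_sided,
            "wilcoxon_method": w.method,
            "n_pairs": w.n_pairs,
            "median_volume_edu_um3": self.coordination.summary_edu.median,
            "median_volume_control_um3": self.coordination.summary_control.median,
            "coordinated": self.coordination.coordinated,
            "tracking_accuracy_vs_truth": self.tracking_accuracy_vs_truth,
        }


def _measured_tables(run: tissue.SimulationRun, config: RunConfig,
                     outdir: Optional[Path]) -> list[pd.DataFrame]:
    """Cell tables per snapshot, via rendering + segmentation or directly
    from the simulator ground truth."""
    tables = []
    for k, snap in enumerate(run.snapshots):
        if config.use_segmentation:
            rp = dataclasses.replace(config.render,
                                     rng_seed=config.render_seed + k)
            img, gt = render_stack(snap, rp)
            labels, table = segment.segment_stack(img, config.segmentation)
            if "edu" not in table.columns:
                table["edu"] = False
            if outdir is not None and config.save_stacks:
                from .images import write_tiff
                write_tiff(img, outdir / f"stack_t{int(snap.t_hr):03d}.tif")
                write_tiff(labels, outdir / f"labels_t{int(snap.t_hr):03d}.tif")
            table = table.assign(t_hr=snap.t_hr)
        else:
            table = tissue.snapshot_table(snap)
        tables.append(table)
    return tables


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline for one configuration."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    run = tissue.simulate(config.preset, config.hours, config.seed,
                          n_cells=config.n_cells,
                          domain_radius=config.domain_radius,
                          thickness=config.thickness, dt=config.dt,
                          snapshot_times=config.snapshot_times)
    tables = _measured_tables(run, config, out)
    times = run.timepoints

    # track consecutive timepoints (full affine handles anisotropic growth)
    lineages = []
    for t0_tab, t1_tab in zip(tables[:-1], tables[1:]):
        transform = tracking.register_affine(t0_tab, t1_tab)
        lineages.append(tracking.track_cells(
            t0_tab, t1_tab, transform,
            max_distance=config.tracking_max_distance))

    track_acc = None
    if not config.use_segmentation:
        correct = total = 0
        for k, lineage in enumerate(lineages):
            truth = run.lineage_between(times[k], times[k + 1])
            for child, parent in lineage.items():
                correct += int(truth.get(child) == parent)
                total += 1
        track_acc = correct / total if total else None

    # the whole sheet as one sector; clones from tracked lineage
    sector = tracking.SectorDefinition(
        founder_ids=set(tables[0]["cell_id"].astype(int)), name="sheet")
    clones = tracking.build_clones(sector, lineages, tables)
    metrics = tracking.sector_metrics(clones, tables)

    # growth tensors on volume-weighted clone centroids
    landmarks = _clone_landmarks(clones, tables)
    growth_results = growth.sector_growth_series(landmarks,
                                                 mode=config.isotropy_mode)

    coord = stats.coordination_report(tables[-1], alpha=config.alpha)
    cv_series, cv_up = stats.heterogeneity_trend(tables)

    report = RunReport(config=config.to_dict(), timepoints=times,
                       n_cells=[len(t) for t in tables],
                       sector_metrics=metrics, growth_results=growth_results,
                       coordination=coord, cv_series=cv_series,
                       cv_increasing=cv_up,
                       tracking_accuracy_vs_truth=track_acc)
    if out is not None:
        _write_outputs(report, run, tables, lineages, out)
    return report


def _clone_landmarks(clones: dict[int, list[set[int]]],
                     tables: list[pd.DataFrame]) -> list[np.ndarray]:
    """Volume-weighted clone centroids, rows matched across timepoints.

    Volume weighting makes a clone's landmark the centroid of its region,
    which transforms exactly under the tissue's affine growth map even
    after divisions change the member list.
    """
    n_t = len(tables)
    founders = [f for f, per_t in clones.items()
                if all(per_t[k] for k in range(n_t))]
    if len(founders) < 3:
        raise ValueError("need >= 3 clones surviving at all timepoints")
    out = []
    for k, table in enumerate(tables):
        t = table.set_index(table["cell_id"].astype(int))
        pts = []
        for f in founders:
            members = sorted(clones[f][k])
            sub = t.loc[members]
            w = sub["volume_um3"].to_numpy()
            xyz = sub[["cx", "cy", "cz"]].to_numpy()
            pts.append((w[:, None] * xyz).sum(axis=0) / w.sum())
        out.append(np.array(pts))
    return out


def _write_outputs(report: RunReport, run: tissue.SimulationRun,
                   tables: list[pd.DataFrame],
                   lineages: list[dict[int, Optional[int]]],
                   out: Path) -> None:
    for table in tables:
        t_hr = float(table["t_hr"].iloc[0])
        cols = [c for c in table.columns]
        table.to_csv(out / f"cells_t{int(round(t_hr)):03d}.csv", index=False,
                     float_format="%.6f", columns=cols)
    tracking.write_lineage_json(lineages, report.timepoints,
                                out / "lineage.json")
    report.sector_metrics.to_csv(out / "sector_metrics.csv", index=False,
                                 float_format="%.6f")
    pairs = report.coordination.pairs
    pairs.to_csv(out / "pairs.csv", index=False, float_format="%.6f")
    (out / "report.json").write_text(
        json.dumps(report.summary(), indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(report.config))


# ---------------------------------------------------------------------------
# regime comparison
# ---------------------------------------------------------------------------

#: Similarity thresholds for :func:`compare_regimes`: two regimes are
#: called similar in a metric when their absolute difference stays below
#: the threshold. Chosen midway between the meristem-like and
#: primordium-like values the presets produce.
SIMILARITY_THRESHOLDS = {
    "n_cells_fold_change": 1.0,
    "mean_volume_change": 0.25,   # on the ratio last/first
    "cv_trend": 0.15,             # on cv(last) - cv(first)
    "isotropy": 0.2,              # on the mean interval isotropy
}


def compare_regimes(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Side-by-side regime comparison of two run reports.

    Rows: cell-number fold change, mean-volume ratio, volume-CV trend,
    mean growth isotropy and the coordination flag; ``similar`` marks
    metrics whose difference is below :data:`SIMILARITY_THRESHOLDS`.
    """
    def metrics(rep: RunReport) -> dict:
        sm = rep.sector_metrics
        return {
            "n_cells_fold_change": rep.n_cells[-1] / rep.n_cells[0],
            "mean_volume_change": float(sm["mean_volume"].iloc[-1]
                                        / sm["mean_volume"].iloc[0]),
            "cv_trend": float(rep.cv_series[-1] - rep.cv_series[0]),
            "isotropy": float(np.mean(rep.isotropy_per_interval)),
            "coordinated": float(rep.coordination.coordinated),
        }

    ma, mb = metrics(report_a), metrics(report_b)
    if set(ma) != set(mb):
        raise ValueError("reports do not share a metric schema")
    rows = []
    for key in ma:
        delta = abs(ma[key] - mb[key])
        thr = SIMILARITY_THRESHOLDS.get(key, 0.5)
        rows.append({"metric": key, "a": ma[key], "b": mb[key],
                     "delta": delta, "threshold": thr,
                     "similar": delta < thr})
    return pd.DataFrame(rows)
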