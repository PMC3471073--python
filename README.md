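# morphodyn

Cell-resolution analysis of growing plant tissue, built around the
question of how an epidermis coordinates cell volume with the cell cycle
while an organ primordium emerges from a meristem. The package bundles
five things that normally live in separate scripts:

1. **A synthetic growing epidermis** — a polygonal cell sheet of uniform
   thickness advanced by a tissue-level exponential growth field
   (isotropic or anisotropic) and a cell-cycle rule: *sizer* (S-phase
   entry at a threshold volume, the meristem checkpoint), *timer*
   (exponential G1, volume-blind) or a mid-run *switch* that removes the
   checkpoint. A terminal 3 h EdU pulse labels cells whose S phase
   overlaps the window. Ground-truth lineage comes for free.
2. **Confocal-like rendering** — wall and nuclear channels on a voxel
   grid, optional Gaussian PSF and Gaussian/Poisson noise, plus the exact
   label-image ground truth.
3. **Seeded 3D watershed segmentation** with voxel-count volumetry
   (volume = voxels × voxel volume) and per-cell EdU classification.
4. **Clone tracking** — Procrustes/affine registration of consecutive
   timepoints, nearest-transformed-centroid lineage assignment, clonal
   sectors and their growth metrics.
5. **Growth tensors and statistics** — least-squares plane projection,
   2D affine estimation, growth isotropy
   `s_min/s_max` of the principal stretches (1 = uniform growth, → 0 =
   strongly oriented), and an exact Wilcoxon signed-rank test on
   EdU⁺/neighbour-control volume pairs.

Intended users: plant developmental biologists and image-analysis people
who want a fully verifiable stand-in for 3D live-imaging pipelines —
every stage here can be scored against simulator ground truth.

## The statistics at the core

For a tracked sector with matched landmarks `x_i(t0), x_i(t1)` the growth
tensor is the least-squares 2×2 map `A` with
`P(x_i(t1)) ≈ A·P(x_i(t0)) + b`, where `P` projects onto the sector's
least-squares plane. With singular values `s_max ≥ s_min` of `A`,

    isotropy = s_min / s_max          (stretch-ratio mode)
    isotropy = (s_min−1)/(s_max−1)    (rate-ratio mode, growth only)

For volume/cell-cycle coordination, each EdU⁺ cell is paired with its
nearest EdU⁻ neighbour; differences `d_i = V_i⁺ − V_i⁻` go into a
Wilcoxon signed-rank test whose p-value is exact (full null enumeration
over sign assignments, mid-ranks for ties) for up to 25 informative
pairs, with a tie-corrected normal approximation beyond.

## Worked example

```python
from morphodyn import coordination_report, simulate

table = simulate("meristem", hours=48.0, seed=1).cell_table(48.0)
rep = coordination_report(table)
print(rep.wilcoxon.n_pairs, rep.summary_edu.median,
      rep.summary_control.median, rep.wilcoxon.p_two_sided,
      rep.coordinated)
```

prints (from `examples/coordination_test.py`):

```
meristem: 72 EdU+/control pairs (normal_approx)
  median volume: EdU+ 161.0 um^3, control 135.6 um^3 (paired median diff +25.2)
  W = 2373.0, two-sided p = 2.85e-09  ->  coordinated = True
```

i.e. under the size checkpoint, cells caught synthesising DNA are
systematically larger than their neighbours (median 161 vs 136 µm³).
Running the same analysis on the `primordium_wt` preset (timer cycle)
gives p = 0.85 — S-phase entry is decoupled from volume — and the
`ectopic` preset (checkpoint removed mid-run) drives the population
median down to ~97 µm³ because cells enter S phase abnormally small.

The growth side (`examples/growth_isotropy.py`): the meristem's isotropic
field scores isotropy 1.000 per 24 h interval, while the primordium's
anisotropic field (0.04 vs 0.01 /hr) scores 0.487, matching the imposed
stretch ratio exp(0.24)/exp(0.96).

Other entry points: `examples/` has one short script per capability, and
`morphodyn simulate|segment|track|growth|stats|run` exposes the same
stages on the command line (`morphodyn run --config run.yaml --out dir/`
writes cell tables, lineage JSON, sector metrics and a report JSON).

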