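# Methods

## Tissue model

The simulated tissue is a single epidermal cell layer: a planar
tessellation of convex polygons extruded to a uniform thickness (default
5 µm), so cell volume is polygon area × thickness throughout. This
reduction is justified by the biology the generator emulates — epidermal
thickness stays uniform while the sheet grows — and it makes every
downstream quantity (volumes, centroids, growth tensors) exactly
computable for verification.

Growth is a tissue-level field, not a per-cell property: over a step
`dt`, every vertex is mapped by `R·diag(exp(r_max·dt), exp(r_min·dt))·Rᵀ`
where `R` rotates into the field's frame. Equal rates give isotropic
expansion; the anisotropic preset uses (0.04, 0.01) /hr with the fast
axis along +y (the apical–basal direction of an emerging organ). Volumes
rescale by the determinant, so total volume bookkeeping is exact to
floating point.

### Cell cycle

Each cell is in G1, S or G2/M. Three entry rules for G1→S:

* **sizer** — entry when volume ≥ `v* · (1+ε)`, with `ε ~ N(0, noise_cv)`
  drawn once per cell. This is the meristem's size checkpoint.
* **timer** — entry after an exponentially distributed G1 duration
  (mean `g1_mean`), independent of volume. The exponential is a choice;
  nothing downstream depends on its shape beyond being volume-blind and
  dispersed.
* **switch** — sizer before `switch_time`, timer after: the
  checkpoint-removal scenario.

S and G2/M have fixed durations; after G2/M the cell divides along the
line perpendicular to its long (principal-moment) axis. The division
plane's intercept is offset stochastically along that axis
(SD = `division_asymmetry` × cell extent, default 0.025), giving slightly
unequal daughters. The offset is not cosmetic: with exact centroid splits
and a shared growth field, a sizer population locks into permanent
synchronous division waves (every daughter of a cohort is identical and
re-reaches the threshold simultaneously); small division asymmetry is
what real tissues have and what keeps the simulated population
desynchronised. Daughter volumes always sum to the mother's volume
exactly (the split is a geometric partition).

### Presets (the study conditions)

| preset | field (/hr) | checkpoint | notes |
|---|---|---|---|
| `meristem` | isotropic 0.0125 | sizer, v* = 150 µm³, cv 0.03 | ~27.7 h cycle; volumes cycle ≈ 104–207 µm³ |
| `primordium_wt` | anisotropic (0.04, 0.01) | timer, mean G1 6 h | faster cycle (~18.5 h), rising volume CV |
| `primordium_jag` | as meristem | as meristem | the reverted-to-meristem condition |
| `ectopic` | isotropic 0.0125 | sizer → timer (G1 2 h) at hours/2 | checkpoint removal mid-run |

S = 5 h and G2/M = 8.3 h everywhere, placing division at
`150·e^(0.025·13.3) ≈ 207 µm³` and births at ~104 µm³, i.e. the meristem
population lives in the 100–200 µm³ band. The growth rate 0.0125/hr sets
a 27.7 h cycle so that no cell divides twice within a 24 h imaging
interval. None of these numbers is a measurement; they are generator
parameters chosen once to put the meristem regime in a realistic volume
band and cycle time.

### Initialisation and burn-in

Founders come from a centroidal Voronoi (Lloyd) tessellation of a disc —
which means they all start at nearly the same volume and, naively, would
divide as one synchronous cohort. Every run therefore starts with a 36 h
burn-in from a proportionally smaller disc under the sizer regime
(timer presets too: their cells descend from meristem cells, and the
regime switch at t = 0 is exactly the biological transition being
modelled). G1 founders additionally draw a first-cycle S-entry threshold
spread uniformly over one G1 length, which removes the founding wave
immediately. The t = 0 snapshot is thus a steady cycling population;
lineage bookkeeping starts there.

EdU labelling marks any cell whose S interval overlaps the final 3 h of
the run (the experimental pulse length); there is no partial-labelling
intensity model.

## Rendering

`render_stack` rasterises a snapshot on a (z, y, x) voxel grid (default
0.5 × 0.25 × 0.25 µm) with 2 µm of empty padding. The wall channel marks
every voxel within half a voxel of a cell boundary — one layer on *each*
side of lateral walls, the tissue outline and the top/bottom faces. The
symmetry matters: the watershed crest then falls on the true boundary,
so basins divide wall voxels the same way the ground truth does. The
nuclear channel places a 2.5 µm-radius sphere at each EdU⁺ cell's
centroid (plant meristem nuclei are large relative to these small
cells; the radius also makes a mean-intensity threshold at half the
nucleus intensity a clean classifier). Optional isotropic Gaussian PSF
and Gaussian or Poisson noise follow; all noise is seeded. The
ground-truth label image is the full partition of the slab: every voxel
whose centre lies in a cell's polygon carries that id, which is the
definition under which voxel counting reproduces polygon-extrusion
volumes.

## Segmentation

Wall channel → Gaussian smoothing (0.3 µm) → h-minima suppression
(depth 0.2 in units of the wall intensity) → one seed per basin →
watershed. Two post-stages:

* **Background**: basins touching the image border with mean smoothed
  intensity below `background_threshold` (0.3) are relabelled 0. (A
  lowest-mean rule alone is degenerate on noiseless stacks where every
  interior is exactly 0.)
* **Weak-boundary merging**: interfaces between adjacent labels whose
  mean smoothed wall intensity is below `merge_boundary_threshold` (0.4)
  are dissolved, iterating until stable. This repairs the one systematic
  watershed failure on these images — a narrow, recently divided cell
  whose interior is pinched into two basins at a junction. A false split
  crosses dark interior; a real wall is bright.

Volumes are voxel counts × voxel volume, exactly. EdU positivity is the
mean nuclear intensity inside the label eroded by 0.75 µm (box min/max
filter; fully eroded cells fall back to the whole mask), thresholded by
Otsu over the per-cell means (degenerate distributions → all negative)
or a fixed cutoff. Defaults were tuned on noiseless rendered fixtures;
on those fixtures the pipeline recovers every cell at Jaccard ≥ 0.95
with median volume error below 1%.

## Tracking and clones

Consecutive cell tables are registered by a similarity Procrustes
(Umeyama) fit. Without anchors, correspondences are mutual nearest
neighbours after normalising both clouds to zero mean and unit RMS
radius — necessary because consecutive snapshots differ by a ~1.4–2×
dilation. For anisotropic growth no similarity transform can align the
clouds, so `register_affine` initialises a full 3D affine from the cloud
covariances (`A = C₁^{1/2}·U·C₀^{-1/2}`, `U` the similarity rotation —
exact when the clouds differ by an affine map) and refines it by
iterated matching with a trimmed least-squares fit.

Each later-timepoint cell takes the parent with the nearest transformed
centroid, gated at `max_distance` (8 µm default); daughters of a
division naturally share a parent. Parents assigned more than 2 children
per transition are logged, not rejected (the primordium's ~18.5 h cycle
makes double divisions per 24 h legitimate). Clones are the transitive
descendants of founder sectors; sector metrics report n_cells,
mean ± *sample* SD of cell volume (n−1 convention), total volume, CV of
cell volumes and CV of per-clone total volumes.

## Growth tensors

Landmarks default to volume-weighted clone centroids — the centroid of a
clone's region transforms exactly under an affine growth map even after
divisions change the membership, which is why the pipeline recovers the
imposed stretch ratio to three digits despite imperfect per-cell
tracking. Each timepoint's landmark set is projected onto its own
total-least-squares plane (per-timepoint frames leave the principal
stretches invariant under rigid motion between acquisitions; for
coplanar time-lapse data this equals using one common frame). The 2D
affine fit minimises `Σ‖A·p0ᵢ + b − p1ᵢ‖²`; isotropy is `s_min/s_max`
of `A`'s singular values (default), or `(s_min−1)/(s_max−1)` clamped to
[0, 1] in rate-ratio mode, which requires actual growth (`s_max > 1`).
Maps with both stretches within 1e−6 of 1 are flagged zero-growth
degenerate and reported as isotropy 1.

## Coordination statistics

Pairing is greedy nearest-neighbour without replacement in increasing
distance order, so a contested control goes to the closer EdU⁺ cell.
The Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
and computes `W` = sum of ranks of positive differences. For ≤ 25
informative pairs the two-sided p is exact: the null distribution of `W`
over all 2ⁿ sign assignments is built by shift convolution on doubled
ranks (integers even with mid-ranks), and the smaller tail is doubled,
capped at 1. Beyond 25, a tie-corrected normal approximation with
continuity correction takes over. The `coordinated` flag requires both
rejection at α (default 0.05, two-sided, single pre-planned test — no
multiplicity correction) and EdU⁺ median > control median; an unpaired
Mann–Whitney p accompanies every report as a sensitivity check.

## Pipeline and regime comparison

`run_all` chains simulate → render → segment → track → growth → stats,
deterministic for fixed seeds down to byte-identical CSV/JSON outputs
(fixed float formatting, no unordered iteration). In synthetic mode the
whole sheet is one region/sector. `compare_regimes` reports deltas in
cell-number fold change, mean-volume ratio, volume-CV trend, mean
isotropy and the coordination flag, with similarity thresholds (1.0,
0.25, 0.15, 0.2) set midway between what the meristem-like and
primordium-like presets produce.

## What the generator does and does not emulate

It reproduces: tight vs widening cell-volume distributions under sizer
vs timer control, isotropic vs oriented tissue expansion, EdU
pulse-labelling logic, confocal-like two-channel stacks with PSF and
noise, and full lineage. It does not model: cell mechanics or wall
stresses, curved 3D organ geometry (the sheet is flat), per-cell growth
variability (growth is a global field), nucleus placement off-centroid,
anisotropic PSFs, or imaging artefacts like attenuation with depth.
Consequently, passing tests show the *analysis chain* is correct and
well calibrated under the stated model; they do not certify performance
on real stacks with depth-dependent signal loss or non-affine
deformation.

## Test problem sizes

Simulations in the test suite use sheets of ~35–60 cells at t = 0 over
24–48 h (a few hundred cells at the end), rendered stacks of roughly
190 × 190 × 18 voxels, 200 simulated datasets per operating-characteristic
arm (~30 pairs each), and 30 rendered fixtures for segmentation scoring —
sizes chosen so the full suite runs in a few minutes on one core while
leaving every statistical margin comfortable.
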