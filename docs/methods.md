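# Methods

`nucleodrift` quantifies interphase nuclear movement in rod-shaped,
tip-growing cells (the fission-yeast geometry) from single-cell fluorescence
time-lapse movies, and ships a synthetic-data generator that emulates the
study conditions so that every pipeline stage can be validated against
ground truth. This note records the model, the measurement definitions, the
numerical choices, and the limits of what the synthetic validation shows.

## 1. Trajectory model

Nuclear position is reduced to one dimension: the axial coordinate `x` (µm)
along the cell's long axis, with the origin at the non-growing tip at t=0
and the growing tip at `L0`. The cell elongates at one tip at rate
`vg` (default 0.03 µm/min, within the 0.02–0.04 µm/min range typical of
25 °C growth); the non-growing tip undergoes slow apparent outward extension
`swell_rate` (default 0.002 µm/min) representing the tip-swelling shape
change that contaminates the uncorrected velocity estimator. The nucleus
follows an Euler–Maruyama discretization of

    dx = f(x, t) dt + sigma dW,

with `sigma` (µm/min^0.5, default 0.03) an effective diffusion amplitude
and the drift `f` set by the regime:

- **wt_dmso** (microtubules present): `f = -k (x - L(t)/2)` — an
  Ornstein–Uhlenbeck restoring force toward the instantaneous cell midpoint
  (`k` default 0.05/min). The observed behavior constrains only that
  recentering velocity grows with displacement; the linear law is the
  minimal choice.
- **wt_mbc** (microtubules depolymerized): `f = v(g) = vmax exp(-g/lam)`,
  where `g = tip_g - x` is the distance from nucleus to the growing tip.
  The observations are qualitative — movement is strong very near the
  growing tip, absent far from it, always directed toward it, and never
  faster than tip growth — so a two-parameter exponential decay is used,
  with `vmax = vg = 0.03 µm/min` enforcing the growth-rate cap.
- **cable_null_mbc** (no actin cables, no microtubules): `f = 0`; only
  diffusion and the swelling artifact remain.
- **myo52_mbc**: `f` alternates between `v(g)` and an aberrant state (zero
  or sign-reversed `v(g)`, chosen with equal probability on entry) via a
  two-state Markov switch with rates 0.05/min each way, reproducing the
  intermittent stalls and reversals of that genotype. Only the phenotype
  mixture is constrained by observation; the switch is the simplest
  generator of it.

**Calibration of `lam`.** The reported net tip-directed velocity in the
depolymerized regime is ≈12 nm/min for nuclei starting near the cell
center. With `vmax` pinned to `vg`, `lam` is the single free parameter; it
is set to 6.0 µm, the value at which `v(g) = 12 nm/min` exactly at
`g = 5.5 µm` (a nucleus at the center of a full-grown ~11 µm cell). Under
the cohort defaults (L0 ~ U(8, 11) µm, x0 near the midpoint) this yields
simulated mean net velocities of 12–14 nm/min including the swelling
artifact, and >95% of 90-min movies classified "toward" at the 0.25 µm
threshold — matching the reported unanimity of direction.

The nucleus is confined to the cell interior with a margin of one nuclear
radius (clamped after each step); `tip_g` advances strictly when `vg > 0`,
and `g = tip_g - x` by construction. Identical config and seed give
identical trajectories.

## 2. Rendering

Each frame is drawn analytically in float intensity: a stadium-shaped cell
(width 3.5 µm) at cytoplasm level on background, a bright 1.5 µm cap at the
growing tip, an anti-aliased nuclear disk (radius 1.2 µm), optionally a
0.3 µm medial septum band; then Gaussian PSF blur (sigma 1.5 px at
0.10 µm/px), Poisson shot noise (1 count/photon), Gaussian read noise
(sd 5 counts), and 16-bit quantization. This emulates a tip+nucleus
reporter in already-projected 2D; the default canvas is 512×128 px with the
cell axis vertical and growth downward. Anti-aliased drawing makes the
noise-free nucleus centroid land within 0.25 px of truth, which is what
lets rendered cohorts serve as an end-to-end accuracy oracle. Things the
renderer deliberately does not model: optical sectioning and Z-projection
artifacts, neighboring cells, photobleaching, uneven illumination, camera
gain structure, cell bending, and nuclear deformation. Passing tests
therefore demonstrate correctness of the measurement chain, not robustness
to every pathology of real microscopy data.

## 3. Measurement pipeline

1. **Ingest**: multi-page TIFF with user-supplied pixel size and frame
   interval; Z-stacks are maximum-projected.
2. **Registration**: two modes. Whole-frame phase correlation with
   sub-pixel refinement (for multi-cell fields or constructed drift), and
   the default for single-cell crops: static-pole anchoring, which shifts
   each frame so the cell edge with the smallest net axial displacement and
   the lateral mask centroid stay at their frame-0 positions. The anchored
   mode exists because with one growing cell on a featureless background,
   tip growth is the dominant image motion and phase correlation absorbs it
   into the estimated translation, silently transferring growth to the
   wrong tip. Anchoring implements the operative criterion that cells are
   stationary in real space apart from their growing tips. Axial anchor
   shifts are integer pixels, so growth and swelling inside the frame are
   preserved as measured.
3. **Geometry**: per-frame three-class Otsu segmentation (background vs
   cell vs bright organelles), largest component, hole filling; principal-
   axis orientation from mask-pixel PCA; bilinear rotation to vertical.
   Tips are localized per frame to sub-pixel precision as the half-maximum
   crossings of the axial intensity profile (averaged over the central five
   columns), with the plateau estimated just inside each tip so the bright
   cap does not bias its own edge. A tip is "growing" when its net outward
   displacement exceeds `theta_grow` (0.5 µm per movie); exactly one
   growing tip = monopolar, two = bipolar (ties classify bipolar and are
   excluded from monopolar analyses), zero = none.
4. **Nucleus**: Otsu inside the cell mask; among bright components the
   largest whose centroid lies more than `d_cap` (1.5 µm) from both tips —
   this is what rejects the tip cap. Position = intensity-weighted centroid
   after subtracting the in-cell background median (binary centroid
   available as an option). Frames with no qualifying component are flagged
   `low_contrast`; per-frame displacements above `max_jump` (1.0 µm/frame;
   ground truth stays below ~0.3) are flagged `jump`; flagged frames are
   linearly interpolated, and tracks with >20% flags are rejected.
5. **Kymographs**: 11-px-wide reslice along the fitted axis (unit steps,
   bilinear samples, perpendicular mean; max available). QC product only —
   velocities come from tracks.
6. **Statistics**: net velocity = change in nucleus-to-non-growing-tip
   distance over the movie (nm/min, positive toward the growing tip),
   reported *uncorrected* for tip swelling; direction classified with a
   ±`epsilon` = 0.25 µm dead band (the qualitative scoring had no stated
   numeric criterion; 0.25 µm is ~2.5 px over a 90-min movie);
   centering ratio s/l and s/(s+l); late-interphase a/b with statistics on
   log2(a/b); septum position from the perpendicular-mean intensity peak in
   the central 60% of the cell with parabolic sub-pixel refinement; OLS of
   velocity on fractional start distance g/L (r² = squared Pearson, p from
   the slope t-statistic); tip growth rate as the least-squares slope of
   the growing-tip coordinate.

Because the axial origin is anchored to the (slowly swelling) static pole,
per-frame *distances* to the tips are the accuracy-bearing quantities;
absolute axial coordinates inherit up-to-1-px steps when the anchor crosses
a pixel boundary. End-to-end accuracy on default-noise renders: per-frame
nucleus-to-tip distance error ≤0.06 µm RMS; noise-free net-velocity error
≤0.5 nm/min per cell.

## 4. Fluctuation statistic

Tracks from 1-min-interval movies are detrended by subtracting a centered
running average of `W` frames (default 5; the original analysis never
stated its window, so `W` is a required, logged parameter). At the series
edges the window shrinks symmetrically, so the residual count equals the
frame count and affine trends are removed exactly everywhere. The
fluctuation amplitude is the RMS of the residuals. For iid noise of sd
sigma the interior residual variance is sigma²(1 − 1/W) — the Monte-Carlo
anchor used in the tests (0.0447 µm at sigma = 0.05, W = 5). Group
comparisons use a non-paired two-tailed t-test. The reported 40–50%
fluctuation increase in cable-null cells cannot be reproduced without the
real movies; the tests instead verify the machinery, including that
cohorts differing only in noise amplitude recover the amplitude ratio.

## 5. Problem sizes and determinism

Simulation-based checks use: 150-cell (drift regime) and 100-cell
(centering regime) rendered cohorts at 512×128 px and 19 frames for the
direction percentages; 20–40-cell cohorts for velocity recovery; 50
replicate 20-cell truth-level cohorts for the regression-signature
contrast; 500–1000 replicates for the statistical-calibration nulls. All
randomness flows through explicit integer seeds (per-cell seeds spawned
from a master seed), so every cohort, render, and test is reproducible
bit-for-bit.

## 6. Known limitations

- Single interphase cell per stack; no mitosis, septation tracking over
  time, or multi-cell scenes.
- Translation-only registration (no rotation correction; synthetic cells
  do not rotate, and orientation is handled by the axis fit).
- The drift law v(g) and the centering law are phenomenological; no
  mechanistic actin-gradient or membrane-tension physics is simulated.
- Whether the ~12 nm/min drift is a steady state or a transient is not
  observationally constrained; the exponential-decay law makes it a slowly
  decaying transient as g grows during the movie.
- The brightness-based growing-tip identification used visually on real
  reporters is replaced by the displacement criterion `theta_grow`;
  cap-brightness identification is not implemented.
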