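# Methods

## The measurement model

A saturation-pulse confocal acquisition alternates three light regimes on a
dark-adapted sample: a dark-reference block, a continuous actinic block, and
a dark relaxation block, with one z-stack acquired per time point.
`pulsescope` treats the protocol as data (`ProtocolTimeline`): each frame
carries a timestamp, a phase (`dark_reference` / `actinic` / `relaxation`,
always in that block order) and a pulse flag. The default protocol is 3 dark
+ 6 actinic + 6 relaxation frames at 60 s spacing (15 min total), with
saturating pulses of 2000 μmol photons m⁻² s⁻¹ for 1.1 s when a pulsed
(Y-mode) protocol is used.

Two measuring regimes are supported:

- **Sub-saturating measuring laser + saturating pulse**: `compute_Y` takes
  F′ as the mean of the pre-pulse frames and Fm as the maximum over the
  pulse frames, and returns `Y = (Fm − F′)/Fm`.
- **Saturating measuring laser** (the laser alone closes PSII in the small
  illuminated region): every frame then directly reads Fm (dark block) or
  Fm′ (light/relaxation). `compute_npq_series` takes Fm as the *mean* over
  the dark-reference block and computes `NPQ(t) = (Fm − F(t))/F(t)` for
  every later frame.

`ΦPSII = (Fm′ − Fs)/Fm′` is the standard saturation-pulse quotient; the
measuring setup defines Fs (steady state under a sub-saturating laser) and
Fm′ (laser + saturating LED concurrently). Where a single acquisition exists
per time point, that frame's corrected value is Fm′; if several acquisitions
share a time point their maximum is used.

Undefined quantities — NPQ at frames with non-positive corrected
fluorescence, slopes with fewer than two window points — propagate as NaN,
never as zeros, so downstream consumers can distinguish "no quenching" from
"not measurable".

## Image treatment

Stacks are ordered `(t, z, y, x)`, 0-based, physical sizes in μm. The z
"sum projection" accumulates integers in `int64` (floats in `float64`), so
for integer input the per-timepoint total intensity is conserved exactly —
this is asserted, not assumed. ROI quantification is the arithmetic mean
gray value over a static pixel mask per time point. Every object ROI is
paired with exactly one *empty* background ROI chosen by the caller; the
background trace is subtracted frame by frame, which also removes the
offset the external actinic light adds to the detector background. Negative
corrected values are kept (clamping would bias the NPQ quotient) and only
logged.

## Kinetic features and slopes

Per cell: NPQav and NPQmax are the mean and maximum NPQ over the actinic
frames; Induction (Decay) is the ordinary-least-squares slope of NPQ
against time, in min⁻¹, over the actinic (relaxation) frames whose time
since the transition is ≤ 120 s, boundary inclusive, with the transition
taken at the first frame of the new phase; Fmax is the dark-adapted Fm of
the cell; AreaFrac is the percent of the cell's projected area occupied by
plastids. Slopes need ≥ 2 points in the window, otherwise NaN.

## 3D reconstruction

Per time point: a box median filter of side `2r+1` (default r = 1, edge
replication) precedes segmentation — the median is edge-preserving, which
keeps thresholded volumes stable; the radius is exposed because no single
value suits all magnifications. Segmentation is a global threshold (Otsu on
the filtered volume by default, or user-supplied) followed by 26-connected
components on the index grid (connectivity is deliberately not
physical-distance based, so anisotropic voxels do not change object
topology), with components below `min_voxels` discarded and labels assigned
1..N by decreasing size. Object volume is voxel count × voxel volume;
integrated and mean fluorescence are summed over the *raw* intensities so
the filter never biases quantification. The interactive segmentation used
in manual workflows is replaced by this deterministic procedure for
reproducibility; the volume and fluorescence formulas are unchanged.

## Angular NPQ scanning

For cells whose plastids are too small and dense to separate: the cell
section is approximated by its equivalent-area circle (centroid centre,
radius √(area/π)); fluorescence is sampled along each radius by bilinear
interpolation (~1 sample per pixel, `ceil(r)+1` points) at 5° steps → 72
angles; per angle, Fm comes from the dark image and Fm′ from the
light-exposed image, and `NPQ(θ) = (Fm − Fm′)/Fm′`. The along-radius
reduction is the mean by default (sum and median are available; the NPQ
quotient is invariant to mean vs sum). Angles are measured from +x,
counter-clockwise in the y-up display convention. Profiles from ≥ 10 z
sections of one cell are aggregated per angle (mean, sample SD). The
interpolation scheme and the reduction are parameters because neither is
uniquely dictated by the measurement itself.

## Feature-table PCA

Six variables mix units, so each column is z-scored with the sample (n−1)
SD — a zero-variance column is a hard error naming the column — making the
decomposition an SVD of the correlation matrix (trace = 6). Eigenvalues are
s²/(n−1); explained-variance percentages are eigenvalues normalised to sum
to 100, which equals eigenvalue/6 × 100 in exact arithmetic but guarantees
the sum-to-100 invariant at float precision. Each loading's
largest-magnitude entry is flipped positive so output is deterministic
across BLAS implementations. Rows with any NaN feature are dropped (with a
logged count) before fitting; metadata columns (genotype, cell type) never
enter the fit.

## The synthetic-scene simulator

The simulator exists because representative raw acquisitions are not
publicly deposited in this domain; it emulates the features of real scenes
that the pipeline must cope with, and provides exact ground truth:

- **Geometry**: cells are axis-aligned boxes (or spheres) side by side,
  with an empty strip reserved for the background ROI. Default grid
  12 × 64 × 96 voxels at (2.0, 0.5, 0.5) μm — a deliberately compact scene
  (a few cells of ~20 × 30 μm with a realistic z extent) chosen so that a
  full render stays fast while preserving the per-axis sampling of a real
  acquisition (0.5 μm pixels, 2 μm z steps).
- **Plastids**: 8 per cell (plastid-rich juvenile-moss cells carry roughly
  5–10), FWHM radius 2 μm, confined random walk (0.2 μm per frame per
  axis, reflecting bounds ≥ 4σ inside the cell). Blobs are rendered as
  voxel-integrated (erf) Gaussian profiles: because voxels partition each
  axis, a blob's total intensity is *exactly* invariant under sub-voxel
  motion, which is what makes noise-free NPQ recovery exact at frame times
  rather than merely approximate.
- **Photophysics**: `F(t) = Fm/(1 + NPQ(t))` per plastid, the direct
  inversion of the NPQ definition. True NPQ follows
  `NPQmax·(1 − e^(−t/τ_ind)) + A_tr·(t/τ_tr)·e^(1 − t/τ_tr)` in the light
  and `NPQ_off·e^(−t/τ_rel)` in the dark (defaults NPQmax 2.0, τ_ind 90 s,
  τ_rel 120 s, no transient). These functional forms are the simulator's
  own model — chosen to reproduce the morphology of measured induction,
  relaxation and low-light transient-overshoot curves — not a mechanistic
  claim.
- **Background and noise**: uniform offset (50 a.u.) plus a step
  (10 a.u.) while the actinic light is on; optional Poisson shot noise
  then Gaussian read noise (default SD 20 a.u. = 5% of the 400 a.u. Fm
  peak). Negative values are clipped to zero, honouring the
  non-negative-counts invariant; the background level is set high enough
  that clipping is rare and does not measurably bias background
  subtraction.
- **Ground truth**: per-frame plastid masks are the half-maximum ellipsoid
  of the *rendered* profile (voxel integration widens the Gaussian by 1/12
  voxel² per axis, and the truth definition accounts for it). Overlapping
  plastids overwrite one another in the label volume, so per-plastid truth
  volumes are exact only for non-overlapping configurations — the
  volume-fidelity tests use 1–2 plastids per cell for that reason. Per-cell
  true NPQ curves, trajectories, cell footprints, the background mask and
  true AreaFrac are recorded alongside.

One seed drives placement, motion and noise; identical seeds give
bit-identical stacks (the OME-TIFF writer also pins its UUID so on-disk
artifacts are byte-identical).

**What passing simulator-based tests does and does not show.** Recovery
tests demonstrate that the analysis inverts the forward model it targets —
formula correctness, conservation, noise robustness at the stated level.
Real acquisitions add PSF blur, photobleaching/photoinhibition, focus drift
and structured (non-empty) backgrounds, none of which the simulator
models; quantitative performance on real data therefore still depends on
instrument-specific validation.

## Problem sizes and numerical choices

Default test and acceptance scenes are 15 frames of 12 × 64 × 96 voxels
(two cells), with 20 seeds for the noisy-recovery study — sizes chosen so
the full suite runs in seconds while keeping ROI statistics comparable to
a cropped real acquisition. Slope windows are boundary-inclusive at
exactly 120 s (with a 1 ns float guard). Segmentation ties in the
size-sorted relabelling are broken by original scan order. Otsu is the
default threshold for user data; simulator-fidelity tests use
background + half blob peak, the threshold that corresponds to the
half-maximum truth-mask definition.

## Known limitations

- Static ROIs: plastid motion is handled by imaging whole-cell volumes,
  not by mask tracking.
- No PSF/optics simulation, no photobleaching or photoinhibition model,
  single spectral channel.
- NPQ mode assumes the caller has verified the measuring laser saturates
  PSII (a laser-intensity titration on the instrument is the recommended
  check before quantitative runs).
- Background ROI placement is the caller's choice; no automatic "nearest
  empty region" heuristic is attempted.
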