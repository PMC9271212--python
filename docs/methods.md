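# Methods

This note documents the models, conventions and deliberate design choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the numerical details a user would need to reproduce or audit
a result.

## Imaging model and registration

Volumes are (z, y, x) voxel arrays with physical voxel sizes in μm;
positions are `index × voxel_size`, 0-based. The default acquisition
geometry is a 250 × 250 × 20 μm volume at 1024 × 1024 × 81 voxels
(≈0.244 μm in-plane, 0.25 μm z-step). Tests and the acceptance script use
scaled-down volumes (typically 80 × 80 × 20 μm at 0.5/1.0 μm voxels) so
that the full pipeline runs in seconds; all detection rules are expressed
in physical units and are unchanged by this choice.

* **Translation** is estimated by phase cross-correlation with 0.1-voxel
  subpixel refinement. The normalized cross-correlation (NCC) at the
  candidate shift is evaluated over the valid overlap only (the margin
  filled in by shifting is excluded — with low-contrast images the filled
  border otherwise dominates the score). A shift whose NCC falls below a
  confidence floor raises instead of returning silently.
* **Cross-day alignment** searches in-plane rotations exhaustively over
  ±5° in 0.25° steps (head-fixed repositioning drift is small), solving a
  translation at each angle. The score is NCC over a 20 %-border-cropped
  core, because rotation with constant fill leaves zeroed corners that
  correlate spuriously between candidate angles.
* **Autofluorescence subtraction** is
  `clamp(green/max(green) − red/max(red), 0) × max(green)`. Negative values
  are clamped because intensities are physical; rescaling to the original
  green maximum is this package's convention (the operation is otherwise
  scale-free). A structurally empty red channel returns the green stack
  unchanged with a warning. Subtraction is idempotent wherever signal and
  autofluorescence do not overlap spatially; where they do overlap, a
  second pass would subtract again — callers should subtract once.
* **Frame averaging** registers each frame to the first and takes the
  per-pixel mean (the 45-frames-per-z-plane convention that raises TS SNR
  by ≈√45).
* **Stitching** uses plain (non-phase-normalized) cross-correlation —
  phase normalization is brittle when the true overlap is partial — and
  resolves the FFT wrap-around ambiguity by scoring each candidate offset's
  overlap NCC, requiring ≥10 % overlap and NCC ≥ 0.5. The overlap is
  blended with a linear ramp along the dominant offset axis.

## Nucleus and TS detection

Nuclei are found by circular Hough voting on Canny edge maps of each XY
slice; per-slice candidates are grouped across z when their centers fall
within one mean radius, the z-centroid/z-radius come from a circle fit to
the radius-vs-z profile (the XZ-plane view of a sphere), and duplicate
groups closer than one mean radius are merged. Nuclei touching the XY
border are flagged `cropped`.

TS detection is rule-based, per nucleus: local maxima brighter than the
nuclear background mean + `k_sigma`·sd (default k = 4; the background is
the dimmest 90 % of nuclear voxels, so a bright TS does not inflate its own
threshold) form per-slice candidates; candidates in adjacent z slices
within one in-plane voxel (`xy_tolerance`) are chained; chains spanning
**at least two consecutive z slices** become detections, and at most two
detections (the brightest; one per allele) are retained per nucleus.

Cell calling: `cropped` nuclei and nuclei with mean GFP outside the
usability bounds (default: 5th–99th percentile of nuclear means) are
**ND**, and exclusion precedes calling — a cropped nucleus with a visible
spot is still ND. Remaining nuclei are Arc+ iff they carry ≥1 accepted
detection. The original workflow's two-blind-raters-plus-adjudicator step
is replaced by this deterministic rule set; k_sigma and the GFP bounds are
the knobs that stand in for rater judgment.

The two-Gaussian threshold fits one normal per labelled intensity group
and returns the equal-likelihood intersection between the means (closed
form via the quadratic in x; the equal-variance case degenerates to the
midpoint). Identical group means raise `inseparable`.

Time-lapse TS linking is greedy nearest-neighbor within `max_jump_um`,
closest pairs first, with configurable bridging of 1-frame gaps.

## smFISH quantification

Particles are fit by least squares to
`A·exp(−Σ(xᵢ−μᵢ)²/2σᵢ²) + b` over the crop, with moment-based
initialization and box bounds; non-convergence or a flat crop raises and
the particle is recorded as rejected. The integrated intensity is
`I = A·σx·σy·σz` (the 3D Gaussian integral up to a constant that cancels
in all ratios used). Classification: amplitude above threshold **and**
width (geometric mean of the three σ) above threshold ⇒ TS; amplitude
below threshold within the single-molecule width band ⇒ single mRNA; else
rejected. Colocalization across the two dye channels is mutual-nearest-
neighbor matching with a 0.3 μm cap — mutual (not one-sided greedy)
matching makes the operation symmetric and pairs unique.

Nascent copy number is `I_TS / median(I_single)` with a floor of 20
measured singles. The median is canonical (robust to the bright tail of
mis-segmented doublets); a `denominator="mean"` option is provided since
both conventions circulate. The estimate is invariant to global intensity
rescaling by construction.

## Calcium processing

ΔF/F: a mono-exponential bleach trend is fit and divided out, the baseline
is a running 20th percentile over a 30 s window, and
`ΔF/F = (F − baseline)/baseline` (replacing manual baseline selection with
a reproducible rule). The noise scale used everywhere downstream is the
robust sd of first differences, `1.4826·MAD(diff)/√2`, which stays
calibrated even when transients occupy much of the trace.

Transient events use hysteresis: onset when ΔF/F exceeds 3 baseline-SDs,
offset on return within 0.5 SD; intervals are half-open and disjoint.

Spike inference solves nonnegative AR(1) deconvolution
(`min ½‖c − y‖² + λΣs`, `s_t = c_t − g·c_{t−1} ≥ 0`,
`g = exp(−Δt/τ)`, default τ = 0.5 s at 30 Hz) with a pool-adjacent-violators
scheme; λ defaults to the trace's noise sd. Reconstruction (kernel ∗
spikes) is exposed for audit.

Bursts: 33-ms bins (one frame at 30 Hz) whose summed inferred-spike
amplitude exceeds 2.5 — interpreted in baseline-sd units of the trace when
a noise scale is supplied, since the threshold's unit is otherwise
conventional; a per-bin spike-count mode is selectable. Contiguous
supra-threshold bins merge into one burst. An optional consolidation step
reassigns each contiguous nonzero spike run to its local-maximum frames
(watershed at the minima between peaks) before binning; deconvolution can
split one spike's mass across adjacent frames, and since genuinely
distinct theta-band bursts are ≥3 frames apart at 30 Hz the reassignment
is unambiguous. Theta-burst events are bursts whose **start-to-start**
interval to their predecessor lies in 100–167 ms (6–10 Hz); the rate
divides by session duration, or by walking-masked duration when a mask is
given.

The walking filter marks frames with speed > 0.5 cm/s, groups them into
runs, and drops runs shorter than 0.5 cm — the sole guard against z-motion
(grooming) artifacts, per the source workflow. Event rate = summed masked
spike amplitude / masked duration.

## Spatial coding

Rate maps: 60 bins over the 3-m track, per-bin masked spike amplitude over
masked occupancy, Gaussian smoothing (σ = 2 bins) applied to numerator and
denominator before division; never-occupied bins are NaN. Spatial
information is the Skaggs bits-per-event form; it is ≥0, zero iff the rate
is constant over occupied bins, and invariant to rate rescaling. Place
cells: circular time-shifts (≥20 s) of the spike train re-scored by SI,
cell accepted iff observed SI exceeds the 95th percentile of ≥1000
shuffles. The bin count, smoothing and shuffle criterion are conventions
(the upstream references do not pin them); they are exposed as arguments.
Track teleports are treated as zero displacement when differencing
position.

## Ensemble statistics

All operations exclude ND cells from the relevant denominator. Pairwise
overlap uses the pairwise universe (cells scoreable in both sessions):
observed `|A∩B|/n`, chance `(|A|/n)(|B|/n)`, inference from the
hypergeometric upper tail, with a label-shuffle alternative. The reported
`p_mid` applies the mid-P correction (half weight on the observed count);
raw tail p-values of a discrete statistic are stochastically conservative,
and mid-P is the standard choice when calibrating against a uniform
reference. Consecutive overlap normalizes by the prior session's positives.
The reexpression tree is built on the cohort of cells scoreable in *all*
sessions; each node stores its cohort fraction and the conditional
probability of expressing next session; leaf fractions sum to 1.

## Correlation networks

Edges come from a per-pair circular-shift null: every trace is rolled by an
independent random offset (preserving autocorrelation), the correlation
matrix is recomputed ≥100 times, and `r_ij` must exceed its own pair's
99th-percentile null. Degree, clustering and Newman's
`Q = Σ_c (e_cc − a_c²)` are computed directly from the boolean adjacency;
Q of the trivial partition is exactly 0 and Q ∈ [−0.5, 1]. Normalized
degree/clustering divide the subpopulation mean by the whole-population
mean; normalized modularity divides observed Q by the mean |Q| of ≥1000
label shuffles, with a two-sided shuffle p-value. The edge rule and the
normalizations are this package's conventions and are recorded in the
graph's provenance fields.

## Reporter simulation

Each cell's transcription is a Poisson process at the basal rate over a
24 h history, plus one evoked event at the stimulus for responders (drawn
with probability 0.25). The RNA indicator reads out 5 min post-stimulus
(within the 4–7 min imaging window) and sees any event whose ~15-min
visibility window covers the readout, so its false-positive probability is
`1 − exp(−r·w)` with `w ≈ on-time − readout delay`. The protein reporter
matures for 1 h, decays with a 2 h half-life, is read 2 h post-stimulus
against a threshold of half one event's amplitude, and therefore
integrates basal history over hours. Kinetic parameters are config
defaults motivated by the indicator's measured on-time and typical
destabilized-GFP kinetics; the acceptance surface is the qualitative
ordering (RNA readout ≥ protein reporter, gap widening with basal rate
over the 0–0.5 h⁻¹ sweep), not specific accuracies. At basal rates far
above this range the protein reporter saturates at calling every cell
positive and the gap closes again; the default sweep covers the
biologically plausible regime. Protein kinetics are single-compartment and
deterministic per event; translation noise is not modeled.

## Freezing quantification

Motion energy is the XOR pixel count between consecutive masks (absolute
pixels by default; fraction-of-body-area is an option). A run of
sub-threshold pairs spanning ≥0.5 s is a freezing bout (a run of k pairs
spans k+1 frames); the rate is total bout time over session time.
Threshold calibration exploits the rate's monotonicity in the threshold
and bisects over the finite grid of achievable thresholds (the distinct
XOR values), returning the smallest threshold reaching the manual rate and
raising with the achievable range when the target is unreachable on a
bounded grid. Body segmentation itself (video → mask) is out of scope;
masks are the input boundary.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic per seed (`numpy.random.default_rng`).

* **Two-photon scenes**: nuclei are soft-edged filled spheres (lognormal
  GFP levels, Gaussian radii, non-overlapping placement) matching the
  circle-finding assumptions; TSs are 3D Gaussians with a
  (0.25, 0.25, 1.0) μm PSF (typical two-photon anisotropy) planted inside
  nuclei; autofluorescent blobs appear in the red channel and bleed into
  green scaled so the max-normalized subtraction cancels them exactly in
  the noise-free limit; Poisson shot noise and Gaussian read noise are
  optional. Not modeled: scattering, depth-dependent attenuation,
  non-rigid motion, photorealistic tissue texture — so passing tests
  demonstrate the rules and estimators, not robustness to those effects.
* **smFISH fields**: singles carry unit-scale lognormal integrated
  intensities; TS intensity is copy_number × median single; channel B
  repeats channel A positions displaced by an isotropic offset, plus
  optional unmatched decoys. Channel-to-channel intensity normalization is
  not modeled.
* **Calcium sessions**: spikes = sparse background Poisson + planted
  theta trains (default 3 bursts at 125 ms start-to-start, inside the
  theta band; train starts rejection-sampled so trains never interleave)
  + place-field Poisson firing while walking; convolution with the AR(1)
  kernel, Gaussian noise. The position trace alternates 2–6 s stationary
  and walking (5–20 cm/s) epochs with teleports. Sessions of 420 s (the
  ~7-min VR session length) give enough track traversals for place-field
  statistics; shorter sessions are used where only burst timing matters.
* **Longitudinal tables**: a two-state Markov chain — active cells
  reactivate with `persistence`, inactive cells activate at the session
  marginal — with independent ND masking. `persistence = activation`
  is the memoryless (chance-overlap) control; `persistence ≫ activation`
  produces the stable-ensemble regime.
* **Behavior masks**: an elliptical body that random-walks `jitter_px` per
  frame and is strictly static inside planted bouts, so a planted bout of
  b−a seconds yields exactly (b−a)·fps still frames.

## Problem sizes

Default test and acceptance workloads: 80 × 80 × 20 μm volumes with 12
nuclei (4 seeds), 500-TS smFISH fields, 10 cells × 120 s × 10 seeds for
burst recall, 500 cells × 200 seeds for the overlap-null calibration, and
10⁴ cells × 20 reps × 5 basal rates for the reporter sweep. These sizes
give binomial/Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run in tens of seconds.

## Known limitations

* The Hough nucleus finder assumes roughly spherical, non-clumped nuclei;
  heavily overlapping nuclei (closer than one radius) merge into one
  detection by design.
* Burst thresholding in baseline-sd units makes the burst count depend on
  the noise estimate; traces with strongly non-stationary noise would need
  a windowed noise model.
* The reporter simulation's conclusions are parametric in the kinetic
  defaults; it is a comparison engine, not a fitted model of any specific
  reporter construct.
* In-vivo percentages from animal experiments (Arc+ fractions per region,
  persistent-overlap percentages) are not reproduction targets of this
  package; the statistics that produced them are, and they are validated
  on synthetic ground truth.
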