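# Methods

This note documents the models, estimators and numerical choices behind
`curtainkit`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Geometry and units

Positions are measured along the kymograph axis with the chromium
barrier (tether point) at 0, increasing toward the free end/pedestal;
frames are 0-based and pixel *i* covers the interval [i, i+1) in pixel
units. Pixels convert to μm with the camera calibration (0.267 μm/px
through the 60× objective) and μm quantities convert to bp by assuming
the full λ contour (48,502 bp) is mapped uniformly onto the mean
measured end-to-end extension of the substrate: 10.75 μm (naked
single-tethered DNA), 9.11 μm (nucleosome-bound), 9.54 μm (U-shaped),
8.0 μm (double-tethered). The same factor applies to distances and
velocities. Because the factor depends on flow and tether geometry,
bp-unit numbers are comparative conveniences, not absolute base-pair
counts; report output rounds them to 3 significant figures while
internal values keep full precision.

## Synthetic curtain

No raw single-molecule data is distributed with the study this package
targets, so a seeded generator stands in for it and carries full ground
truth. Its defaults are the condensin I naked-DNA study conditions; all
are plain dataclass fields.

* **Lag times** (time from protein arrival to compaction onset):
  exponential with scale 400 s over a 1200 s (20 min) record, untruncated
  — a lag beyond the window means that molecule never initiates. A
  uniform alternative is provided. The data only constrain lags to be
  "spread over the whole window"; the exponential form and scale are
  declared assumptions.
* **Velocities**: lognormal, parameterized to hit a target median and
  IQR exactly (μ = ln median, σ = asinh(IQR/2·median)/z₀.₇₅); defaults
  0.201 (0.216) μm/s. The lognormal family is an assumption (strictly
  positive, right-skewed, two parameters); the source data report only
  median (IQR).
* **Processivities**: exponential run length (memoryless), natural
  parameter the half-life (default 5.2 μm). Consistent with the
  survival-curve presentation; not derivable from the published
  figures beyond that.
* **Single-step release** is modeled as a *competing exponential
  distance hazard*: a release point is drawn independently of the run
  budget, with scale set so the marginal per-event release probability
  equals `p_release_per_event` (default 0.315). This matters: releases
  are attributed to protein dissociation and therefore right-censor the
  processivity, and the Kaplan-Meier estimator is only consistent when
  the censoring distance is independent of the true run length. A
  simple "flip a coin at run end" release would censor events exactly
  at their true value and bias KM medians upward.
* **Terminations**: a run ends *complete* (censored) if it comes within
  1 px of the barrier; *release* (censored) if the release hazard fires
  first — the free end returns to full extension within one frame;
  otherwise *reversal* (gradual climb over 4 frames at 0.3–0.8× the
  compaction speed) or *stall* (position holds), split by `p_reversal`.
  A run still moving at the record end is cut and censored. After a
  release or reversal a new lag and run may follow.
* **Pauses**: with `stall_rate` per frame (default 0.01), single frames
  of zero motion are inserted inside runs; they emulate brief pauses
  below the study's 5 s resolution and do not terminate runs.
* **Nucleosomes**: 3–4 per DNA, uniform over the interior. Each crossing
  draws bypass (p = 0.8), of which 10% pause for 2 frames; non-bypass
  collisions terminate the run at the nucleosome with a stall / release /
  reversal outcome.
* **Rendering**: DNA as a uniform-intensity line with fractional
  coverage in the edge pixel; the compacted punctum as a Gaussian
  (σ = 1 px) whose integrated intensity is proportional to the
  compacted length; nucleosome spots in a second channel travel with
  the punctum once collected and return on release; Poisson shot noise.
  Trajectory-level position noise is Gaussian with σ = 0.5 px — a
  choice representing sub-pixel tracking error on bright YOYO-1 DNA.
* **Determinism**: one integer seed; per-molecule substreams are spawned
  from `SeedSequence((seed, molecule_id))`, so any subset of molecules
  reproduces byte-identically.

Features of real curtain data the generator does **not** emulate:
photophysics beyond single-step bleaching (no blinking), hydrodynamic
force profiles along the DNA, diffusive punctum motion, stage drift,
uneven illumination, and DNA-to-DNA brightness variation. Tests passing
on synthetic data therefore validate the estimators under the stated
models, not robustness to every instrumental artifact.

## Free-end tracking

Background and its noise are estimated from the distal margin of the
field (median and MAD of the last 5 pixel columns, which lie beyond the
DNA); the DNA plateau intensity comes from the above-threshold pixels of
the first five frames. Per frame the end is first localized as the
farthest-from-barrier pixel above background + max(3σ, 0.3·plateau),
with the contiguity rule that the DNA may not contain a gap of more
than 3 px (isolated bright noise pixels cannot drag the end outward).
Sub-pixel refinement then uses, in order of punctum brightness: a
half-plateau threshold crossing with linear interpolation (no punctum);
an iterative centroid of the punctum residual after subtracting the
plateau with fractional pixel coverage (faint punctum); and a
three-point log-parabola on the residual (punctum > 2× plateau), which
is exact for Gaussian spots and immune to window truncation at the
barrier. On noiseless renders the estimator is accurate to < 0.3 px
everywhere; under shot noise the RMS error is ≈ 0.8 px. Gaps of ≤ 2
frames are interpolated; an all-background kymograph raises an error.

## Segmentation and event extraction

Trajectories are decomposed by an exact penalized least-squares
piecewise-linear partition (O(n²) dynamic program; trajectories are a
few hundred frames). The per-segment penalty is 3·σ̂²·ln n — slope,
intercept and breakpoint count as free parameters — with σ̂ from the
MAD of *second* differences, which cancels linear trends so a molecule
moving for most of its record does not inflate its own noise estimate.
Minimum segment length is 3 frames. Ties in the partition (a boundary
sample of a continuous signal lies on both adjoining lines) are resolved
toward the latest breakpoint, and each segment is refit by OLS including
the shared boundary sample; a segment's displacement counts the interval
entering it, so summed displacements are conserved.

The stall threshold v_min is 0.5 px/frame (≈ 0.027 μm/s at 0.267 μm/px
and 5 s frames) — the tracking noise floor; slopes within ±v_min are
stalls, more negative slopes are compaction ("toward"), more positive
are "away". A *run* is a maximal group of toward segments (interleaved
stalls do not split a run — the summed positive displacement spans
them) delimited by away segments or record boundaries. Velocities are
the positive toward-segment slopes; processivity is the run's summed
positive displacement; lag is the start of the first run minus the
arrival time.

**Censoring.** An event is right-censored when (i) its run reaches
within 1 px of the barrier (complete), (ii) it is still moving at
either record boundary, (iii) it terminates in a single-step release —
attributed to protein dissociation (toggle
`release_is_dissociation`) — or (iv) an explicit annotation marks
dissociation or DNA breakage. A run that terminates by stalling is
*not* censored even if the stall persists to the record end: its
positive displacement is fully observed.

**Termination.** Precedence complete > release > reversal > stall. A
release requires ≥ 80% of the compacted distance recovered between two
consecutive frames with the final position within 10% of the
pre-compaction extension (both config-exposed quantifications of
"single step within one frame"); a reversal requires a following away
segment of ≥ 2 frames; runs cut by the record end default to stall and
are always censored, so the label carries no analytical weight there.

**Collisions.** A ±2 px window is placed around each nucleosome; a
crossing with no frame of sub-v_min speed inside the window is an
unimpeded bypass, ≥ 1 such frame is a paused bypass (pause length in
frames), and a run terminating inside the window inherits its
termination label. Per-frame speeds are computed on a 3-point median
smoothed trajectory by default.

**Detection floor.** Events shorter than roughly 2–4 px of total
displacement are invisible at 0.5 px noise and 3-frame minimum
segments. Because run lengths are exponential, many true events are
that small; detected-event medians are therefore biased upward relative
to the generative half-life, and the detected release fraction
understates the true one (small releases are missed). Closed-loop
recovery of the processivity half-life is accordingly checked on the
ground-truth event table (censoring bookkeeping + product-limit
estimator), and the slope-recovery check (< 5% median error at 0.5 px
noise) uses long processive runs (half-life 20 μm, releases off) where
every slope is identifiable; under full study conditions the median
slope error is ≈ 6%, dominated by 3–5-frame runs near the frame
resolution.

## Survival statistics

`km_estimate` wraps the standard product-limit estimator (lifelines)
and returns aligned arrays plus the Greenwood 95% band with the
log(−log) transform, which keeps the band inside [0, 1]; censored
observations tied with deaths are processed after deaths. The median
("half-life") convention is the smallest *observed event* value with
S ≤ 0.5, with no interpolation; if S never reaches 0.5 the median is
`None`. This convention has a small negative bias (≈ 1–2% at n = 300)
relative to the distributional median. Group comparisons: the two-group
log-rank χ² (1 df), and the Mann-Whitney U with an exact enumeration
p-value when both samples have ≤ 8 untied observations and the
tie-corrected normal approximation otherwise. The approximation omits
the continuity correction so that U at its null mean yields p = 1
exactly; the cost is a somewhat larger gap to the exact p at very small
n (up to ≈ 0.06 at n = 7).

## Loop-extrusion symmetry

The statistic β is the least-squares slope of the left/right side-length
ratio against the reaction coordinate x = (t − t₀)/(t_end − t₀) ∈ [0, 1].
Frames with a zero denominator are dropped; ≥ 5 usable frames are
required. β is invariant to rescaling both sides and flips sign when
the sides are swapped, so the two-sided rule is orientation-free:
*asymmetric* iff |β − μ| > k·σ strictly, with (μ, σ) from the mean and
SD of a seeded random half of the events known to be symmetric and
k = 5 by default; the package ships the reference calibration
(0.03, 0.07). The raw ratio (not its log) is retained to mirror the
established procedure; its noise is asymmetric in the two sides, which
is a documented limitation. Simulated loop events stop when a side
reaches 1 μm — side lengths are not measurable closer to the tether
points — which is also what keeps the reference σ at the ~0.07 scale.
Loop velocity: symmetric events use the growth rate of the looped
overlap, `initial_total − (left + right)`; asymmetric events use the
shrinkage rate of the reeling side (equivalently the punctum
displacement rate).

## Photobleaching

Steps are found by the same exact penalized partition with a constant
(level) cost, penalty 2·σ̂²·ln n, σ̂ from the first-difference MAD, and
minimum segment 2 frames. A change-point is a bleaching step when the
level drops by ≥ 3σ̂ (config-exposed); upward level changes (blinking
returns) are flagged and excluded from the count. The original counts
were presumably manual; the automated detector and both thresholds are
this package's choices. On traces with ≥ 5σ steps separated by ≥ 10
frames, count accuracy exceeds 98% for 0–3 true steps; steps closer
than the minimum segment merge, which is a resolution limit shared with
manual counting.

## Biochemical fits

The FP model is the quadratic (ligand-depletion) isotherm, required
because the labeled-probe concentration (0.05 μM) is comparable to the
dissociation constants (1.2 and 3.0 μM); its dilute-probe limit is the
familiar hyperbola FP_max·C/(C + K_d). All replicate points are fit
globally (equal weights; no replicate variance model) for shared K_d
and FP_max by Levenberg-Marquardt with positivity bounds; a constant
signal or non-finite covariance raises a `FitError`. The simulated
titration grid is 11 log-spaced concentrations from 0.05 to 20 μM,
spanning both reported constants, with 3 replicates and Gaussian noise
of 2% of FP_max.

ATPase rates come from a least-squares line over the linear range of
the ADP/(ADP+ATP) fraction — the maximal prefix below 0.3
(config-exposed) — with the slope rescaled by [ATP]_total/[enzyme] to
ATP·s⁻¹·holocomplex⁻¹. The fit keeps a free intercept by default to
absorb background ADP in real assays; for synthetic courses, which have
zero background by construction, the through-origin variant
(`fit_intercept=False`) is the lower-variance correct estimator and is
what the benchmark script uses. The synthetic course is exactly linear
(slope k = rate·[E]/[ATP]) up to a hydrolyzed fraction of 0.25 and
rolls over through a C¹ exponential knee toward full conversion, so the
linear-range fit inverts the generator exactly in the noiseless case.
Default design: 8 timepoints over 10 min at 0.2 μM enzyme and 2 mM ATP,
3 replicates, noise σ = 0.005 on the fraction.

## Pipeline and formats

`run_pipeline` executes simulate → quantify → survive → symmetry →
bleach → fits, writes stage CSVs (comma-separated, UTF-8, header row,
positions in μm with 4 decimals, times in s), a JSON report whose
bp-unit numbers always equal the units module applied to its μm
numbers, and the resolved configuration with the tool version; output
is deterministic under a fixed seed. Kymographs are exchanged as
channel-major float32 TIFF stacks, one file per molecule. Problem sizes
in the shipped tests and demo (tens to hundreds of molecules, 100–400
repeated fits) are chosen to exercise every code path while a full
suite run completes in well under a minute of compute.

## Known limitations

* Event detection has a displacement floor of a few pixels; quantities
  computed from detected events inherit a selection bias that the
  ground-truth table does not have.
* Per-frame pause scoring in collision analysis is noise-sensitive at
  0.5 px; it is intended for the simulated noise regime and clean data.
* The ratio-based symmetry statistic becomes heteroscedastic when one
  side is short; events are truncated at 1 μm side length for that
  reason, and a log-ratio variant is a possible future improvement.
* `half_life` is a step-function median; for small samples it can sit
  one order statistic below the distributional median.
* The tracker assumes the field of view extends beyond the DNA (for
  background estimation) and a single molecule per kymograph.
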