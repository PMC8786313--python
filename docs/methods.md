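# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generators emulate
(and deliberately do not), and the numerical decisions taken where the
underlying workflow was originally manual.

## Coordinate and data conventions

All images are carried as `(T, Z, C, Y, X)` arrays with 0-based `(row,
col) = (Y, X)` pixel coordinates; z index 0 is the first acquired slice.
Default calibration mirrors typical TIRF/confocal acquisitions of synapse
microclusters: 65 nm/pixel laterally and 0.19 µm z-steps.  ROIs are a JSON
schema (circle, rectangle, polygon); a pixel belongs to a circle iff its
center lies within the radius — a deterministic rule that can be checked by
brute-force enumeration.  Bleach and control ROIs in one set must be
disjoint, since a control that overlaps the bleach spot cannot report
imaging-only bleaching.

## Structure detection

Detection follows the manual endosome/microcluster counting workflow: a
single global threshold — supplied manually, or computed by Otsu's method
on the reference plane (the z-slice with the most size-passing components
under a provisional global Otsu) — is applied to every slice with a strict
`>` comparison; connected components are labelled per slice and filtered to
a size window of 5–1000 px.  The lower cut-off rejects single-pixel noise,
the upper rejects merged or cell-scale blobs.  Components are never merged
across z: a stack's count is the sum of per-slice counts.  Axial profiles
place slice z at `(z − z0)·z_step` µm relative to a chosen reference slice
(by convention the first plane where the cell comes into focus), and the
axial peak is the position of the maximal count, ties resolved to the
smallest position.

Choices made where the manual procedure is silent: in-plane connectivity
defaults to 8 (4 available); thresholding is strict so that a threshold
equal to the global maximum yields an empty mask.  Count-vs-threshold
monotonicity holds for thresholds above the background level — below it the
field becomes a single giant component and the size filter dominates.

## Colocalization and compartment ratios

Channel overlap uses the mask-arithmetic construction of the original
FIJI workflow: the inverted second mask subtracted from the first, clamped
at zero.  This equals the pixelwise logical AND, and the implementation
asserts that equivalence on every call.  Object-level colocalization counts
a structure as overlapping if at least `min_overlap_px` (default 1) of its
pixels fall in the other channel's mask; the percentage is over all
structures of the first channel and is undefined (an error) when none were
detected.

Cluster/cytosol fold change splits the field by thresholding the cluster
channel; the fold is the ratio of mean intensities of a second channel
inside vs outside the cluster mask, and is invariant to any positive
rescaling of the measured image.  The nuclear translocation ratio is
integrated nuclear intensity over integrated whole-cell intensity (the
headline metric); the nucleus/cytoplasm variant familiar from the
intensity-ratio plugin is available via `denominator="cytoplasm"`.

## Photoactivation pulse-chase

Compartments are rebuilt from the cluster channel in every frame, because
clusters move; `--static-mask`-style frozen masks can be emulated by
passing a fixed `cell_mask`.  The photoactivated channel's mean is
measured in cluster and cytosol per frame and the fold change reported
with time zero at activation onset.  An empty cluster mask in a frame
flags that frame's values as missing (NaN) rather than aborting the
series.

Vesicle counting smooths each frame with a 3×3 uniform mean filter
(parameterizable — minimal smoothing that suppresses single-pixel noise),
thresholds, size-filters (same 5–1000 px window) and counts components.
The threshold is subject to a calibration contract: if any pre-activation
frame yields a nonzero count, the threshold is rejected with the offending
frame and count in the error.  This encodes the rule that a valid
endosome threshold must detect nothing before photoactivation.

## FRAP processing and fitting

1. **Bleach correction** divides the bleached-ROI trace by the mean
   relative decay of unbleached control ROIs, each referenced to its first
   acquired frame (its level before any imaging bleach).  This removes a
   shared multiplicative decay exactly; referencing to the pre-bleach mean
   would leave a constant offset of order `k_b·t_pre/2` when the controls
   themselves decay during the pre-bleach window.  Any remaining constant
   scale cancels in normalization.
2. **Normalization** maps the trace to `[0, 1]`:
   `(F(t) − F_post) / (F_pre − F_post)` with `F_pre` the pre-bleach mean
   and `F_post` the first post-bleach value, so the normalized curve is 0
   at t = 0 by construction and approaches the mobile fraction F_∞.  The
   operation is idempotent.  A trace whose pre-bleach level does not
   exceed its post-bleach value is rejected (no bleach occurred).
3. **Fitting** uses `F(t) = F_∞·(1 − Σ wᵢ e^(−t/τᵢ))` with Σwᵢ = 1 —
   equivalently, the unrecovered fraction decays multi-exponentially.
   Internally the model is parameterized by non-negative component
   amplitudes `Aᵢ = F_∞·wᵢ` (bounded so F_∞ ≤ 1.2), which removes the
   simplex constraint; τ's are reported sorted ascending.  Residuals are
   weighted by 1/SEM when per-timepoint SEMs are available (ensemble
   means), uniformly for single cells; the weighted SSR is the
   model-selection statistic.  Optimization is trust-region least squares
   with 16 starts per fit: τ starts log-spaced over `[dt, 10·t_max]` plus
   seeded log-uniform draws.  Higher-order fits are warm-started from the
   best lower-order solution padded with a zero-amplitude component, which
   guarantees the SSR never increases with model order.
4. **Model selection** walks n = 1, 2, 3 and accepts the first n whose
   weighted SSR the (n+1)-component fit fails to improve by more than 5%
   (relative, configurable).  The 5% parsimony margin is a design choice;
   with it, simulated mono- and bi-exponential curves at noise sd 0.02 are
   classified correctly in ≳95% of runs.
5. **Readouts**: normalized recovery at a requested time (default 380 s),
   nearest frame within half a sampling interval, reported as a
   percentage.

Both single-cell fitting and fitting of ensemble mean curves are
supported; ensembles require ≥ 2 members on a common grid for a SEM.

## Divergence and group statistics

Pointwise comparison of two curve ensembles uses Welch's unequal-variance
t-test per timepoint (two-tailed), with Mann–Whitney as the nonparametric
alternative; no multiplicity correction is applied across timepoints by
default, matching how divergence timepoints are conventionally reported,
and Benjamini–Hochberg can be applied downstream by users who want it.
The time of divergence is the earliest grid time from which p < α holds at
every subsequent timepoint ("all_subsequent", the default — it matches
reporting a single divergence time per condition pair and keeps the null
false-call rate well below α because a false divergence must persist to
the end of the series); a k-consecutive variant is provided.  Degenerate
timepoints where both groups are constant get p = 1 (equal) or p = 0
(deterministically different).

Experiment-level aggregation computes per-experiment means first; grand
mean, SEM and any downstream test operate on those means, not on pooled
cells.  A single experiment leaves the SEM undefined (flagged NaN).  The
internalisation ratio is `100·(internalised/surface)` normalised by the
same ratio in the wild-type reference.

## Synthetic data: what it emulates, and what it does not

Scenes are isotropic 2-D Gaussian spots (σ in px) on a constant
background — the appearance of diffraction-limited clusters; detection
operates on thresholded masks, so the exact profile shape is immaterial.
Noise is Poisson shot noise plus Gaussian read noise, both optional; the
noise-free state gives exact oracles.  Generators plant, and record in a
`SyntheticTruth`: spot positions and pairing (cluster scenes with a
controllable co-centered fraction and a minimum separation that keeps
masks disjoint), per-slice spot counts (z-stacks), multi-exponential
recovery parameters and an imaging-bleach rate (FRAP traces), compartment
intensity functions and vesicle events (photoactivation series), and a
divergence time with post-divergence effect size (two-condition
ensembles).  Same seed and parameters give bit-identical scenes.

FRAP series are generated at ROI-trace level: the quantification consumes
ROI mean intensities, so image rendering would add nothing to what the
tests can check.  Generated traces are not clipped at zero — they model
background-subtracted ROI means, whose read noise can dip below zero right
after a full bleach; clipping would bias the post-bleach anchor upward.

Not emulated: point-spread-function optics, camera-specific noise
calibration, cluster motion and splitting/merging, 3-D diffusion of the
exchanging species, and spatially varying background.  Passing tests
therefore demonstrate correctness of the measurement procedures against
known ground truth, not robustness to every artefact of real microscopy
data (uneven illumination, drift, touching clusters needing watershed
splitting are explicitly out of scope).

## Problem sizes and default study conditions

Cluster scenes default to 128×128 px fields with 10–20 spots of σ = 2 px,
amplitude 200 on background 10 (suggested threshold: background + half
amplitude); the default noise condition is Poisson shot noise plus read
noise of sd 3.  FRAP traces default to 10 pre-bleach and 191 post-bleach
frames at dt = 2 s (a 382 s window, covering the conventional 380 s
recovery readout) with reference kinetics τ = 20/200 s, w = 0.6/0.4,
F_∞ = 0.7 and noise sd 0.02 relative to the pre-bleach plateau.
Parameter-recovery and model-selection simulations use a 600 s acquisition
(300 post-bleach frames): estimating a 200 s time constant requires ≥ 3·τ
of data, the standard design rule for exponential fitting — at 382 s the
slow component is covered by < 2·τ and its estimate is
identifiability-limited (~20% median error) rather than noise-limited.
Divergence ensembles default to 10 replicates per group over 150
timepoints at dt = 2 s with a saturating baseline and an offset of 10
noise sd after the planted divergence time.  Two-sided checks in the test
suite use 20–100 seeds per condition; all seeds are fixed.
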