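# Methods

This note documents the models, parameter choices and numerical decisions
behind `wormtriage`, and what its synthetic benchmarks do and do not show
about real screen data.

## Video model and tracking

The tracker assumes stereomicroscope video of dark animals on a bright
plate: grayscale frames, mild illumination flicker, and worms that move over
the recording (45 s at 5 frames/s is the default acquisition the pipeline is
tuned for). The processing chain is deliberately simple and matches common
ImageJ practice:

1. **De-flicker** — each frame is rescaled multiplicatively so its mean
   equals the whole-stack mean. Idempotent; preserves the global mean.
2. **Background** — per-pixel *maximum* over time. Because animals are
   darker than the plate and keep moving, the temporal maximum is worm-free
   wherever a worm does not park for the entire video. This fails for a worm
   that never moves; such data should be trimmed upstream.
3. **Subtraction** — `clip(background − frame, 0)`. Pixels brighter than the
   background are sensor noise, not animals, so they clamp to zero rather
   than folding back via an absolute value.
4. **Otsu threshold** — 256 equal bins over the observed `[min, max]`,
   threshold = upper edge of the bin maximizing between-class variance, ties
   resolved toward the lowest bin. This mirrors 8-bit ImageJ behaviour while
   accepting float input. One global threshold over the whole subtracted
   stack is the default (the foreground area per frame is small and nearly
   constant, so pooling is more stable than per-frame thresholds).
5. **Linking** — greedy nearest-neighbour in ascending distance order with a
   gating radius (default: twice the median body width), each track and blob
   used at most once per frame; unmatched blobs seed tracks, unmatched
   tracks terminate, tracks shorter than 25 frames (5 s) are dropped. The
   greedy rule is deterministic and permutation-invariant (ties break on
   track id, then blob position). Worm-worm contact is out of scope: merged
   blobs are not split, and the simulator never produces contact.

**Body length** is the median over a track's frames of the blob skeleton's
longest geodesic path (orthogonal steps 1, diagonal steps √2), in µm. The
median is robust to occasional bad segmentations; `perimeter_half` and
`feret` estimators are available as alternatives. **BLPS** is path length
(sum of consecutive centroid distances) divided by body length and by track
duration. Centroid positions are the binary pixel means; no smoothing is
applied.

Noise floor: segmentation jitter plus genuine centroid wobble of an
undulating body contribute roughly 0.01–0.015 BLPS of apparent speed. This
is negligible for crawling speeds (0.1–0.3 BLPS) but dominates the relative
error at the very bottom of the range (≤ 0.03 BLPS); the speed-recovery
benchmark therefore reports the *median* relative error across the range,
which stays under 5%.

All physical thresholds are applied in µm/µm² after calibration. No default
pixel size is claimed: stacks must carry an explicit `pixel_size_um` /
`frame_interval_s` (CLI flags or a sidecar JSON), never silently guessed
from TIFF tags.

## Foci detection and suppression calls

Aggregate foci are "discrete, bright" spots on diffuse muscle fluorescence.
The detector operationalizes the visual criterion as: residual above a local
background (median filter, radius 5 µm) exceeding k = 4 robust standard
deviations (1.4826·MAD of the residual), followed by the assay's physical
detection limits as a disjunction — area ≥ 7 µm² (round foci) OR maximum
caliper ≥ 3 µm (elongated foci). Both the k·σ rule and its parameters are
this package's operationalization of a human scorer's judgement, and they
are exposed in `FociDetectParams`. Detection is invariant under global
intensity rescaling (threshold scales with the MAD).

Suppression calls compare per-animal foci counts with the mean of the EV
control population (plates are populations; no animal pairing exists).
Boundary semantics are read literally from the screen's wording: "more than
50% of the animals" is strict, "50% or higher reduction" inclusive, the
counter-screens' "> 25%" strict. The strong-hit rule is encoded as
reduction ≥ 0.60 in ≥ 75% of animals (the upper "80%" figure in the assay
description is descriptive, not a bound). Calls are monotone (lowering any
treated count never turns a positive negative) and scale-invariant.

## FRAP

RFI uses the standard double normalization: the bleach-ROI / whole-cell
intensity ratio divided by its pre-bleach mean. Normalizing the *ratio*
(rather than the two channels separately) makes the pre-bleach RFI average
exactly 1 by construction and reduces to T₀·I(t)/(T(t)·I₀) whenever the
whole-cell channel is flat before the bleach; acquisition bleaching cancels
through T(t) either way. The recovery plateau is the mean of the final 10%
of post-bleach samples — an empirical estimator chosen because the assay
reports raw recovery curves, not fitted rate constants (a single-exponential
fit is provided as an option). Mobile fraction is
(plateau − RFI_postbleach)/(1 − RFI_postbleach), clamped to [0, 1] with a
warning if recovery trends downward; it is undefined (NaN) when no
effective bleach occurred. Classification defaults: soluble ≥ 0.8,
immobile ≤ 0.3.

## Expression controls

ΔΔCT assumes amplification efficiency exactly 2 (the plain comparative-CT
method; no efficiency correction). Replicate CTs are averaged per
(gene, sample) before differencing — biological-replicate averaging is the
default. Western band ratios (reporter/tubulin per biological replicate) are
compared with a classic pooled-variance Student t-test ("unchanged" iff
p > 0.05); Welch is available by flag.

## Triage tree

Stage thresholds, all configurable through `TriageConfig`:

| stage | rule | default |
|---|---|---|
| genome screen | suppression rule (f = 0.5, r = 0.5; strong 0.75/0.60) | strict/inclusive as above |
| soluble-reporter counter-screen | artifact flag | exclude |
| cross-reporter classification | counter-screen rule (> 25% in > 50%) | Class A iff positive |
| SOD1 co-suppression | same counter-screen rule | recorded subset of Class A |
| wild-type motility filter | two-sided pooled t vs wt EV control | α = 0.001 |
| polyQ motility classes | two-sided pooled t vs polyQ EV control, direction by sign | single α = 0.05 |
| TS rescue | relative reduction ≥ 0.40 AND two-proportion z | α = 0.01; core iff ≥ 1/4 strains |

Two genuinely open design points and the choices made:

* The assay's published significance annotations for the motility classes
  mix per-direction alphas; its exact assignment procedure is not fully
  specified. The reference implementation uses one two-sided α = 0.05 with
  the direction taken from the sign of the mean difference; a "legend" mode
  with separate stricter alphas (0.01 up / 0.001 down) is provided.
* Whether toxicity suppression requires restoring motility *to wild-type
  levels* or merely a significant improvement is ambiguous; the
  implementation uses significant improvement.

Percentages are rounded half away from zero and recomputed from the sets —
the rounding rule is the single source of printed integers. TS phenotype
data enter as penetrance percentages over ≥ 50 animals, so a two-proportion
z-test (pooled) is the default significance gate; the "≥ 40% relative
reduction" is the effect-size gate and the upper "90%" figure is
descriptive. `TriageResult.validate()` asserts the set algebra on every run
(partition of survivors into Class A/B, core ⊆ toxicity suppressors ⊆
wt-passing Class A, percentages summing to 100 ± 1).

Chi-square enrichment of functional classes uses expected counts =
library fraction × hits, df = classes − 1; classes with expected < 1 must be
pooled by the caller.

## Synthetic data

The generators define the package's study conditions; every generator
derives its RNG stream from (seed, purpose-tag), so outputs are bit-identical
per seed and adding a generator never perturbs existing fixtures.

**Worm videos.** Worms are thick sinusoidal midlines (arc length = body
length, solved for the chord by bisection) advancing at speed × body length
per second along smoothly drifting headings, each confined to its own arena
cell by steering back toward the centre (no contact, by construction). The
body tapers to a point over the last ~tenth of each end so the rendered
tip-to-tip extent equals the midline arc length — this is what makes the
skeleton estimator unbiased to ~1%. Defaults emulate the motility assay:
1 mm × 70 µm adult worms, 60 µm undulation amplitude at 0.4 Hz with two
waves along the body, 12 µm pixels, 45 s at 5 fps, ±10% sinusoidal flicker,
Gaussian noise σ = 4 on a background of 180 with worm contrast 90. What the
simulation does *not* model: worm-worm contact and occlusion, posture
dynamics (real undulation frequency coupling to speed), tapered grayscale
texture, vignetting, or debris — so passing benchmarks demonstrate the
pipeline's arithmetic and robustness to flicker/noise, not performance on
crowded or low-contrast plates.

**Foci images.** Diffuse fluorescence (level 100) with smooth texture
(Gaussian-filtered noise, 6 µm scale, amplitude 6), sensor noise σ = 3, and
planted discs/capsules of amplitude 60 at 0.5 µm pixels, placed without
overlap by rejection sampling. Plant sizes are drawn away from the 7 µm² /
3 µm detection limits so ground-truth classification is unambiguous; the
benchmark measures detection, not boundary calibration of marginal foci.

**FRAP traces.** Post-bleach RFI follows
f_m·(1 − e^(−t/τ))·(1 − RFI₀) + RFI₀ with RFI₀ = 0.2, τ = 2 s, sampled
every 123.35 ms with 10 pre-bleach frames and 200 post-bleach frames, mild
per-frame acquisition bleaching (0.15%/frame) on the whole-cell channel, and
2% multiplicative ROI noise.

**Screen tables.** The reference scenario (fixture seed 1002438, part of
the packaged parameter set) plants the screen's documented structure onto
the bundled gene tables: 300 genes of which 151 genome-screen positives
(91 strong), no soluble-reporter artifacts, the 88 bundled Class A modifiers
(81 strong), 63 SOD1-common, 33 wild-type-motility exclusions, a 23/20/12
suppress/no-change/enhance split of the remaining 55, and the 9 bundled core
modifiers with their TS tallies. Per-animal foci counts (50 animals,
control mean 35 ± 4) are drawn from per-class reduction distributions with
comfortable margins relative to the rules; BLPS samples (75 tracks,
wt 0.20 ± 0.05, polyQ 0.12 ± 0.04, planted shifts to 0.14/0.19/0.08) and TS
penetrances (60 animals, control ~80%, planted reductions 0.50–0.70 vs
0.05–0.25) likewise. Because the tables are *defined* by their planted
memberships, each gene's draw is accepted only if the stage's own test
reproduces its planted outcome (bounded seeded redraw); the triage cascade
therefore recovers the planted structure exactly, which is the point of the
fixture — it validates the decision tree's wiring, not the power of the
tests on borderline real data.

## Problem sizes and numerics

The packaged benchmarks run at desk scale on one CPU: the tracked-deficit
experiment uses 20 worms per group split across five 4-worm videos (45 s at
5 fps each); the speed-recovery sweep uses 20 single-worm videos across
0.02–0.30 BLPS; foci precision/recall uses 100 images of 10 + 2 planted
foci; body-length medians subsample every third frame in the workflow paths
(the estimate is stable well below that). Float32 stacks are used for
simulated video; all statistics are computed in float64. Degenerate inputs
raise typed errors (constant image, zero control mean, zero-length body,
single-frame stack) rather than returning sentinel values; the CLI maps
input errors to exit 2 and degenerate data to exit 3.
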