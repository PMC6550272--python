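# Methods

This note documents the models, numerical choices and known limitations of
affectkit, and what its synthetic-data generators do and do not emulate.

## Feature extraction

Face boxes are inputs (0-based, pixel-center, `(x, y, width, height)`,
half-open): face *detection* is deliberately out of scope so any tracker can
be plugged in. Extraction crops the box (clipped to the image; an entirely
outside box raises a distinct "no-face" error) and resamples bilinearly to a
square patch via `scipy.ndimage.map_coordinates` with pixel-center
alignment and nearest-edge clamping.

Illumination normalization is per-patch standardization followed by a
logistic squash back to [0, 1]. It is exactly invariant to affine intensity
maps `a·p + c` (a > 0) that do not clip, which makes the whole
patch→descriptor map invariant to global lighting gain/offset. An exactly
constant patch maps to the all-0.5 patch by convention rather than raising.

The HOG descriptor is authored here rather than delegated, because its
contracts are verified against brute-force oracles at 1e-6 and the exact
mirror-symmetry identity below requires control over the voting scheme:

* gradients by central differences (`np.gradient`; one-sided at borders),
* unsigned orientation θ ∈ [0, π), magnitude-weighted **circular linear
  interpolation** between the two nearest of the 9 bin centers at
  (k + ½)·π/9 — hard binning would break mirror symmetry on axis-aligned
  gradients, linear circular voting makes it exact,
* 8×8 px cells, overlapping 2×2-cell blocks at single-cell stride, L2-hys
  (L2 → clip 0.2 → re-L2, ε = 1e-5).

Mirroring a patch permutes the descriptor exactly: block columns and cell
columns reverse, and orientation bin k maps to 8 − k. The suite verifies
this to 1e-6, plus agreement with `skimage.feature.hog` (same layout,
different internal voting) at cosine similarity > 0.9 as an independent
cross-check. Descriptor length is a pure function of the configuration:
`blocks_per_side² · block_size² · n_orientations` (1764 at defaults).

Default parameters (64×64 patch, 8 px cell, 2×2 block, 9 bins) are the
canonical published HOG configuration; they are configurable and carry no
claim of matching any deployed system.

Augmentation mirrors each frame (labels preserved; an involution on image
and box) and re-extracts features after Gaussian jitter of the box corners
(tracker-error model; corners clipped to the image, redraw up to 10 times if
a side falls under 8 px, then error). Output size is exactly
`n·(1 + mirror)·(1 + n_jitter)`.

## Classifier

"Logistic regression" is implemented as a single multinomial softmax (a
one-vs-rest switch exists) so the session engine receives one coherent
probability vector for feedback gating. The training objective is

    mean NLL + (λ/2)·‖W‖²_F      (bias unpenalized),

minimized by sklearn's deterministic lbfgs solver (`C = 1/(nλ)` maps the
two conventions; iteration cap 500, tol 1e-8; hitting the cap raises a
diagnostic error). λ defaults to 1e-2: features are block-normalized and
O(1), so this is a mild ridge. A from-scratch gradient-descent oracle in the
tests confirms the solver reaches the convex minimum to 1e-6. For binary
problems sklearn's single-row parameterization is expanded to symmetric
per-class rows so downstream shapes are uniform.

Ties in `classify` break to the lowest canonical label index. The feedback
confidence gate defaults to 0.5 in sessions and 0 for offline evaluation —
real-time cues should not fire on ambiguous frames; the value is a design
choice, not an empirical one.

Neutral subtraction maintains a per-person running mean of
neutral-expression features (`mean' = (n·mean + x)/(n+1)`), seeded from
calibration frames labeled neutral; an optional online path folds in frames
classified neutral with p ≥ 0.9 (calibration-only is the default). An empty
reference subtracts nothing. Under the generator's per-user additive
offsets, subtraction removes the user offset and the shared neutral
prototype, so cross-user transfer improves; the suite asserts
non-inferiority over 10 seeded worlds.

## User adaptation

The hierarchical scheme specializes, under a fixed shipped base model, to
per-user MAP with the global coefficients as the Gaussian prior mean:

    argmin  mean NLL(cal) + (1/(2σ²n))·(‖Wᵤ − W_g‖²_F + ‖bᵤ − b_g‖²).

The penalty is scaled per-sample so calibration-set size does not silently
change prior strength. Optimized in the deviation parameterization by
L-BFGS-B with analytic gradients; an empty calibration set returns the
global coefficients verbatim (prior mode) without invoking the optimizer.
σ² defaults to 0.1. Verified properties: deviation norm non-decreasing in
σ²; σ² → 0 pins to the global model; σ² → ∞ matches an unregularized
user-only fit; MAP recovery of a known coefficient perturbation improves
monotonically with calibration size (10 → 100 → 1000 frames, averaged over
10 seeds). A joint mode re-estimates the shared mean across several users
by alternating optimization, for families calibrated together.

Calibration emulation uses ~8 emotions × 25 frames per person — a few
seconds of video per emotion, far less than a five-minute sitting provides.

## Session engine

Frames are logged at 30 fps (the rate at which the wearable saves video
frames). Debounce (default 5 consecutive identical detections) and a
refractory interval (default 2 s) are not protocol constants but necessary
rate-limiting for 30 fps classifier output; both are configurable and echoed
into every log header. At most one feedback event fires per debounced run.
Free Play cues on all eight labels including neutral (a suppression flag
exists, default off).

Capture the Smile draws prompts uniformly without immediate repetition from
a seeded generator; a success is a debounced detection of the current
prompt; the session ends at min(180 s, 20th success). Whether the original
game required sustained or single-frame detection is unknown; debounce is
the interpretation here. Guess the Emotion validates every round's labels
before running, never calls the classifier (asserted by a monkeypatch probe
in the tests), and is untimed.

Timelines are run-length encodings of detected labels; a segment ends one
frame period after its last frame, so segment durations sum exactly to
(detected frames)/fps. Usage compliance counts qualifying sessions
(≥ 20 min) in consecutive 7-day blocks anchored at the first session; a
partial final week is excluded from the weekly minimum (≥ 3); more than two
sessions in a calendar day is flagged.

## Synthetic data

Everything is a pure function of (parameters, seed).

**Faces.** Feature mode draws per-frame vectors
`class_separation·μ_e + offset_u + N(0, noise_sd²)` with seeded unit-norm
class prototypes and `N(0, user_offset_sd²)` user offsets — the minimal
structure exhibiting class signal plus user-specific appearance. Render
mode draws a cartoon face (distance-field strokes: head outline, eyes whose
aperture varies, brows whose angle varies, a mouth whose curvature/opening/
asymmetry varies) from a fixed 5-parameter-per-emotion lookup table, with
user offsets and noise applied to geometry and pixels. It makes no claim of
facial realism; it exists so the full image→HOG→classifier pipeline can be
exercised and beats chance by ≥ 5× at defaults. Neither mode reproduces
pose variation, occlusion, or identity-expression interactions of real
faces — passing tests demonstrate pipeline correctness, not field accuracy.

**Cohorts.** Paired total T-scores are bivariate normal. Defaults are the
study conditions: n = 14, intake 80.07 (SD 9.53), change −7.14 (conclusion
SD 10.29); emotion-guessing intake 28.45 (SD 11.0), change +9.55
(conclusion SD 2.68), with the first 3 participants unassessed at intake.
The pre/post correlations (0.89 and 0.74) are back-solved once from the
reported paired F statistics via sd²_diff = s₁² + s₂² − 2ρs₁s₂ and
t = Δ/(sd_diff/√n), F = t².

Subscale intake scores load 0.9 on the shared severity latent plus a
persistent subscale trait. Subscale *change* is driven by a single
participant-level improvement factor — the centred total change — with
scale-proportional loadings plus 0.25 T-points of per-timepoint noise. This
reflects that all six scores come from one parent-reported instrument whose
total is a function of the same items (a single informant's global
impression shift moves everything together); its consequence is that under
a null total change the whole ANOVA family is essentially one test, and
subscale conclusion SDs are emergent rather than directly calibrated.
Subscale mean changes scale proportionally with the requested total change,
so a null total is a null generator throughout.

The 65 ordinal items derive from the same latent via per-item graded
thresholds (centers U(−1.2, 1.2), spreads U(0.8, 1.2), item noise SD 0.8),
giving intake item means in roughly the 1.8–3.3 range and realistic ties
for the Wilcoxon tests. T-scores are never computed from items — the
item-to-T conversion tables are proprietary — so item-level and T-score
analyses are decoupled, here as in the analytics.

Emotion-guessing scores are Binomial(40, Φ(θ)) with θ paired normal; (m, s)
are moment-matched to the requested score-scale mean/SD by Gauss–Hermite
quadrature + `fsolve`, keeping scores in [0, 40] without truncation
artifacts even at the near-ceiling conclusion mean of 38.

**Sessions.** Streams alternate seeded 'none' gaps with emotion runs (mean
2 s) at exactly `duration_min·60·fps` frames, so schedule minutes are
conserved exactly; `include_frames=False` yields summary records only, for
usage accounting at scale.

## Analytics

* Two-timepoint repeated-measures ANOVA is computed as the squared paired
  t: F = t², df = (1, n−1), two-sided p from the F distribution. n < 2 or
  zero difference variance raise with the condition named. Cross-checked
  against pingouin's rm-ANOVA and a hand formula; null type-I error is
  verified by Monte-Carlo (2000 replicates at n = 14) to sit in the
  binomial band around α.
* Item tests default to the Wilcoxon signed-rank (correct for paired data;
  a rank-sum variant mirrors common loose usage): mid-rank ties, exact
  distribution when the effective n ≤ 25 with no ties (verified against
  full 2ⁿ enumeration), otherwise normal approximation with continuity
  correction. An all-tied item reports p = 1 with a degenerate flag.
* Benjamini–Hochberg is statsmodels' step-up over the m = 65 items,
  verified against a brute-force oracle on all subsets of six p-values.
  Note the step-up is *not* idempotent on its own output (re-adjusting a
  monotone vector q yields min_{j≥i} q_(j)·m/j); the tests assert the true
  invariants (elementwise ≥ raw, order-monotone, permutation-equivariant).
* Severity bands overlap at the published edges; the fixed convention is
  normal < 60, mild [60, 65], moderate (65, 75], severe > 75.
* SDs use n−1; SEM = SD/√n; all tests two-sided. The human-readable report
  prints `p < .001`-style thresholds; exact values live in the JSON report.

## Problem sizes and determinism

Monte-Carlo checks use sizes chosen for a laptop-class single core: 2000
null replicates for the ANOVA type-I error, 60 seeded cohorts for the
family-wise specificity check, 10 seeds for the adaptation and
neutral-subtraction comparisons, 10⁴ draws for jitter-SD and guessing-score
expectations. Every stochastic path takes an explicit seed or
`numpy.random.Generator`; hypothesis-based property tests run derandomized.

## Known limitations

* No real face data anywhere: classifier accuracies reported by the tests
  characterize the generators, not deployed performance.
* The cartoon renderer varies three facial regions only; emotions that
  differ mainly in texture (e.g. disgust vs anger wrinkles) are separated
  here by geometry alone.
* The joint hierarchical mode re-estimates the shared mean as an
  unweighted average (a flat hyperprior); it is provided for completeness
  and not tuned.
* Compliance weeks are 7-day blocks from the first session, not calendar
  weeks; studies anchored differently will classify boundary sessions
  differently.
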