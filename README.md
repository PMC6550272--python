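# affectkit

An offline, fully testable toolkit for wearable social-affective learning
systems: an 8-emotion facial-affect classifier with neutral subtraction and
per-user Bayesian adaptation, deterministic state machines for three therapy
game modes with debounced feedback and 30 fps session logging, seeded
synthetic-data generators, and the paired pre/post outcome analytics used to
evaluate such interventions.

It is aimed at researchers prototyping emotion-feedback therapy tools for
children with autism spectrum disorder (ASD) — and at anyone who needs the
statistical plumbing for small paired intake/conclusion cohorts (SRS-2-style
ordinal questionnaires, bespoke emotion-labeling assessments, usage
compliance) without access to participant-level data.

## The model

**Classifier.** A face box (from any upstream tracker) is cropped,
bilinearly resampled to a 64×64 patch, illumination-normalized (per-patch
standardization + logistic squash, invariant to affine lighting changes) and
encoded as a histogram-of-oriented-gradients descriptor (8 px cells, 2×2
blocks, 9 unsigned bins, L2-hys). Emotions are scored by L2-regularized
multinomial logistic regression,

  P(k | x) ∝ exp(wₖ·x + bₖ),  Ŵ = argmin mean-NLL + (λ/2)‖W‖²_F,

over the eight classes *happy, sad, angry, scared, surprised, neutral,
disgust, contempt* (aliases *calm*→neutral, *meh*→contempt, *afraid*→scared
accepted). A per-person running mean of neutral-expression features is
subtracted from every frame to remove identity-specific appearance.
Training-time augmentation mirrors frames and jitters the face box with
Gaussian noise to emulate tracker error.

**Personalization.** Per-user models are MAP estimates under a Gaussian
prior centred on the global coefficients:

  (Ŵᵤ, b̂ᵤ) = argmin mean-NLL(cal) + (1 / 2σ²n)(‖Wᵤ−W_g‖²_F + ‖bᵤ−b_g‖²).

With no calibration data the prior mode (the global model) is returned; as
σ² grows the fit interpolates toward an unregularized user-only model.

**Sessions.** Three game modes are simulated as deterministic state
machines over classified frame streams at 30 fps: Free Play (a cue whenever
an emotion is detected on `debounce_frames` consecutive frames, subject to a
refractory interval), Capture the Smile (prompted evocation; ends at 180 s
or 20 successes), and Guess the Emotion (app-only rounds; never touches the
classifier). Logs serialize as JSON Lines and replay byte-identically.

**Analytics.** Two-timepoint repeated-measures ANOVA (≡ squared paired t,
df = (1, n−1)), per-item Wilcoxon tests with Benjamini–Hochberg correction,
Pearson correlations, severity banding of SRS-2 T-scores, the 40-item
emotion-guessing protocol (8 × 5 in a fixed seeded order), and usage /
compliance accounting.

## Worked example

```python
import numpy as np
from affectkit import (EmotionClassifier, FaceGenParams, generate_face_dataset,
                       calibrate_user, AdaptationConfig, CohortGenParams,
                       generate_cohort, analyze_cohort)

g = generate_face_dataset(FaceGenParams(n_users=6, frames_per_user_per_emotion=20,
                                        class_separation=1.5, user_offset_sd=1.0,
                                        noise_sd=0.4, n_features=32, rng_seed=0))
X, y, uids = g.features, np.asarray(g.labels), np.asarray(g.user_ids)
tr = np.isin(uids, [f"user_{u}" for u in range(4)])
model = EmotionClassifier(l2=1e-2).fit(X[tr], y[tr])

new = uids == "user_4"
Xu, yu = X[new], y[new]
cal = np.concatenate([np.where(yu == e)[0][:4] for e in np.unique(yu)])
hold = np.setdiff1d(np.arange(len(yu)), cal)
user = calibrate_user(model, Xu[cal], yu[cal], AdaptationConfig(sigma2=1.0))
print(f"global model held-out accuracy on user_4: {(model.predict(Xu[hold]) == yu[hold]).mean():.3f}")
print(f"adapted model held-out accuracy on user_4: {(user.predict(Xu[hold]) == yu[hold]).mean():.3f}")

rep = analyze_cohort(generate_cohort(CohortGenParams(rng_seed=1)))
t = rep["srs2_anova"]["total"]
print(f"SRS-2 total: {t['mean_intake']:.2f} -> {t['mean_conclusion']:.2f} "
      f"(F({t['df1']},{t['df2']}) = {t['F']:.2f}, p = {t['p']:.2g})")
```

prints

```
global model held-out accuracy on user_4: 0.344
adapted model held-out accuracy on user_4: 0.977
SRS-2 total: 81.38 -> 72.74 (F(1,13) = 44.44, p = 1.5e-05)
```

The new user's strong appearance offset cripples the global model (34%
accuracy); 32 calibration frames under the Gaussian prior recover 98%. The
cohort report reproduces the analysis pipeline on a synthetic 14-participant
table: total T-scores near 80 at intake dropping ~7 points, tested with
F(1, 13).

A CLI mirrors the main flows:

```sh
affectkit gen-cohort --out cohort.csv --seed 2
affectkit analyze-cohort --cohort cohort.csv --out report/
affectkit simulate-session --mode capture_the_smile --duration-min 3 --out s.jsonl
```

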