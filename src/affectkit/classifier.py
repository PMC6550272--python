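"""8-class regularized multinomial logistic-regression emotion classifier.

The model is a softmax regression over HOG features: P(class k | x) ∝
exp(w_k · x + b_k), trained by minimizing the mean multinomial negative
log-likelihood plus an L2 penalty (lambda/2)·||W||_F² (bias unpenalized).
"Logistic regression" is read as a single multinomial softmax so the session
engine gets one coherent probability vector to gate feedback on; a
one-vs-rest variant is available behind ``multi_class="ovr"``.

Neutral subtraction: a per-person running mean of neutral-expression
features is subtracted from every frame's features before classification,
removing person-specific appearance offsets so the classifier sees
expression-specific signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .features import FaceFrame, HogConfig, frame_features, jitter_box, mirror_frame
from .labels import EMOTIONS, NONE_LABEL, canonical, label_index

__all__ = [
    "NeutralReference",
    "neutral_subtract",
    "update_neutral",
    "LabeledDataset",
    "AugmentSpec",
    "augment_dataset",
    "softmax_scores",
    "classify",
    "EmotionClassifier",
    "ConvergenceError",
    "train",
    "save_model",
    "load_model",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge within its iteration cap; carries diagnostics."""


@dataclass
class NeutralReference:
    """Running mean of neutral-expression feature vectors for one person."""

    mean_feature: np.ndarray
    n_frames: int = 0

    @classmethod
    def empty(cls, dim: int) -> "NeutralReference":
        return cls(mean_feature=np.zeros(dim), n_frames=0)


def neutral_subtract(x: np.ndarray, ref: NeutralReference) -> np.ndarray:
    """x minus the neutral mean; with an empty reference, x is returned unchanged."""
    x = np.asarray(x, dtype=float)
    if ref.n_frames == 0:
        return x
    if x.shape[-1] != ref.mean_feature.shape[0]:
        raise ValueError(
            f"feature dim {x.shape[-1]} != neutral reference dim {ref.mean_feature.shape[0]}"
        )
    return x - ref.mean_feature


def update_neutral(ref: NeutralReference, x: np.ndarray) -> NeutralReference:
    """Fold one neutral frame into the running mean: mean' = (n·mean + x)/(n+1)."""
    x = np.asarray(x, dtype=float)
    if ref.n_frames and x.shape != ref.mean_feature.shape:
        raise ValueError("feature dim mismatch in neutral update")
    n = ref.n_frames
    mean = (n * ref.mean_feature + x) / (n + 1) if n else x.astype(float).copy()
    return NeutralReference(mean_feature=mean, n_frames=n + 1)


@dataclass
class LabeledDataset:
    """Feature matrix with canonical labels and optional per-row user ids."""

    features: np.ndarray
    labels: list[str]
    user_ids: list | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = [canonical(l) for l in self.labels]
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("row counts of features and labels disagree")
        if self.user_ids is not None and len(self.user_ids) != len(self.labels):
            raise ValueError("user_ids length mismatch")


@dataclass(frozen=True)
class AugmentSpec:
    """Training-time augmentation: mirroring and tracker-box jitter."""

    mirror: bool = True
    n_jitter: int = 0
    jitter_sigma: float = 3.0


def augment_dataset(
    frames: Sequence[FaceFrame],
    spec: AugmentSpec,
    config: HogConfig | None = None,
    rng_seed: int | None = None,
) -> LabeledDataset:
    """Expand frames by mirroring and box jitter, then featurize.

    Per input frame the output holds the original, ``n_jitter`` jittered-box
    re-extractions, and (if ``spec.mirror``) the mirror of each of those:
    n·(1 + mirror)·(1 + n_jitter) rows, labels inherited.
    """
    if spec.n_jitter < 0 or spec.jitter_sigma < 0:
        raise ValueError("n_jitter and jitter_sigma must be >= 0")
    config = config or HogConfig()
    rng = np.random.default_rng(rng_seed)
    feats, labels = [], []
    for i, frame in enumerate(frames):
        variants = [frame]
        for _ in range(spec.n_jitter):
            try:
                box = jitter_box(frame.box, spec.jitter_sigma, rng, frame.image.shape)
            except ValueError as exc:
                raise ValueError(f"frame {i}: {exc}") from exc
            variants.append(FaceFrame(frame.image, frame.timestamp, box, frame.label))
        if spec.mirror:
            variants.extend(mirror_frame(v) for v in list(variants))
        for v in variants:
            try:
                feats.append(frame_features(v, config))
            except Exception as exc:
                raise type(exc)(f"frame {i}: {exc}") from exc
            labels.append(v.label)
    return LabeledDataset(np.asarray(feats), labels)


def softmax_scores(weights: np.ndarray, bias: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Stable softmax probabilities for one feature vector (max-subtraction)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite entries")
    z = weights @ x + bias
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def classify(
    weights: np.ndarray,
    bias: np.ndarray,
    x: np.ndarray,
    classes: Sequence[str] = EMOTIONS,
    min_confidence: float = 0.0,
) -> str:
    """Argmax label if its probability clears the gate, else ``"none"``.

    Ties break to the lowest canonical label index (deterministic).
    """
    if not (0 <= min_confidence < 1):
        raise ValueError("min_confidence must be in [0, 1)")
    p = softmax_scores(weights, bias, x)
    best = min(range(len(classes)), key=lambda i: (-p[i], label_index(classes[i])))
    if p[best] >= min_confidence:
        return canonical(classes[best])
    return NONE_LABEL


class EmotionClassifier(ClassifierMixin, BaseEstimator):
    """Multinomial logistic-regression over emotion labels, sklearn-style.

    Minimizes mean NLL + (l2/2)·||W||_F² (bias unpenalized) with a
    deterministic quasi-Newton solver. Fitted attributes: ``classes_``
    (canonical label strings, in canonical index order), ``coef_`` (one row
    per observed class — 8 × d when all eight emotions are present),
    ``intercept_``, ``n_iter_``.

    Parameters
    ----------
    l2 : float
        Penalty strength lambda (> 0). Features are block-normalized and O(1)
        in scale, so the default 1e-2 is a mild ridge.
    min_confidence : float
        Probability gate used by :meth:`predict_gated`; 0 disables the gate
        (offline evaluation), 0.5 is the session-feedback default.
    """

    def __init__(
        self,
        l2: float = 1e-2,
        min_confidence: float = 0.0,
        max_iter: int = 500,
        tol: float = 1e-8,
        multi_class: str = "multinomial",
    ) -> None:
        self.l2 = l2
        self.min_confidence = min_confidence
        self.max_iter = max_iter
        self.tol = tol
        self.multi_class = multi_class

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = [canonical(l) for l in y]
        if self.l2 <= 0:
            raise ValueError("l2 must be > 0")
        if len(set(y)) < 2:
            raise ValueError("training data must contain at least 2 distinct labels")
        n = X.shape[0]
        # sklearn minimizes sum-NLL + (1/(2C))||W||²; C = 1/(n·lambda) recovers
        # mean-NLL + (lambda/2)||W||².
        est = LogisticRegression(
            C=1.0 / (n * self.l2),
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        if self.multi_class == "ovr":
            from sklearn.multiclass import OneVsRestClassifier

            self._impl_ = OneVsRestClassifier(est).fit(X, y)
            self.coef_ = np.vstack([e.coef_ for e in self._impl_.estimators_])
            self.intercept_ = np.concatenate([e.intercept_ for e in self._impl_.estimators_])
            raw_classes = self._impl_.classes_
            n_iter = max(int(e.n_iter_[0]) for e in self._impl_.estimators_)
        else:
            est.fit(X, y)
            self._impl_ = est
            self.coef_ = est.coef_
            self.intercept_ = est.intercept_
            raw_classes = est.classes_
            n_iter = int(est.n_iter_[0])
            if len(raw_classes) == 2 and self.coef_.shape[0] == 1:
                # expand binary parameterization to symmetric softmax rows
                self.coef_ = np.vstack([-self.coef_[0] / 2, self.coef_[0] / 2])
                self.intercept_ = np.array(
                    [-self.intercept_[0] / 2, self.intercept_[0] / 2]
                )
        # reorder rows into canonical emotion-index order
        order = np.argsort([label_index(c) for c in raw_classes])
        self.classes_ = np.asarray(raw_classes)[order]
        self.coef_ = np.asarray(self.coef_)[order]
        self.intercept_ = np.asarray(self.intercept_)[order]
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        if n_iter >= self.max_iter:
            raise ConvergenceError(
                f"solver hit the iteration cap ({self.max_iter}); "
                f"n={n}, d={X.shape[1]}, l2={self.l2}, tol={self.tol}"
            )
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite entries")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        Z = X @ self.coef_.T + self.intercept_
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes_[P.argmax(axis=1)]

    def predict_gated(self, X, min_confidence: float | None = None) -> list[str]:
        """Per-row argmax label, or ``"none"`` where the top probability
        misses the confidence gate."""
        gate = self.min_confidence if min_confidence is None else min_confidence
        if not (0 <= gate < 1):
            raise ValueError("min_confidence must be in [0, 1)")
        P = self.predict_proba(X)
        idx = P.argmax(axis=1)
        return [
            self.classes_[i] if P[r, i] >= gate else NONE_LABEL
            for r, i in enumerate(idx)
        ]

    def mean_objective(self, X, y) -> float:
        """Mean NLL + (l2/2)||W||² at the fitted coefficients (diagnostic)."""
        X = self._check_X(X)
        yi = np.array([list(self.classes_).index(canonical(l)) for l in y])
        Z = X @ self.coef_.T + self.intercept_
        Z -= Z.max(axis=1, keepdims=True)
        logp = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
        nll = -logp[np.arange(len(yi)), yi].mean()
        return float(nll + 0.5 * self.l2 * np.sum(self.coef_**2))


def train(
    dataset: LabeledDataset,
    l2: float = 1e-2,
    augment: AugmentSpec | None = None,
    frames: Sequence[FaceFrame] | None = None,
    hog_config: HogConfig | None = None,
    rng_seed: int | None = None,
) -> EmotionClassifier:
    """Train the base model; with ``augment`` given, featurizes ``frames``
    through the augmentation pipeline first."""
    if augment is not None:
        if frames is None:
            raise ValueError("augmentation requires the raw frames")
        dataset = augment_dataset(frames, augment, hog_config, rng_seed)
    model = EmotionClassifier(l2=l2)
    model.fit(dataset.features, dataset.labels)
    if hog_config is not None:
        model.hog_config_ = hog_config
    return model


_SCHEMA_VERSION = "1.0"


def save_model(model: EmotionClassifier, path, extra: dict | None = None) -> None:
    """Single-file JSON serialization (weights as nested lists, config echo)."""
    check_is_fitted(model, "coef_")
    cfg = getattr(model, "hog_config_", None)
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "kind": "emotion_classifier",
        "classes": [str(c) for c in model.classes_],
        "weights": model.coef_.tolist(),
        "bias": model.intercept_.tolist(),
        "l2": getattr(model, "l2", None),
        "min_confidence": getattr(model, "min_confidence", 0.0),
        "hog_config": None
        if cfg is None
        else {
            "patch_size": cfg.patch_size,
            "cell_size": cfg.cell_size,
            "block_size": cfg.block_size,
            "n_orientations": cfg.n_orientations,
            "block_norm_eps": cfg.block_norm_eps,
        },
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> EmotionClassifier:
    doc = json.loads(Path(path).read_text())
    model = EmotionClassifier(
        l2=doc.get("l2") or 1e-2, min_confidence=doc.get("min_confidence") or 0.0
    )
    model.classes_ = np.asarray(doc["classes"])
    model.coef_ = np.asarray(doc["weights"], dtype=float)
    model.intercept_ = np.asarray(doc["bias"], dtype=float)
    model.n_features_in_ = model.coef_.shape[1]
    model.n_iter_ = 0
    if doc.get("hog_config"):
        model.hog_config_ = HogConfig(**doc["hog_config"])
    return model
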