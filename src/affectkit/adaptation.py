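"""Per-user classifier personalization under a Gaussian prior.

Hierarchical Bayesian domain adaptation, specialized to deployment: the
shipped global model is fixed and each user's coefficients get a Gaussian
prior centred on it. The MAP estimate minimizes

    mean NLL(cal; W_u, b_u) + (1 / (2·sigma2·n)) · (||W_u − W_g||_F² + ||b_u − b_g||²)

over the user's calibration frames. The penalty is scaled per-sample so the
effective prior strength does not silently change with calibration-set size.
As sigma2 → 0 the user model collapses onto the global model; as sigma2 → ∞
it approaches an unregularized user-only fit. With an *empty* calibration
set the prior mode — the global coefficients — is returned verbatim.

An optional joint mode re-estimates the shared mean across several users
(alternating optimization), for the case where all family members are
calibrated together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classifier import ConvergenceError, EmotionClassifier
from .labels import NONE_LABEL, canonical

__all__ = [
    "AdaptationConfig",
    "UserAdaptedClassifier",
    "calibrate_user",
    "evaluate_adaptation",
    "fit_hierarchical",
]


@dataclass(frozen=True)
class AdaptationConfig:
    """Prior variance and optimizer settings for user calibration."""

    sigma2: float = 0.1
    max_iter: int = 500
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


def _one_hot(y_idx: np.ndarray, k: int) -> np.ndarray:
    Y = np.zeros((len(y_idx), k))
    Y[np.arange(len(y_idx)), y_idx] = 1.0
    return Y


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


class UserAdaptedClassifier(ClassifierMixin, BaseEstimator):
    """MAP-adapted per-user emotion classifier (sklearn-style estimator).

    Parameters
    ----------
    prior : fitted EmotionClassifier
        The global model; its coefficients are the Gaussian prior mean.
    sigma2 : float
        Prior variance on the coefficient deviation. Small values pin the
        user model to the global one; large values let calibration dominate.
    user_id : optional identifier carried through reports/serialization.
    """

    def __init__(
        self,
        prior: EmotionClassifier,
        sigma2: float = 0.1,
        max_iter: int = 500,
        tol: float = 1e-10,
        user_id: str | None = None,
    ) -> None:
        self.prior = prior
        self.sigma2 = sigma2
        self.max_iter = max_iter
        self.tol = tol
        self.user_id = user_id

    def fit(self, X, y):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        check_is_fitted(self.prior, "coef_")
        Wg = np.asarray(self.prior.coef_, dtype=float)
        bg = np.asarray(self.prior.intercept_, dtype=float)
        self.classes_ = np.asarray(self.prior.classes_)
        self.n_features_in_ = Wg.shape[1]

        X = np.atleast_2d(np.asarray(X, dtype=float)) if len(X) else np.empty((0, Wg.shape[1]))
        n = X.shape[0]
        self.n_calibration_ = n
        if n == 0:
            # prior mode: global coefficients verbatim
            self.coef_ = Wg.copy()
            self.intercept_ = bg.copy()
            self.n_iter_ = 0
            return self
        if X.shape[1] != Wg.shape[1]:
            raise ValueError(
                f"calibration feature dim {X.shape[1]} != model dim {Wg.shape[1]}"
            )
        class_list = list(self.classes_)
        y_idx = np.array([class_list.index(canonical(l)) for l in y])
        k, d = Wg.shape
        Y = _one_hot(y_idx, k)
        lam = 1.0 / (self.sigma2 * n)

        def objective(v: np.ndarray):
            dW = v[: k * d].reshape(k, d)
            db = v[k * d :]
            Z = X @ (Wg + dW).T + (bg + db)
            Zs = Z - Z.max(axis=1, keepdims=True)
            logZ = np.log(np.exp(Zs).sum(axis=1, keepdims=True))
            logp = Zs - logZ
            nll = -logp[np.arange(n), y_idx].mean()
            pen = 0.5 * lam * (np.sum(dW * dW) + db @ db)
            P = np.exp(logp)
            G = (P - Y) / n
            gW = G.T @ X + lam * dW
            gb = G.sum(axis=0) + lam * db
            return nll + pen, np.concatenate([gW.ravel(), gb])

        res = minimize(
            objective,
            np.zeros(k * d + k),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
        )
        if not res.success and "ITERATIONS" in str(res.message).upper():
            raise ConvergenceError(
                f"adaptation solver hit iteration cap: {res.message}; n={n}, sigma2={self.sigma2}"
            )
        self.coef_ = Wg + res.x[: k * d].reshape(k, d)
        self.intercept_ = bg + res.x[k * d :]
        self.n_iter_ = int(res.nit)
        self.objective_value_ = float(res.fun)
        return self

    # prediction mirrors EmotionClassifier
    predict_proba = EmotionClassifier.predict_proba
    predict = EmotionClassifier.predict
    predict_gated = EmotionClassifier.predict_gated
    _check_X = EmotionClassifier._check_X

    @property
    def min_confidence(self) -> float:
        return self.prior.min_confidence

    def deviation_norm(self) -> float:
        """||W_u − W_g||_F, a measure of how far calibration pulled the model."""
        check_is_fitted(self, "coef_")
        return float(np.linalg.norm(self.coef_ - self.prior.coef_))


def calibrate_user(
    global_model: EmotionClassifier,
    cal_X,
    cal_y,
    config: AdaptationConfig | None = None,
    user_id: str | None = None,
) -> UserAdaptedClassifier:
    """Fit one user's MAP-adapted model from a calibration sitting."""
    config = config or AdaptationConfig()
    return UserAdaptedClassifier(
        prior=global_model,
        sigma2=config.sigma2,
        max_iter=config.max_iter,
        tol=config.tol,
        user_id=user_id,
    ).fit(cal_X, cal_y)


def evaluate_adaptation(
    global_model: EmotionClassifier,
    users: Sequence[tuple],
    config: AdaptationConfig | None = None,
) -> pd.DataFrame:
    """Per-user global-vs-adapted held-out accuracy table.

    ``users`` is a sequence of ``(user_id, (cal_X, cal_y), (hold_X, hold_y))``.
    Users with empty holdouts are skipped with a warning row (acc = NaN).
    An aggregate ``mean`` row is appended.
    """
    config = config or AdaptationConfig()
    rows = []
    for user_id, (cal_X, cal_y), (hold_X, hold_y) in users:
        adapted = calibrate_user(global_model, cal_X, cal_y, config, user_id=str(user_id))
        if len(hold_y) == 0:
            rows.append(
                {
                    "user_id": user_id,
                    "n_cal": len(cal_y),
                    "acc_global": np.nan,
                    "acc_adapted": np.nan,
                    "warning": "empty holdout; skipped",
                }
            )
            continue
        y_true = np.array([canonical(l) for l in hold_y])
        acc_g = float(np.mean(global_model.predict(hold_X) == y_true))
        acc_a = float(np.mean(adapted.predict(hold_X) == y_true))
        rows.append(
            {
                "user_id": user_id,
                "n_cal": len(cal_y),
                "acc_global": acc_g,
                "acc_adapted": acc_a,
                "warning": "",
            }
        )
    df = pd.DataFrame(rows)
    scored = df[df["warning"] == ""]
    agg = {
        "user_id": "mean",
        "n_cal": scored["n_cal"].mean() if len(scored) else np.nan,
        "acc_global": scored["acc_global"].mean() if len(scored) else np.nan,
        "acc_adapted": scored["acc_adapted"].mean() if len(scored) else np.nan,
        "warning": "",
    }
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)


def fit_hierarchical(
    global_model: EmotionClassifier,
    user_datasets: Sequence[tuple],
    sigma2: float = 0.1,
    n_rounds: int = 3,
) -> tuple[np.ndarray, np.ndarray, list[UserAdaptedClassifier]]:
    """Joint mode: alternate per-user MAP fits with re-estimation of the
    shared prior mean (the average of the user coefficients).

    ``user_datasets`` is a sequence of ``(user_id, X, y)``. Returns the final
    shared (W, b) and the per-user adapted models referencing it.
    """
    check_is_fitted(global_model, "coef_")
    shared = EmotionClassifier(l2=global_model.l2)
    shared.classes_ = np.asarray(global_model.classes_)
    shared.coef_ = np.asarray(global_model.coef_, dtype=float).copy()
    shared.intercept_ = np.asarray(global_model.intercept_, dtype=float).copy()
    shared.n_features_in_ = shared.coef_.shape[1]
    shared.n_iter_ = 0
    users: list[UserAdaptedClassifier] = []
    for _ in range(n_rounds):
        users = [
            UserAdaptedClassifier(prior=shared, sigma2=sigma2, user_id=str(uid)).fit(X, y)
            for uid, X, y in user_datasets
        ]
        shared.coef_ = np.mean([u.coef_ for u in users], axis=0)
        shared.intercept_ = np.mean([u.intercept_ for u in users], axis=0)
    return shared.coef_, shared.intercept_, users
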