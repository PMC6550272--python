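"""Shared experiment builders used by both unit and acceptance tests."""

import numpy as np

from affectkit.adaptation import AdaptationConfig, evaluate_adaptation
from affectkit.classifier import EmotionClassifier
from affectkit.labels import EMOTIONS
from affectkit.synthetic import FaceGenParams, generate_face_dataset


def offset_user_experiment(seed, n_new_users=4, offset_sd=1.5, n_cal=3, n_hold=8,
                           sigma2=1.0):
    """Train a global model on 4 users, adapt to 4 unseen offset users; return
    mean held-out accuracy gain of adaptation over the global model."""
    g = generate_face_dataset(
        FaceGenParams(
            n_users=n_new_users + 4,
            frames_per_user_per_emotion=n_cal + n_hold,
            class_separation=1.5,
            user_offset_sd=offset_sd,
            noise_sd=0.4,
            n_features=16,
            rng_seed=seed,
        )
    )
    X = g.features
    uids = np.asarray(g.user_ids)
    labels = np.asarray(g.labels)
    train_mask = np.isin(uids, [f"user_{u}" for u in range(4)])
    model = EmotionClassifier(l2=1e-2).fit(X[train_mask], labels[train_mask])
    users = []
    for u in range(4, 4 + n_new_users):
        mask = uids == f"user_{u}"
        Xu, yu = X[mask], labels[mask]
        cal_idx = np.concatenate([np.where(yu == e)[0][:n_cal] for e in EMOTIONS])
        hold_idx = np.setdiff1d(np.arange(len(yu)), cal_idx)
        users.append((f"user_{u}", (Xu[cal_idx], yu[cal_idx]), (Xu[hold_idx], yu[hold_idx])))
    table = evaluate_adaptation(model, users, AdaptationConfig(sigma2=sigma2))
    agg = table[table["user_id"] == "mean"].iloc[0]
    return float(agg["acc_adapted"] - agg["acc_global"])
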