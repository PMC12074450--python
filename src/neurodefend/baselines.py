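"""Comparison methods: undefended identity, brain-ablated regressors,
noise-averaging defenses, and ideal adversarial training.

Every baseline shares the defense's evaluation surface (a predicted D-vector
per test image) so all of them land in the same report:

* ``clip_identity``     — the raw encoder, i.e. the attack's success rate;
* ``train_no_fmri``     — the same regressor trained on augmented views only
                          (input width D): isolates the brain contribution;
* ``train_noise_baseline`` — brain feature replaced by a fixed random unit
                          vector per sample: the chance level;
* ``randomized_smoothing`` / ``random_self_ensemble`` — noise-averaging
                          defenses adapted from classification to embedding
                          regression (average, then renormalize / plain mean);
* ``train_adversarial`` — the "ideal" upper bound: trained on embeddings of
                          adversarial examples from the very attack later
                          used for evaluation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .attacks import AttackConfig, attack
from .augmentation import build_augmented_set, encode_augmented_set
from .defense import (
    HIDDEN_FACTOR,
    MLP,
    DefenseModel,
    TrainConfig,
    build_training_matrices,
)
from .encoders import JointEncoder
from .synthetic_world import Dataset

__all__ = [
    "BASELINE_NAMES",
    "clip_identity",
    "train_no_fmri",
    "train_noise_baseline",
    "noise_feature_for",
    "randomized_smoothing",
    "random_self_ensemble",
    "train_adversarial",
]

BASELINE_NAMES = ("clip_identity", "pm_no_fmri", "pm_noise", "rs", "rse", "at")

RS_SIGMA = 0.05
RS_M = 16
RSE_SIGMA = 0.02
RSE_M = 10


def clip_identity(encoder: JointEncoder, x: np.ndarray) -> np.ndarray:
    """The undefended encoder itself: predicted feature = image embedding."""
    return encoder.image_encode(x)


def train_no_fmri(
    train_set: Dataset,
    encoder: JointEncoder,
    aug_seed: int = 0,
    model_config: TrainConfig | None = None,
) -> DefenseModel:
    """Regressor trained on the augmented image set alone (input width D)."""
    if len(train_set.samples) == 0:
        raise ValueError("training set is empty")
    cfg = model_config or TrainConfig()
    D = encoder.D
    X, T, groups = build_training_matrices(train_set, encoder, aug_seed, None, use_brain=False)
    mlp = MLP(D, HIDDEN_FACTOR * D, D, seed=cfg.seed)
    trace = mlp.fit(X, T, groups, cfg)
    return DefenseModel(mlp=mlp, D=D, uses_brain=False, fidelity=None,
                        train_config=cfg, loss_trace=trace)


def noise_feature_for(sample, noise_seed: int, D: int) -> np.ndarray:
    """Fixed random unit vector per sample id — identical at train and test."""
    rng = np.random.default_rng(np.random.SeedSequence([noise_seed, sample.index, 13]))
    v = rng.standard_normal(D)
    return v / np.linalg.norm(v)


def train_noise_baseline(
    train_set: Dataset,
    encoder: JointEncoder,
    aug_seed: int = 0,
    model_config: TrainConfig | None = None,
    noise_seed: int = 0,
) -> DefenseModel:
    """Chance-level control: the brain slot carries a per-sample random unit
    vector (input width 2D, same pipeline as the defense otherwise)."""
    if len(train_set.samples) == 0:
        raise ValueError("training set is empty")
    cfg = model_config or TrainConfig()
    D = encoder.D
    from .defense import integrate  # local import avoids a cycle at module load

    X_rows, T_rows, groups = [], [], []
    for s in train_set.samples:
        aug = build_augmented_set(
            s.pixels, seed=int(np.random.SeedSequence([aug_seed, s.index]).generate_state(1)[0] % (2**31))
        )
        F_a = encode_augmented_set(encoder, aug)
        f_o = encoder.image_encode(s.pixels)
        F_i = integrate(F_a, noise_feature_for(s, noise_seed, D))
        X_rows.append(F_i.T)
        T_rows.append(np.tile(f_o, (F_i.shape[1], 1)))
        groups.extend([s.index] * F_i.shape[1])
    X, T = np.vstack(X_rows), np.vstack(T_rows)
    mlp = MLP(2 * D, HIDDEN_FACTOR * D, D, seed=cfg.seed)
    trace = mlp.fit(X, T, np.asarray(groups), cfg)
    model = DefenseModel(mlp=mlp, D=D, uses_brain=True, fidelity=None,
                         train_config=cfg, loss_trace=trace)
    model.noise_seed = noise_seed  # evaluation regenerates the same vectors
    return model


def randomized_smoothing(
    encoder: JointEncoder,
    x: np.ndarray,
    sigma: float = RS_SIGMA,
    M: int = RS_M,
    seed: int = 0,
) -> np.ndarray:
    """Average embedding over M Gaussian-noised copies of x, renormalized."""
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64)
    acc = np.zeros(encoder.D)
    for _ in range(M):
        noisy = np.clip(x + rng.normal(0.0, sigma, size=x.shape), 0.0, 1.0) if sigma > 0 else x
        acc += encoder.image_encode(noisy)
    mean = acc / M
    n = float(np.linalg.norm(mean))
    if n < 1e-12:
        raise ValueError("smoothed embedding collapsed to zero")
    return mean / n


def random_self_ensemble(
    model: DefenseModel,
    integrated_feature: np.ndarray,
    sigma_layer: float = RSE_SIGMA,
    M: int = RSE_M,
    seed: int = 0,
) -> np.ndarray:
    """Mean over M forward passes with Gaussian noise on hidden pre-activations."""
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")
    X = np.atleast_2d(np.asarray(integrated_feature, dtype=np.float64))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected input width {model.input_dim}, got {X.shape[1]}")
    if sigma_layer == 0.0:
        return model.mlp.forward(X)[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(model.D)
    for _ in range(M):
        acc += model.mlp.forward(X, hidden_noise=(sigma_layer, rng))[0]
    return acc / M


def train_adversarial(
    train_set: Dataset,
    encoder: JointEncoder,
    attack_config: AttackConfig,
    model_config: TrainConfig | None = None,
) -> DefenseModel:
    """Ideal adversarial training: D -> D regressor from adversarial-example
    embeddings to clean embeddings, using the evaluation attack itself."""
    if len(train_set.samples) == 0:
        raise ValueError("training set is empty")
    cfg = model_config or TrainConfig()
    D = encoder.D
    X_rows, T_rows, groups = [], [], []
    for s in train_set.samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = attack(encoder, s.pixels, s.caption, attack_config)
        X_rows.append(encoder.image_encode(res.x_adv))
        T_rows.append(encoder.image_encode(s.pixels))
        groups.append(s.index)
    X, T = np.vstack(X_rows), np.vstack(T_rows)
    mlp = MLP(D, HIDDEN_FACTOR * D, D, seed=cfg.seed)
    trace = mlp.fit(X, T, np.asarray(groups), cfg)
    model = DefenseModel(mlp=mlp, D=D, uses_brain=False, fidelity=None,
                         train_config=cfg, loss_trace=trace)
    model.trained_attack = attack_config
    return model
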