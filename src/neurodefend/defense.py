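"""Feature integration, the 3-layer regression network, and its training.

The defense concatenates the (attack-invariant) brain feature above each
augmented-view visual feature, and trains a 3-layer fully connected network
g_theta : R^{2D} -> R^{D} (hidden widths 4D, rectified-linear activations,
linear output) to regress the clean image embedding f_o under a cosine loss

    L = (1/N) * sum_n [ 1 - cos(f_o, g_theta(f_n_i)) ].

Every predicted column of a sample is supervised against that sample's single
f_o. At test time no augmentation is applied: the network sees the single
test image's embedding stacked under the clean-derived brain feature.

Implemented in plain numpy (hand-derived backprop, Adam), single-threaded and
bit-deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augmentation import build_augmented_set, encode_augmented_set
from .encoders import JointEncoder
from .synthetic_world import Dataset, reference_embedding, simulate_brain_feature, _rng_for

__all__ = [
    "TrainConfig",
    "MLP",
    "DefenseModel",
    "integrate",
    "cosine_loss",
    "train_defense",
    "defend",
    "build_training_matrices",
]

HIDDEN_FACTOR = 4  # hidden widths = 4D


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 0.0  # decoupled, applied to weight matrices only


def integrate(F_a: np.ndarray, f_b: np.ndarray) -> np.ndarray:
    """Stack the shared brain feature above every visual column: (2D, N).

    Pure concatenation — no renormalization — so splitting the halves
    recovers (f_b, F_a) exactly.
    """
    F_a = np.asarray(F_a, dtype=np.float64)
    f_b = np.asarray(f_b, dtype=np.float64)
    if F_a.ndim != 2 or f_b.ndim != 1 or F_a.shape[0] != f_b.shape[0]:
        raise ValueError(
            f"dimension mismatch: F_a {F_a.shape} vs f_b {f_b.shape}"
        )
    top = np.tile(f_b[:, None], (1, F_a.shape[1]))
    return np.vstack([top, F_a])


def cosine_loss(f_o: np.ndarray, F_hat: np.ndarray) -> float:
    """Mean over columns of (1 - cosine to f_o); range [0, 2]."""
    f_o = np.asarray(f_o, dtype=np.float64)
    F_hat = np.asarray(F_hat, dtype=np.float64)
    if F_hat.ndim == 1:
        F_hat = F_hat[:, None]
    no = float(np.linalg.norm(f_o))
    norms = np.linalg.norm(F_hat, axis=0)
    if no < 1e-12 or np.any(norms < 1e-12):
        raise ValueError("cosine loss undefined for zero vectors")
    cosines = (f_o @ F_hat) / (no * norms)
    return float(np.mean(1.0 - cosines))


class MLP:
    """3-layer fully connected network, ReLU hidden activations, linear output.

    Rows are samples. Forward/backward are hand-derived for the cosine loss;
    optimization is Adam. Deterministic given the init seed.
    """

    def __init__(self, d_in: int, d_hidden: int, d_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dims = (d_in, d_hidden, d_out)

        def he(fan_in, shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "W1": he(d_in, (d_in, d_hidden)), "b1": np.zeros(d_hidden),
            "W2": he(d_hidden, (d_hidden, d_hidden)), "b2": np.zeros(d_hidden),
            "W3": he(d_hidden, (d_hidden, d_out)), "b3": np.zeros(d_out),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def forward(self, X: np.ndarray, cache: dict | None = None,
                hidden_noise: tuple[float, np.random.Generator] | None = None) -> np.ndarray:
        """X: (n, d_in) -> (n, d_out). Optional zero-mean Gaussian noise on
        each hidden pre-activation (random-self-ensemble inference mode)."""
        p = self.params
        a1 = X @ p["W1"] + p["b1"]
        if hidden_noise is not None:
            sigma, rng = hidden_noise
            a1 = a1 + rng.normal(0.0, sigma, size=a1.shape)
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ p["W2"] + p["b2"]
        if hidden_noise is not None:
            a2 = a2 + rng.normal(0.0, sigma, size=a2.shape)
        h2 = np.maximum(a2, 0.0)
        y = h2 @ p["W3"] + p["b3"]
        if cache is not None:
            cache.update(X=X, a1=a1, h1=h1, a2=a2, h2=h2, y=y)
        return y

    @staticmethod
    def _cosine_loss_grad(Y: np.ndarray, T: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean (1 - cos(y_i, t_i)) over rows and its gradient w.r.t. Y.

        Targets T are unit rows; d cos/d y = t/|y| - (t.y) y / |y|^3.
        """
        n = Y.shape[0]
        ynorm = np.linalg.norm(Y, axis=1, keepdims=True)
        ynorm = np.maximum(ynorm, 1e-12)
        dots = np.sum(Y * T, axis=1, keepdims=True)
        cos = dots / ynorm
        loss = float(np.mean(1.0 - cos))
        dcos_dY = T / ynorm - dots * Y / ynorm**3
        return loss, -dcos_dY / n

    def train_step(self, X: np.ndarray, T: np.ndarray, lr: float,
                   weight_decay: float = 0.0) -> float:
        cache: dict = {}
        Y = self.forward(X, cache=cache)
        loss, dY = self._cosine_loss_grad(Y, T)
        p = self.params
        g = {}
        g["W3"] = cache["h2"].T @ dY
        g["b3"] = dY.sum(axis=0)
        dh2 = dY @ p["W3"].T
        da2 = dh2 * (cache["a2"] > 0)
        g["W2"] = cache["h1"].T @ da2
        g["b2"] = da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (cache["a1"] > 0)
        g["W1"] = cache["X"].T @ da1
        g["b1"] = da1.sum(axis=0)

        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k in p:
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g[k]
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g[k] ** 2
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            if weight_decay > 0 and k.startswith("W"):
                p[k] *= 1.0 - lr * weight_decay
        return loss

    def fit(self, X: np.ndarray, T: np.ndarray, groups: np.ndarray,
            config: TrainConfig, epoch_refresh=None) -> list[float]:
        """Mini-batch training; ``groups`` maps rows to their sample index so
        shuffling happens per sample (all N columns of a sample travel
        together — the loss stays a mean per sample).

        ``epoch_refresh(epoch, X, T)``, when given, may mutate X in place
        before each epoch (used to redraw simulated brain-decoding noise)."""
        rng = np.random.default_rng(config.seed + 1)
        sample_ids = np.unique(groups)
        trace: list[float] = []
        for epoch in range(config.epochs):
            if epoch_refresh is not None:
                epoch_refresh(epoch, X, T)
            order = rng.permutation(sample_ids)
            losses, weights = [], []
            for start in range(0, len(order), config.batch_size):
                chosen = order[start : start + config.batch_size]
                mask = np.isin(groups, chosen)
                loss = self.train_step(X[mask], T[mask], config.lr, config.weight_decay)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {len(trace)}"
                    )
                losses.append(loss)
                weights.append(int(mask.sum()))
            trace.append(float(np.average(losses, weights=weights)))
        return trace


@dataclass
class DefenseModel:
    """Trained regression network plus everything needed to reuse it."""

    mlp: MLP
    D: int
    uses_brain: bool  # True -> input width 2D; False -> visual-only width D
    fidelity: float | None
    train_config: TrainConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return 2 * self.D if self.uses_brain else self.D

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected input width {self.input_dim}, got {X.shape[1]}")
        return self.mlp.forward(X)

    def save(self, path: str | Path) -> None:
        """Flat named-parameter archive with a JSON manifest (text format)."""
        payload = {
            "manifest": {
                "D": self.D,
                "uses_brain": self.uses_brain,
                "fidelity": self.fidelity,
                "dims": list(self.mlp.dims),
                "train_config": vars(self.train_config) if not hasattr(self.train_config, "__dataclass_fields__") else {
                    k: getattr(self.train_config, k) for k in ("lr", "epochs", "batch_size", "seed")
                },
                "n_params": self.mlp.n_params,
            },
            "params": {k: v.tolist() for k, v in self.mlp.params.items()},
            "loss_trace": self.loss_trace,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DefenseModel":
        payload = json.loads(Path(path).read_text())
        man = payload["manifest"]
        mlp = MLP(*man["dims"], seed=0)
        mlp.params = {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
        return cls(
            mlp=mlp, D=man["D"], uses_brain=man["uses_brain"],
            fidelity=man["fidelity"],
            train_config=TrainConfig(**man["train_config"]),
            loss_trace=list(payload.get("loss_trace", [])),
        )


def brain_feature_for(sample, world, fidelity: float | None) -> np.ndarray:
    """The sample's brain feature at the requested decoding fidelity.

    ``None`` returns the stored feature; otherwise the feature is re-simulated
    from the clean image embedding using the sample's own seed stream, so the
    same vector is produced at train and test time.
    """
    if fidelity is None:
        return sample.brain_feature
    f_o = reference_embedding(world, sample.pixels)
    # Dedicated sub-stream: independent of the draws used during generation.
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, sample.index, 7]))
    return simulate_brain_feature(f_o, fidelity, rng)


def build_training_matrices(
    train_set: Dataset,
    encoder: JointEncoder,
    aug_seed: int,
    fidelity: float | None,
    use_brain: bool = True,
):
    """Assemble (X, T, groups) for the regression: one row per augmented view.

    X rows are integrated features [f_b ; f_a] (or f_a alone when
    ``use_brain`` is False); T rows repeat the sample's clean embedding f_o.
    """
    X_rows, T_rows, groups = [], [], []
    for s in train_set.samples:
        aug = build_augmented_set(
            s.pixels, seed=int(np.random.SeedSequence([aug_seed, s.index]).generate_state(1)[0] % (2**31))
        )
        F_a = encode_augmented_set(encoder, aug)  # (D, N)
        f_o = encoder.image_encode(s.pixels)
        if use_brain:
            f_b = brain_feature_for(s, train_set.world, fidelity)
            F_i = integrate(F_a, f_b)  # (2D, N)
        else:
            F_i = F_a
        X_rows.append(F_i.T)
        T_rows.append(np.tile(f_o, (F_i.shape[1], 1)))
        groups.extend([s.index] * F_i.shape[1])
    return np.vstack(X_rows), np.vstack(T_rows), np.asarray(groups)


def train_defense(
    train_set: Dataset,
    encoder: JointEncoder,
    aug_seed: int = 0,
    fidelity: float | None = None,
    model_config: TrainConfig | None = None,
) -> DefenseModel:
    """Train g_theta on integrated (brain + augmented-view) features.

    Per sample: augmented set -> F_a -> integrate with f_b -> predict each
    column -> cosine loss against the sample's clean embedding f_o.

    When ``fidelity`` is given, the orthogonal decoding-noise component of
    every brain feature is redrawn each epoch at that fidelity (emulating
    trial-to-trial fMRI variability); this keeps the network from memorizing
    any particular noise vector and pushes it toward the generalizing
    estimator. Test-time features remain the fixed per-sample vectors. With
    ``fidelity=None`` the stored features are used unchanged throughout.
    """
    if len(train_set.samples) == 0:
        raise ValueError("training set is empty")
    cfg = model_config or TrainConfig()
    D = encoder.D
    X, T, groups = build_training_matrices(train_set, encoder, aug_seed, fidelity, use_brain=True)

    refresh = None
    if fidelity is not None:
        rho = float(fidelity)
        noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))

        def refresh(epoch, Xm, Tm):
            raw = noise_rng.standard_normal(Tm.shape)
            raw -= np.sum(raw * Tm, axis=1, keepdims=True) * Tm
            norms = np.maximum(np.linalg.norm(raw, axis=1, keepdims=True), 1e-12)
            Xm[:, :D] = rho * Tm + np.sqrt(max(1.0 - rho * rho, 0.0)) * (raw / norms)

    mlp = MLP(2 * D, HIDDEN_FACTOR * D, D, seed=cfg.seed)
    trace = mlp.fit(X, T, groups, cfg, epoch_refresh=refresh)
    return DefenseModel(mlp=mlp, D=D, uses_brain=True, fidelity=fidelity,
                        train_config=cfg, loss_trace=trace)


def defend(
    model: DefenseModel,
    encoder: JointEncoder,
    x_test: np.ndarray,
    f_b: np.ndarray,
) -> np.ndarray:
    """Test-time path: g_theta([f_b ; image_encode(x_test)]).

    No augmentation at test time — the single (possibly attacked) test image
    is encoded and stacked under the clean-derived brain feature.
    """
    if not model.uses_brain:
        raise ValueError("model was trained without brain features; pass f_a only")
    f_a = encoder.image_encode(x_test)
    f_b = np.asarray(f_b, dtype=np.float64)
    if f_b.shape != f_a.shape:
        raise ValueError(f"brain feature width {f_b.shape} != embedding width {f_a.shape}")
    return model.predict(np.concatenate([f_b, f_a]))[0]
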