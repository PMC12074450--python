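"""L-infinity gradient attacks on the image-caption cosine objective.

All three attacks minimize J(x') = cos(image_encode(x'), text_encode(caption))
within an epsilon-ball around the clean image, intersected with the [0, 1]
pixel box, and report the best (lowest-objective) iterate:

* ``pgd``  — iterated signed-gradient descent, fixed step eps/4;
* ``apgd`` — PGD with momentum 0.75 and an adaptive step-halving schedule at
  shrinking checkpoint intervals, restarting from the best iterate whenever a
  checkpoint interval brought no improvement;
* ``cw``   — the margin-loss attack family adapted to the bounded embedding
  objective: continuous (un-signed) gradient normalized to unit L-infinity per
  step, step eps/10, same projections.

Brain features are never touched by any attack: the perturbation lives purely
in pixel space, which is exactly the invariance hypothesis the defense rests
on. The module also carries the perceptibility audit (PSNR / SSIM against the
40 dB / 0.985 imperceptibility thresholds).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .encoders import JointEncoder, cosine_sim

__all__ = [
    "AttackConfig",
    "AttackResult",
    "attack",
    "psnr",
    "ssim",
    "audit_attack",
    "PSNR_THRESHOLD_DB",
    "SSIM_THRESHOLD",
]

ATTACK_NAMES = ("pgd", "apgd", "cw")

# Imperceptibility thresholds below/above which humans cannot tell images apart.
PSNR_THRESHOLD_DB = 40.0
SSIM_THRESHOLD = 0.985


@dataclass(frozen=True)
class AttackConfig:
    name: str = "pgd"
    epsilon: float = 2.0 / 255.0
    n_iter: int = 20
    step_size: float | None = None  # default: eps/4 (pgd), 2*eps (apgd), eps/10 (cw)
    seed: int = 0
    random_start: bool = False

    def __post_init__(self):
        if self.name not in ATTACK_NAMES:
            raise ValueError(f"unknown attack {self.name!r}; choose from {ATTACK_NAMES}")
        if self.epsilon < 0 or self.epsilon > 1:
            raise ValueError("epsilon must lie in [0, 1] pixel units")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.name}@{self.epsilon:.6g}"


@dataclass
class AttackResult:
    x_adv: np.ndarray
    objective_trace: list[float]
    final_cos: float
    linf: float


def _project(x: np.ndarray, x0: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(np.clip(x, x0 - eps, x0 + eps), 0.0, 1.0)


def _apgd_checkpoints(n_iter: int) -> list[int]:
    """Checkpoint iterations: p0=0, p1=0.22, p_{j+1}=p_j+max(p_j-p_{j-1}-0.03, 0.06)."""
    ps = [0.0, 0.22]
    while ps[-1] < 1.0:
        ps.append(ps[-1] + max(ps[-1] - ps[-2] - 0.03, 0.06))
    ckpts = sorted({int(math.ceil(p * n_iter)) for p in ps if 0 < p < 1.0})
    return [c for c in ckpts if c < n_iter]


def attack(
    encoder: JointEncoder,
    x: np.ndarray,
    caption: Sequence[int],
    config: AttackConfig,
) -> AttackResult:
    """Run the configured attack; always returns the best iterate found.

    With ``random_start`` off the start point is the clean image itself, so
    the reported objective can never exceed the clean objective.
    """
    t = encoder.text_encode(caption)
    x0 = np.asarray(x, dtype=np.float64)

    def J(xi: np.ndarray) -> float:
        return cosine_sim(encoder.image_encode(xi), t)

    clean_cos = J(x0)
    if config.epsilon == 0.0:
        warnings.warn("epsilon=0: attack returns the clean image unchanged")
        return AttackResult(x_adv=x0.copy(), objective_trace=[clean_cos],
                            final_cos=clean_cos, linf=0.0)

    eps = config.epsilon
    rng = np.random.default_rng(config.seed)
    if config.random_start:
        xi = _project(x0 + rng.uniform(-eps, eps, size=x0.shape), x0, eps)
    else:
        xi = x0.copy()

    trace = [J(xi)]
    best_x, best_J = xi.copy(), trace[0]
    if not config.random_start and clean_cos < best_J:
        best_x, best_J = x0.copy(), clean_cos

    if config.name == "pgd":
        alpha = config.step_size if config.step_size is not None else eps / 4.0
        for _ in range(config.n_iter):
            g = encoder.cosine_grad(xi, t)
            xi = _project(xi - alpha * np.sign(g), x0, eps)
            j = J(xi)
            trace.append(j)
            if j < best_J:
                best_x, best_J = xi.copy(), j

    elif config.name == "cw":
        alpha = config.step_size if config.step_size is not None else eps / 10.0
        for _ in range(config.n_iter):
            g = encoder.cosine_grad(xi, t)
            gmax = float(np.max(np.abs(g)))
            if gmax < 1e-18:
                break
            xi = _project(xi - alpha * (g / gmax), x0, eps)
            j = J(xi)
            trace.append(j)
            if j < best_J:
                best_x, best_J = xi.copy(), j

    elif config.name == "apgd":
        # Canonical initial step 2*eps: the first step saturates the ball and
        # the halving schedule then refines it.
        alpha = config.step_size if config.step_size is not None else 2.0 * eps
        momentum = 0.75
        ckpts = set(_apgd_checkpoints(config.n_iter))
        x_prev = xi.copy()
        best_at_last_ckpt = best_J
        alpha_at_last_ckpt = alpha
        improved_steps = 0
        interval_len = 0
        for k in range(config.n_iter):
            g = encoder.cosine_grad(xi, t)
            z = _project(xi - alpha * np.sign(g), x0, eps)
            if k == 0:
                x_next = z
            else:
                x_next = _project(
                    xi + momentum * (z - xi) + (1.0 - momentum) * (xi - x_prev), x0, eps
                )
            j_prev = trace[-1]
            j_z = J(z)  # the plain projected step is a candidate too
            if j_z < best_J:
                best_x, best_J = z.copy(), j_z
            x_prev, xi = xi, x_next
            j = J(xi)
            trace.append(min(j, j_z))
            interval_len += 1
            if j < j_prev:
                improved_steps += 1
            if j < best_J:
                best_x, best_J = xi.copy(), j
            if (k + 1) in ckpts:
                # Halve when the interval mostly failed to improve, or when
                # the step was already halved and the best stalled entirely.
                stalled = (
                    alpha == alpha_at_last_ckpt
                    and best_J >= best_at_last_ckpt - 1e-12
                )
                if improved_steps < 0.75 * interval_len or stalled:
                    alpha *= 0.5
                    xi = best_x.copy()
                    x_prev = xi.copy()
                best_at_last_ckpt = best_J
                alpha_at_last_ckpt = alpha
                improved_steps = 0
                interval_len = 0

    linf = float(np.max(np.abs(best_x - x0)))
    # best_J tracks every evaluated point (incl. the clean start), so it
    # equals the trace minimum: best-iterate monotonicity by construction.
    return AttackResult(x_adv=best_x, objective_trace=trace,
                        final_cos=float(best_J), linf=linf)


# ---------------------------------------------------------------------------
# Perceptibility audit


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 1] scale (scale-free ratio).

    Identical inputs return ``math.inf``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Mean structural similarity: 7x7 Gaussian window (sigma 1.5), K1=0.01,
    K2=0.03, computed per channel and averaged."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape[0], x.shape[1]) < 7:
        raise ValueError("image sides must be >= 7 for the 7x7 SSIM window")
    return float(
        structural_similarity(
            x, y, win_size=7, gaussian_weights=True, sigma=1.5,
            K1=0.01, K2=0.03, data_range=1.0, channel_axis=-1,
        )
    )


def audit_attack(dataset, encoder: JointEncoder, config) -> pd.DataFrame:
    """Mean PSNR/SSIM of adversarial vs clean images, with pass/fail flags.

    ``config`` may be a single AttackConfig or a sequence; one table row per
    attack configuration.
    """
    configs = [config] if isinstance(config, AttackConfig) else list(config)
    if len(dataset.samples) == 0:
        raise ValueError("cannot audit an empty dataset")
    rows = []
    for cfg in configs:
        psnrs, ssims = [], []
        for s in dataset.samples:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = attack(encoder, s.pixels, s.caption, cfg)
            psnrs.append(psnr(s.pixels, res.x_adv))
            ssims.append(ssim(s.pixels, res.x_adv))
        mean_psnr = float(np.mean(psnrs))
        mean_ssim = float(np.mean(ssims))
        rows.append(
            {
                "attack": cfg.name,
                "epsilon": cfg.epsilon,
                "mean_psnr_db": mean_psnr,
                "mean_ssim": mean_ssim,
                "psnr_pass": mean_psnr > PSNR_THRESHOLD_DB,
                "ssim_pass": mean_ssim > SSIM_THRESHOLD,
            }
        )
    df = pd.DataFrame(rows)
    df["imperceptible"] = df["psnr_pass"] & df["ssim_pass"]
    return df
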