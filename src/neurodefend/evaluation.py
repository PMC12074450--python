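"""Evaluation metrics and the experiment driver.

Four metrics summarize each (method, condition) cell:

* ``Sim_image`` — mean cosine between predicted features and the clean image
  embeddings of the test set;
* ``Sim_text``  — mean cosine between predicted features and the paired
  caption embeddings;
* ``Rank``      — mean retrieval position of the ground-truth caption among
  all S test captions (competition ranking: 1 + number of candidates with
  strictly greater similarity);
* ``Recall@k``  — fraction of samples whose ground-truth caption lands in the
  top-k (residual ties broken by ascending candidate index).

``run_experiment`` drives the whole protocol from a single config dict:
generate the world and splits, train the requested methods, attack the test
images against the encoder (the white-box threat model), and tabulate every
metric for every (method, attack, epsilon | clean) condition.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines as bl
from .attacks import AttackConfig, attack
from .defense import DefenseModel, TrainConfig, brain_feature_for, defend, train_defense
from .encoders import JointEncoder, ToyEncoder, cosine_sim
from .synthetic_world import DEFAULT_FIDELITY, make_world, sample_dataset

__all__ = [
    "RetrievalPool",
    "EvalReport",
    "sim_image",
    "sim_text",
    "rank_metric",
    "recall_at_k",
    "run_experiment",
    "render_retrieval_examples",
    "default_config",
]

METHOD_NAMES = ("clip_identity", "pm", "pm_no_fmri", "pm_noise", "rs", "rse", "at")
RECALL_KS = (1, 5, 10)


@dataclass
class RetrievalPool:
    """Candidate caption embeddings plus the ground-truth index per sample."""

    caption_embeddings: np.ndarray  # (S, D)
    gt_index: list[int]  # ground-truth candidate index for sample j

    @property
    def S(self) -> int:
        return self.caption_embeddings.shape[0]


@dataclass
class EvalReport:
    table: pd.DataFrame  # rows keyed by (method, attack, epsilon)
    S: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        df = self.table.copy()
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].map(lambda v: f"{v:.3f}")
        return df.to_string(index=False)


def _mean_cosine(predicted: Sequence[np.ndarray], targets: Sequence[np.ndarray]) -> float:
    if len(predicted) != len(targets):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(targets)}")
    if len(predicted) == 0:
        raise ValueError("need at least one sample")
    return float(np.mean([cosine_sim(p, t) for p, t in zip(predicted, targets)]))


def sim_image(predicted: Sequence[np.ndarray], originals: Sequence[np.ndarray]) -> float:
    """Mean cosine between predicted and clean image embeddings."""
    return _mean_cosine(predicted, originals)


def sim_text(predicted: Sequence[np.ndarray], caption_feats: Sequence[np.ndarray]) -> float:
    """Mean cosine between predicted and paired caption embeddings."""
    return _mean_cosine(predicted, caption_feats)


def _sims_matrix(predicted: Sequence[np.ndarray], pool: RetrievalPool) -> np.ndarray:
    P = np.stack([np.asarray(p, dtype=np.float64) for p in predicted])
    pn = np.linalg.norm(P, axis=1, keepdims=True)
    C = pool.caption_embeddings
    cn = np.linalg.norm(C, axis=1, keepdims=True)
    if np.any(pn < 1e-12) or np.any(cn < 1e-12):
        raise ValueError("zero vectors in retrieval similarity computation")
    return (P / pn) @ (C / cn).T  # (S_pred, S_pool)


def _ranks(predicted: Sequence[np.ndarray], pool: RetrievalPool) -> np.ndarray:
    if len(pool.gt_index) != len(predicted):
        raise ValueError("pool must provide exactly one ground truth per sample")
    sims = _sims_matrix(predicted, pool)
    ranks = np.empty(len(predicted))
    for j in range(len(predicted)):
        gt = pool.gt_index[j]
        ranks[j] = 1 + int(np.sum(sims[j] > sims[j, gt]))
    return ranks


def rank_metric(predicted: Sequence[np.ndarray], pool: RetrievalPool) -> float:
    """Mean competition rank of the ground-truth caption; in [1, S]."""
    return float(np.mean(_ranks(predicted, pool)))


def recall_at_k(predicted: Sequence[np.ndarray], pool: RetrievalPool, k: int) -> float:
    """Fraction of samples whose ground-truth caption is in the top-k."""
    if not (1 <= k <= pool.S):
        raise ValueError(f"k must lie in [1, {pool.S}], got {k}")
    if len(pool.gt_index) != len(predicted):
        raise ValueError("pool must provide exactly one ground truth per sample")
    sims = _sims_matrix(predicted, pool)
    hits = 0
    for j in range(len(predicted)):
        gt = pool.gt_index[j]
        greater = int(np.sum(sims[j] > sims[j, gt]))
        ties_before = int(np.sum((sims[j] == sims[j, gt]) & (np.arange(pool.S) < gt)))
        if greater + ties_before + 1 <= k:
            hits += 1
    return hits / len(predicted)


# ---------------------------------------------------------------------------
# Experiment driver


def default_config(seed: int = 0) -> dict:
    """The toy-world study conditions in one place."""
    return {
        "seed": int(seed),
        "world": {"D": 32, "H": 32, "W": 32, "vocab_size": 128},
        "data": {"n_train": 600, "n_test": 100, "fidelity": DEFAULT_FIDELITY,
                 "pixel_noise_std": 0.01},
        "methods": ["clip_identity", "pm", "pm_no_fmri", "pm_noise"],
        "attacks": [
            {"name": "pgd", "epsilons": [1 / 255, 2 / 255]},
            {"name": "apgd", "epsilons": [1 / 255, 2 / 255]},
            {"name": "cw", "epsilons": [1 / 255, 2 / 255]},
        ],
        "attack_iters": 20,
        "model": {"lr": 1e-3, "epochs": 200, "batch_size": 32},
        "recall_ks": list(RECALL_KS),
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def _attack_conditions(config: dict) -> list[AttackConfig]:
    out = []
    for a in config.get("attacks", []):
        for eps in a.get("epsilons", [2 / 255]):
            out.append(AttackConfig(name=a["name"], epsilon=float(eps),
                                    n_iter=int(config.get("attack_iters", 20))))
    return out


def _predict(method: str, models: dict, encoder: JointEncoder, world, sample,
             x_input: np.ndarray, fidelity: float | None, seed: int) -> np.ndarray:
    """Predicted feature for one test image under one method."""
    if method == "clip_identity":
        return bl.clip_identity(encoder, x_input)
    if method == "pm":
        f_b = brain_feature_for(sample, world, fidelity)
        return defend(models["pm"], encoder, x_input, f_b)
    if method == "pm_no_fmri":
        return models["pm_no_fmri"].predict(encoder.image_encode(x_input))[0]
    if method == "pm_noise":
        m = models["pm_noise"]
        f_b = bl.noise_feature_for(sample, m.noise_seed, encoder.D)
        return m.predict(np.concatenate([f_b, encoder.image_encode(x_input)]))[0]
    if method == "rs":
        return bl.randomized_smoothing(encoder, x_input, seed=seed + sample.index)
    if method == "rse":
        f_b = brain_feature_for(sample, world, fidelity)
        fi = np.concatenate([f_b, encoder.image_encode(x_input)])
        return bl.random_self_ensemble(models["pm"], fi, seed=seed + sample.index)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(config: dict) -> EvalReport:
    """Run the full protocol described by ``config`` and tabulate all metrics.

    Unknown method or attack names are rejected before any compute. Attacked
    images are generated once per condition against the encoder and shared by
    all methods (the attacker targets the backbone, not the defenses).
    """
    cfg = {**default_config(), **config}
    seed = int(cfg["seed"])
    for m in cfg["methods"]:
        if m not in METHOD_NAMES:
            raise ValueError(f"unknown method {m!r}; choose from {METHOD_NAMES}")
    attack_conditions = _attack_conditions(cfg)  # validates attack names

    world = make_world(seed, **cfg["world"])
    data_cfg = cfg["data"]
    fidelity = data_cfg.get("fidelity", DEFAULT_FIDELITY)
    train_set = sample_dataset(world, data_cfg["n_train"], "train", seed,
                               pixel_noise_std=data_cfg.get("pixel_noise_std", 0.01),
                               fidelity=fidelity)
    test_set = sample_dataset(world, data_cfg["n_test"], "test", seed,
                              pixel_noise_std=data_cfg.get("pixel_noise_std", 0.01),
                              fidelity=fidelity)
    encoder = ToyEncoder(world)
    tc = TrainConfig(seed=seed, **cfg["model"])

    # --- training phase -----------------------------------------------------
    methods = list(cfg["methods"])
    models: dict = {}
    needs_pm = any(m in ("pm", "rse") for m in methods)
    if needs_pm:
        models["pm"] = train_defense(train_set, encoder, aug_seed=seed,
                                     fidelity=fidelity, model_config=tc)
    if "pm_no_fmri" in methods:
        models["pm_no_fmri"] = bl.train_no_fmri(train_set, encoder, aug_seed=seed,
                                                model_config=tc)
    if "pm_noise" in methods:
        models["pm_noise"] = bl.train_noise_baseline(train_set, encoder, aug_seed=seed,
                                                     model_config=tc, noise_seed=seed)
    at_models: dict[str, DefenseModel] = {}
    if "at" in methods:
        for ac in attack_conditions:
            at_models[ac.label] = bl.train_adversarial(train_set, encoder, ac,
                                                       model_config=tc)

    # --- shared evaluation targets ------------------------------------------
    f_o = [encoder.image_encode(s.pixels) for s in test_set.samples]
    f_t = [encoder.text_encode(s.caption) for s in test_set.samples]
    pool = RetrievalPool(caption_embeddings=np.stack(f_t),
                         gt_index=list(range(len(test_set.samples))))
    ks = [k for k in cfg.get("recall_ks", RECALL_KS) if k <= pool.S]

    # --- conditions: clean + each attack ------------------------------------
    conditions: list[tuple[str, float | None, list[np.ndarray]]] = [
        ("clean", None, [s.pixels for s in test_set.samples])
    ]
    for ac in attack_conditions:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            advs = [attack(encoder, s.pixels, s.caption, ac).x_adv
                    for s in test_set.samples]
        conditions.append((ac.name, ac.epsilon, advs))

    rows = []
    for cond_name, eps, images in conditions:
        for method in methods:
            if method == "at":
                # "ideal": the model trained on this very attack; for the
                # clean condition, the model trained on the first attack.
                if cond_name == "clean":
                    if not at_models:
                        continue
                    model = next(iter(at_models.values()))
                else:
                    model = at_models[f"{cond_name}@{eps:.6g}"]
                predicted = [model.predict(encoder.image_encode(xi))[0] for xi in images]
            else:
                predicted = [
                    _predict(method, models, encoder, world, s, xi, fidelity, seed)
                    for s, xi in zip(test_set.samples, images)
                ]
            row = {
                "method": method,
                "attack": cond_name,
                "epsilon": np.nan if eps is None else eps,
                "sim_image": sim_image(predicted, f_o),
                "sim_text": sim_text(predicted, f_t),
                "rank": rank_metric(predicted, pool),
            }
            for k in ks:
                row[f"recall@{k}"] = recall_at_k(predicted, pool, k)
            rows.append(row)

    table = pd.DataFrame(rows)
    meta = {"seed": seed, "config_hash": _config_hash(cfg), "S": pool.S,
            "fidelity": fidelity}
    return EvalReport(table=table, S=pool.S, metadata=meta)


def render_retrieval_examples(
    predicted: Sequence[np.ndarray],
    pool: RetrievalPool,
    captions: Sequence[Sequence[int]],
    n_show: int = 5,
    top_k: int = 5,
) -> str:
    """Plain-text panel of top-k retrieved captions with ground-truth flags.

    ``captions[i]`` is the token list of candidate i in the pool. Returns one
    block per shown sample; empty string for ``n_show == 0``.
    """
    if n_show == 0:
        return ""
    sims = _sims_matrix(predicted, pool)
    lines = []
    for j in range(min(n_show, len(predicted))):
        gt = pool.gt_index[j]
        order = sorted(range(pool.S), key=lambda i: (-sims[j, i], i))[:top_k]
        lines.append(f"sample {j}  (ground truth: candidate {gt})")
        for pos, i in enumerate(order, start=1):
            flag = " <-- GT" if i == gt else ""
            toks = " ".join(str(t) for t in captions[i])
            lines.append(f"  top{pos}: cand {i:3d}  cos={sims[j, i]:+.3f}  [{toks}]{flag}")
        lines.append("")
    return "\n".join(lines)
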