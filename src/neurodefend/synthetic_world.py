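"""Synthetic paired image/caption/brain-feature world.

Generates a desk-scale stand-in for an fMRI natural-scenes dataset: each
sample couples a latent unit vector ``z`` with (a) pixels produced by a fixed
linear latent-to-pixel map, (b) a caption built from the vocabulary tokens
closest to ``z`` in the shared embedding space, and (c) a simulated
brain-decoded feature whose cosine similarity to the clean image embedding is
controlled exactly by a fidelity parameter ``rho``.

The brain feature is always derived from the *clean* image, never from a
perturbed one: this encodes the working hypothesis that imperceptible
adversarial perturbations leave brain activity — and hence decoded brain
features — unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "WorldSpec",
    "PairedSample",
    "Dataset",
    "make_world",
    "sample_dataset",
    "simulate_brain_feature",
    "reference_embedding",
    "save_dataset",
    "load_dataset",
]

# Defaults defining the study conditions of the toy world.
DEFAULT_D = 32
DEFAULT_H = 32
DEFAULT_W = 32
DEFAULT_VOCAB = 128
DEFAULT_N_TRAIN = 600  # ~9:1 train/test, mirroring the source dataset ratio
DEFAULT_N_TEST = 100
DEFAULT_CAPTION_LEN = 6
DEFAULT_PIXEL_NOISE = 0.01
DEFAULT_FIDELITY = 0.85  # "good but imperfect" brain decoding

_MAX_IDS = 10**6  # width of the zero-padded id namespace per split


def _rng_for(seed: int, index: int) -> np.random.Generator:
    """Per-sample random stream hashed from (global seed, sample index).

    Insertion order never changes draws: sample ``index`` always sees the
    same stream regardless of how many samples are generated.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _unit(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < tol:
        raise ValueError("zero-norm vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class WorldSpec:
    """Fixed generative parameters of the synthetic image/caption universe."""

    seed: int
    D: int
    H: int
    W: int
    vocab_size: int
    G: np.ndarray  # (H*W*3, D), orthonormal columns
    token_table: np.ndarray  # (vocab_size, D), unit rows
    n_train: int = DEFAULT_N_TRAIN
    n_test: int = DEFAULT_N_TEST
    caption_len: int = DEFAULT_CAPTION_LEN

    @property
    def pixel_dim(self) -> int:
        return self.H * self.W * 3

    def to_config(self) -> dict:
        """JSON-serializable config from which the world regenerates exactly."""
        return {
            "seed": self.seed,
            "D": self.D,
            "H": self.H,
            "W": self.W,
            "vocab_size": self.vocab_size,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "caption_len": self.caption_len,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "WorldSpec":
        return make_world(
            cfg["seed"],
            D=cfg.get("D", DEFAULT_D),
            H=cfg.get("H", DEFAULT_H),
            W=cfg.get("W", DEFAULT_W),
            vocab_size=cfg.get("vocab_size", DEFAULT_VOCAB),
            n_train=cfg.get("n_train", DEFAULT_N_TRAIN),
            n_test=cfg.get("n_test", DEFAULT_N_TEST),
            caption_len=cfg.get("caption_len", DEFAULT_CAPTION_LEN),
        )


@dataclass
class PairedSample:
    """One (pixels, caption, brain feature) record; the unit of all datasets."""

    id: str
    index: int
    z: np.ndarray  # latent unit vector, R^D
    pixels: np.ndarray  # H x W x 3 in [0, 1], channel-last
    caption: list[int]  # ordered token indices
    brain_feature: np.ndarray  # unit vector, R^D, derived from clean pixels


@dataclass
class Dataset:
    world: WorldSpec
    samples: list[PairedSample]
    split: str  # "train" | "test"

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


def make_world(
    seed: int,
    D: int = DEFAULT_D,
    H: int = DEFAULT_H,
    W: int = DEFAULT_W,
    vocab_size: int = DEFAULT_VOCAB,
    n_train: int = DEFAULT_N_TRAIN,
    n_test: int = DEFAULT_N_TEST,
    caption_len: int = DEFAULT_CAPTION_LEN,
) -> WorldSpec:
    """Build the fixed generative parameters of a synthetic world.

    ``G`` (latent-to-pixel map) has orthonormal columns so a linear encoder
    can invert it exactly; ``token_table`` rows are unit vectors shared by
    caption construction and text encoding.
    """
    if D < 8:
        raise ValueError(f"embedding dimension D must be >= 8, got {D}")
    if H * W * 3 < D:
        raise ValueError(f"pixel dimension {H * W * 3} must be >= D={D}")
    if vocab_size < 2 * D:
        raise ValueError(f"vocab_size must be >= 2*D={2 * D}, got {vocab_size}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    pixel_dim = H * W * 3
    # QR of a Gaussian matrix: orthonormal columns, deterministic in seed.
    M = rng.standard_normal((pixel_dim, D))
    G, R = np.linalg.qr(M)
    # Fix the sign convention so the factorization is unique.
    G = G * np.sign(np.diag(R))

    tokens = rng.standard_normal((vocab_size, D))
    tokens /= np.linalg.norm(tokens, axis=1, keepdims=True)

    return WorldSpec(
        seed=int(seed), D=D, H=H, W=W, vocab_size=vocab_size,
        G=G, token_table=tokens,
        n_train=n_train, n_test=n_test, caption_len=caption_len,
    )


def reference_embedding(world: WorldSpec, pixels: np.ndarray) -> np.ndarray:
    """The world's own embedding of an image: normalize(G^T (2x - 1)).

    Identical formula to the toy encoder; kept here so dataset generation
    does not depend on the encoder module.
    """
    u = 2.0 * np.asarray(pixels, dtype=np.float64).reshape(-1) - 1.0
    return _unit(world.G.T @ u)


def simulate_brain_feature(
    f_o: np.ndarray, fidelity: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulated fMRI-decoded feature with exact cosine ``fidelity`` to ``f_o``.

    Returns ``rho * f_o + sqrt(1 - rho^2) * u`` with ``u`` a seed-deterministic
    unit vector orthogonal to ``f_o``, so ``cos(f_b, f_o) == rho`` exactly.

    Callers must pass the CLEAN image's embedding: the simulator thereby
    encodes the invariance of brain activity to imperceptible perturbations.
    """
    f_o = np.asarray(f_o, dtype=np.float64)
    norm = float(np.linalg.norm(f_o))
    if norm < 1e-12:
        raise ValueError("brain simulation requires a nonzero clean embedding")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"f_o must be unit norm (got {norm:.6f})")
    rho = float(fidelity)
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"fidelity must lie in [0, 1], got {rho}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rho == 1.0:
        return f_o.copy()
    # Redraw in the (measure-zero) event the draw is collinear with f_o.
    while True:
        raw = rng.standard_normal(f_o.shape[0])
        raw -= (raw @ f_o) * f_o  # project out the f_o component
        if np.linalg.norm(raw) > 1e-9:
            break
    u = _unit(raw)
    f_b = rho * f_o + np.sqrt(1.0 - rho * rho) * u
    return _unit(f_b)  # numerically already unit; renormalize for safety


def _make_caption(world: WorldSpec, z: np.ndarray) -> list[int]:
    """Indices of the caption_len tokens most aligned with z, descending."""
    scores = world.token_table @ z
    order = np.argsort(-scores, kind="stable")
    return [int(t) for t in order[: world.caption_len]]


def sample_dataset(
    world: WorldSpec,
    n: int,
    split_label: str,
    seed: int,
    pixel_noise_std: float = DEFAULT_PIXEL_NOISE,
    fidelity: float = DEFAULT_FIDELITY,
) -> Dataset:
    """Draw ``n`` paired samples, deterministic in (seed, sample index).

    Each sample: ``z`` uniform on the unit sphere; pixels
    ``clamp01(0.5 + 0.5 * G z + noise)``; caption = nearest tokens to ``z``;
    brain feature simulated from the clean-pixel embedding at ``fidelity``.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if n > _MAX_IDS:
        raise ValueError(f"requested {n} samples exceeds the id space {_MAX_IDS}")

    samples: list[PairedSample] = []
    # Distinct index offsets per split keep train/test streams independent.
    offset = 0 if split_label == "train" else _MAX_IDS
    for i in range(n):
        rng = _rng_for(seed, offset + i)
        z = _unit(rng.standard_normal(world.D))
        clean = 0.5 + 0.5 * (world.G @ z).reshape(world.H, world.W, 3)
        if pixel_noise_std > 0:
            clean = clean + rng.normal(0.0, pixel_noise_std, size=clean.shape)
        pixels = np.clip(clean, 0.0, 1.0)
        caption = _make_caption(world, z)
        f_o = reference_embedding(world, pixels)
        f_b = simulate_brain_feature(f_o, fidelity, rng)
        samples.append(
            PairedSample(
                id=f"{split_label}-{i:06d}", index=offset + i,
                z=z, pixels=pixels, caption=caption, brain_feature=f_b,
            )
        )
    ids = [s.id for s in samples]
    assert len(set(ids)) == len(ids)
    return Dataset(world=world, samples=samples, split=split_label)


# ---------------------------------------------------------------------------
# Serialization: PNG images, JSON-lines captions, TSV feature tables.
# PNG quantizes pixels to 8 bits; the TSV tables are the canonical float dump.


def _features_frame(ids: Sequence[str], vectors: np.ndarray) -> pd.DataFrame:
    cols = {f"d{j}": vectors[:, j] for j in range(vectors.shape[1])}
    return pd.DataFrame({"id": list(ids), **cols})


def save_dataset(ds: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for s in ds.samples:
        arr = np.clip(np.round(s.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{s.id}.png")
    with open(out / "captions.jsonl", "w") as fh:
        for s in ds.samples:
            fh.write(json.dumps({"id": s.id, "tokens": s.caption}) + "\n")
    ids = [s.id for s in ds.samples]
    _features_frame(ids, np.stack([s.z for s in ds.samples])).to_csv(
        out / "latents.tsv", sep="\t", index=False
    )
    _features_frame(ids, np.stack([s.brain_feature for s in ds.samples])).to_csv(
        out / "brain_features.tsv", sep="\t", index=False
    )
    with open(out / "world.json", "w") as fh:
        json.dump({**ds.world.to_config(), "split": ds.split}, fh, indent=2)


def load_dataset(in_dir: str | Path) -> Dataset:
    """Reload a saved dataset (pixels carry 8-bit PNG quantization)."""
    src = Path(in_dir)
    with open(src / "world.json") as fh:
        cfg = json.load(fh)
    world = WorldSpec.from_config(cfg)
    split = cfg.get("split", "train")

    latents = pd.read_csv(src / "latents.tsv", sep="\t")
    brains = pd.read_csv(src / "brain_features.tsv", sep="\t")
    captions: dict[str, list[int]] = {}
    with open(src / "captions.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            captions[rec["id"]] = [int(t) for t in rec["tokens"]]

    dim_cols = [c for c in latents.columns if c != "id"]
    offset = 0 if split == "train" else _MAX_IDS
    samples = []
    for i, sid in enumerate(latents["id"]):
        pixels = np.asarray(Image.open(src / "images" / f"{sid}.png"), dtype=np.float64) / 255.0
        samples.append(
            PairedSample(
                id=sid, index=offset + i,
                z=latents.loc[i, dim_cols].to_numpy(dtype=np.float64),
                pixels=pixels,
                caption=captions[sid],
                brain_feature=brains.loc[i, dim_cols].to_numpy(dtype=np.float64),
            )
        )
    return Dataset(world=world, samples=samples, split=split)
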