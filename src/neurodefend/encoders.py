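"""Joint image-text encoder contract and its differentiable toy instance.

The contract mirrors a contrastively pretrained vision-language encoder pair:
images and token lists map to unit vectors in a shared D-dimensional space
where matching pairs have high cosine similarity. The toy instance is linear
(pixels recentred to [-1, 1], projected through the transpose of the world's
latent-to-pixel map, then normalized), which makes attack gradients exact
closed forms while keeping every downstream formula dimension-agnostic.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Sequence

import numpy as np

from .synthetic_world import WorldSpec

__all__ = ["JointEncoder", "ToyEncoder", "cosine_sim", "DegenerateInputError"]


class DegenerateInputError(ValueError):
    """Input maps to the zero vector and has no defined embedding."""


def cosine_sim(a: np.ndarray, b: np.ndarray) -> float:
    """Standard cosine similarity in [-1, 1]; raises on zero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


class JointEncoder(ABC):
    """Abstract joint encoder: what the defense needs from any backbone.

    Implementations must produce unit-norm embeddings, be deterministic given
    pixels, and expose the gradient of the image-caption cosine objective
    with respect to the input pixels (the quantity every gradient attack
    consumes). A real pretrained backbone can be adapted to this contract
    without touching the rest of the pipeline.
    """

    @property
    @abstractmethod
    def D(self) -> int:
        """Embedding dimension."""

    @abstractmethod
    def image_encode(self, pixels: np.ndarray) -> np.ndarray:
        """Pixels (H, W, 3) in [0,1] -> unit vector R^D."""

    @abstractmethod
    def text_encode(self, caption: Sequence[int]) -> np.ndarray:
        """Token list -> unit vector R^D."""

    @abstractmethod
    def cosine_grad(self, pixels: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Gradient of cos(image_encode(x), target) w.r.t. the pixels."""


class ToyEncoder(JointEncoder):
    """Linear desk-scale encoder bound to a WorldSpec.

    image_encode(x) = normalize(A^T (2 flatten(x) - 1)) with A = G, so on
    noise-free world pixels the latent is recovered exactly. text_encode is
    an order-free bag of token-table rows, renormalized.
    """

    def __init__(self, world: WorldSpec):
        self.world = world
        self.A = world.G  # (pixel_dim, D)

    @property
    def D(self) -> int:
        return self.world.D

    def _project(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        expected = (self.world.H, self.world.W, 3)
        if pixels.shape != expected:
            raise ValueError(f"expected pixels shaped {expected}, got {pixels.shape}")
        u = 2.0 * pixels.reshape(-1) - 1.0
        return self.A.T @ u

    def image_encode(self, pixels: np.ndarray) -> np.ndarray:
        v = self._project(pixels)
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise DegenerateInputError(
                "image projects to the zero vector (constant mid-gray input)"
            )
        return v / n

    def text_encode(self, caption: Sequence[int]) -> np.ndarray:
        caption = list(caption)
        if not caption:
            raise ValueError("caption must contain at least one token")
        table = self.world.token_table
        for t in caption:
            if not (0 <= int(t) < self.world.vocab_size):
                raise ValueError(f"token {t} outside vocabulary [0, {self.world.vocab_size})")
        s = table[np.asarray(caption, dtype=int)].sum(axis=0)
        n = float(np.linalg.norm(s))
        if n < 1e-12:
            raise DegenerateInputError("caption tokens cancel to the zero vector")
        return s / n

    def cosine_grad(self, pixels: np.ndarray, target: np.ndarray) -> np.ndarray:
        # J(x) = e(x) . t_hat with e = v/|v|, v = A^T (2x - 1):
        # dJ/dv = (t_hat - (e . t_hat) e) / |v|;  dJ/dx = 2 A dJ/dv.
        v = self._project(pixels)
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise DegenerateInputError("gradient undefined at the zero embedding")
        e = v / n
        t_hat = np.asarray(target, dtype=np.float64)
        tn = float(np.linalg.norm(t_hat))
        if tn < 1e-12:
            raise ValueError("target must be nonzero")
        t_hat = t_hat / tn
        dv = (t_hat - (e @ t_hat) * e) / n
        return (2.0 * (self.A @ dv)).reshape(self.world.H, self.world.W, 3)
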