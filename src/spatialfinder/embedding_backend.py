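"""Embedding-provider contract plus a deterministic synthetic backend.

Real vision-language encoders (frozen pathology VLMs producing 1024-dim patch
and 512-dim nucleus embeddings) plug in behind the same small surface:
``embed_images`` for pixel arrays, ``embed_text`` for prompts, and a declared
``dim``. The core package never imports model weights; the synthetic backend
lets the whole pipeline run offline.

The synthetic backend assigns each class a row of a seeded random orthonormal
basis as its prototype, embeds items as ``prototype + Gaussian noise`` and
text labels as the exact prototype, so zero-shot cosine classification is
exact at zero noise. An optional *modality gap* rotates the image centroid of
class *k* toward the prototype of class *k+1*, mimicking the image–text
misalignment of CLIP-style joint embedding spaces, where zero-shot transfer is
imperfect even on clean data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "TextEmbedding",
    "SyntheticBackend",
    "cosine_similarity",
    "embed_patches",
    "embed_text",
]


@dataclass
class EmbeddingMatrix:
    """N x D float vectors aligned to item ids (patch anchors or nucleus ids)."""

    ids: list
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be an (n_items, D) matrix aligned to ids")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class TextEmbedding:
    prompt: str
    vector: np.ndarray


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """``a.b / (|a||b|)``; raises on zero vectors or mismatched dimensions."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must share a dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def cosine_similarity_matrix(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cosine similarity of every row of ``x`` against a single vector ``v``."""
    x = np.asarray(x, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nv = np.linalg.norm(v)
    nx = np.linalg.norm(x, axis=1)
    if nv == 0 or (nx == 0).any():
        raise ValueError("cosine similarity undefined for a zero vector")
    return np.clip(x @ v / (nx * nv), -1.0, 1.0)


class SyntheticBackend:
    """Deterministic stand-in for a frozen vision-language encoder.

    Parameters
    ----------
    n_classes : number of planted classes (>= 2).
    dim : embedding dimension (>= n_classes).
    sigma : per-dimension Gaussian noise added to image embeddings.
    seed : seeds the prototype basis and all noise draws.
    class_names : optional names mapping text prompts to prototypes.
    modality_gap_deg : rotation (degrees) of each image class centroid toward
        the next class prototype; 0 means image and text spaces coincide.
    """

    def __init__(
        self,
        n_classes: int,
        dim: int,
        sigma: float = 0.0,
        seed: int = 0,
        class_names: list[str] | None = None,
        modality_gap_deg: float = 0.0,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if dim < n_classes:
            raise ValueError(f"dim {dim} < n_classes {n_classes}: prototypes cannot be orthogonal")
        self.n_classes = n_classes
        self.dim = dim
        self.sigma = float(sigma)
        self.seed = int(seed)
        self.class_names = list(class_names) if class_names else [
            f"class_{k}" for k in range(n_classes)
        ]
        if len(self.class_names) != n_classes:
            raise ValueError("class_names length must equal n_classes")
        rng = np.random.default_rng(seed)
        # rows of a random orthonormal basis (QR of a Gaussian matrix)
        q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        self.prototypes = q[:n_classes].copy()
        theta = np.deg2rad(modality_gap_deg)
        nxt = np.roll(np.arange(n_classes), -1)
        self.image_centroids = (
            np.cos(theta) * self.prototypes + np.sin(theta) * self.prototypes[nxt]
        )

    # -- class-indexed embedding (used by the synthetic slide generator) -----

    def embed_classes(self, class_idx, rng: np.random.Generator) -> np.ndarray:
        """Image embeddings for items with planted class indices."""
        class_idx = np.asarray(class_idx, dtype=int)
        vecs = self.image_centroids[class_idx]
        if self.sigma > 0:
            vecs = vecs + rng.normal(scale=self.sigma, size=(len(class_idx), self.dim))
        return vecs

    # -- pixel-array embedding (backend contract) ----------------------------

    def embed_images(self, patches) -> np.ndarray:
        """Deterministically embed pixel arrays: a patch hashes to a class.

        The same patch always maps to the same vector (frozen-extractor
        semantics); distinct pixel content spreads over the prototype set.
        """
        out = np.empty((len(patches), self.dim))
        for i, patch in enumerate(patches):
            h = zlib.crc32(np.ascontiguousarray(patch).tobytes())
            k = h % self.n_classes
            vec = self.image_centroids[k]
            if self.sigma > 0:
                rng = np.random.default_rng([self.seed, h])
                vec = vec + rng.normal(scale=self.sigma, size=self.dim)
            out[i] = vec
        return out

    def embed_text(self, prompt: str) -> np.ndarray:
        """Text prompts map to exact class prototypes (unknown prompts hash)."""
        if prompt in self.class_names:
            return self.prototypes[self.class_names.index(prompt)].copy()
        k = zlib.crc32(prompt.encode()) % self.n_classes
        return self.prototypes[k].copy()


def embed_patches(patches, backend, ids=None) -> EmbeddingMatrix:
    """Embed retained patches through a backend; validates shape and finiteness."""
    vectors = np.asarray(backend.embed_images(patches), dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != backend.dim:
        raise ValueError(
            f"backend returned shape {vectors.shape}, expected (n, {backend.dim})"
        )
    if ids is None:
        ids = list(range(len(patches)))
    return EmbeddingMatrix(ids=list(ids), vectors=vectors)


def embed_text(prompt: str, backend) -> TextEmbedding:
    if not prompt:
        raise ValueError("text prompt must be non-empty")
    vec = np.asarray(backend.embed_text(prompt), dtype=np.float64)
    if vec.shape != (backend.dim,):
        raise ValueError(f"backend returned shape {vec.shape}, expected ({backend.dim},)")
    if not np.isfinite(vec).all():
        raise ValueError("text embedding contains non-finite entries")
    return TextEmbedding(prompt=prompt, vector=vec)
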