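"""Patch-based transformer feature extraction.

The contract: a 224x224x3 image goes in, a 14x14x768 spatial feature map
comes out.  The image is cut into 196 non-overlapping 16x16 patches
(row-major), each flattened to a 768-long raw vector, linearly embedded,
summed with position embeddings and passed through a stack of pre-norm
transformer encoder blocks (multi-head self-attention + MLP, residual
connections, layer normalisation).  The final token sequence is reshaped
row-major back to the 14x14 grid; no class token is used.

Two weight sources satisfy the contract:

``seeded-test``
    A compact, randomly initialised encoder (default depth 2) whose weights
    are a pure function of ``BackboneSpec.seed``.  It is a real encoder —
    attention mixes patches, position embeddings make it
    permutation-sensitive — sized to run whole datasets on one CPU.  It is
    never trained; it acts as a fixed nonlinear feature bank.

``pretrained-adapter``
    Hook for loading released ViT-B/16 weights (depth 12) through an
    external loader.  Registering a loader is the integrator's job; calling
    it without one raises.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy.special import erf

__all__ = [
    "BackboneSpec",
    "TestBackbone",
    "patchify",
    "unpatchify",
    "normalize_image",
    "extract_features",
    "extract_features_batch",
    "get_backbone",
    "register_pretrained_loader",
]

#: Per-channel normalisation: uint8 [0, 255] -> [-1, 1].
NORM_CENTER = 127.5
NORM_SCALE = 127.5


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    """Geometry and provenance of the feature extractor.

    ``grid = image_size / patch_size`` tokens per side; with the defaults,
    196 patches of 16x16x3 = 768 raw values each, embedded at width 768.
    """

    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 4
    mlp_ratio: float = 2.0
    image_size: int = 224
    weights_source: str = "pretrained-adapter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.weights_source not in ("pretrained-adapter", "seeded-test"):
            raise ValueError(f"unknown weights source {self.weights_source!r}")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid**2

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3

    @staticmethod
    def for_testing(seed: int = 0, depth: int = 2) -> "BackboneSpec":
        """The seeded CPU-sized backbone used throughout the test pipeline."""
        return BackboneSpec(depth=depth, weights_source="seeded-test", seed=seed)


def patchify(img: np.ndarray, patch_size: int = 16) -> np.ndarray:
    """Cut an HxWx3 image into flattened non-overlapping patches, row-major.

    Returns an ``(n_patches, patch_size*patch_size*3)`` array; concatenating
    the patches back (:func:`unpatchify`) reconstructs the image exactly.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got {img.shape}")
    h, w, _ = img.shape
    if h % patch_size or w % patch_size:
        raise ValueError(f"image {h}x{w} not divisible by patch size {patch_size}")
    gh, gw = h // patch_size, w // patch_size
    patches = (
        img.reshape(gh, patch_size, gw, patch_size, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(gh * gw, patch_size * patch_size * 3)
    )
    return patches


def unpatchify(patches: np.ndarray, image_size: int, patch_size: int = 16) -> np.ndarray:
    """Inverse of :func:`patchify` for square images."""
    g = image_size // patch_size
    return (
        np.asarray(patches)
        .reshape(g, g, patch_size, patch_size, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(image_size, image_size, 3)
    )


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Map uint8 intensities to [-1, 1] (identical for all triplet members)."""
    return (np.asarray(img, dtype=np.float32) - NORM_CENTER) / NORM_SCALE


_INV_SQRT2 = float(1.0 / np.sqrt(2.0))


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def _layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mean) / np.sqrt(var + 1e-6) * gamma + beta


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TestBackbone:
    """Seeded random transformer encoder implementing the feature contract.

    All weights are drawn once from ``numpy.random.default_rng(spec.seed)``,
    so two instances with the same spec are bit-identical.  Forward passes
    run in float32.
    """

    def __init__(self, spec: BackboneSpec):
        if spec.weights_source != "seeded-test":
            raise ValueError("TestBackbone requires a 'seeded-test' spec")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d = spec.embed_dim
        hidden = int(round(d * spec.mlp_ratio))
        scale = 0.05

        def w(*shape):
            return rng.normal(0.0, scale, size=shape).astype(np.float32)

        # The patch embedding is initialised an order of magnitude larger
        # than the mixing blocks: the LayerNorms inside each block decouple
        # block-output magnitude from the embedding scale, so this keeps the
        # linear image statistics (the part a GAP probe can read) from being
        # drowned by random nonlinear mixing, while attention and position
        # embeddings still make the output pattern- and order-sensitive.
        self.patch_w = rng.normal(0.0, 1.0, size=(spec.patch_dim, d)).astype(np.float32)
        self.patch_b = w(d)
        self.pos = rng.normal(0.0, 0.5, size=(spec.n_patches, d)).astype(np.float32)
        self.blocks = []
        for _ in range(spec.depth):
            self.blocks.append(
                {
                    "ln1_g": np.ones(d, dtype=np.float32),
                    "ln1_b": np.zeros(d, dtype=np.float32),
                    "qkv_w": w(d, 3 * d),
                    "qkv_b": w(3 * d),
                    "proj_w": w(d, d),
                    "proj_b": w(d),
                    "ln2_g": np.ones(d, dtype=np.float32),
                    "ln2_b": np.zeros(d, dtype=np.float32),
                    "mlp_w1": w(d, hidden),
                    "mlp_b1": w(hidden),
                    "mlp_w2": w(hidden, d),
                    "mlp_b2": w(d),
                }
            )
        self.final_g = np.ones(d, dtype=np.float32)
        self.final_b = np.zeros(d, dtype=np.float32)

    def _attention(self, x: np.ndarray, blk: dict) -> np.ndarray:
        b, n, d = x.shape
        h = self.spec.n_heads
        dh = d // h
        qkv = x @ blk["qkv_w"] + blk["qkv_b"]  # (b, n, 3d)
        qkv = qkv.reshape(b, n, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, b, h, n, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = _softmax((q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dh)))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return out @ blk["proj_w"] + blk["proj_b"]

    def forward_tokens(self, patches: np.ndarray) -> np.ndarray:
        """Token sequences -> encoded token sequences.

        ``patches``: (batch, n_patches, patch_dim) float32.
        """
        x = patches.astype(np.float32) @ self.patch_w + self.patch_b + self.pos
        for blk in self.blocks:
            x = x + self._attention(_layer_norm(x, blk["ln1_g"], blk["ln1_b"]), blk)
            y = _layer_norm(x, blk["ln2_g"], blk["ln2_b"])
            y = _gelu(y @ blk["mlp_w1"] + blk["mlp_b1"]) @ blk["mlp_w2"] + blk["mlp_b2"]
            x = x + y
        # No final LayerNorm: the residual stream keeps the input's intensity
        # scale, which downstream linear probes rely on.
        return x

    def __call__(self, imgs: np.ndarray) -> np.ndarray:
        """Batch of (B, S, S, 3) uint8 images -> (B, grid, grid, embed_dim)."""
        spec = self.spec
        imgs = np.asarray(imgs)
        if imgs.ndim == 3:
            imgs = imgs[None]
        if imgs.shape[1:] != (spec.image_size, spec.image_size, 3):
            raise ValueError(
                f"expected (B, {spec.image_size}, {spec.image_size}, 3), got {imgs.shape}"
            )
        patches = np.stack([patchify(normalize_image(im), spec.patch_size) for im in imgs])
        tokens = self.forward_tokens(patches)
        g = spec.grid
        return tokens.reshape(len(imgs), g, g, spec.embed_dim)


_PRETRAINED_LOADER: Callable[[BackboneSpec], object] | None = None


def register_pretrained_loader(loader: Callable[[BackboneSpec], object]) -> None:
    """Register a callable that builds a pretrained ViT-B/16 feature extractor.

    The callable receives the spec and must return an object with the same
    ``__call__`` signature as :class:`TestBackbone`.
    """
    global _PRETRAINED_LOADER
    _PRETRAINED_LOADER = loader


def get_backbone(spec: BackboneSpec):
    """Instantiate the feature extractor named by ``spec.weights_source``."""
    if spec.weights_source == "seeded-test":
        return TestBackbone(spec)
    if _PRETRAINED_LOADER is None:
        raise RuntimeError(
            "no pretrained-weights loader registered; call "
            "register_pretrained_loader() or use BackboneSpec.for_testing()"
        )
    return _PRETRAINED_LOADER(spec)


def extract_features(img: np.ndarray, backbone) -> np.ndarray:
    """One 224x224x3 image -> one (14, 14, 768) feature map."""
    return extract_features_batch(np.asarray(img)[None], backbone)[0]


def extract_features_batch(
    imgs: np.ndarray, backbone, chunk_size: int = 32
) -> np.ndarray:
    """Batch feature extraction in memory-bounded chunks."""
    if isinstance(backbone, BackboneSpec):
        backbone = get_backbone(backbone)
    imgs = np.asarray(imgs)
    outs = [backbone(imgs[i : i + chunk_size]) for i in range(0, len(imgs), chunk_size)]
    return np.concatenate(outs, axis=0)
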