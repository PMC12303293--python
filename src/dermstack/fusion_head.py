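"""Multiplicative feature fusion and the image-branch prediction head.

Three 14x14x768 feature maps come out of the backbone, one per triplet
member.  The original map is multiplied element-wise with the black-hat map
and with the adaptive map — the products emphasise channels that respond in
both the original image and the enhanced representation (dark contours,
thresholded structures) — and the three maps are concatenated along the
width axis into a 14x42x768 fused map:

    M_bh = F_orig * F_bh
    M_ad = F_orig * F_ad
    F_fused = concat_x(F_orig, M_bh, M_ad)

The head is global average pooling over the 14x42 spatial grid followed by
one dense layer and a softmax over the six classes, trained with a
categorical focal loss and inverse-frequency class weights.  Because the
concatenation is along a spatial axis of equal-sized maps, GAP of the fused
map is exactly the arithmetic mean of the three branch GAPs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "HeadConfig",
    "ImageHead",
    "multiply_features",
    "concat_features",
    "fuse_triplet_features",
    "global_average_pool",
    "softmax",
    "dense_softmax",
    "focal_loss",
    "compute_class_weights",
    "fit_image_head",
]

N_CLASSES = 6

#: Probabilities are clipped at this epsilon inside the focal loss.
LOSS_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class HeadConfig:
    """Training configuration for the image head.

    ``gamma`` and ``alpha`` are the focal-loss focusing exponent and balance
    factor; class weights (if None) are computed from the training labels as
    ``N / (K * n_c)``.  Optimisation is full-batch gradient descent with
    momentum, deterministic given ``seed``.
    """

    gamma: float = 2.0
    alpha: float = 0.25
    class_weights: tuple[float, ...] | None = None
    epochs: int = 300
    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.class_weights is not None:
            if len(self.class_weights) != N_CLASSES:
                raise ValueError("class_weights must have 6 entries")
            if any(w <= 0 for w in self.class_weights):
                raise ValueError("class weights must be positive")


def multiply_features(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Element-wise product of two feature maps of identical shape."""
    fa, fb = np.asarray(fa), np.asarray(fb)
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    return fa * fb


def concat_features(
    f: np.ndarray, m_bh: np.ndarray, m_ad: np.ndarray
) -> np.ndarray:
    """Concatenate (original, black-hat product, adaptive product) along x.

    Three (g, g, d) maps -> one (g, 3g, d) map; slicing columns recovers the
    inputs exactly.
    """
    f, m_bh, m_ad = np.asarray(f), np.asarray(m_bh), np.asarray(m_ad)
    if not (f.shape == m_bh.shape == m_ad.shape):
        raise ValueError(
            f"shape mismatch: {f.shape}, {m_bh.shape}, {m_ad.shape}"
        )
    return np.concatenate([f, m_bh, m_ad], axis=1)


def fuse_triplet_features(
    f_orig: np.ndarray, f_bh: np.ndarray, f_ad: np.ndarray
) -> np.ndarray:
    """Full fusion: multiply enhanced maps into the original, concatenate."""
    return concat_features(
        f_orig,
        multiply_features(f_orig, f_bh),
        multiply_features(f_orig, f_ad),
    )


def global_average_pool(fmap: np.ndarray) -> np.ndarray:
    """Per-channel mean over all spatial positions: (h, w, d) -> (d,)."""
    fmap = np.asarray(fmap)
    if fmap.ndim != 3:
        raise ValueError(f"expected (h, w, channels), got {fmap.shape}")
    if not np.all(np.isfinite(fmap)):
        raise ValueError("feature map contains non-finite values")
    return fmap.mean(axis=(0, 1))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dense_softmax(v: np.ndarray, weights: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """One dense layer plus softmax: ``softmax(v @ W + b)``."""
    w, b = weights
    return softmax(np.asarray(v, dtype=np.float64) @ w + b)


def focal_loss(
    p: np.ndarray,
    y: int,
    cfg: HeadConfig | None = None,
    weight: float = 1.0,
) -> float:
    """Categorical focal loss of one prediction.

    ``-alpha * weight * (1 - p_y)**gamma * log(p_y)``; reduces to weighted
    cross-entropy at ``gamma = 0``.  ``p_y`` is clipped at ``LOSS_EPS``.
    """
    if cfg is None:
        cfg = HeadConfig()
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or not np.all(p >= -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector")
    py = float(np.clip(p[int(y)], LOSS_EPS, 1.0))
    return float(-cfg.alpha * weight * (1.0 - py) ** cfg.gamma * np.log(py))


def compute_class_weights(labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse-frequency weights ``w_c = N / (K * n_c)``.

    Balanced labels give all-ones; every class must be present.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes)
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes absent from labels: {missing}")
    return len(labels) / (n_classes * counts.astype(np.float64))


def _as_gap_matrix(features) -> np.ndarray:
    """Accept fused maps (n, h, w, d) / list of maps, or GAP vectors (n, d)."""
    if isinstance(features, (list, tuple)):
        features = np.stack([np.asarray(f) for f in features])
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 4:
        return features.mean(axis=(1, 2))
    if features.ndim == 2:
        return features
    raise ValueError(f"expected (n, h, w, d) maps or (n, d) vectors, got {features.shape}")


class ImageHead:
    """GAP -> dense -> softmax classifier over fused feature maps.

    Inputs are standardised with the training mean/std; weights live in
    ``self.w`` (d x 6) and ``self.b`` (6,).
    """

    def __init__(self, w: np.ndarray, b: np.ndarray, mean: np.ndarray, std: np.ndarray,
                 cfg: HeadConfig):
        self.w, self.b, self.mean, self.std, self.cfg = w, b, mean, std, cfg

    def predict_proba(self, features) -> np.ndarray:
        """(n, 6) class probabilities, each row summing to 1."""
        x = (_as_gap_matrix(features) - self.mean) / self.std
        return softmax(x @ self.w + self.b)

    def predict(self, features) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)


def _focal_grad(p: np.ndarray, onehot: np.ndarray, py: np.ndarray,
                gamma: float, alpha: float, weights: np.ndarray) -> np.ndarray:
    """Gradient of the mean focal loss w.r.t. the logits.

    With g(q) = -(1-q)^gamma log(q) and dq/dz_k = p_y (1[k=y] - p_k),
    dL/dz = alpha * w * g'(p_y) * p_y * (onehot - p), where
    g'(q) = gamma (1-q)^(gamma-1) log q - (1-q)^gamma / q.  At gamma = 0 this
    collapses to the cross-entropy gradient alpha * w * (p - onehot).
    """
    q = np.clip(py, LOSS_EPS, 1.0 - LOSS_EPS)
    gprime = gamma * (1.0 - q) ** np.maximum(gamma - 1.0, 0.0) * np.log(q) \
        - (1.0 - q) ** gamma / q
    coeff = alpha * weights * gprime * q  # (n,)
    return coeff[:, None] * (onehot - p) / len(p)


def fit_image_head(features, labels, cfg: HeadConfig | None = None) -> ImageHead:
    """Train the dense-softmax head with focal loss and class weights.

    Full-batch gradient descent with momentum; all randomness (the weight
    initialisation) flows from ``cfg.seed``, so identical inputs and config
    give bit-identical heads.
    """
    if cfg is None:
        cfg = HeadConfig()
    x = _as_gap_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(x) == 0:
        raise ValueError("no training samples")
    if len(x) != len(y):
        raise ValueError("features and labels length mismatch")

    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), 1e-8)
    xs = (x - mean) / std

    if cfg.class_weights is not None:
        cw = np.asarray(cfg.class_weights, dtype=np.float64)
    else:
        cw = compute_class_weights(y)
    sample_w = cw[y]

    rng = np.random.default_rng(cfg.seed)
    d = xs.shape[1]
    w = rng.normal(0.0, 0.01, size=(d, N_CLASSES))
    b = np.zeros(N_CLASSES)
    onehot = np.eye(N_CLASSES)[y]
    vel_w = np.zeros_like(w)
    vel_b = np.zeros_like(b)

    for _ in range(cfg.epochs):
        p = softmax(xs @ w + b)
        py = p[np.arange(len(y)), y]
        gz = _focal_grad(p, onehot, py, cfg.gamma, cfg.alpha, sample_w)
        gw = xs.T @ gz + cfg.weight_decay * w
        gb = gz.sum(axis=0)
        vel_w = cfg.momentum * vel_w - cfg.learning_rate * gw
        vel_b = cfg.momentum * vel_b - cfg.learning_rate * gb
        w = w + vel_w
        b = b + vel_b

    return ImageHead(w=w, b=b, mean=mean, std=std, cfg=cfg)
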