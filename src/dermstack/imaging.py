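"""Deterministic preprocessing of smartphone lesion photographs.

The enhancement pipeline turns one RGB photograph into the triplet of
representations consumed by the feature extractor:

    resize (224x224) -> grayscale -> +-- morphological closing -> black-hat
                                     +-- Gaussian blur -> adaptive threshold

The black-hat transform (closing minus original) highlights dark, thin
structures — hairs, pigment network, dark borders — that are smaller than
the structuring element.  Adaptive Gaussian thresholding binarises the image
against a local Gaussian-weighted mean minus a constant ``C``, which is
robust to the uneven illumination typical of hand-held phone captures.

Conventions fixed here so that results are bit-reproducible:

* grayscale uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114), rounded
  half up;
* morphology and blur reflect the image at its borders (symmetric padding);
* the threshold comparison is strict (``pixel > local_mean - C`` is white,
  ties go to black);
* resize uses area (box) interpolation when shrinking and bilinear when
  enlarging.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.morphology import ellipse as _sk_ellipse

__all__ = [
    "CLASS_NAMES",
    "LUMA_WEIGHTS",
    "StructuringElement",
    "ThresholdConfig",
    "EnhancedTriplet",
    "encode_class",
    "decode_class",
    "to_grayscale",
    "morph_close",
    "black_hat",
    "gaussian_blur",
    "adaptive_threshold",
    "resize",
    "replicate_channels",
    "enhance_triplet",
    "load_image",
    "save_image",
]

#: Diagnostic classes in code order (code = index).
CLASS_NAMES = ("ACK", "BCC", "MEL", "NEV", "SCC", "SEK")
_NAME_TO_CODE = {name: code for code, name in enumerate(CLASS_NAMES)}

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Side length of the working resolution.
IMAGE_SIDE = 224

#: Gaussian truncation used by :func:`gaussian_blur`, in standard deviations.
BLUR_TRUNCATE = 4.0

#: Tolerance for the strict threshold comparison: exact ties go to black.
TIE_EPS = 1e-9


def encode_class(name: str) -> int:
    """Map a diagnostic class name (case-insensitive) to its integer code.

    ACK->0, BCC->1, MEL->2, NEV->3, SCC->4, SEK->5.
    """
    code = _NAME_TO_CODE.get(str(name).strip().upper())
    if code is None:
        raise ValueError(
            f"unknown diagnostic class {name!r}; expected one of {CLASS_NAMES}"
        )
    return code


def decode_class(code: int) -> str:
    """Inverse of :func:`encode_class`."""
    code = int(code)
    if not 0 <= code < len(CLASS_NAMES):
        raise ValueError(f"class code {code} out of range 0..5")
    return CLASS_NAMES[code]


@dataclasses.dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element for grayscale morphology.

    Parameters
    ----------
    shape
        One of ``"rectangle"``, ``"ellipse"``, ``"cross"``.
    size
        Odd ``(height, width)``, both >= 3.
    """

    shape: str = "ellipse"
    size: tuple[int, int] = (9, 9)

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse", "cross"):
            raise ValueError(f"unknown structuring-element shape {self.shape!r}")
        h, w = self.size
        for s in (h, w):
            if s < 3 or s % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 3, got {self.size}")

    def footprint(self) -> np.ndarray:
        """Boolean neighbourhood mask of shape ``size``."""
        h, w = self.size
        if self.shape == "rectangle":
            return np.ones((h, w), dtype=bool)
        if self.shape == "ellipse":
            return _sk_ellipse(h // 2, w // 2).astype(bool)
        fp = np.zeros((h, w), dtype=bool)  # cross
        fp[h // 2, :] = True
        fp[:, w // 2] = True
        return fp


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of adaptive Gaussian thresholding.

    ``window`` is the odd side of the local neighbourhood, ``C`` the constant
    subtracted from the local weighted mean, ``sigma`` the standard deviation
    of the noise-reduction blur applied *before* thresholding.
    """

    window: int = 21
    C: float = 5.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if not np.isfinite(self.C):
            raise ValueError("C must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclasses.dataclass(frozen=True)
class EnhancedTriplet:
    """The three 224x224x3 representations fed to the backbone."""

    original: np.ndarray
    blackhat: np.ndarray
    adaptive: np.ndarray

    def __post_init__(self) -> None:
        for member in (self.original, self.blackhat, self.adaptive):
            if member.shape != (IMAGE_SIDE, IMAGE_SIDE, 3):
                raise ValueError(
                    f"triplet members must be {(IMAGE_SIDE, IMAGE_SIDE, 3)}, "
                    f"got {member.shape}"
                )

    def members(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.original, self.blackhat, self.adaptive


def _require_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    return img


def _require_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel HxW image, got shape {img.shape}")
    return img


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion, rounded half up to uint8."""
    img = _require_rgb(img)
    luma = np.asarray(img, dtype=np.float64) @ np.asarray(LUMA_WEIGHTS)
    return np.clip(_round_half_up(luma), 0, 255).astype(np.uint8)


def _check_kernel_fits(img: np.ndarray, k: StructuringElement) -> None:
    h, w = k.size
    if h > img.shape[0] or w > img.shape[1]:
        raise ValueError(
            f"structuring element {k.size} does not fit in image {img.shape}"
        )


def morph_close(img: np.ndarray, k: StructuringElement | None = None) -> np.ndarray:
    """Grayscale closing (dilation then erosion) with reflected borders.

    Closing is extensive (output >= input everywhere) and idempotent; it
    fills dark gaps narrower than the structuring element.
    """
    if k is None:
        k = StructuringElement()
    img = _require_gray(img)
    _check_kernel_fits(img, k)
    fp = k.footprint()
    dilated = ndimage.grey_dilation(img, footprint=fp, mode="reflect")
    return ndimage.grey_erosion(dilated, footprint=fp, mode="reflect")


def black_hat(img: np.ndarray, k: StructuringElement | None = None) -> np.ndarray:
    """Black-hat transform: ``closing(img) - img``.

    Non-negative by extensivity of closing; bright responses mark dark
    structures (hairs, dark spots, lesion borders) smaller than the kernel.
    """
    img = _require_gray(img)
    closed = morph_close(img, k)
    return (closed.astype(np.int16) - img.astype(np.int16)).astype(np.uint8)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a sampled, normalised kernel.

    The kernel is truncated at ``BLUR_TRUNCATE`` standard deviations and the
    image is reflected at its borders.  Returns float64 so that downstream
    thresholding keeps full precision.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = _require_gray(img)
    return ndimage.gaussian_filter(
        np.asarray(img, dtype=np.float64),
        sigma=sigma,
        mode="reflect",
        truncate=BLUR_TRUNCATE,
    )


def threshold_weight_sigma(window: int) -> float:
    """Standard deviation of the Gaussian window weights for a given window.

    Uses the conventional size-to-sigma rule ``0.3 * ((window - 1)/2 - 1) + 0.8``
    so that the weights taper to near zero at the window edge.
    """
    return 0.3 * ((window - 1) * 0.5 - 1.0) + 0.8


def threshold_window_weights(window: int) -> np.ndarray:
    """Normalised 2-D Gaussian weights over the ``window x window`` region."""
    sigma = threshold_weight_sigma(window)
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def adaptive_threshold(img: np.ndarray, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Binarise against the local Gaussian-weighted mean minus ``C``.

    A pixel is white (255) iff its intensity strictly exceeds the weighted
    mean of its ``window x window`` neighbourhood minus ``C``; ties go to
    black, with a 1e-9 tolerance absorbing round-off in the weighted mean so
    an exact tie (e.g. a constant image at C = 0) is classified black
    regardless of summation order.  Borders are reflected.  Blurring is a
    separate, prior step (:func:`gaussian_blur`).
    """
    if cfg is None:
        cfg = ThresholdConfig()
    img = _require_gray(img)
    values = np.asarray(img, dtype=np.float64)
    local_mean = ndimage.correlate(
        values, threshold_window_weights(cfg.window), mode="reflect"
    )
    out = np.where(values - (local_mean - cfg.C) > TIE_EPS, 255, 0).astype(np.uint8)
    return out


def resize(img: np.ndarray, target: tuple[int, int] = (IMAGE_SIDE, IMAGE_SIDE)) -> np.ndarray:
    """Resize to ``target`` (height, width), keeping 3 channels.

    Area (box) interpolation when both dimensions shrink — so downscaling by
    an integer factor is an exact block mean — and bilinear otherwise.
    Channels are resampled in float and rounded half up back to uint8.
    """
    img = _require_rgb(img)
    if img.size == 0:
        raise ValueError("empty image")
    th, tw = target
    if (img.shape[0], img.shape[1]) == (th, tw):
        return np.array(img, dtype=np.uint8, copy=True)
    shrinking = th <= img.shape[0] and tw <= img.shape[1]
    method = Image.Resampling.BOX if shrinking else Image.Resampling.BILINEAR
    channels = []
    for c in range(3):
        plane = Image.fromarray(np.asarray(img[:, :, c], dtype=np.float32), mode="F")
        channels.append(np.asarray(plane.resize((tw, th), resample=method)))
    out = np.stack(channels, axis=-1)
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def replicate_channels(gray: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image across 3 channels."""
    gray = _require_gray(gray)
    return np.repeat(gray[:, :, None], 3, axis=2)


def enhance_triplet(
    img: np.ndarray,
    k: StructuringElement | None = None,
    cfg: ThresholdConfig | None = None,
) -> EnhancedTriplet:
    """Build the (original, black-hat, adaptive) triplet at 224x224x3.

    The single-channel black-hat and binary adaptive results are replicated
    across three channels so all members share the backbone input geometry.
    """
    if k is None:
        k = StructuringElement()
    if cfg is None:
        cfg = ThresholdConfig()
    original = resize(_require_rgb(img))
    gray = to_grayscale(original)
    bh = black_hat(gray, k)
    blurred = gaussian_blur(gray, cfg.sigma)
    ad = adaptive_threshold(blurred, cfg)
    return EnhancedTriplet(
        original=original,
        blackhat=replicate_channels(bh),
        adaptive=replicate_channels(ad),
    )


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an HxWx3 or HxW uint8 array as PNG."""
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)
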