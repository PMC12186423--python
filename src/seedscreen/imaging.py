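"""Raster-image primitives.

Images are plain numpy arrays: a grayscale frame is a 2-D ``uint8`` array in
[0, 255], an RGB frame is ``(H, W, 3) uint8``.  All conversions between the
two are explicit.  These are the preprocessing steps shared by both imaging
modes: grayscale conversion, contrast inversion for brightfield frames,
scale-bar removal, fixed and automatic (Otsu) intensity thresholding, and
sRGB → CIELAB conversion for the colorimetric mode.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure

from .errors import ConstantImageError, ParameterError

log = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for RGB → grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class LabPlanes(NamedTuple):
    """CIELAB planes of an RGB image (D65 white point).

    ``L`` is lightness in [0, 100]; ``a`` is the green–red axis; ``b`` is the
    blue–yellow axis (yellow seeds high, red seeds low).
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as uint8.

    16-bit inputs are linearly rescaled to 0–255 (with a logged warning);
    an alpha channel, if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit input rescaled to 0-255", path)
        arr = np.rint(arr / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.rint(np.clip(arr, 0, 255)).astype(np.uint8)
    if arr.ndim not in (2, 3):
        raise ParameterError(f"unsupported image shape {arr.shape} in {path}")
    return arr


def is_rgb(img: np.ndarray) -> bool:
    return img.ndim == 3 and img.shape[-1] == 3


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion; a grayscale input is returned unchanged."""
    if not is_rgb(img):
        if img.ndim != 2:
            raise ParameterError(f"expected a 2-D or (H, W, 3) image, got {img.shape}")
        return img
    w = np.asarray(GRAY_WEIGHTS)
    lum = img.astype(np.float64) @ w
    return np.rint(lum).astype(np.uint8)


def invert(img: np.ndarray) -> np.ndarray:
    """Map every pixel v to 255 - v (brightfield seeds become bright)."""
    if img.ndim != 2:
        raise ParameterError("invert expects a grayscale image")
    return (255 - img.astype(np.int16)).astype(np.uint8)


def modal_intensity(img: np.ndarray) -> int:
    """Most frequent intensity; the weigh-boat background dominates it."""
    return int(np.bincount(img.ravel(), minlength=256).argmax())


def remove_scale_bar(
    img: np.ndarray,
    exclusion_rect: tuple[int, int, int, int] | None = None,
    *,
    min_aspect: float = 8.0,
    min_extent: float = 0.95,
) -> np.ndarray:
    """Blank out a scale bar so it cannot masquerade as seeds.

    With ``exclusion_rect = (row, col, height, width)`` exactly that window is
    filled with the image's modal intensity.  Without it, bright connected
    components that touch the image border, are long and thin
    (bounding-box aspect ratio > ``min_aspect``) and nearly solid
    (fill fraction > ``min_extent``) are erased — bars are long, thin, solid
    and border-adjacent; seeds are none of these.  If nothing qualifies the
    image is returned unchanged.
    """
    if img.ndim != 2:
        raise ParameterError("remove_scale_bar expects a grayscale image")
    out = img.copy()
    fill = modal_intensity(img)
    if exclusion_rect is not None:
        r, c, h, w = exclusion_rect
        out[r : r + h, c : c + w] = fill
        return out
    try:
        thr = auto_threshold(img)
    except ConstantImageError:
        return out
    mask = img > thr
    labels = _skmeasure.label(mask, connectivity=2)
    H, W = img.shape
    for prop in _skmeasure.regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == H or c1 == W
        h, w = r1 - r0, c1 - c0
        aspect = max(h, w) / min(h, w)
        if touches and aspect > min_aspect and prop.extent > min_extent:
            out[labels == prop.label] = fill
            log.info("removed bar-like component (bbox %s, aspect %.1f)", prop.bbox, aspect)
    return out


def binarize(img: np.ndarray, intensity_threshold: float) -> np.ndarray:
    """Foreground = pixels strictly brighter than the threshold.

    The strict comparison makes the foreground monotone non-increasing in the
    threshold, with threshold 255 giving an empty mask.
    """
    if img.ndim != 2:
        raise ParameterError("binarize expects a grayscale image")
    if not 0.0 <= float(intensity_threshold) <= 255.0:
        raise ParameterError(
            f"intensity threshold {intensity_threshold!r} outside [0, 255]"
        )
    return img > intensity_threshold


def _otsu_index(hist: np.ndarray, centers: np.ndarray) -> tuple[int, float]:
    """Best split index and separability for a histogram.

    Returns ``(k, eta)`` where class 0 is bins ``<= k``, and ``eta`` is the
    between-class fraction of the total variance (1 = perfectly separable).
    Ties are broken toward the lowest index.
    """
    hist = hist.astype(np.float64)
    total = hist.sum()
    if total == 0:
        raise ConstantImageError("empty histogram")
    p = hist / total
    mu = centers
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * mu)
    m_tot = m0[-1]
    w1 = 1.0 - w0
    # between-class variance for every cut k (class0 = bins <= k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (m_tot - m0) / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    k = int(np.argmax(sigma_b))
    var_tot = float(np.sum(p * (mu - m_tot) ** 2))
    if var_tot <= 0 or sigma_b[k] <= 0:
        raise ConstantImageError("histogram has no separable classes")
    return k, float(sigma_b[k] / var_tot)


def auto_threshold(img: np.ndarray) -> float:
    """Otsu threshold of an 8-bit grayscale image.

    Maximises the between-class variance over the 256 integer candidate
    thresholds; intended to be combined with :func:`binarize`'s strict ``>``
    comparison.  Raises :class:`ConstantImageError` on a constant image.
    """
    if img.ndim != 2:
        raise ParameterError("auto_threshold expects a grayscale image")
    hist = np.bincount(img.ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise ConstantImageError("constant image: no separable intensity classes")
    k, _ = _otsu_index(hist, np.arange(256, dtype=np.float64))
    return float(k)


def otsu_threshold(
    values: np.ndarray, *, n_bins: int = 256, value_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Otsu split of a real-valued sample (e.g. an L* or b* plane).

    Histograms ``values`` into ``n_bins`` and returns ``(threshold, eta)``:
    values strictly below ``threshold`` form the low class, and ``eta`` is the
    between-class variance fraction used as a bimodality guard.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0 or np.ptp(v) == 0:
        raise ConstantImageError("constant plane: no separable classes")
    rng = value_range if value_range is not None else (float(v.min()), float(v.max()))
    hist, edges = np.histogram(v, bins=n_bins, range=rng)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k, eta = _otsu_index(hist, centers)
    return float(edges[k + 1]), eta


def to_cielab(img: np.ndarray) -> LabPlanes:
    """sRGB (D65) → CIELAB conversion of an RGB frame."""
    if not is_rgb(img):
        raise ParameterError("to_cielab expects an (H, W, 3) RGB image")
    lab = _skcolor.rgb2lab(img.astype(np.float64) / 255.0)
    return LabPlanes(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def save_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, img)
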