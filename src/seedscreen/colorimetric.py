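"""Colorimetric (RUBY) mode: CIELAB thresholding + colour classification.

Betalain-producing RUBY seeds are dark red; untransformed seeds are yellow.
On a white background every seed is darker than the paper, so the L*
(lightness) plane segments all seeds: seed pixels are those with L* below a
threshold.  The radial-threshold noise filter and marker-seeded watershed
then run exactly as in fluorescence mode.  Each final seed is classified by
its mean b* (blue–yellow axis): yellow wild-type seeds have high b*, red
RUBY seeds low b*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .errors import BimodalityError, ConstantImageError, ParameterError
from .imaging import is_rgb, otsu_threshold, to_cielab
from .segmentation import SegmentationParams, SeedRegion, segment_mask

log = logging.getLogger(__name__)

#: Minimum between-class variance fraction for a split to count as "two real
#: modes".  Otsu applied to a single-colour population fabricates a
#: threshold, and its between-class fraction is ~0.64 on a pure Gaussian and
#: 0.75 on a uniform sample, so the guard must sit well above those; two
#: genuinely separated colour classes score > 0.9.  Below this separability
#: an automatic b* split is refused and an explicit b_threshold is demanded.
B_BIMODALITY_MIN = 0.85


def _background_split(L: np.ndarray) -> float:
    """L* cut isolating the white-background mode from all seed modes.

    Plain Otsu on a three-mode histogram (dark red seeds, yellow seeds,
    white paper) can place its cut between the two *seed* colours when the
    darker class dominates.  The background is by precondition the brightest
    mode, so the cut is pushed upward while the upper class still splits into
    two clearly separated modes.
    """
    t, _ = otsu_threshold(L, value_range=(0.0, 100.0))
    for _ in range(3):
        hi = L[L >= t]
        if hi.size < 100 or np.ptp(hi) == 0:
            break
        t2, eta = otsu_threshold(hi)
        if eta < B_BIMODALITY_MIN or t2 <= t:
            break
        t = t2
    return t


@dataclass(frozen=True)
class ColorClassParams:
    """Thresholds for RUBY-mode classification.

    ``L_threshold`` (lightness cut in [0, 100]; seeds are *below* it) and
    ``b_threshold`` (RUBY iff mean b* below it) both accept ``"auto"``,
    resolved by Otsu on the relevant plane.  Radial settings are reused from
    the embedded :class:`SegmentationParams`.
    """

    L_threshold: float | Literal["auto"] = "auto"
    b_threshold: float | Literal["auto"] = "auto"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self):
        Lt = self.L_threshold
        if Lt != "auto" and not 0.0 <= float(Lt) <= 100.0:
            raise ParameterError(f"L* threshold {Lt!r} outside [0, 100]")


@dataclass
class ColorimetricResult:
    """Segmentation plus per-seed colour class for one RGB frame."""

    labels: np.ndarray
    all_regions: list[SeedRegion]
    ruby_regions: list[SeedRegion]
    mean_b: dict[int, float]
    L_threshold: float | None
    b_threshold: float | None

    @property
    def counts(self) -> tuple[int, int]:
        """(total seeds, RUBY seeds)."""
        return len(self.all_regions), len(self.ruby_regions)


def classify_colorimetric(
    rgb: np.ndarray, params: ColorClassParams | None = None
) -> ColorimetricResult:
    """Count all seeds and RUBY seeds in a white-background RGB image.

    Seed mask = ``L* < L_threshold``; segmentation as in fluorescence mode;
    a seed is RUBY iff its mean b* falls below ``b_threshold``.  The RUBY
    regions are always a subset of all regions (same labels).  An all-white
    image yields empty outputs; an automatic b* threshold on a population
    that is not clearly two-coloured raises :class:`BimodalityError`.
    """
    params = params or ColorClassParams()
    if not is_rgb(rgb):
        raise ParameterError("colorimetric mode expects an (H, W, 3) RGB image")
    lab = to_cielab(rgb)

    L_t = params.L_threshold
    if L_t == "auto":
        try:
            L_t = _background_split(lab.L)
        except ConstantImageError:
            if float(np.mean(lab.L)) >= 90.0:
                log.warning("blank white image: 0 seeds")
                return ColorimetricResult(
                    np.zeros(rgb.shape[:2], np.int32), [], [], {}, None, None
                )
            raise
    mask = lab.L < float(L_t)

    labels, regions = segment_mask(mask, params.segmentation, intensity=lab.L)
    if not regions:
        return ColorimetricResult(labels, [], [], {}, float(L_t), None)

    ids = np.array([r.label for r in regions])
    means = ndi.mean(lab.b, labels=labels, index=ids)
    mean_b = {int(k): float(v) for k, v in zip(ids, means)}

    b_t = params.b_threshold
    if b_t == "auto":
        seed_b = lab.b[labels > 0]
        thr, eta = otsu_threshold(seed_b)
        if eta < B_BIMODALITY_MIN:
            raise BimodalityError(
                f"seed b* histogram is not bimodal (separability {eta:.2f} < "
                f"{B_BIMODALITY_MIN}); pass an explicit b_threshold"
            )
        b_t = thr
    ruby = [r for r in regions if mean_b[r.label] < float(b_t)]
    return ColorimetricResult(labels, regions, ruby, mean_b, float(L_t), float(b_t))
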