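"""Seed detection: components, radial threshold, chamfer/watershed splitting.

This is the core counting stack.  A binary seed mask is cleaned by one
morphological opening, labelled with 8-connectivity, and filtered by an
adaptive *radial threshold* — a pixel distance derived from the median seed
size.  The same threshold then carves marker cores out of the chamfer
distance map, and a marker-seeded watershed on the negated distance map
splits touching seeds.  Counting is the number of final watershed labels.

The radial threshold can be given directly in pixels, or as the scale-free
*radial threshold ratio*: ``threshold = ratio * r_med`` where ``r_med`` is
the equivalent radius (``sqrt(area / pi)``) of the median-area region.  The
ratio form transfers across magnifications and species with different seed
sizes; its default is 0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage.segmentation import watershed as _sk_watershed

from ._chamfer import chamfer_3_4
from .errors import ConstantImageError, NoMarkersError, NoRegionsError, ParameterError
from .imaging import auto_threshold, binarize

log = logging.getLogger(__name__)

DEFAULT_RADIAL_RATIO = 0.4


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the counting pipeline.

    intensity_threshold
        Brightness cut in [0, 255] applied to the (bright-seed) grayscale
        frame, or ``"auto"`` for Otsu.
    radial_threshold / radial_threshold_ratio
        Mutually exclusive.  Pixel level on the distance transform used both
        to cull small noise regions and to carve watershed marker cores.
        When neither is given, the ratio defaults to 0.4 of the median
        equivalent radius.
    min_region_area
        Optional explicit area floor in px²; when unset the noise filter is
        the radial threshold itself (area >= pi * t², the same scale).
    """

    intensity_threshold: float | Literal["auto"] = "auto"
    radial_threshold: float | None = None
    radial_threshold_ratio: float | None = None
    min_region_area: int | None = None

    def __post_init__(self):
        if self.radial_threshold is not None and self.radial_threshold_ratio is not None:
            raise ParameterError(
                "set at most one of radial_threshold and radial_threshold_ratio"
            )
        if self.radial_threshold is not None and self.radial_threshold < 0:
            raise ParameterError("radial_threshold must be >= 0")
        r = self.radial_threshold_ratio
        if r is not None and not 0.0 < r < 1.0:
            raise ParameterError("radial_threshold_ratio must lie in (0, 1)")
        t = self.intensity_threshold
        if t != "auto" and not 0.0 <= float(t) <= 255.0:
            raise ParameterError(f"intensity threshold {t!r} outside [0, 255]")
        if self.min_region_area is not None and self.min_region_area < 0:
            raise ParameterError("min_region_area must be >= 0")

    @property
    def resolved_ratio(self) -> float:
        return (
            self.radial_threshold_ratio
            if self.radial_threshold_ratio is not None
            else DEFAULT_RADIAL_RATIO
        )


@dataclass
class SeedRegion:
    """One detected seed: label, geometry and mean source intensity."""

    label: int
    area_px: int
    centroid: tuple[float, float]
    mean_intensity: float | None = None
    contour: np.ndarray | None = None  # (N, 2) closed (row, col) polygon

    @property
    def equivalent_radius(self) -> float:
        """Radius of the disc with the same area, sqrt(area / pi)."""
        return float(np.sqrt(self.area_px / np.pi))


def _regions_from_labels(labels: np.ndarray, intensity: np.ndarray | None = None):
    props = _skmeasure.regionprops(
        labels, intensity_image=intensity if intensity is not None else None
    )
    out = []
    for p in props:
        out.append(
            SeedRegion(
                label=int(p.label),
                area_px=int(p.area),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                mean_intensity=float(p.intensity_mean) if intensity is not None else None,
            )
        )
    return out


def label_components(mask: np.ndarray, intensity: np.ndarray | None = None):
    """8-connected components of a binary mask.

    Returns ``(labels, regions)``: an int32 label image (0 = background) and
    one :class:`SeedRegion` per component with area and centroid filled in.
    """
    labels = _skmeasure.label(np.asarray(mask, bool), connectivity=2).astype(np.int32)
    return labels, _regions_from_labels(labels, intensity)


def derive_radial_threshold(regions, ratio: float) -> float:
    """Radial threshold from the median seed size: ``ratio * sqrt(median_area/pi)``.

    Adapting to the median area is what makes one ratio work across species
    with different seed sizes.
    """
    if not 0.0 < ratio < 1.0:
        raise ParameterError("radial threshold ratio must lie in (0, 1)")
    if not regions:
        raise NoRegionsError(
            "no regions detected; lower the intensity threshold and retry"
        )
    med_area = float(np.median([r.area_px for r in regions]))
    return ratio * float(np.sqrt(med_area / np.pi))


def filter_noise(regions, radial_threshold: float):
    """Drop regions whose equivalent radius falls below the radial threshold."""
    if radial_threshold < 0:
        raise ParameterError("radial threshold must be >= 0")
    return [r for r in regions if r.equivalent_radius >= radial_threshold]


def morphological_clean(mask: np.ndarray) -> np.ndarray:
    """One opening with a 3x3 elliptical (plus-shaped) element.

    Removes isolated pixels and pixel-scale speckle before it can seed
    spurious markers, while trimming convex seed regions by at most a
    one-pixel boundary band.
    """
    return _skmorph.opening(np.asarray(mask, bool), _skmorph.disk(1)).astype(bool)


def chamfer_distance(mask: np.ndarray) -> np.ndarray:
    """3-4 chamfer distance (in pixel units) to the nearest background pixel.

    Background pixels are exactly 0.  Raises on an all-foreground mask, where
    the distance is undefined.
    """
    m = np.asarray(mask, bool)
    if m.size and m.all():
        raise ParameterError("all-foreground mask: distance to background undefined")
    return chamfer_3_4(m.astype(np.uint8)) / 3.0


def make_markers(
    mask: np.ndarray, radial_threshold: float, *, distance: np.ndarray | None = None
) -> np.ndarray:
    """Watershed marker cores: components of ``{chamfer >= radial_threshold}``.

    At threshold 0 the cores are the mask components themselves.  For two
    overlapping seeds the distance values in the contact neck stay below the
    threshold, so each seed contributes its own core.  A positive-threshold
    core set is cleaned with the same 3x3 opening as the seed mask: the
    quantised chamfer map can leave pixel-scale slivers just above the
    threshold near a contact neck, and a sliver must not become an extra
    seed.  Raises :class:`NoMarkersError` when no core survives (threshold
    too high).
    """
    if radial_threshold < 0:
        raise ParameterError("radial threshold must be >= 0")
    m = np.asarray(mask, bool)
    dist = chamfer_distance(m) if distance is None else distance
    core = m & (dist >= radial_threshold)
    if radial_threshold > 0:
        core = morphological_clean(core)
    markers = _skmeasure.label(core, connectivity=2).astype(np.int32)
    if markers.max() == 0:
        raise NoMarkersError(
            f"no marker cores at radial threshold {radial_threshold:.3g}; "
            "lower the radial threshold (or ratio)"
        )
    return markers


def watershed_split(
    surface: np.ndarray, mask: np.ndarray, markers: np.ndarray
) -> np.ndarray:
    """Flood ``surface`` from the markers, constrained to ``mask``.

    The counting pipeline passes the negated chamfer map as the surface so
    floods meet along distance-map ridges between touching seeds.  Every
    marker keeps its label, the labelled pixels exactly cover the mask
    components that contain a marker, and the number of output labels equals
    the number of marker labels; these contracts are asserted on every call.
    """
    m = np.asarray(mask, bool)
    markers = np.asarray(markers)
    if markers.shape != m.shape or surface.shape != m.shape:
        raise ParameterError("surface, mask and markers must share one shape")
    marker_ids = np.unique(markers[markers > 0])
    if marker_ids.size == 0:
        raise NoMarkersError("watershed needs at least one marker")
    if np.any((markers > 0) & ~m):
        raise ParameterError("markers must lie inside the mask foreground")
    out = _sk_watershed(surface, markers=markers, mask=m, connectivity=2).astype(np.int32)
    # contract checks: markers preserved, marked components partitioned
    sel = markers > 0
    if not np.array_equal(out[sel], markers[sel]):
        raise RuntimeError("watershed altered marker labels")
    comp = _skmeasure.label(m, connectivity=2)
    marked = np.unique(comp[sel])
    if not np.array_equal(out > 0, np.isin(comp, marked)):
        raise RuntimeError("watershed output does not partition marked components")
    if np.unique(out[out > 0]).size != marker_ids.size:
        raise RuntimeError("watershed label count differs from marker count")
    return out


def extract_contours(labels: np.ndarray) -> list[np.ndarray]:
    """One closed (row, col) polygon per label, tracing its outer boundary.

    Contours are traced at the 0.5 iso-level of each label's indicator image
    (padded so border-touching regions still close), so every pixel centre of
    the label lies inside its polygon and pixels of other labels lie outside.
    Returned in increasing label order.
    """
    out = []
    for k in np.unique(labels[labels > 0]):
        ind = np.pad((labels == k).astype(float), 1)
        # fully_connected="high" keeps 8-connected (diagonally linked)
        # regions inside a single closed curve, matching the labelling
        conts = _skmeasure.find_contours(ind, 0.5, fully_connected="high")
        longest = max(conts, key=len)
        out.append(longest - 1.0)
    return out


def segment_mask(
    mask: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    intensity: np.ndarray | None = None,
):
    """Run the counting stack on an already-binarized seed mask.

    opening → components → radial threshold → noise filter → chamfer →
    marker cores → watershed → contours.  Returns ``(labels, regions)``;
    an empty mask yields 0 seeds with a logged warning.
    """
    params = params or SegmentationParams()
    m = morphological_clean(mask)
    labels0, regions0 = label_components(m, intensity)
    empty = np.zeros_like(labels0)
    if not regions0:
        log.warning("segment_mask: no foreground regions, returning 0 seeds")
        return empty, []
    if params.radial_threshold is not None:
        rt = params.radial_threshold
    else:
        rt = derive_radial_threshold(regions0, params.resolved_ratio)
    kept = filter_noise(regions0, rt)
    if params.min_region_area is not None:
        kept = [r for r in kept if r.area_px >= params.min_region_area]
    if not kept:
        log.warning(
            "segment_mask: every region fell below the radial threshold %.3g", rt
        )
        return empty, []
    keep_ids = np.array([r.label for r in kept], dtype=np.int32)
    mask2 = np.isin(labels0, keep_ids)
    dist = chamfer_distance(mask2)
    markers = make_markers(mask2, rt, distance=dist)
    coreless = np.setdiff1d(keep_ids, np.unique(labels0[markers > 0]))
    if coreless.size:
        log.warning(
            "segment_mask: %d region(s) have no distance core at threshold %.3g "
            "and are dropped from the count",
            coreless.size,
            rt,
        )
        mask2 &= ~np.isin(labels0, coreless)
        if not mask2.any():
            return empty, []
    final = watershed_split(-dist, mask2, markers)
    regions = _regions_from_labels(final, intensity)
    for region, contour in zip(regions, extract_contours(final)):
        region.contour = contour
    return final, regions


def segment_seeds(gray: np.ndarray, params: SegmentationParams | None = None):
    """Full fluorescence-mode pipeline on a preprocessed grayscale frame.

    The frame must already follow the bright-seeds-on-dark-background
    convention (inverted brightfield, or a raw fluorescent channel).
    Returns ``(labels, regions)``; the seed count is ``len(regions)``.
    """
    params = params or SegmentationParams()
    t = params.intensity_threshold
    if t == "auto":
        try:
            t = auto_threshold(gray)
        except ConstantImageError:
            log.warning("segment_seeds: constant image, returning 0 seeds")
            return np.zeros(gray.shape, np.int32), []
    mask = binarize(gray, float(t))
    return segment_mask(mask, params, intensity=gray)


def resolve_intensity_threshold(gray: np.ndarray, params: SegmentationParams):
    """Materialise an ``"auto"`` intensity threshold for reporting purposes."""
    if params.intensity_threshold == "auto":
        return replace(params, intensity_threshold=auto_threshold(gray))
    return params
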