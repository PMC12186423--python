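"""Verification overlays: per-seed contours and numeric labels on the input.

The rendered overlay is what a user eyeballs to confirm the segmentation:
each counted seed is outlined and numbered, and in colorimetric mode the
outline colour encodes the class (red = RUBY, yellow-green = wild-type).
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw
from skimage.segmentation import find_boundaries

from .imaging import is_rgb

CONTOUR_DEFAULT = (0, 255, 0)
CONTOUR_RUBY = (255, 40, 40)
CONTOUR_WILDTYPE = (200, 220, 0)
LABEL_COLOR = (40, 120, 255)


def render_overlay(
    image: np.ndarray,
    labels: np.ndarray,
    *,
    classes: dict[int, str] | None = None,
    path=None,
) -> np.ndarray:
    """Draw region boundaries and label numbers over ``image``.

    ``classes`` optionally maps a label id to ``"marker"``/``"ruby"`` (drawn
    red) or anything else (drawn yellow-green).  Returns the RGB array and,
    if ``path`` is given, also writes it as PNG.
    """
    rgb = image if is_rgb(image) else np.stack([image] * 3, axis=-1)
    rgb = rgb.astype(np.uint8).copy()

    if classes:
        for lab in np.unique(labels[labels > 0]):
            edge = find_boundaries(labels == lab, mode="outer")
            cls = classes.get(int(lab), "")
            color = CONTOUR_RUBY if cls in ("marker", "ruby") else CONTOUR_WILDTYPE
            rgb[edge] = color
    else:
        rgb[find_boundaries(labels > 0, mode="outer")] = CONTOUR_DEFAULT

    pil = Image.fromarray(rgb)
    draw = ImageDraw.Draw(pil)
    for lab in np.unique(labels[labels > 0]):
        rr, cc = np.nonzero(labels == lab)
        draw.text((float(cc.mean()), float(rr.mean())), str(int(lab)),
                  fill=LABEL_COLOR, anchor="mm")
    out = np.asarray(pil)
    if path is not None:
        pil.save(path)
    return out


def save_label_map(path, labels: np.ndarray) -> None:
    """Export a label map as 16-bit PNG (label ids preserved up to 65535)."""
    Image.fromarray(labels.astype(np.uint16)).save(path)
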