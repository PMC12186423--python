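"""Ground-truth synthetic scenes: seed layouts plus rendered images.

Emulates the study substrate: a single layer of 50–200 Arabidopsis-like
seeds poured onto a light weigh boat and photographed twice (brightfield +
fluorescent channel), or once in RGB for the colorimetric RUBY assay.  Every
scene carries its exact layout (centres, ellipse axes, classes), so rendered
images come with known counts for benchmarking the counting pipeline.

Seeds are ellipses with aspect ratio 1.2–1.8 (Arabidopsis seeds are ovoid)
and lognormal brightness.  A configurable fraction of seeds is laid down in
touching pairs: because real seeds are solid objects in a monolayer, paired
seeds are placed at 93–100% of their contact distance, i.e. they touch or
interpenetrate slightly (up to ~15% of a radius) as projected seeds leaning
on each other do.  Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, SceneError
from .imaging import save_image

#: Default canvas fill fraction (seed area / canvas area) when the canvas is
#: sized automatically; a loosely packed monolayer.
TARGET_FILL = 0.08

#: Rendering palette for the colorimetric mode (sRGB).  Yellow wild-type
#: seeds have b* ~ +64, dark red RUBY seeds b* ~ +21: well over the 20-unit
#: class separation the classifier needs.
WILDTYPE_RGB = (210.0, 170.0, 30.0)
RUBY_RGB = (120.0, 28.0, 32.0)


@dataclass(frozen=True)
class SyntheticSeed:
    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    orientation: float  # radians, major axis vs column axis
    seed_class: str  # "marker" or "wildtype"
    brightness: float  # multiplicative, lognormal around 1


@dataclass(frozen=True)
class SyntheticScene:
    seeds: tuple[SyntheticSeed, ...]
    canvas: tuple[int, int]  # (H, W)
    overlap_pairs: int
    rng_seed: int
    scale_bar: tuple[int, int, int, int] | None = None  # (row, col, h, w)

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def n_marker(self) -> int:
        return sum(1 for s in self.seeds if s.seed_class == "marker")


def _ellipse_radius(a: float, b: float, psi: float) -> float:
    # boundary radius of an (a, b) ellipse in direction psi from its major axis
    return 1.0 / np.sqrt((np.cos(psi) / a) ** 2 + (np.sin(psi) / b) ** 2)


def generate_scene(
    n_seeds: int,
    marker_fraction: float = 0.75,
    overlap_fraction: float = 0.0,
    radius_mean_px: float = 20.0,
    radius_cv: float = 0.08,
    rng_seed: int = 0,
    *,
    canvas: tuple[int, int] | None = None,
    scale_bar: bool = False,
    max_tries: int = 400,
) -> SyntheticScene:
    """Lay out ``n_seeds`` ellipses by rejection sampling.

    ``overlap_fraction`` of the seeds (rounded) are placed as touching pairs;
    classes are independent Bernoulli draws at ``marker_fraction``.  The
    canvas is sized automatically for a ~8% fill unless given.  Raises
    :class:`SceneError` when the layout cannot be packed.
    """
    if n_seeds < 0:
        raise ParameterError("n_seeds must be >= 0")
    for name, f in (("marker_fraction", marker_fraction), ("overlap_fraction", overlap_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0]))

    if canvas is None:
        if n_seeds == 0:
            canvas = (256, 256)
        else:
            area = n_seeds * np.pi * radius_mean_px**2 * (1 + radius_cv**2) / TARGET_FILL
            w = int(np.ceil(np.sqrt(area * 1.25)))
            canvas = (max(256, int(np.ceil(area / w))), max(256, w))
    H, W = canvas

    # per-seed attributes drawn up front so classes/sizes are independent of
    # how hard the placement was
    sigma = float(np.sqrt(np.log1p(radius_cv**2)))
    radii = radius_mean_px * rng.lognormal(-0.5 * sigma**2, sigma, n_seeds)
    aspect = rng.uniform(1.2, 1.8, n_seeds)
    a_ax = radii * np.sqrt(aspect)
    b_ax = radii / np.sqrt(aspect)
    orient = rng.uniform(0.0, np.pi, n_seeds)
    classes = np.where(rng.random(n_seeds) < marker_fraction, "marker", "wildtype")
    brightness = rng.lognormal(-0.5 * 0.15**2, 0.15, n_seeds)

    n_pairs = int(round(n_seeds * overlap_fraction)) // 2
    sep = 2.0  # clearance between non-paired seeds, px
    centers: list[tuple[float, float]] = []

    def margin(i):
        return a_ax[i] + 2.0

    def clear_of_others(c, i, exempt=()):
        for j, cj in enumerate(centers):
            if j in exempt:
                continue
            if np.hypot(c[0] - cj[0], c[1] - cj[1]) < a_ax[i] + a_ax[j] + sep:
                return False
        return True

    def in_canvas(c, i):
        m = margin(i)
        return m <= c[0] <= H - m and m <= c[1] <= W - m

    idx = 0
    for _pair in range(n_pairs):
        i, j = idx, idx + 1
        for _t in range(max_tries):
            pm = margin(i) + 2.0 * radius_mean_px  # room for the partner
            ci = (rng.uniform(pm, H - pm), rng.uniform(pm, W - pm))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rho_i = _ellipse_radius(a_ax[i], b_ax[i], theta - orient[i])
            rho_j = _ellipse_radius(a_ax[j], b_ax[j], theta + np.pi - orient[j])
            d = rng.uniform(0.93, 1.0) * (rho_i + rho_j)
            cj = (ci[0] + d * np.sin(theta), ci[1] + d * np.cos(theta))
            if (
                in_canvas(ci, i)
                and in_canvas(cj, j)
                and clear_of_others(ci, i)
                and clear_of_others(cj, j)
            ):
                centers.extend([ci, cj])
                break
        else:
            raise SceneError("canvas too small to place overlapping pairs")
        idx += 2
    for i in range(idx, n_seeds):
        for _t in range(max_tries):
            c = (rng.uniform(margin(i), H - margin(i)), rng.uniform(margin(i), W - margin(i)))
            if clear_of_others(c, i):
                centers.append(c)
                break
        else:
            raise SceneError(f"canvas too small to place {n_seeds} seeds")

    seeds = tuple(
        SyntheticSeed(
            center=centers[i],
            semi_major=float(a_ax[i]),
            semi_minor=float(b_ax[i]),
            orientation=float(orient[i]),
            seed_class=str(classes[i]),
            brightness=float(brightness[i]),
        )
        for i in range(n_seeds)
    )
    bar = (H - 12, 6, 6, int(0.25 * W)) if scale_bar else None
    return SyntheticScene(
        seeds=seeds, canvas=(H, W), overlap_pairs=n_pairs,
        rng_seed=int(rng_seed), scale_bar=bar,
    )


def _paint(canvas: np.ndarray, seed: SyntheticSeed, value) -> None:
    """Alpha-composite one anti-aliased ellipse into a float canvas."""
    H, W = canvas.shape[:2]
    r0 = max(0, int(seed.center[0] - seed.semi_major - 2))
    r1 = min(H, int(seed.center[0] + seed.semi_major + 3))
    c0 = max(0, int(seed.center[1] - seed.semi_major - 2))
    c1 = min(W, int(seed.center[1] + seed.semi_major + 3))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy = rr - seed.center[0]
    dx = cc - seed.center[1]
    co, si = np.cos(seed.orientation), np.sin(seed.orientation)
    x = dx * co + dy * si
    y = -dx * si + dy * co
    q = np.sqrt((x / seed.semi_major) ** 2 + (y / seed.semi_minor) ** 2)
    alpha = np.clip((1.0 - q) * seed.semi_minor + 0.5, 0.0, 1.0)
    patch = canvas[r0:r1, c0:c1]
    if canvas.ndim == 3:
        patch += alpha[..., None] * (np.asarray(value) - patch)
    else:
        patch += alpha * (value - patch)


def _noise_rng(scene: SyntheticScene, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([scene.rng_seed & 0x7FFFFFFF, stream])
    )


def _finish(img: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.rint(np.clip(img, 0, 255)).astype(np.uint8)


def render_fluorescence_pair(
    scene: SyntheticScene,
    noise_sd: float = 3.0,
    bg_level: float = 200.0,
    *,
    seed_level: float = 60.0,
    fl_bg_level: float = 8.0,
    fl_seed_level: float = 180.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the (brightfield, fluorescent) image pair of a scene.

    Brightfield: every seed as a dark ellipse on a light background (the
    raw, pre-inversion convention).  Fluorescent: only marker-class seeds,
    bright on a dark background.  Per-seed lognormal brightness exercises the
    intensity-threshold tuning path; edges are anti-aliased; Gaussian pixel
    noise of ``noise_sd`` is added to both frames.
    """
    bf = np.full(scene.canvas, bg_level, np.float64)
    fl = np.full(scene.canvas, fl_bg_level, np.float64)
    for s in scene.seeds:
        _paint(bf, s, np.clip(seed_level * s.brightness, 0.0, 255.0))
        if s.seed_class == "marker":
            _paint(fl, s, np.clip(fl_seed_level * s.brightness, 0.0, 255.0))
    if scene.scale_bar is not None:
        r, c, h, w = scene.scale_bar
        bf[r : r + h, c : c + w] = 20.0
        fl[r : r + h, c : c + w] = 230.0
    return (
        _finish(bf, noise_sd, _noise_rng(scene, 1)),
        _finish(fl, noise_sd, _noise_rng(scene, 2)),
    )


def render_colorimetric(scene: SyntheticScene, noise_sd: float = 2.0) -> np.ndarray:
    """Render the RGB colorimetric frame: yellow wild-type / dark-red RUBY
    seeds on a white background, with per-seed hue jitter."""
    rng = _noise_rng(scene, 3)
    img = np.full((*scene.canvas, 3), 250.0, np.float64)
    for s in scene.seeds:
        base = np.asarray(RUBY_RGB if s.seed_class == "marker" else WILDTYPE_RGB)
        jitter = rng.uniform(0.88, 1.08) * rng.uniform(0.96, 1.04, 3)
        _paint(img, s, np.clip(base * jitter, 0.0, 255.0))
    if scene.scale_bar is not None:
        r, c, h, w = scene.scale_bar
        img[r : r + h, c : c + w] = (40.0, 40.0, 40.0)
    return _finish(img, noise_sd, rng)


def write_scene_truth(scene: SyntheticScene, path) -> None:
    """Per-seed ground truth as CSV (seed id, centre, axes, class)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["seed_id", "row", "col", "semi_major", "semi_minor",
             "orientation", "seed_class", "brightness"]
        )
        for i, s in enumerate(scene.seeds):
            w.writerow(
                [i, f"{s.center[0]:.3f}", f"{s.center[1]:.3f}",
                 f"{s.semi_major:.3f}", f"{s.semi_minor:.3f}",
                 f"{s.orientation:.5f}", s.seed_class, f"{s.brightness:.5f}"]
            )


def write_fixture_suite(
    outdir,
    n_scenes: int = 10,
    rng_seed: int = 0,
    *,
    n_range: tuple[int, int] = (50, 200),
    overlap_fraction: float = 0.1,
    noise_sd: float = 3.0,
    colorimetric: bool = False,
) -> list[tuple[str, SyntheticScene]]:
    """Materialise a directory of rendered scenes plus truth CSVs.

    Images follow the batch naming convention (``<id>_BF.png`` /
    ``<id>_FL.png``, or ``<id>_RGB.png`` in colorimetric mode) so the
    directory can be fed straight to the batch runner.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = np.random.default_rng(
        np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 99])
    )
    out = []
    for i in range(n_scenes):
        n = int(meta.integers(n_range[0], n_range[1] + 1))
        scene = generate_scene(
            n, overlap_fraction=overlap_fraction,
            rng_seed=int(meta.integers(0, 2**31 - 1)),
        )
        sample_id = f"scene{i:03d}"
        if colorimetric:
            save_image(outdir / f"{sample_id}_RGB.png", render_colorimetric(scene, noise_sd))
        else:
            bf, fl = render_fluorescence_pair(scene, noise_sd)
            save_image(outdir / f"{sample_id}_BF.png", bf)
            save_image(outdir / f"{sample_id}_FL.png", fl)
        write_scene_truth(scene, outdir / f"{sample_id}_truth.csv")
        out.append((sample_id, scene))
    return out
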