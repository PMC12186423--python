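"""Shared fixtures and deterministic scene builders."""

from __future__ import annotations

import numpy as np
import pytest

from seedscreen.synthetic import SyntheticScene, SyntheticSeed, _ellipse_radius


def build_grid_scene(
    n_singles: int,
    pair_contacts: tuple[float, ...] = (),
    *,
    r: float = 16.0,
    aspect: float = 1.4,
    classes: list[str] | None = None,
    brightness: float = 1.0,
) -> SyntheticScene:
    """Hand-built scene: seeds on a regular grid, optional touching pairs.

    ``pair_contacts`` gives, per pair, the centre distance as a fraction of
    the two ellipses' contact distance (1.0 = exactly touching, 0.97 =
    slight interpenetration).  Deterministic by construction — no rng —
    so tests built on it assert exact counts.
    """
    a, b = r * np.sqrt(aspect), r / np.sqrt(aspect)
    slot = 7.0 * r
    n_slots = n_singles + len(pair_contacts)
    cols = int(np.ceil(np.sqrt(n_slots)))
    rows = int(np.ceil(n_slots / cols))
    seeds = []
    k = 0  # seed index for orientation variety / class lookup

    def cls(i):
        return classes[i] if classes is not None else "wildtype"

    for s in range(n_slots):
        cy = (s // cols + 0.5) * slot
        cx = (s % cols + 0.5) * slot
        if s < len(pair_contacts):
            c = pair_contacts[s]
            th1, th2 = (0.3 * s) % np.pi, (0.3 * s + 1.1) % np.pi
            d = c * (_ellipse_radius(a, b, -th1) + _ellipse_radius(a, b, np.pi - th2))
            for cxx, th in ((cx - d / 2, th1), (cx + d / 2, th2)):
                seeds.append(SyntheticSeed((cy, cxx), a, b, th, cls(k), brightness))
                k += 1
        else:
            seeds.append(SyntheticSeed((cy, cx), a, b, (0.4 * s) % np.pi, cls(k), brightness))
            k += 1
    H, W = int(rows * slot), int(cols * slot)
    return SyntheticScene(tuple(seeds), (H, W), len(pair_contacts), rng_seed=0)


def scene_with_exact_classes(n: int, n_marker: int, rng_seed: int, **kw) -> SyntheticScene:
    """A random scene whose class labels are overwritten to an exact tally."""
    from seedscreen.synthetic import generate_scene

    scene = generate_scene(n, rng_seed=rng_seed, **kw)
    seeds = tuple(
        SyntheticSeed(s.center, s.semi_major, s.semi_minor, s.orientation,
                      "marker" if i < n_marker else "wildtype", s.brightness)
        for i, s in enumerate(scene.seeds)
    )
    return SyntheticScene(seeds, scene.canvas, scene.overlap_pairs,
                          scene.rng_seed, scene.scale_bar)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
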