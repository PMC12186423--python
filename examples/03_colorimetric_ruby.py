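"""RUBY-mode classification: one RGB photo, seeds split by CIELAB colour.

Dark-red betalain-producing RUBY seeds have low b* (blue-yellow axis),
yellow wild-type seeds high b*; the white background is removed on L*.
"""

import seedscreen as ss

scene = ss.generate_scene(60, marker_fraction=0.75, rng_seed=5)
rgb = ss.render_colorimetric(scene)

res = ss.classify_colorimetric(rgb)
n_all, n_ruby = res.counts
print(f"ground truth: {scene.n_seeds} seeds, {scene.n_marker} RUBY")
print(f"counted:      {n_all} seeds, {n_ruby} RUBY")
print(f"auto thresholds: L* < {res.L_threshold:.1f} is seed, "
      f"mean b* < {res.b_threshold:.1f} is RUBY")

counts = ss.combine_counts(n_all, n_ruby)
test = ss.chi_squared_segregation(counts)
print(f"chi2={test.chi2_statistic:.3f} p={test.p_value:.3f} -> {test.call}")
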