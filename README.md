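# seedscreen

Image-based counting of transgenic and wild-type seeds, and chi-squared
screening for single-locus T-DNA insertion lines.

## The problem

Plant transformation frequently integrates a T-DNA at more than one genomic
locus. Because multi-locus lines complicate downstream genetics and invite
transgene silencing, researchers screen T2 seed for lines whose marker
segregates 3:1 — the Mendelian ratio of a selfed plant hemizygous at a
single dominant locus. With fluorescent (FAST) or colorimetric (RUBY) seed
markers this normally means hand-counting hundreds of seeds per line under a
stereomicroscope. `seedscreen` automates the count and the statistics:

* **Fluorescence mode** takes a brightfield image (all seeds) and a
  fluorescent image (marker-positive seeds) of the same field.
* **Colorimetric mode** takes one RGB photo of seeds on a white background
  and separates dark-red RUBY seeds from yellow wild-type seeds in CIELAB
  space (seeds found by low L\*, classes split by b\*).

## Method

Counting is a classical marker-seeded watershed stack. For a grayscale
frame with bright seeds on a dark background (brightfield frames are
inverted first, scale bars blanked):

1. binary threshold at an adjustable intensity *t*ᵢ (or Otsu),
   one 3×3 morphological opening, 8-connected component labelling;
2. an adaptive **radial threshold** *t* = ρ·r_med, where
   r_med = √(median area/π) is the median seed's equivalent radius and ρ is
   the scale-free *radial threshold ratio* (default 0.4; at a typical
   Arabidopsis stereomicroscope scale — median seed radius ≈ 20 px —
   ρ = 0.45 gives *t* = 9.0 and ρ = 0.50 gives *t* = 10.0);
   regions with equivalent radius < *t* are discarded as noise;
3. a two-pass 3-4 **chamfer distance transform** D to the background;
4. marker cores = connected components of {D ≥ *t*}; touching seeds whose
   contact neck has D < *t* yield separate cores;
5. a **watershed** flood of −D from the cores partitions the foreground;
   the seed count is the number of watershed labels, each reported with
   area, centroid and a verification contour.

Segregation is then tested with Pearson's chi-squared statistic on the
(transgenic, wild-type) pair against expectations (f·N, (1−f)·N), f = 3/4,
1 df, no continuity correction. Lines with p < 0.05 are flagged as
inconsistent with a single locus (excess of marker seeds suggests multiple
loci, e.g. 15:1 for two; a deficit suggests silencing). The expected
fraction for k independent loci is 1 − (1/4)ᵏ.

## Worked example

No microscope needed — the package ships a ground-truth scene generator:

```python
import seedscreen as ss

scene = ss.generate_scene(100, marker_fraction=0.75, overlap_fraction=0.1,
                          rng_seed=42)
bf, fl = ss.render_fluorescence_pair(scene)   # brightfield + fluorescent

_, all_seeds   = ss.segment_seeds(ss.invert(bf))
_, marker_seeds = ss.segment_seeds(fl)
counts = ss.combine_counts(len(all_seeds), len(marker_seeds))
res = ss.chi_squared_segregation(counts)
print(len(all_seeds), len(marker_seeds))
print(f"chi2={res.chi2_statistic:.3f} p={res.p_value:.3f} -> {res.call}")
```

prints

```
97 72
chi2=0.031 p=0.860 -> single_locus_consistent
```

The scene truly contains 100 seeds (74 marker-positive); a few deeply
overlapping pairs merge at the default ratio, giving 97 — a 3% count error
on this particular draw (the mean over many scenes is ~1.2%, and raising
`radial_threshold_ratio` recovers merged pairs). 72/97 marker seeds is
fully compatible with 3:1 (p = 0.86), so the line is called consistent with
a single T-DNA locus.

The same workflow from a shell, with overlay images and a CSV:

```
seedscreen fluor line1_BF.png line1_FL.png --radial-ratio 0.45 \
    --fl-intensity 13 --out results.csv --overlay-dir overlays/
seedscreen batch images/ --out results.csv     # <id>_BF/<id>_FL pairs
seedscreen color ruby_RGB.png                  # RUBY colorimetric mode
seedscreen fixtures demo/ --n-scenes 5         # synthetic benchmark suite
```

See `examples/` for short narrative scripts covering each capability.

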