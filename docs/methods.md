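# Methods

## Counting model

A seed field is modelled as bright, roughly convex blobs on a darker
background. Both imaging modes are reduced to this common form: brightfield
frames are grayscaled (ITU-R BT.601 weights 0.299/0.587/0.114 — the common
imaging-library default; the choice is otherwise free) and inverted;
fluorescent frames are used as-is; colorimetric RGB frames contribute a
binary mask `L* < t_L` instead of an intensity image (seeds are darker than
the white paper, the opposite polarity of the fluorescence convention).

Scale bars are blanked before thresholding, either with an explicit
exclusion rectangle or automatically: any bright connected component that
touches the image border with bounding-box aspect ratio > 8 and fill
fraction > 0.95 is replaced by the image's modal intensity (bars are long,
thin, solid and border-adjacent; seeds are none of these; the modal
intensity is the weigh-boat background).

Binarization is strict (`v > t`), which makes the foreground monotone
non-increasing in the threshold and threshold 255 exactly empty. The
automatic threshold is Otsu's criterion evaluated exhaustively over the 256
integer candidates, ties broken toward the lowest maximiser; a constant
image is an error rather than an arbitrary cut.

## Radial threshold and watershed splitting

All size reasoning is in units of the *equivalent radius* r = √(area/π).
The radial threshold t is either given in pixels or derived per image as
t = ρ·r_med from the median detected region area; adapting to the median
makes one ratio ρ transfer across magnifications and species. The default
is ρ = 0.4; the benchmark-optimal settings for Arabidopsis at typical
stereomicroscope magnification (t = 9.0 at ρ = 0.45 for fluorescent frames,
t = 10.0 at ρ = 0.50 for brightfield) correspond to a median seed of
equivalent radius 20 px, the scale the synthetic generator reproduces.

t is used twice:

* **noise filter** — regions with equivalent radius < t are discarded;
* **marker cores** — the t-level set of a two-pass 3-4 chamfer distance
  transform (weights 3 edge / 4 diagonal, divided by 3; within ~6% of
  Euclidean) is labelled, and each core seeds a watershed flood of the
  negated distance map restricted to the mask.

Flooding the negated distance transform, rather than raw intensity, is the
standard construction for separating touching convex objects and matches
the distance-transform step feeding the watershed here. Geometry fixes what
this can and cannot split: for two discs of radius r whose centres are d
apart, the distance-map saddle in the neck is √(r² − (d/2)²), so a t-level
core separates the pair iff the interpenetration depth δ = 2r − d satisfies
δ ≲ t²/r. At ρ = 0.4 that is ~16% of a radius — seeds leaning on each other
resolve; deeply fused blobs merge and require a raised ratio, which is
exactly the intended tuning workflow. Marker cores at positive t are
cleaned with the same 3×3 opening as the seed mask because the quantised
chamfer map can leave one- or two-pixel slivers just above t near a contact
neck, and a sliver must not become an extra seed. At t = 0 the cores are,
exactly, the mask components.

Degenerate cases: an empty mask or a mask whose regions all fall below the
noise filter yields zero seeds with a warning; a threshold that leaves *no*
core at all is an error with a tuning hint; a surviving region whose core
vanished (only possible for very elongated regions, since an ellipse's core
is connected and non-empty while its semi-minor axis exceeds t) is dropped
with a warning. Seeds touching the image border are counted. Components
are 8-connected throughout, so anti-aliased diagonal boundaries do not
fragment; the watershed is asserted on every call to preserve marker
labels, partition the marked components, and emit exactly one label per
marker.

## Colour classification (RUBY mode)

The L\* seed cut resolves "auto" with a background-isolating split rather
than a single Otsu pass: on the three-mode histogram (dark red seeds,
yellow seeds, white background) plain Otsu places its cut between the two
*seed* colours whenever the red class carries more weight, silently
dropping the yellow seeds. Since the background is by precondition the
brightest mode, the cut is pushed upward while the upper class still splits
with between-class variance fraction ≥ 0.85.

Each segmented seed is classified RUBY iff its *mean* b\* falls below the
b\* threshold (region means are robust to specular highlights; per-pixel
voting is not). The automatic b\* threshold is Otsu on seed pixels guarded
by the same 0.85 separability bound: Otsu always returns *some* split, and
its between-class fraction is 2/π ≈ 0.64 on a pure Gaussian and 0.75 on a
uniform sample, so any guard at or below those values would pass unimodal
(single-colour) populations and fabricate classes. Two genuinely separated
colour classes (b\* means ≥ 20 units apart at within-class spreads of a few
units) score > 0.9. When the guard trips, the run demands an explicit
`b_threshold` instead of guessing.

## Segregation statistics

Pearson's chi-squared on the two categories (transgenic, wild-type) with
expectations (fN, (1−f)N), f = 3/4 by default, one degree of freedom and no
continuity correction, delegated to `scipy.stats.chisquare`. The call is
"rejected" iff p < α (strict; α = 0.05 default). The direction of the
deviation is annotated — an excess of marker seeds points toward multiple
independent loci (two loci give f = 15/16), a deficit toward transgene
silencing — but the package never auto-calls a locus number; the k-locus
expectation 1 − (1/4)ᵏ is provided for reference. No multiple-testing
correction is applied across a batch; the batch log reports how many lines
were tested. Linked/tandem insertions are outside the power of ratio-based
screening and out of scope.

## Synthetic scenes

The generator emulates the study substrate: a loosely packed monolayer
(~8% canvas fill) of 50–200 ellipses with aspect ratio 1.2–1.8 and
equivalent radii lognormal around 20 px (CV 0.08), brightness lognormal
(σ = 0.15) to exercise intensity tuning, anti-aliased edges, Gaussian pixel
noise (σ = 3 by default), optional solid scale bar (25% of width × 6 px,
bottom-left). Classes are independent Bernoulli draws at the marker
fraction (0.75 default, the single-locus expectation). A configurable
fraction of seeds is laid down as touching pairs at 93–100% of their
directional contact distance: solid seeds in a monolayer cannot
interpenetrate deeply, so apparent overlap in a projection is shallow. The
deepest draws in that range exceed the ρ = 0.4 splitting bound on purpose,
so default-parameter count recovery is good (mean |error| ≲ 1.5% at 10%
paired seeds) but not exact — matching the method's real failure mode.
Colorimetric renders use a yellow/dark-red palette ~43 b\* units apart with
per-seed hue jitter on a near-white (250) background.

Everything is reproducible bit-for-bit from one integer seed. What the
generator does *not* model — seed-coat texture, optical PSF and glare,
uneven illumination, dirt, white-balance drift of phone photos — means
passing tests demonstrate the algorithmic contracts and the counting
statistics under controlled conditions, not robustness to every real
microscope artefact; on real images the intensity and radial parameters
remain the user's tuning surface.

## Problem sizes and numerics

The test and acceptance workloads use 50-scene batches for count recovery,
10-image sweeps (3 intensity × 6 ratio settings spanning the practical
working range 0.35–0.6), 10,000-draw calibrations of the chi-squared layer,
and brute-force oracles (flood fill, KD-tree Euclidean distances, exact
rational Pearson statistics, 256-candidate Otsu searches) on small arrays.
Chamfer distances are exact integers divided by 3; its documented
worst-case deviation from Euclidean (~6%, bound used in tests: 8%) is on
diagonal paths. The 16-bit image path rescales linearly to 8-bit on load
with a warning. Known limitations: deeply fused seed clusters under-count
at the default ratio; very elongated debris longer than ~8× aspect touching
the border may be mistaken for a scale bar; colorimetric auto-thresholds
assume the background is the brightest mode.
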