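# Methods

## Measurement model

The package quantifies the caliber of primary retinal vessels in fundus
fluorescein angiograms. Perfused vessels are bright against the fundus;
the major arterioles and venules leave the optic disc in a roughly radial
pattern. A circle centred on the disc therefore crosses each primary
vessel once, close to perpendicular, and the intensity profile along the
circle is a sequence of bright pulses — one per vessel — on a darker
background.

Measurements are taken in the annulus between 2 and 4 optic-disc radii.
The inner bound keeps the scan clear of the disc's own brightness and of
the central vessel trunks; the outer bound stays inside the region where
the primary vessels usually have not yet branched. When a vessel does
branch inside the annulus, a per-vessel inner-radius override
(`ScanConfig.inner_radius_overrides`) starts that vessel's series just
past the branch point; no automatic branch resolution is attempted.

### Contrast enhancement

Vessel/background contrast can be poor, in particular on hypopigmented
fundi where the background itself is bright. The pre-processing step takes
a binary vessel-selection mask (produced by hand in an image editor, or by
any external segmentation) and paints the selected pixels to the maximum
representable intensity. This guarantees masked vessels exceed any
threshold expressed as a fraction of full scale and makes the measurement
depend only on the mask geometry, not on the original vessel brightness.
The operation is idempotent and never lowers a pixel.

### Ring sampling and edge detection

Each of `n_rings` (default 30) circles, evenly spaced across the annulus,
is sampled by bilinear interpolation at `ceil(2*pi*r)` points — about 1 px
arc spacing, matching pixel-level edge localisation. Angles run clockwise
from 12 o'clock in display coordinates (y down) and are reported in
[0, 2*pi).

The detection threshold defaults to 0.80 of the bit-depth maximum (204 for
8-bit). Since enhancement sets vessels to the representable maximum, full
scale is the natural reference; `threshold_relative_to="image_max"`
switches to 0.80 of the observed maximum for unenhanced images. Crossing
detection first rotates the scan origin to the first below-threshold
sample, so no vessel pulse straddles the angular seam; a ring with no
below-threshold sample raises an error ("no background on ring") rather
than guessing. Crossing angles are refined by linear interpolation between
the two bracketing samples, giving sub-sample edge positions. Rising
crossings are vessel starts, falling crossings ends; by construction they
alternate with equal counts (an invariant asserted in code).

### Chaining and the shortest-distance diameter

Pulses are linked across rings greedily by nearest start angle, matching
against each chain's most recently matched angle so chains can track the
steady angular drift of obliquely coursing vessels. The association
tolerance `max_angle_gap` defaults to `2*atan(15/r_inner)` — about the
angular footprint of a 30 px vessel on the innermost ring; wider gaps risk
capturing neighbours, narrower ones splitting oblique vessels. Chains
spanning fewer than `min_ring_support` (default 80%) of the rings are
discarded as spurious; survivors are numbered in order of mean start
angle.

The diameter at each ring is the minimum Euclidean distance from that
ring's start point to *any* end point of the same chain, across all its
rings. For a straight ribbon this minimum equals the perpendicular width
regardless of crossing obliquity, which is what makes the ring geometry
insensitive to how vessels are oriented. Ties take the lowest ring index
(the value is unaffected). Per-vessel summaries are the mean, median and
sample SD (ddof 1; 0 for a single ring) of the series.

One diameter is recorded per ring the chain spans — up to 30 under the
defaults. `drop_first_ring=True` excludes the innermost ring, yielding a
29-value series for workflows that treat the first ring as a positioning
ring rather than a measurement.

### Artery/vein labels

Mouse fundus arterioles and venules typically alternate around the disc
(~80% of eyes in common wild-type strains), and venules are wider. With
vessels ordered by angle, labeling reduces to choosing the phase of an
alternating pattern: `alternate_auto` anchors the vein phase at the widest
vessel; `alternate_anchored` pins one vessel's label; `manual` applies a
complete map for the minority of eyes violating the pattern. Focus-level
and dye-filling-time cues, which distinguish the vessel types in dynamic
imaging, are not computable from a single frame and are out of scope. Odd
vessel counts cannot alternate consistently around a circle; the seam
conflict is a warning, not an error. All-equal widths make auto-anchoring
ambiguous and raise an error directing the caller to an explicit anchor.

### Group statistics

Each image reduces to one value per metric and vessel class: the mean of
per-vessel mean diameters, the vessel count, and the combined diameter
(count × mean), a proxy for total vascularisation when groups differ in
vessel number. Unlabeled vessels count in "both" only. Combined diameter
is computed per image and then averaged per group (which supports group
error bars); the product of group-level mean count and mean diameter is
also reported (`combined_of_means`) since "mean number × mean diameter"
admits either reading.

Two-group comparisons use Shapiro–Wilk normality per group at alpha
(default 0.05); if both groups pass, a two-tailed pooled-variance
(Student's) t-test (`welch=True` for unequal variances), otherwise the
two-sided Mann–Whitney rank-sum test, with the exact null distribution
whenever the pooled sample has no ties and groups are small (n ≤ 25), the
normal approximation otherwise. Constant samples are treated as trivially
normal (Shapiro–Wilk is undefined there), so identical groups give t = 0,
p = 1. Effect sizes: `percent_of_reference = round(100·a/b)` and
`percent_increase = 100·(a−b)/b` to one decimal. P-values are reported
per comparison; a Holm step-down adjustment is available but off by
default.

## Synthetic data generator

The simulator emulates exactly the image features the algorithm relies
on:

- a bright circular optic disc (soft 1 px edge), default radius 36 px in
  a 320×320 8-bit frame, intensity 245;
- vessels as straight ribbons of specified perpendicular width leaving
  the disc edge, plateau intensity 230 (above the 204 threshold), with
  optional course obliquity and a quadratic bend to exercise chaining;
  edges are anti-aliased by a 1 px signed-distance ramp, because real
  vessel edges are not binary and this exercises the interpolation;
- background default 40 (dark, pigmented fundus) with an elevated
  variant (~120) emulating the raised background and reduced contrast of
  hypopigmented eyes;
- clipped additive Gaussian noise (Poisson noise is out of scope);
- the ground-truth mask as the ribbon union at the half-intensity
  contour, plus per-vessel centreline parameters, widths and alternating
  artery/vein labels.

Cohorts draw per-image vessel widths from Normal(mean, sd) per label
(clipped at 2 px), default 6 vessels (3 arteries, 3 veins) per image —
within the range reported for mouse retinas — with per-image child seeds
spawned deterministically from the cohort seed and recorded. Layouts are
rejection-sampled until ribbons are disjoint inside the annulus, since
oblique neighbours can converge.

What the simulator does **not** model: vessel taper and tortuosity beyond
the quadratic bend, capillary plexus, dye leakage, vignetting, focus
differences between vessel types, and realistic texture. Passing tests
therefore demonstrate the correctness of the scanning/chaining/measuring
machinery and of the statistics under known geometry — not robustness to
every property of real angiograms, where mask quality (the manual
selection) dominates accuracy.

## Numerical behaviour and known limitations

- **Systematic edge bias.** With mask enhancement, vessels are binary
  255-regions on a darker background; bilinear sampling turns each edge
  into a ~1 px ramp, and the 204 threshold sits 0.76 of the way up it, so
  each edge is localised ~0.26 px inside the vessel. Measured widths
  therefore run ~0.5–0.8 px below the rasterised truth — well inside the
  max(1.5 px, 5%) validation tolerance, and cancelling almost entirely in
  between-group *ratios* (a +16.7% generative effect measures ~+17.7% in
  expectation at these widths).
- **Exact-tie rasterisation.** A ribbon whose edges fall exactly on pixel
  centres (e.g. an even-width vessel perfectly aligned with the pixel
  grid) is a degenerate input: the half-intensity contour is ambiguous at
  the tie, and the measured width can jump by ~0.5 px. The simulator's
  mask uses the strict (> 0.5) side of the contour; validation layouts
  use generic angles.
- **Discrete end-point sampling.** The shortest distance is taken over
  end points sampled on rings (~2.5 px apart radially), not over a
  continuous edge, adding a small positive bias for very narrow, very
  oblique vessels; it is second-order for the widths validated (4–20 px).
- **Determinism.** Everything is deterministic given inputs and seeds;
  repeated runs produce byte-identical CSVs.
- **Validation problem sizes.** The standing experiments use a 36-cell
  width × obliquity grid, 100 seeded layouts for count recovery, and
  cohorts of 6 and 50 images per group for effect-size recovery — sizes
  at which the sampling error of the checks is small relative to their
  tolerances.

## Design choices where the design was open

- Ring spacing is uniform across the annulus (step `2·r_disc/(n_rings−1)`);
  any monotone spacing would do, uniform is the least surprising.
- The shortest-distance search runs over end points of **all** rings of
  the chain, not just the start point's own ring; the all-rings search is
  what makes the measurement obliquity-independent.
- Scan direction and origin (clockwise from 12 o'clock, y down) are a
  convention; any consistent choice yields the same diameters.
- RGB inputs default to the green channel, where fluorescein emission is
  imaged; ITU BT.709 luminance is available for non-angiographic use.
- JPEG input is accepted with a warning: block artifacts can displace
  threshold crossings by a pixel or more.
- Automatic optic-disc detection is deliberately out of scope; the disc
  centre and radius are user inputs, matching workflows where the disc is
  located by eye.
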