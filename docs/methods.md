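# Methods

This note documents the models and procedures behind `mechcomp`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions taken where the design was open.

## Coordinate and unit conventions

Physical positions are micrometres, times are hours, densities are cells
per 10,000 μm². Pixel origin is the top-left corner, x rightward, y
downward; physical coordinate = pixel × `pixel_size`; frames are 0-based
with frame 0 at t = 0. Velocity calibration is
(px/frame) × pixel_size / frame_interval = μm/h and is applied in exactly
one place (`VelocityField.to_um_per_h`).

## Density measurements

**Global density** is a count divided by an effective area. Effective
areas come from exclusion masks (`detection.apply_exclusion`): regions
with cysts, overexposure or no cells are removed from both the count and
the area, frame by frame.

**Local density** is the kernel crowding score
ρᵢ = Σ_{j≠i, dᵢⱼ ≤ r} exp(−dᵢⱼ²/2σ²), with σ = 20 μm and cutoff
r = 50 μm by default (`LocalDensityParams`). This form is dimensionless,
zero for an isolated cell and increasing with crowding. The alternative
literal reading "sum of Gaussian-weighted distances",
Σ d·exp(−d²/2σ²), *increases* with distance at short range and therefore
cannot be a density; it is nevertheless available for comparison via
`kernel="distance_weighted"`. σ is taken in μm (the cutoff is specified
in μm) and no normalisation constant is applied — the score is reported
on its natural arbitrary scale. Neighbour search uses a k-d tree; an
O(n²) all-pairs reference in the test suite agrees to 1e−12.

**Density–marker association** is Spearman rank correlation with
average-rank ties and a two-sided p-value (scipy's implementation, which
is exactly this algorithm); a hand-rolled rank-then-Pearson oracle
cross-checks it in the tests. Constant inputs raise rather than return
NaN.

## Detection, linking, drift

Nuclei are detected as local maxima of the σ²-normalised negated
Laplacian-of-Gaussian response above a relative threshold, refined to
subpixel by a separable quadratic fit on the 3×3 neighbourhood. This is a
standard, parameter-sparse substitute for wavelet spot detection and is
validated on rendered Gaussian spots (precision = recall = 1 at a 2 px
matching radius on noiseless 100-cell scenes, RMS error < 0.5 px).
Maxima in the outermost pixel row/column are discarded because they have
no fit neighbourhood — detection within one pixel of the image border is
out of scope.

Linking is optimal one-to-one assignment (Hungarian algorithm) between
consecutive frames minimising total squared displacement, with links
longer than `max_disp_um` forbidden; unmatched detections open new
tracks. There is no gap closing: the movies this emulates are densely
sampled, and determinism was preferred over recovering rare missed
detections. Linking is invariant to detection row order up to track
relabelling.

Drift is estimated per frame pair by subpixel phase correlation (images)
or by the mean displacement of assignment-matched centroids (detection
tables), and accumulated; subtracting it re-registers a series to < 0.2 px
residual in the round-trip test.

## Kinematics and migration onset

The directionality index D = net (Euclidean) displacement / total path
length lies in [0, 1]; zero-length paths are flagged undefined rather
than assigned a value. The population axis is the unit vector from winner
centroid to loser centroid. Front displacement per population is the
per-frame mean ± sd of each cell's displacement from its own start
projected on that axis, over cells with unbroken tracks.

The time base of a front-series pair is aligned so the first frame at
which *both* populations sustain a projected speed ≥ 2 μm/h for 4
consecutive frames maps to t* = 5 h. The 2 μm/h / 4-frame criterion is a
package choice (the qualitative description "formed a broad interface and
moved concertedly" fixes no threshold) and both knobs are exposed.

Migration onset is estimated by fitting, for every interior breakpoint, a
continuous two-segment piecewise-linear model (least squares on a hinge
basis) and keeping the minimum-SSE breakpoint. An exhaustive scan was
chosen over CUSUM-style detectors because it is deterministic and
oracle-checkable: on noiseless two-segment data the recovered breakpoint
is exact. An onset is only *reported* when |post slope| >
3 × |pre slope| **and** the slope change is ≥ 0.5 μm/h; the second gate
exists because a ratio alone fires on near-zero pre-slopes in flat noise.
"No onset" is a valid result. The winner→loser lag is the difference of
the two onset times; temporal resolution is one frame (0.25 h in the
default trajectory fixture).

## Shape and orientation

A cell's shape is the ellipse sharing its second central moments: full
axes are 4·√eigenvalue of the position covariance (for a filled ellipse
of semi-axes a, b the eigenvalues are a²/4, b²/4, so this recovers 2a and
2b), aspect ratio = major/minor ≥ 1, orientation is the major-eigenvector
angle, axial in [0°, 180°). Collinear input raises. Axis-vs-motion angles
are the acute angle between the unoriented major axis and the velocity,
in [0°, 90°], binned as [0°, 40°), [40°, 80°), [80°, 90°] — 40° bins over
an axial-deviation range whose last bin is narrower by construction. The
[0°, 90°] range was chosen because deviation between an unoriented axis
and a vector is inherently acute.

## PIV and kymographs

PIV is single-pass windowed cross-correlation (default 32 px windows,
50% overlap, no iterative window deformation — monolayer displacements
per frame are small relative to the window). Windows are mean-subtracted
and correlated linearly via zero-padded FFT; the correlation surface is
normalised by the per-lag overlap area, which removes the bias toward
zero displacement that circular correlation introduces. Displacements are
limited to ±window/2; the peak is refined by a Gaussian three-point fit,
and vectors whose first-to-second peak ratio falls below 1.2 (or whose
windows are featureless) are flagged invalid. Applied integer and
subpixel translations are recovered within 0.2 px in the tests.

Kymographs: each frame is shifted by minus its cumulative drift (bicubic
spline), rotated so the motion direction is horizontal (bicubic,
intensities clipped to the input range), max-projected across the
transverse dimension into one row, and the rows stacked by time. A
static movie therefore gives time-constant columns, and a drift-only
movie after correction matches the static kymograph within interpolation
tolerance. The phrase "projecting the maximum intensity of the centroid"
admits a second reading — projecting centroid positions rather than raw
intensity — implemented as `kymograph_from_scenes` (per-frame histograms
of projected centroids); the intensity projection is the default.

## Competition metrics

Growth rate is Δlog₂(count)/Δt per interval and doubling time its
reciprocal (finite differences, not curve fitting — the simplest faithful
reading of a "growth rate (doubling time)" profile); zero-count intervals
are skipped, zero rates report infinite doubling time. Death fraction is
events / total nuclei, after the caspase-3-positive-events over
DAPI-positive-nuclei readout.

"Fully surrounded" is operationalised geometrically: clone boundary cells
are the clone's convex-hull vertices; the clone is *surrounded* when
every boundary cell has an other-population neighbour within the contact
radius and no clone cell lies within that radius of the field edge,
*contacted* when only some do (or the clone touches the edge), *isolated*
when none do. The default contact radius (90th-percentile
nearest-neighbour distance of the scene) assumes the populations abut
directly; on synthetic scenes with a depleted annulus between clone and
winners a radius of about two cell diameters (≈ 20–25 μm at these
densities) is the appropriate setting, and the tests pass it explicitly.

Normalised time courses divide a count series by its pre-event mean; the
post-event plateau is summarised over the last 5 frames by default, and
`percent_at(t)` reads off specific time points (e.g. day 6 after
treatment). Standard two-sample comparisons (KS by default, Student's t,
rank-sum) are delegated to scipy and reported with the
*P*<0.05 / 0.005 / 0.0005 star convention.

## The synthetic generator

The generator produces every input the pipeline consumes, with ground
truth recorded for parameter recovery. Its presets encode the study
conditions (`src/mechcomp/presets.yaml`): a wild-type homeostatic plateau
of 61 cells per 10⁴ μm² on Ø 800 μm discs; a pure-loser confluent density
of one third of that (61/3 ≈ 20.33); a surrounded clone compacted
4.5-fold above pure losers inside a 500 × 500 μm winner field; a marker
rank correlation of 0.56; a 2 h winner-before-loser onset lag; a 3-fold
compression death multiplier; treatment endpoints of 74% (monoculture)
and 17% at day 6 (competition). The wild-type preset value 61 is used for
both winner and control fields — whether induced winner fields reach
exactly the uninduced plateau is not independently specified, so one
preset serves both roles.

**Point placement** is sequential-rejection hard-core sampling on a cell
grid (uniform proposals, acceptance iff no accepted point lies within
`min_spacing`), with a proposal budget of max(10⁵, 400·n); requests above
~70% of the triangular-lattice packing limit raise with the achievable
maximum. Counts are `round(density × area / 10⁴)` exactly, so density
operations recover presets up to rounding. Within-population and
cross-population spacing both hold; a free annulus of one `min_spacing`
separates the clone from the winner field.

**Marker intensities** couple each cell's empirical density normal score
Φ⁻¹(rank/(n+1)) to a latent normal via a Gaussian copula with Pearson
parameter ρ = 2·sin(π·r_s/6), the inverse of the Gaussian-copula Spearman
relation, then apply a log-normal marginal (median 100, log-sd 0.4). The
marginal is invariant to r_s; r_s = ±1 is special-cased to a
deterministic monotone map. The copula target is the pipeline's own
kernel density evaluated on the generated points — a deliberate,
self-consistent circularity appropriate for recovery tests.

**Trajectories**: persistent random walk (AR(1) heading with turn sd
(1−p)·π per step) at 4 μm/h before onset; after a population's onset,
headings are drawn von Mises about the inter-population axis with
concentration (p/(1−p))² at 12 μm/h (winners advance at t = 3 h, losers
retreat at t = 5 h in the default 12 h, 0.25 h-interval fixture with 80
cells per population). Cells are not reflected at the field boundary: the
field is a view into an extended monolayer, and an earlier reflecting
variant made post-onset displacement saturate against the far wall,
biasing change-point estimates early. A `directed_fraction` < 1 leaves
the remainder random-walking at the post-contact speed.

**Rendering** stamps each alive cell as an isotropic Gaussian of sd
`psf_sigma_px` (peak 1000 counts by default) and adds Poisson shot noise
and Gaussian read noise when requested, quantised to 8/16 bits.
Ground-truth scenes ride along on the `ImageStack`.

**Death events** are per-interval Bernoulli draws at
rate × Δt × multiplier (compressed) with dead cells staying dead. The
compression fixture is a single fixed-endpoint exposure (two scenes, 1 h
apart, 20,000 cells per condition), mirroring a fix-and-stain assay; with
one interval the expected compressed/uncompressed fraction ratio equals
the multiplier exactly, whereas long movies would saturate it below the
hazard ratio (1−(1−p)^T is concave). At this n the ratio's sampling sd is
≈ 0.13.

**Count time courses** follow deterministic mean paths — logistic growth
to a carrying count (homeostasis; rate 0.08 h⁻¹ from ~30% seeding),
logistic rise then exponential collapse (loser_collapse), flat baseline
then exponential relaxation to the endpoint fraction with τ = 24 h
(treatment_monoculture), and an exponential decline calibrated to pass
through the day-6 endpoint exactly (treatment_competition; only the
endpoint is specified, so the functional form is a package choice) —
with independent per-frame multiplicative log-normal jitter (cv 2%,
roughly Poisson-scale for ~2000-cell fields) and rounding to non-negative
integers. Real count series have temporally correlated residuals
(cells persist between frames); independent jitter was accepted for
simplicity and slightly *overstates* frame-to-frame noise.

### What the generator does not emulate

No mechanical force model, vertex/agent physics, cell divisions in the
point scenes, brightfield texture, cyst morphology (exclusion masks are
synthesised directly as rasters), segmentation-grade nuclear shapes, or
3-D structure. Passing recovery tests therefore demonstrates that the
*measurement operations* are correct and unbiased under realistic
statistical structure — not that they are robust to every real-microscopy
artefact (touching nuclei, focus drift, bleaching), which is out of scope.

## Problem sizes and determinism

All fixtures run in seconds on one CPU: the density/copula fixture uses
~10,000 cells, trajectories 160 cells × 49 frames, the death assay
2 × 20,000 cells, count series ≤ 73 frames, rendered test images ≤
300 × 300 px. Every stochastic step takes an explicit integer seed
through `numpy.random.default_rng`; identical config + seed gives
bit-identical scenes, tracks, images and counts (asserted in tests).
`scripts/acceptance.py` derives per-fixture sub-seeds from its `--seed`
argument and recomputes all reported quantities from scratch.

## Known limitations

- The onset lag is quantised to the frame interval; lags are only
  meaningful to ±1 frame.
- `classify_clone`'s convex-hull boundary is jittery for small or ragged
  clones, and the default contact radius is inappropriate when a depleted
  gap separates the populations (see above).
- PIV assumes displacements ≤ window/2 per frame pair and no rotation or
  strong shear within a window.
- The LoG detector does not split touching nuclei beyond what the
  scale-normalised response separates, and ignores the outermost pixel
  row/column.
- Exclusion masks are provided, not inferred: the pipeline does not
  detect cysts or overexposed regions itself.
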