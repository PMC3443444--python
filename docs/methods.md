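# Methods

## Image model and coordinate conventions

A B-scan is a (rows × columns) grid of intensities normalised to [0, 1];
the row index grows with axial depth (anterior surface at small rows),
the column index runs laterally.  Curves are stored as (column, row)
points so lateral position is the independent variable; every image
carries an explicit `Calibration` (µm/px lateral and axial), defaulting
to 18 µm/px — the axial-resolution class of time-domain anterior-segment
scanners — because export pixel pitches differ by device and must come
from the user.

## Phantom model

The synthetic scan contains

* a corneal band: a circular-arc anterior surface (apex row 60 px,
  sagitta 40 px across a 512-px width, i.e. a radius of ~840 px) of
  constant thickness 30 px at intensity 0.8 on a 0.05 background;
* a graft: the region between two shallow circular arcs sharing the two
  corner endpoints.  The anterior (interface) arc by default continues
  the posterior corneal surface through the corners; the posterior arc
  sits `graft_central_thickness` below it at the chord midpoint
  (default 10 px = 180 µm over a 280-px ≈ 5 mm chord, area ≈ 6.06·10⁵
  µm² at 18×18 µm/px).

The host–graft interface is rendered as an intensity step of
`interface_contrast` × band intensity (contrast 0 ⇒ graft
radiometrically identical to host stroma).  Speckle is multiplicative
unit-mean lognormal noise with scale `speckle_sigma` — the standard
first-order OCT speckle model; it reproduces exactly under a fixed seed.
Rendering uses 8× axial supersampling so boundaries have sub-pixel
radiometric position, and output is quantised to the 16-bit grid so
PNG round-trips are lossless.

Ground truth is analytic: the area between two arcs sharing a chord is
the difference of signed circular-segment areas,
A_seg = R² arccos((R−h)/R) − (R−h)√(2Rh−h²) with R = (a²+h²)/2h for
half-chord a and sagitta h.  Tests verify this against quadrature and
against the shoelace area of densely sampled outlines (0.1%).

What the phantom does **not** emulate: depth-dependent attenuation and
shadowing, refraction at interfaces, motion artifacts, the epithelial
layering of a real cornea, spatially correlated speckle, and blunt-cut
graft ends (the arcs share endpoints, so the corner pairs coincide).
Passing phantom tests therefore demonstrates correctness of the
geometry, the detection logic and the failure-mode mechanics — not
clinical-grade performance on scanner data.

## Automated pipeline

1. **Preprocess** — Gaussian smoothing, default scale 1 px (0 disables).
2. **Canny edges** — derivative scale 2 px; hysteresis thresholds are
   gradient-magnitude quantiles (0.80, 0.95), which makes the edge map
   invariant to affine intensity rescaling.  The gradient magnitude is
   kept alongside the binary map for tie-breaking and sub-pixel work.
3. **Boundary sampling** — one edge pixel per sampled column (default
   every 10 px, which damps speckle perturbation of the polyline).
   Selection policies: `strongest` (greatest gradient, ties toward the
   smaller row — the default), `deepest`, `shallowest`.  The pipeline
   uses the deepest-edge envelope: below the graft there is only
   background, so the deepest edge per column is the posterior boundary
   of host or graft.  Columns without edges are recorded as gaps, never
   interpolated.  Envelope rows are refined to sub-pixel position at the
   parabolic vertex of the axial intensity drop.
4. **Corners** — turn angles over a 10-sample k-cosine support along the
   envelope; candidates are peaks whose prominence exceeds both a 3°
   floor and 2.5× the local angle-noise scale (estimated from first
   differences).  A global z-score was tried and rejected: on the short
   structured envelope the smooth corneal-arc bend is about half the
   corner response, so corner z-scores saturate near 1.5.  The lateral
   extremes of the candidate set give the coarse corners (a lens cusp
   serves as both the anterior and posterior corner of its side); a
   fixed-window two-piece quadratic changepoint on the per-column
   envelope refines them to single-column resolution.

   Curvature alone, however, cannot place the corners accurately: within
   ~1.5×blur of the corner the interface and posterior edges merge into
   one gradient ridge and the observable kink sits 10–30 px inside the
   true corner.  The pipeline therefore moves each corner to where the
   graft posterior surface meets the host posterior surface: the host is
   fitted laterally to the span by a quadratic with one-sided robust
   trimming (graft tissue only ever hangs *below* the host surface, so
   positive residuals are trimmed aggressively and the fit converges to
   the upper support of the point cloud); the graft surface is either a
   quadratic through the reliable mid-span envelope (wide cores,
   ≥ 60 px, where the extrapolation is a small fraction of the support)
   or, for short cores, the zero-crossing of a line through the flank of
   the envelope's deviation from the host fit.  Corner refinement and
   the reliable-core estimate are iterated (≤ 3 passes) because each
   depends on the other.
5. **Interface extraction** — for every column between the corners, a
   band anterior to the posterior boundary is searched for the strongest
   *interior* local maximum of the downward intensity drop above an
   absolute floor (0.005 intensity/px).  Band top: 1.5× the median
   band-thickness estimate, where the estimate is the distance from the
   posterior boundary to the next detected edge above it — the interface
   itself when it is visible.  When the interface leaves no edges the
   next edge is the anterior corneal surface and the band balloons;
   detection then follows bright host-stromal speckle anterior of the
   true interface, which is precisely the thin-graft overestimation
   failure of automated analysis.  An anatomical ceiling (the host
   posterior extrapolation minus one median band thickness) bounds how
   far the overshoot can run.  The band ends 3 px above the posterior
   boundary so that boundary's own gradient tail stays out; columns
   whose geometric thickness lies inside that margin hold no resolvable
   interface and are excluded from the gap statistics.  Isolated picks
   ≥ 4 px (or 3 robust SDs) off the local median path are dropped.  If
   more than half of the resolvable columns yield no significant
   response, `LowContrastError` signals the thin-graft regime.
6. **Curve fitting** — cubic smoothing splines through the interface
   picks and the reliable posterior envelope points, with a residual
   budget of 1 px² per control point and an exact linear endpoint
   correction pinning each curve to its corners; gaps are bridged by the
   spline.  Thickness is checked at 257 columns: crossings deeper than
   2.5 px (beyond spline-overshoot scale) are invariant violations;
   shallower ones are clamped to zero thickness in all metrics.

The pipeline is fully deterministic given image + configuration; all
parameters live in `RunConfig` (TOML/JSON loadable, unknown keys
rejected).

## Semi-automated mode

`adjust_control_points` applies `(curve, index, (col, row))` edits,
re-fits, and re-validates single-valuedness, in-image position, shared
domain and non-negative thickness, rejecting a violating edit set with
the violated invariant named.  `snap_to_truth` expresses the ideal
observer: every control point moved onto the phantom's true arcs; tests
require the resulting area to land within 1% of truth, i.e. the
refinement API is sufficient to correct any automated error.

## Metrics

Area: the closed outline (anterior left→right, posterior right→left,
≥ 2 samples/px) is evaluated with the shoelace formula (via shapely) in
px² and scaled by the lateral×axial pixel pitch.  Orientation is
normalised so traversal direction cannot flip the sign.  A brute-force
oracle — counting sub-pixel raster points inside the polygon — agrees
within 0.5%.  The thickness profile is sampled at evenly spaced lateral
positions; its trapezoidal integral reproduces the area within 1%.

The trephine volume estimate multiplies the area in µm² by the trephine
diameter; the default convention keeps the diameter in mm without unit
conversion (20 000 µm² × 8.5 → 170 000), reproducing the published
arithmetic as printed even though the units are inconsistent; a
dimensionally consistent µm³ variant (`consistent_units=True`) converts
the diameter to µm first.

## Agreement statistics

Bland–Altman: differences d = a − b (first-listed arm minus second),
bias = mean(d), SD with n−1 denominator, LoA = bias ± 1.96·SD (the 1.96
multiplier is part of the method's definition, not a t quantile);
95% CIs use t(n−1): bias ± t·SD/√n, limits ± t·SD·√(3/n).

ICC: two-way ANOVA decomposition (subjects × raters), single measures.
The default is absolute agreement, ICC(A,1) =
(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) — the reproducibility
default of common clinical stats packages, sensitive to systematic
offsets between arms — with the McGraw–Wong F-based confidence bounds
(Satterthwaite df); a consistency variant ICC(C,1) is selectable.
Implemented from the mean squares directly; tests cross-check both the
point estimate and the CI against an independent published
implementation (pingouin) and a brute-force ANOVA oracle.

Degenerate inputs: zero total variance makes the ICC undefined (error);
identically zero differences define t = 0, p = 1 (and the table writer
flags the row's p as undefined); zero arm variance makes r undefined
(error).  MSE = 0 with subject variance gives ICC exactly 1 with CI
(1, 1).

## Acceptance-script problem sizes

20 phantoms per imaging condition (noise-free, speckle σ = 0.15, and the
thin/low-contrast condition), 20 random geometries for the raster
cross-check, and n = 200 subjects for the synthetic-observer agreement
study — sizes at which each statistic's sampling error is comfortably
inside the tolerance it is compared against, while a full run stays
under a minute.  The thin-graft condition uses `thin_graft_spec`
(closed-form area just below 80 000 µm², central thickness 6 px over a
~60 px chord at the default calibration) with interface contrast 0.12
and speckle σ = 0.10: an interface gradient at the speckle-gradient
level, the "not easily discernible" regime.

## Known limitations

* Corner accuracy for wide, shallow menisci relies on quadratic
  extrapolation of the graft surface; residual span error of 2–4 px is
  the dominant contribution to the ~1.5% automated area error on clean
  phantoms.
* The interface detector assumes the graft is darker than (or equal to)
  host stroma at the rendered step; inverted-contrast interfaces would
  need the drop sign flipped.
* Only lens-shaped (shared-endpoint) graft silhouettes are exercised by
  the phantom; blunt-ended grafts pass through the corner API (distinct
  anterior/posterior corners) but have no generator support.
* Full-thickness and anterior lamellar grafts, 3-D volume stacks and
  DICOM ingestion are out of scope.
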