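# Methods

## The scene generator

The generator emulates what a pedestrian-detection system sees in busy
urban streets: hourly still frames from fixed cameras, each frame a point
pattern of pedestrians on the walkable ground plane of the camera's
viewshed, modeled as a rectangle (default 650 m², aspect ratio 2.0, i.e.
about 36.1 m × 18.0 m). Coordinates are continuous Cartesian meters with
the origin at a rectangle corner; there is no grid discretization and no
identity tracking across frames.

**Crowd sizes.** Per-frame person counts are drawn from a negative binomial
truncated to [2, 67] by exact inverse-CDF sampling on the truncated
support. The defaults — dispersion r = 1.2, pre-truncation mean 8.0 — were
moment-matched so the truncated law has median 7 and SD ≈ 7.7, the
overdispersed, long-right-tail regime typical of street crowding. Frames
with fewer than 2 persons are excluded throughout (a person alone cannot
have a close encounter), so the truncation floor is 2.

**Companion groups.** Street pedestrians often walk with household members
or companions. Crowds are partitioned into groups with size distribution
P(1)=0.55, P(2)=0.30, P(3)=0.10, P(4)=0.05 (singletons and dyads dominate);
members are placed at a uniform distance within the companion-spacing band
of their group anchor, at a uniform angle. The spacing default is
U[0.5, 3.0] m. The band deliberately extends past the 1.5 m threshold:
it represents loose companionship (walking offset, single file, drifting
apart), and a band entirely inside 1.5 m would force every grouped person —
two-thirds of all persons under the group-size default — to violate,
pushing the person-level violation rate far above the ~0.44 the generator
is calibrated to reproduce.

**Anchor attraction.** Group anchors follow a sequential parent–offspring
process with a single knob c (`clustering_strength`): the first anchor is
uniform; each subsequent anchor attaches to a uniformly chosen earlier
anchor with probability c/(1+c) and is scattered around it with an
isotropic Gaussian (sd 2.0 m, rejection-sampled into the rectangle),
otherwise it is placed uniformly. At c = 0 with singleton groups this
reduces *exactly* to uniform independent placement — the same geometry as
the null model — which the tests exploit. A literal Thomas process would
need a second knob (parent intensity); the sequential form keeps one knob
and nests the uniform limit. Default c = 0.3.

**Calibration.** With these defaults the generator reproduces the intended
study conditions: person-level violation rate ≈ 0.45 (target band
0.38–0.50), frame-level violations-per-person slope ≈ 0.57 with R² ≈ 0.80,
and all per-camera slopes positive across 49 cameras. Per-camera
heterogeneity of areas and crowding is not modeled by default (all cameras
share one viewshed spec); the `ViewshedSpec` list passed to
`generate_dataset` is the hook for it.

**Randomness.** One root seed; per-camera and per-frame child streams are
derived through `SeedSequence([seed, camera_index, frame_index])`, so
output is byte-for-byte reproducible and independent of generation order.

**What the generator does not emulate.** Detection noise (missed or
spurious detections, localization error), camera-specific occlusion and
viewshed shapes, temporal correlation between consecutive frames,
day/time-varying crowding, and any behavioral response beyond static
attraction. Tests passing on this synthetic data show the *pipeline* is
correct and that the analysis recovers known structure; they do not
validate substantive conclusions about real pedestrians.

## Proximity scoring

Violations use the closed ball: distance ≤ threshold counts. "Within a
1.5-meter radius" is a measure-zero boundary choice with no statistical
effect, but fixing it keeps tests bit-exact. Distances are Euclidean in the
ground plane. The neighbor search uses a k-d tree (`scipy.spatial.cKDTree`),
which is exact; the brute-force O(n²) double loop is the normative
definition and the test oracle. Group identity, although known to the
generator, is never used in scoring — the ≥2-contact outcome (`violation2`)
is the only household proxy, mirroring what a detector-based study can do.

## Inference

* **LPM with cluster-robust SEs.** OLS point estimates; sandwich variance
  with CR1 small-sample scaling G/(G−1)·(N−1)/(N−k) (the Stata default,
  switchable to CR0 via `small_sample=False`), clusters = still frames.
  Implemented through statsmodels' `cov_type="cluster"`; an independently
  coded sandwich formula in the tests confirms agreement to 1e−10. With
  every observation its own cluster, CR1 collapses exactly to HC1 (both
  scale by N/(N−k)), asserted in the tests.
* **Confidence intervals** use normal quantiles (z = 3.4808 at 99.95%,
  z = 2.8070 at 99.5%); with thousands of clusters the t correction is
  negligible, and the choice is documented rather than silent.
* **Camera fixed effects** are absorbed by within-camera demeaning of
  outcome and predictor, which is exact for the slope. The small-sample
  correction keeps k = 2 (intercept + slope); the absorbed camera means are
  not counted, which with ~1,000 observations per camera changes SEs in the
  third decimal at most.
* **Winsorizing** caps values above the Tukey outer fence Q3 + 3·IQR, with
  type-7 (linear-interpolation) quartiles — the fence value depends on the
  quartile algorithm, so it is pinned. Idempotent by construction.
* **Binned scatterplots** use equal-count quantile bins (default 20; the
  method convention leaves the count free): stable sort by x, split into
  chunks whose sizes differ by at most one, plot within-bin means.
* **Krippendorff's α** is computed from the full coincidence matrix with
  squared-difference distance at the interval level (ratio available);
  counts of violations per frame are interval-scale ratings here. If every
  rating is identical the expected disagreement is zero and α = 1 by
  convention, flagged `degenerate`. Hand-implemented because no installed
  package provides it; verified against a literal nested-loop computation.

## Null model

Uniform placement of n points in a rectangle of area A (aspect 2.0, plain
boundary by default — a literal street rectangle), counting pairs within
d = 1.5 m and persons with ≥1 such neighbor. Defaults: A ∈ {650, 300, 150}
m², 10,000 replicates per n, per-n child RNG streams. Coincident points are
allowed (no hard-core radius), matching pure random location assignment.

The no-edge expectation C(n,2)·πd²/A is exact on the torus, so a torus mode
exists purely as an analytic validation device; the plain rectangle is
bounded above by it (edge effects are one-signed). For n = 2 the exact
plain-rectangle close-pair probability is the classical rectangle
line-picking CDF

    F(d) = [π·w·h·d² − (4/3)(w+h)·d³ + d⁴/2] / (w²h²),   d ≤ min(w, h),

used as the simulation oracle (cross-checked against numerical integration
during development).

The capacity figure uses the linear convention floor(A/d) — 650/1.5 → 433.
It is not a packing bound; the geometrically correct hexagonal-packing
capacity floor(2A/(√3·d²)) = 333 at 650 m² is exposed alongside as
`capacity_hex_packing`, clearly labeled, and the divergence between the two
conventions is deliberate and documented.

`compare_observed_to_null` interpolates null curves linearly at crowd sizes
not simulated and flags those rows; whether a study's frame-level violation
count means violating persons or violating pairs is ambiguous in general,
so both overlays are computed (pairs are the quantity the null simulation
defines; violators are the person-level aggregate).

## Pipeline

Stages communicate via on-disk CSVs so each is independently re-runnable;
the manifest records config, seeds, row counts, wall times and SHA-256
checksums. Figures render to SVG and PNG with their data always emitted as
CSV, so tests never read pixels. Default problem sizes — 49 cameras × 100
frames (~47,000 persons), 10,000 null replicates per crowd size, 500
parameter-recovery replicates — were chosen as the smallest sizes at which
the stochastic calibration bands are comfortably resolved.

## Numerical choices and degenerate inputs

* Cluster-robust variance can be exactly zero in degenerate fixtures
  (e.g. two symmetric clusters); tiny negative diagonals from floating
  error are clamped to zero before the square root.
* Truncated crowd distributions with (near-)zero mass inside the truncation
  range raise a configuration error rather than looping.
* `threshold_m = 0` is allowed in the null model as a degenerate check (all
  means zero) but rejected in scoring and generation.
* Off-rectangle placement proposals are rejection-sampled up to 50 times,
  then clipped; clipping is a boundary event with negligible mass at the
  default scatter scales.

## Known limitations

Static single-moment analysis only: no exposure duration, no movement, no
social-force dynamics. The LPM is linear by design (the binned scatter is
the tool for functional form); logistic alternatives are out of scope. The
synthetic calibration matches a handful of reported marginal statistics,
not joint distributions of real footage; per-camera heterogeneity defaults
to none.
Spatial autocorrelation is addressed only by frame clustering and
frame-level aggregation.
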