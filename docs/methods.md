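# Methods

This note documents the models, conventions and numerical choices behind
`swarmspace`, and what the synthetic-data tests do and do not establish
about real trajectory data.

## Kinematic preprocessing

Trajectories arrive as per-individual fix sequences. Geographic coordinates
are projected with a local equirectangular map about the dataset centroid
(x = R·cosφ₀·Δλ, y = R·Δφ, R = 6 371 000 m); at the few-kilometre extent of
a herd or troop the distortion is far below the GPS error floor, and no
external projection database is needed. Fixes are linearly interpolated onto
a regular grid of spacing `dt`; frames strictly inside an observation gap
longer than `max_gap` are marked invalid rather than bridged.

Headings come from central differences of position (one-sided at the ends),
which keeps heading consistent with the realized path; speed is the
displacement rate smoothed by a centered rolling mean spanning
`smooth_window` seconds with a floor of 3 samples (the simplest defensible
smoother; the window is configurable). A member's heading is undefined on
frames where its displacement is below 0.05× its own median inter-frame
displacement — direction is noise-dominated for a near-stationary animal,
and excluding it is conservative for polarization.

Polarization P(t) is the modulus of the mean unit-heading vector over
members with defined headings (1 = perfectly aligned, 0 = no net
alignment); group speed V(t) is the mean smoothed member speed. Both are
undefined (NaN) with fewer than two qualifying members. Angles are degrees
at every interface and radians internally.

## Event segmentation

A frame passes detection iff V(t) ≥ the q-quantile of V and P(t) ≥ the
q-quantile of P (linear-interpolation quantiles over defined frames); the
same q is applied to both variables, per dataset. Events are maximal runs
of passing frames; runs separated by at most `max_gap` failing frames can
be merged (default 0 — strictly uninterrupted — but GPS dropouts make
strict contiguity brittle in the field). Frames with undefined polarization
fail detection.

Event duration counts `n_frames × dt` (each frame represents one sampling
interval), so `end_t` is exclusive: a 100-frame run at 1 Hz is a 100 s
event. Events shorter than the minimum representative window (default 15 s)
are dropped before any metric analysis.

Choosing q: the threshold must lie below the fraction of time the group is
*not* in collective motion, otherwise it lands inside the coordinated
distribution and fragments genuine events. Datasets where coordination is
the norm warrant small q (0.05); datasets where it is rare warrant large q
(0.9).

## Local and group metrics

For each frame: pairwise Euclidean distances; topological neighbour ranks
(ties broken by member order); the signed bearing angle β from a focal's
heading to each neighbour's position, positive to the focal's right, in
(−180°, 180°]; and frontness f = |β|/180 ∈ [0, 1] (1 = focal directly in
front of the neighbour, 0 = directly behind). Per-focal frontness and |β|
are first averaged over all of that focal's neighbours, then averaged (and
sample-SD'd) across focals, weighting individuals equally. By construction
the frame mean of |β| equals 180× the frame mean of frontness over the same
relation set — the two metrics are collinear, which is why the mean
absolute bearing is kept in the event vector but excluded from embeddings
by default.

Group shape is the acute angle θ ∈ [0°, 90°] between the group heading
(direction of the resultant unit-heading vector — "group heading" admits
several definitions and this is the one adopted) and the short-side
direction of the minimum-area rotated bounding rectangle of member
positions, normalized to s = θ/90. 90° is a group elongated along its
direction of motion, 0° a perfectly wide group. The box comes from the
convex hull (rotating-calipers optimum via shapely). Degenerate inputs:
collinear groups get a zero-width box whose short side is perpendicular to
the line; coincident groups have no shape; for an exactly square box the
side making the smaller angle with the heading is declared short
(deterministic tie-break, relative tolerance 1e-9).

**Non-uniqueness caveat.** The minimum-area box orientation is not always
unique: every edge-flush box of an acute triangle has area 2× the triangle
(hulls of 3 points always tie), and exact ties between distinct
orientations occur with positive probability even for quadrilateral hulls
(verified in the test suite with exact rational arithmetic). On such frames
the shape angle depends on which optimal box the solver returns, for any
implementation. This matters only for very small groups (shape is reported
from n = 3 up); at the 5–34 member sizes the pipeline targets, hulls are
larger and ties have measure zero. The rigid-motion invariance test
therefore skips shape comparison on exactly-tied frames and asserts that
such frames remain a minority.

The 10-component event vector: means over frames of {NND, |β|,
polarization, shape}; sample SDs (ddof = 1 throughout) over frames of
{NND, polarization, shape, group speed}; means over frames of the
within-group SDs of {NND, frontness}. Events with fewer than two
metric-defined frames are dropped. Neighbour-density maps histogram β by
topological rank (1–4 by default), normalized per rank.

## Swarm space

Metrics are z-scored (sample SD) and the correlation matrix
eigendecomposed. Eigenvalues then sum to the number of metrics and are
interpretable against 1 (an axis below 1 carries less variance than a
single metric). Loadings are unit eigenvectors with signs fixed so each
axis's largest-|loading| metric loads positive (reproducible across
linear-algebra backends); scores are the z-table times the loadings, so
per-axis score variance equals the eigenvalue. Contributions follow the
factor-map convention, 100× squared loading, summing to 100 per axis.
Metrics whose maximum contribution over the first `n_axes` (default 3) axes
falls below the uniform reference 100/p are flagged and the PCA refitted on
the retained set. Covariance-matrix PCA is available behind
`standardize=False` but forfeits the eigenvalue-vs-1 reading.

t-SNE (scikit-learn) complements the linear map: perplexity 10 and 10 000
iterations by default to emphasize local structure, deterministic given a
seed, with learning rate and exaggeration recorded in the output metadata.
It requires at least 3× perplexity rows. Tests use fewer iterations; the
defaults are for analysis runs.

## Snapshot representativeness (ICC)

For each candidate duration, one uniformly placed contiguous window is
drawn per eligible event (one window keeps events independent as subjects)
and the window means of polarization and shape are paired with full-event
means. Agreement is ICC(A,1) — two-way random effects, absolute agreement,
single measure (computed by pingouin), the variant that penalizes constant
offsets, with its F-based 95% CI. The minimum representative window is the
smallest tested duration whose ICC reaches `icc_min` (default 0.9) in
every dataset simultaneously — an explicit operationalization of what is
otherwise a judgment call; when no duration qualifies the largest tested
one is returned with a warning. The ICC is undefined without
between-event variance: if all events of a dataset have essentially the
same true mean, no snapshot length can demonstrate agreement, and the
analysis needs more heterogeneous data rather than longer snapshots.

## Reliability of cumulative means

Per metric, events are ordered chronologically and the cumulative mean
series y_k (k = 1..n) is analysed:

* **Broken line.** y_k = a + b·(min(k, τ) − τ): slope b before τ,
  exactly flat at level a after, continuous at the join. τ is profiled
  over the integer grid 2..n−2 (events are discrete); a, b by least
  squares per τ. Significance against the flat-mean null uses the
  likelihood ratio n·log(RSS₀/RSS₁) with a χ²(1) reference. The CI for τ
  collects grid points with n·log(RSS(τ)/RSS(τ̂)) within the χ²(1)
  cutoff, extended one grid step outward on each side because the
  continuous-τ boundary falls between integers; both 95% and 90% sets are
  reported. A flat series (no RSS improvement) is flagged non-informative
  with τ̂ pinned at n−2.
* **Bootstrap.** Events are resampled i.i.d. with replacement — order is
  destroyed on purpose — and τ̂ refitted per replicate (default B = 10 000,
  seeded). Because the resampled pool has no intrinsic change-point, the
  replicate distribution is wide; the informative outputs are the median
  (near the original estimate when order carried no special information)
  and the percentile interval.
* **KPSS.** Level-stationarity test (statsmodels) with Bartlett-window
  long-run variance and lags = ⌊4(n/100)^0.25⌋ — the short-lag rule; the
  p-value is interpolated from the standard critical-value table and
  clamped to [0.01, 0.1]. A zero-variance series is stationary by
  convention. With these lags the test holds its nominal size on white
  noise (~6% rejections at 5%) and rejects random walks in ≳95% of cases
  at n = 200; longer lag rules sacrifice that power.

The report crosses the two verdicts per metric × dataset: *change-point*
(significant, non-stationary — an informative stabilization estimate),
*change-point (stationary)* (significant but the series is stationary, so
the estimate is uninformative), *stationary*, and *no change-point* (more
data needed, or the variability is itself characteristic). Note that the
cumulative mean of i.i.d. noise settles like 1/√k, which the broken-line
test legitimately detects; the KPSS cross-flag exists precisely to qualify
such cases.

## Synthetic data

The generator emulates the study conditions of the real systems: group
sizes 5–34, sampling intervals 0.02–1 s, alternating
coordinated/uncoordinated regimes, controllable formation, NND scale and
heading noise. Members start on a rigid lattice (column, line abreast,
45° echelon, or isotropic Gaussian blob scaled to the target NND) with a
static positional jitter of 10% of the target NND so nearest-neighbour
statistics are nondegenerate, then integrate independent steps of length
(speed draw)·dt in direction (travel heading + von-Mises noise). Von-Mises
noise is the circular-statistics standard; κ = ∞ gives exact rigid
translation (polarization 1), κ = 0 uniformly random headings, whose
downstream polarization matches the Rayleigh mean-resultant-length
expectation. Uncoordinated phases use κ = 0 at a tenth of the base speed so
both detection criteria fail jointly. Phases may override base parameters
so consecutive events differ in coordination strength, as real events do.
Defaults (10 members, 2 m NND, 1 m/s, κ = 20, dt = 0.5 s) describe a
mid-sized terrestrial group.

What the generator does *not* emulate: interaction rules
(attraction/alignment/avoidance), so members drift apart slowly under
heading noise instead of re-cohering; GPS error; fission–fusion of group
membership; 3D motion. Passing tests therefore establish the correctness of
the measurement pipeline on motion with known ground truth, not the
biological realism of any particular dataset.

The metric-sequence generator plants a change-point directly: the target
cumulative mean follows the broken line c_k = level + slope·(min(k, τ) − τ)
and per-event values are recovered by telescoping, x_k = k·c_k −
(k−1)·c_{k−1}, plus i.i.d. Gaussian noise. Noiseless sequences are
recovered exactly; at n = 200, τ = 25, noise SD 0.1 the planted index is
recovered with median error 0 and the 95% CI covers it in ≥90% of seeds.

## Problem sizes in tests

The suite runs simulation studies at deliberately modest sizes chosen to
make the statistical assertions stable: 100 seeds for change-point
coverage (n = 200 events), 1000 seeds for KPSS size/power (n = 200), 50
seeds for ICC monotonicity (15 events × 40 frames), 200 random frames for
metric-oracle equivalence, 50 events per formation for the
swarm-space separability check. The bundled demo uses four pseudo-species
with 10 coordinated phases each.
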