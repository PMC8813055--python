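# Methods

`endozone` quantifies the organization and dynamics of the postsynaptic
endocytic zone (EZ) — the stable clathrin-coated structure sitting next to
the postsynaptic density (PSD) of excitatory synapses — from three kinds of
data: single-molecule localization tables (dSTORM-level), time-lapse
movies/traces (spinning-disk level), and binary puncta masks
(confocal/STED level). Every analysis is exercised end-to-end on a
synthetic-data generator with known ground truth; this note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Localization preprocessing (`loc_io`)

A localization table has columns `frame, x, y, precision, channel`
(coordinates in nm, image convention: origin top-left, y down; frames
0-based). Two preprocessing steps precede all geometry:

* **Consecutive-frame merging.** One fluorophore blinking event produces a
  run of localizations over consecutive frames. Runs are found as connected
  components of the graph that links localizations of the same channel in
  adjacent frames (optionally across `max_gap_frames` dark frames) within
  `merge_radius` (default 30 nm; twice the precision cutoff — the radius is
  not dictated by the data, only its order of magnitude). Each run is
  replaced by its precision-weighted mean position with pooled SD
  `1/sqrt(sum 1/sigma_i^2)` and the run's first frame. The single-pass
  collapse is iterated to a fixed point, which makes the operation exactly
  idempotent; component-based linking also makes it independent of row
  order. At realistic acquisition lengths (10,000 frames) chain-merging of
  distinct molecules costs ~1% of molecules.
* **Precision cutoff.** Rows with localization precision above 15 nm are
  discarded (boundary inclusive). The cutoff is read as a precision filter
  applied after merging; a merge-radius reading of the same number is
  available by passing a different `merge_radius`.

All region tests (ROI crops, ring membership, association discs) use
closed boundaries: a point on the edge is inside.

## Cluster geometry (`nanomap`)

**DBSCAN.** Standard semantics (core point: >= `min_pts` neighbours within
`eps`, self included), delegated to scikit-learn; the printed parameter
pairs are eps 0.2 µm / 100 points for PSD-scale maps and 0.35 µm / 50
points for EZ and accessory channels. The unit-less eps values are
interpreted as µm — 200 and 350 nm are the only physically sensible
neighbourhood scales for 150–250 nm structures. Tests pin the
implementation to a brute-force density-expansion oracle, label-for-label.

**Borders.** A cluster's outline is the convex hull of its member
localizations by default (counter-clockwise simple polygon); an alpha-shape
(maximum triangle circumradius `alpha_nm`) is available for concave
structures. Known limitation: any extreme-point outline is biased outward
under localization noise — the hull of n noisy points overshoots the true
boundary by roughly the expected maximum of the radial noise (≈ +10%
linear at sigma = 8 nm, n = 2000, even after merging). Measurements made
*relative to the same border* (as ring profiles of real data always are)
are insensitive to this; comparisons against an independent ground-truth
border are not, and the edge-recovery acceptance check is therefore run in
the low-noise limit where the derivation that places the Beta(8,2) mode in
the 80–100% ring actually applies.

**FWTM dimensions.** Principal axes from the covariance of member
positions; 1D histograms of the projections (bin 5 nm) smoothed with a
Gaussian (sigma = 2 bins); full width where the smoothed profile stays
>= 10% of its maximum, with linear interpolation at the crossings. The
broadening introduced by the estimator itself (smoothing kernel plus
bin-quantization variance) is subtracted in quadrature, so a Gaussian
cluster of SD sigma measures `2*sqrt(2 ln 10)*sigma` (= 214.6 nm at
sigma = 50 nm) without bias. Degenerate clusters (zero spread) measure 0.

**Signed distances.** `distance_to_border` and
`border_to_centroid_distance` are negative inside the polygon, positive
outside, zero on the boundary — so a histogram of accessory-protein
distances peaking "within 25 nm of the edge" straddles 0.

**Primary/secondary classification.** Among the clathrin clusters near one
PSD, the largest-area cluster is the primary structure (the EZ); ties go
to the cluster nearer the PSD border.

**Scaled rings.** Ring k is the region between the border scaled by
`edges[k]` and `edges[k+1]` about its centroid (homothety), with the
standard edges 0–20–40–60–80–100–120–140–160%. For any simple polygon the
scaled copy's area is exactly f² times the original, so ring area
fractions are the analytic `(f2² − f1²)/1.6²`, polygon-independent. The
nesting of the scaled copies (and hence the ring regions and the
normalized-radius binning) additionally requires the border to be
star-shaped about its centroid — always true for the convex default.

**Ring density profile.** Each query localization gets a normalized radius
(its centroid distance divided by the border crossing distance along its
ray, computed by vectorized ray-edge intersection). `loc_fraction[k]` is
the fraction of query points (among those within the 160% scale — points
beyond it are excluded from the denominator) in ring k; density is
`loc_fraction/area_fraction` renormalized to unit sum. "Normalized to 1"
is ambiguous between unit sum and unit max; unit sum is the default and
`normalize="max"` is available. Per-EZ profiles are averaged
arithmetically for population plots.

## Morphometry (`morphometry`)

Feret (caliper) diameters of binary masks: maximum pairwise distance
between pixel centers plus one pixel (length), and the minimum caliper
width over orientations plus one pixel (width), via rotating calipers on
the convex hull; a single pixel measures one pixel in both. Circularity is
`4*pi*A/P²` with the perimeter from marching-squares contour tracing
(pixel-count perimeter estimators collapse on 1-px-wide structures),
clipped to 1. EZ–PSD association: a PSD is positive when at least one
8-connected mask component intersects the closed disc of diameter
`roi_diameter_um` (default 0.79 µm, midpoint of the 0.69–0.89 µm range
used for synaptic regions) centered on it; the number of distinct
intersecting components is the CCS-per-PSD count.

## Dynamics (`dynamics`)

**Kymographs.** Rows = time, columns = distance along a polyline sampled
at ~1 px, max-projected across `line_width_px` perpendicular offsets
(bilinear interpolation).

**Direction filtering.** In the 2D DFT of a kymograph, a feature moving at
v px/frame lies on the line `k_t = −v (T/L) k_x`. The spectrum is
partitioned into three conjugate-symmetric masks: a stationary band of
`band_t` bins around zero temporal frequency (default 1 bin — exactly the
`k_t = 0` row, where time-constant structures live), and the remaining
half-plane pairs with `sign(k_x·k_t) < 0` (anterograde) and `> 0`
(retrograde). The spatial-DC column and any Nyquist rows/columns join the
stationary mask so that every mask is conjugate-symmetric: the three
inverse transforms are then real and sum *exactly* to the input (Parseval
partition). Physical limits worth knowing: motion slower than ~1 px/frame
leaves genuine energy in the stationary band of a short (61-frame)
acquisition, and motion faster than ~2 PSF sigmas/frame temporally
aliases (dotted lines whose spectrum wraps across Nyquist). The synthetic
generator's default speeds (1.8–3.6 µm/min at 5 s/100 nm sampling, i.e.
1.5–3 px/frame) sit between these limits for exactly these reasons.

**CV, tracking, lifetimes.** Intensity CV is sample SD / mean. Track
linking is greedy nearest-neighbour frame-to-frame assignment under
`max_link_nm` with optional gap closing — sufficient for sparse synaptic
puncta, and provably optimal when spots are well separated; it is not a
global LAP solver, a documented limitation for dense scenes. Lifetime =
(last − first + 1) frames × interval. Classification uses the strict
boundaries: short < 3 min, persistent > 9 min (exactly 3 or 9 min is
intermediate); a synapse is "stable" if any of its tracks persists
> 9 min. Tracks touching the first or last movie frame are flagged
censored.

## FRAP (`frap`)

Double normalization: `I_norm = [(roi − bg)/(ref − bg)] / baseline mean`,
then re-zeroed at the first post-bleach frame,
`F = (I_norm − I_norm(0⁺))/(1 − I_norm(0⁺))`, which removes background,
acquisition photobleaching (via the unbleached reference) and the residual
post-bleach intensity, so the mobile fraction is read directly from the
plateau. A flat trace (no bleach) raises rather than dividing by ~0.
`fit_frap` runs bounded least squares of `F(t) = A(1 − e^{−Kt})` with
A ∈ [0, 1.5], K > 0, initialized at the last observed value and the
inverse half-rise time; non-convergence is returned as a flagged fit, not
silently replaced. All points are weighted equally on the non-uniform
acquisition schedule (2 min baseline at 20 s; then 3 min at 20 s, 12 min
at 60 s, 4 min at 120 s — 19 min of recovery).

Identifiability caveat: when only a fraction of the plateau is observed
(e.g. tau = 36.2 min in a 19-min window), A and K are almost perfectly
anticorrelated and per-trace fits at realistic noise do not constrain the
mobile fraction (linearized sd(Â) ≈ 0.8 at sigma = 0.05). The analysis
drivers therefore normalize each cell's trace and fit the
population-averaged curve, which recovers both parameter sets used in the
study (fast: A = 0.758, tau = 13 min; slow: A = 0.38, tau = 36.2 min)
from cohorts of 14–30 traces.

## Synthetic data (`synthetic`)

The generator emulates, with tractable parametric ground truth:

* **SMLM scenes** — a disc-shaped PSD cluster (radius 180 nm), an
  elliptical EZ (semi-axes 112 × 73 nm, i.e. ~225 × 146 nm across,
  area ≈ 25.7 × 10³ nm²) whose centroid sits 10.6 nm outside the PSD
  border, and an accessory channel placed at radius
  `r = R(θ)·Beta(edge_alpha, edge_beta)` along uniform directions from the
  EZ centroid (Beta(1,1): uniform radius fraction; Beta(8,2): edge
  enrichment with mode at r = 0.875). Each molecule blinks as a geometric
  run of consecutive frames (mean `blink_run_length`) over a 10,000-frame
  acquisition, jittered by isotropic Gaussian noise of SD
  `precision_sigma` (default 8 nm; the precision column carries sigma).
  The EZ border is convex by construction so border-method choice cannot
  confound recovery tests.
* **Dynamics scenes** — a 20 µm 1D line movie (100 nm px, 5 s interval,
  5 min) of Gaussian spots (PSF sigma 1.5 px): stationary particles with
  multiplicative intensity fluctuations (CV 0.06) and moving particles at
  1.8–3.6 µm/min whose trajectories stay in-field; the stationary/
  anterograde/retrograde component movies are returned separately as
  ground truth. Plus an event stream on a sparse spatial grid with
  two-exponential mixture lifetimes (default p = 0.5, means 1.5/15 min),
  and raw FRAP recordings on the 19-min schedule with reference
  photobleaching, residual post-bleach intensity and additive noise.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate on real data: fluorophore photophysics beyond geometric
runs, drift, chromatic offsets (two-color registration is assumed already
applied), non-convex or fragmented EZ outlines, heterogeneous per-molecule
precision, spot-detection errors in movies (detections are given), and
crowded scenes where greedy linking would need a global assignment solver.

## Problem sizes

Tests and the acceptance script use: 100 scenes of ≤ 500 points for the
clustering oracle; 50 scenes × 10⁴ points for the flat ring-profile null;
100 scenes × 2000 localizations for edge-enrichment recovery; 10⁴ points
for the FWTM check; 500 point/polygon pairs for signed distances; 100
noise replicates for FRAP; 3 seeded movies for direction separation; 1000
events for the lifetime mixture. The full suite runs in well under a
minute on one CPU.
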