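# Methods

## Chamber geometry

Soil-mimicking layouts start from a face-centred cubic (FCC) bed of unit
spheres (lattice constant 2√2, so neighbouring spheres touch). FCC is one
canonical close packing; it is easy to enumerate and its symmetry-plane
families ({100}, {110}, {111}) are known, which matters because the section
plane must avoid them: a cut parallel to a symmetry plane produces a
regular, crystal-like column array rather than the irregular arrangement of
natural grains. Planes within 5° of any symmetry family are rejected; the
default normal (1, 0.37, 0.22) clears every family by a wide margin and the
default offset passes through the bed centroid.

Grain-size heterogeneity is modelled by redrawing every sphere radius
i.i.d. uniform on [0.4, 1.0] (centres stay on the lattice). The section of
a sphere of radius r at centre distance d < r is a circle of radius
√(r²−d²). Section circles are mapped to physical units by one linear scale
anchoring the largest circle to 200 µm; circles scaling below 80 µm or
protruding beyond the chamber are discarded, so all columns lie in the
80–200 µm radius range of fine-to-medium sand. Radius perturbation can
leave two section circles overlapping; since fused columns are not
manufacturable, the smaller member of an overlapping pair is shrunk until
tangent with a 5 µm clearance (and dropped if that takes it below 80 µm).
Columns keep a 25 µm margin from the chamber walls. The mapping of
arbitrary units onto [80, 200] µm (anchor at the maximum, filter below the
minimum) and the overlap rule are this package's choices; only the final
range itself is a design constraint of the emulated devices. One integer
seed drives the single NumPy generator used for the whole construction, so
layouts are bit-reproducible.

Defaults (`generate_soil_layout`): 6 FCC cells per axis, 4000×2000 µm
chamber, 75 µm depth. This yields ~25–40 columns and ~40–70 tessellation
regions per chamber — enough regions for region-level statistics while
keeping images at a tractable size.

## Wall shear stress

For a rectangular channel the floor shear is τ = (Δp/L)(H/2). The default
model is plane Poiseuille flow (parallel plates), for which
Δp/L = 12αU/H² and hence τ = 6αU/H, with α the dynamic viscosity
(10⁻³ Pa·s for water), U the mean speed and H the channel height. At the
typical operating point (U = 175 µm/s, H = 75 µm) this gives τ = 0.014 Pa.
An optional rectangular-duct mode computes Δp/L from the classical series
solution (truncated at 20 odd terms), which accounts for side-wall drag:
at fixed U it exceeds the parallel-plate value by a factor ≈ 1/(1−0.63·H/W),
i.e. ~6.7% at W/H = 10, converging below 1% only for W/H ≳ 65. The two
routes therefore agree only in the wide-channel limit, and the test suite
checks their 1% agreement at W/H = 100.

## Tessellation region analysis

The unit of spatial analysis is the triangular region of the Delaunay
triangulation of column centres (columns are nodes, centre-to-centre
segments are edges). Delaunay is the unique triangulation in general
position and matches the visual geometry of such chamber analyses; regions
outside the convex hull of the nodes (near chamber walls) are excluded.
Masks are rasterized at image resolution: each pixel belongs to the
triangle containing its centre (scipy's point locator; deterministic,
including its tie behaviour on edges), and pixels under a column disk are
removed from every region's *effective* mask. Conservation — effective
plus column-overlap area summing to the hull area — holds to well within
0.5% at the default 8 µm/px.

Column detection inverts the image (columns are dark PDMS disks on a
fluorescent background), thresholds it (Otsu), and lets the disk boundary
pixels vote in a circular Hough transform over the expected radius range;
each accepted peak is then refined to subpixel accuracy using the centroid
and equivalent-disk radius of its connected dark component. When a layout
file is available, registration (µm → px division) replaces detection.

Occupancy calls threshold the distribution of per-region mean intensities,
not pixels: Otsu (default) or background median + k·MAD (k = 5). A region
mean exactly at the threshold calls negative. Otsu makes the calls
invariant to affine intensity rescaling. Flow calls binarize the
max-projected bead-streak stack at the global median + 5·MAD and score a
region *open* when streak pixels cover at least `min_coverage` (default
0.1%) of its effective area; coverage exactly at threshold is open. Max
projection (rather than summation) is used to integrate frames because
streaks are sparse and bright; the binarization outcome is the same for
noise-free stacks and more robust under noise.

## Synthetic data

The generator emulates, with known region-level truth: (i) 16-bit
epifluorescence scenes — uniform background (300 counts), near-zero column
disks, 1–4 Gaussian biofilm blobs per occupied region, Poisson shot noise
plus Gaussian read noise (sd 10); (ii) bead-streak stacks — anti-aliased
polylines joining the most-interior pixels of adjacent open regions, split
across 12 frames (within the 10–15 frames typical of integrated bead
acquisitions), with no streak pixels in blocked regions or on columns;
(iii) competition tables — Δf = a·f0(1−f0) (uniform positive) or
a·f0(1−f0)(f_c−f0) (negative frequency-dependent, default f_c = 0.6),
plus Gaussian noise, clipped so f72 ∈ [0, 1]; (iv) logistic OD600 curves
sampled every 30 min by default (a 10-min preset mirrors faster plate
readers; neither is privileged).

Clogging is emulated, not simulated: the blocked set grows breadth-first
from a random clog site across the region-adjacency graph until 40% of
regions are blocked, giving one connected clogged patch (a clog and its
wake); clog sites are redrawn (≤20 tries) if the blockage would sever
every open corridor between inlet and outlet, since a fully sealed chamber
is the degenerate case rather than the scenario of interest. Default
occupancy probabilities encode the study scenario: wild type settles
independently of flow (p = 0.5), the mutant at 0.75 in blocked versus 0.15
in open regions (5:1 odds).

Two rendering choices are deliberate idealizations. Blobs are clipped to
their region's effective mask and renormalized to a fixed total flux
(region-mean lift 60 counts), so the region-level truth is exact by
construction and the occupied/background mean separation does not depend
on region shape. Real biofilm clusters straddle region boundaries and vary
in brightness; passing the round-trip tests therefore shows that the
measurement chain (tessellation, averaging, thresholding, streak scoring)
is correct, not that the thresholds would be optimal on real micrographs.
Similarly, streaks follow region-interior waypoints rather than
hydrodynamic streamlines — adequate for testing flow scoring, silent on
actual flow fields. For statistical studies that need hundreds of replicate
experiments (test power, type-I calibration), a region-level generator
(`sample_occurrence_calls`) draws truth tables directly with log-normal
region areas (CV 0.6), skipping rendering.

## Co-occurrence statistics

For strain s and flow class c, occurrence frequency = (effective area of
regions in c occupied by s) / (total effective area of c) — area weighting
follows from normalizing "to the total area" of each class and makes
frequencies comparable across unequal triangles; an unweighted count mode
is available for sensitivity analysis. Replicate-level blocked-vs-open
frequencies are compared per strain with a pooled-variance two-tailed
t-test (df = n₁+n₂−2, matching the replicate designs whose statistics such
studies print), and the per-strain p-values are Bonferroni-corrected
(strict p < α/m). Degenerate inputs are defined: zero pooled variance with
equal means gives t = 0, p = 1; with unequal means an infinite-t flag;
empty flow classes yield flagged NaN frequencies excluded from tests.

## Selection-function fit

Δf is regressed on the basis {f0(1−f0), f0²(1−f0)}, which forces Δf → 0 at
f0 ∈ {0, 1} (an absent or fixed strain cannot change frequency). Writing
Δf = f0(1−f0)(b0 + b1·f0), the sign of Δf on (0, 1) is the sign of the
linear factor, so the regime is classified from that factor's sign pattern
on a 999-point interior grid and the critical frequency is the bracketed
positive-to-negative zero located by bisection (tolerance 10⁻¹⁰).
Uncertainty comes from a percentile bootstrap over records (default 1000
resamples); resamples without an interior crossing contribute no f_c, and
the CI is reported only when at least 10% of resamples yield one. The fit
requires ≥8 records spanning an f0 range of ≥0.5. Under the reference
conditions (n = 30, noise sd 0.03, f_c = 0.6) the estimator is unbiased
with sampling sd ≈ 0.035, so single experiments scatter accordingly; the
acceptance script reports the median over 25 experiments, and the 95%
bootstrap CI covers the generating f_c in ≳90% of experiments. This
parametric estimator formalizes what is otherwise read off a scatter plot
(a crossover near 0.6) and is validated only on synthetic data.

Growth rates are the maximum over sliding windows (default 5 points ≈ 2 h
at 30-min sampling) of the least-squares slope of OD versus time, on raw
OD — "maximum slope of growth curves" — with the window max necessarily
slightly below the instantaneous logistic maximum rK/4 on coarse grids
(within 2% at the default sampling). A log-OD variant is not provided;
users wanting exponential rates can transform before calling. The absolute
growth rates printed in the motivating literature are not a target: their
stated units are internally inconsistent and the underlying plate-reader
data are not published, so only estimator correctness on synthetic curves
is claimed.

## Problem sizes and determinism

Test and acceptance runs use 4000×2000 µm chambers at 8 µm/px (500×250 px,
~50–70 regions), 2–4 scenes per imaging check (≥200 regions aggregated),
100 repetitions for detection-rate studies, 1000 for type-I calibration,
and 25 experiments for critical-frequency recovery — sizes at which every
reported rate has a standard error comfortably inside its acceptance band.
Every stochastic step takes a NumPy `default_rng` seed derived from one
master seed (`SeedSequence` spawning, kept below 2³¹); identical seeds give
byte-identical outputs, and each pipeline run writes a provenance record
(config hash, seed, versions) beside its outputs.

## Known limitations

- No hydrodynamics: flow states are sampled labels, streaks are not
  streamlines, and no Stokes/CFD solution is attempted (by design).
- Truth states are imposed, not emergent: the generator cannot test
  whether clogging *causes* mutant accumulation, only whether the analysis
  recovers imposed spatial associations.
- The t-tests assume replicate frequencies are approximately normal;
  with 3 replicates of ~50–150 regions this is adequate (type-I error
  calibrates to 5% ± 1.5%), but heavier designs should consider
  mixed-effects models, which are out of scope here.
- Column detection is tuned for dark disks ≥ ~8 px radius on a brighter
  background; heavily confluent biofilm over a column edge can in
  principle distort the Hough vote, in which case layout-file registration
  is the intended fallback.
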