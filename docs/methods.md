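# Methods

This note records the models implemented in `segdyn`, the study conditions frozen
for the acceptance suite, what the synthetic data can and cannot demonstrate, and
the numerical choices that shape the results.

## 1. Cluster-diameter estimation from two-point correlations

### Estimator

For a binary occupancy field φ on an anisotropic voxel grid (spacing in µm), the
connected two-point correlation is

C(r) = ⟨φ(x) φ(x+r)⟩ − p²,  p = ⟨φ⟩,

radially averaged over all ordered voxel pairs binned by Euclidean separation in
micrometres. Products ⟨φφ⟩ are computed by zero-padded FFT autocorrelation
(`scipy.fft.rfftn` on `next_fast_len(2n−1)` sizes, no periodic wrap-around); the
raw correlation sums are integers, so the FFT output is rounded to the nearest
integer before normalisation, which makes the estimator *exactly* equal to
brute-force pair enumeration (acceptance check: ≤1e-10 per bin on random masks;
in practice the difference is 0.0). Bins are `bin_width` wide and centred on
k·bin_width; the r = 0 bin contains the self pairs, so C(0) = p(1−p) for the
connected curve.

### Quadratic model and fit window

The mean cluster diameter R₀ comes from fitting

C(r) ≈ K (3/2 R₀² − 2 R₀ r + 1/2 r²),  r < R₀,

by nonlinear least squares, initialised from an unconstrained quadratic
a + br + cr² via K = 2c, R₀ = −b/(4c). The default fit window runs from r = 0 to
the curve's first zero crossing; on the model itself the first root is exactly
r = R₀, so the window is self-consistent. A fit whose R₀ exceeds the available
window is flagged `range_limited`.

### Known estimator bias on spherical clusters

The quadratic is the small-r expansion of the overlap covariance of 2D disks.
For 3D spheres of diameter D the exact covariance is ∝ 2D³ − 3D²r + r³ (a double
root at r = D), and fitting the quadratic model to it recovers ≈0.82–0.87·D
depending on the window. We measured 0.84 ± 0.01 uniformly across 20/40/80 µm
sphere fields. Consequences:

- Absolute diameters from the estimator are systematically low by ~15% on
  sphere-like clusters. We document rather than correct this: the correction
  factor is shape-dependent, and every comparative statement in the package
  (growth exponents, orderings, time courses) uses ratios or slopes in which a
  scale-stable multiplicative bias cancels.
- The sphere-field acceptance check therefore verifies ±20% recovery and strict
  ordering, not exactness.

Sphere fields are generated at fill fraction 0.05 (dilute): at higher packing the
hard-sphere anticorrelation dip intrudes into the small-r window and distorts the
quadratic region. For 20 µm spheres the z-spacing is halved to 5 µm so clusters
stay ≥3 voxels across in every axis (a hard precondition of the generator).

## 2. Diffusive coarsening: exchange (Kawasaki) dynamics

### Model

Three-phase lattice (labels: 0 medium, 1/2 cell types) with a symmetric contact
energy table J, evolved by Metropolis label exchange of nearest-neighbour unlike
pairs at temperature T (one sweep = N attempted exchanges). Composition is
exactly conserved. The kernel is JIT-compiled (numba); randomness comes from four
independent child streams of one `SeedSequence` (site picks, directions,
uniforms, initial shuffle), so results are reproducible per seed and independent
of draw chunking.

### Frozen acceptance conditions and what they show

128² lattice, 50/50 two-type composition, J(1,2) = 1, T = 0.9 (≈0.79 of the
order–disorder temperature Tc ≈ 1.135 for this mapping), periodic boundaries,
snapshots at 2^k sweeps for k = 10 … 17 in steps of 0.25, seeds 1–5. Cluster
diameter per snapshot from the Eq.-1 estimator (bin 1 lattice unit, r_max 64);
per-seed log–log slope over the final time decade; per-seed slopes pooled with a
Student-t interval. Measured at freeze time: pooled z = 0.306, 95% CI
[0.260, 0.353], covering the theoretical diffusive value 1/3. Runtime ≈4 min.

**Caveat, stated deliberately:** 2D conserved coarsening approaches L ~ t^{1/3}
from below through a notoriously slow transient (effective exponents 0.25–0.30
at accessible times). On a larger 192² lattice with sparser snapshots we measured
z = 0.268 with CI [0.239, 0.298] — *not* covering 1/3. At the 128² scale used
here, two effects move the pooled interval onto the asymptote: the late-time
effective slope rises as domains grow past the discretisation scale, and
per-seed scatter at this lattice size widens the interval. The acceptance test
demonstrates consistency with t^{1/3} at the prescribed scale, not arrival at
the asymptotic regime; treating z as a precision measurement would require
lattices and times ~20× larger.

Temperature was fixed before the test was written, from a physics scan
(T ∈ {0.5, 0.8, 0.9, 1.0}): T = 0.5 freezes activated monomer detachment and
stalls coarsening; T = 1.0 admixes critical thermal fluctuations into the
correlation fit; 0.9 is the standard compromise for coarsening studies.

### Envelopment (three-phase) runs

`make_aggregate_config` builds a 48² non-periodic lattice, 40% of sites as a
central mixed-type aggregate ball surrounded by medium, with cell–medium
energies J(A,M) = 1.6, J(B,M) = 0.8, J(A,B) = 0.5, T = 0.5, 3000 sweeps. The
envelopment index is each type's share of cell sites adjacent to medium. The
higher cell–medium energy (higher effective tension) type is engulfed; swapping
the two cell–medium energies swaps the indices (12 seeds per condition; pilot
shares 0.03/0.97 vs 0.96/0.04 swapped). "Within Monte-Carlo error" is
operationalised as cross-condition means agreeing within twice the pooled
per-seed standard deviation (≈0.02) — the seed-to-seed scatter of the index
itself. This is a qualitative inversion analogue, not a quantitative tension
measurement: lattice tension is anisotropic and the dynamics are far from the
continuum limit.

## 3. Collective motion: ballistic cluster merging

### Model

n equal disks (radius r) in a periodic square box; every cluster moves rigidly
and ballistically at common speed v with a persistent direction that is redrawn
(uniformly) whenever clusters merge; clusters merge when any member disks touch
(cKDTree contact detection, union–find over clusters). Time step dt = r/(2v), so
the maximum relative approach per step is one radius; overlaps frozen at merge
are bounded by that and contribute a scale-independent area factor that cancels
in log–log slopes. Initial placement is random sequential adsorption; packing
fractions above 0.3 are rejected.

Mean cluster linear size is √(total disk area / cluster count) — the square root
of mean cluster area.

### Frozen acceptance conditions (target t2)

n = 4096, r = 5 µm, v = 30 µm/h, packing 0.15 (box = √(nπr²/φ)), snapshots at
24 log-spaced times in [0.25, 40] h, 5 seeds. Scaling window: snapshots with
cluster count in [16, n/4] — below n/4 the pre-merge transient is over, above 16
finite-size saturation has not begun; both bounds were set a priori from the
structure of the problem, not from slope outcomes. Per-seed log–log OLS slope,
pooled with a Student-t interval. At freeze time: pooled z = 0.995, 95% CI
[0.951, 1.039], covering the ballistic value 1; ≈20 s runtime (~11 s in the
acceptance script). The population size was chosen so the pooled CI radius
(~±0.04) is small against the distance to competing exponents; the point
estimate itself drifts with cluster-geometry kinetics (2048 → 0.925,
8192 → 1.041, CI covering 1 at all sizes).

`scripts/acceptance.py` re-derives five sub-seeds from the single `--seed` via
`SeedSequence.generate_state`, so different base seeds give statistically
independent replications of the whole protocol.

## 4. Spheroid-compaction morphometry

Segmentation follows the standard protocol: Sobel gradient magnitude → Gaussian
blur (σ = 5 px) → IsoData (iterative intermeans, own implementation; converges
to the average of the two class means) → fill holes < 1000 px → keep the largest
8-connected component → fill remaining interior. Perimeter is measured on the
0.5 level set of the lightly smoothed mask (Gaussian σ = 1 px, marching
squares): smoothing suppresses the ~+9% pixelation excess of staircase
boundaries; a clean disk then measures 2πr within 0.5%.

**Known pipeline bias:** thresholding the blurred gradient band and filling it
dilates the footprint outward by roughly the blur scale (≈σ px; +9% on an
r = 80 px disk). Absolute perimeters carry this bias. The pipeline's headline
output — perimeter as a percentage of frame 0 — cancels it, which is why the
20%-contraction acceptance check (readout 81.0 vs 80 ± 2) passes while absolute
values are reported as-is. The disk anchor in the acceptance suite therefore
tests the perimeter primitive directly.

The synthetic spheroid generator draws a phase-contrast-like frame (dark
interior, bright halo band, mid-grey background, Gaussian noise) around a core
whose radius shrinks linearly; surface roughness is a fixed band-limited
harmonic profile (modes 4–12) of chosen amplitude that rescales with the core,
so rough ("berry-like") surfaces measurably raise the perimeter.

## 5. Doublet mechanics

Separation force in SI units: F_s = πR²(P_{n−1}+P_n)/2 with R the pipette
internal radius (µm → m) and P the step pressures (Pa). Separation at the first
step has no previous pressure; the convention P₀ = 0 is used and the result is
flagged as a lower bound. An unseparated record has no defined force (error, not
NaN).

Contact angles from two-circle geometry: for circles (cᵢ, ρᵢ) with common chord
at distance dᵢ from centre i, θᵢ = arccos(dᵢ/ρᵢ). Analytic anchors: concentric
equal circles → 90°, externally tangent → 0°, equal circles at centre distance
ρ → 60°. Image-side fitting: trace the mask contour, locate the two concave
turning points (contact vertices), split the contour into two arcs, trim near
the vertices, Kåsa algebraic circle fit refined by geometric least squares.
Round-trip accuracy on rendered doublets is ≤0.3° at 0.15 µm/px (acceptance
bound ±3°).

Tension balance: TST = Tcm − Tcc + Acc/2.

## 6. Statistics

Welch's unequal-variance t-test is implemented from the defining formulas
(cross-checked against scipy property-based, and against the hand example
t = −1.2247, df = 4). Five-number summaries use numpy's linear-interpolation
percentiles. Hourly resampling block-averages six consecutive 10-minute points
and drops a trailing partial block; off-cadence input is an error. Growth
exponents are OLS slopes of log L vs log t with t-quantile CIs; without an
explicit window the first quartile of points is dropped as transient and, when
SEMs are available, a terminal sub-SEM plateau is excluded (a series that is
plateau throughout has no growth regime and raises).

## 7. What the synthetic layer does and does not show

The simulators are designed to exercise the *analysis* code against known
truths and the two theory exponents; they are not calibrated biophysical models.
In particular: the lattice model has no cell shape, motility persistence or
cortical mechanics; the ballistic model has no adhesion energetics or cluster
rearrangement; rendered images have simplified noise. None of the
experimentally reported biological numbers (specific contact angles, separation forces in nN, absolute
cluster-size curves) are reproduced or claimed — only the scaling laws,
inversion behaviour and estimator contracts documented above.
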