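# segdyn

Quantitative analysis of 3D cell-segregation experiments: cluster-size
estimation from two-point correlations, spheroid-compaction morphometry,
doublet mechanics (separation forces and contact angles), tissue-surface-tension
balance, and segregation-dynamics statistics — together with a synthetic-data
layer (lattice exchange dynamics and ballistic cluster merging, plus image
renderers) that provides ground truth for every pipeline.

## Science in one paragraph

When a heterotypic cell mixture demixes ("cell sorting"), homotypic clusters
coarsen over time, and the *growth exponent* of mean cluster size L ~ t^z
distinguishes the mechanism: purely diffusive, composition-conserving dynamics
gives z = 1/3, while coherently moving clusters that merge on contact give
z = 1. Cluster size is measured from fluorescence z-stacks via the connected
two-point correlation C(r) = ⟨φφ⟩ − p², whose small-r quadratic form
C(r) ≈ K(3/2 R₀² − 2R₀r + 1/2 r²) vanishes at the mean cluster diameter R₀.
Which cell type ends up enveloping the other is set by the tissue surface
tension balance TST ≈ Tcm − Tcc + Acc/2, measurable at the doublet level
through contact angles and dual-pipette separation forces
F_s = πR²(P_{n−1}+P_n)/2. `segdyn` implements all of these measurements, their
file formats, and simulators that realise both coarsening regimes.

## Worked example: cluster diameter from a synthetic z-stack

```python
from segdyn.correlation import binarize_channel, two_point_correlation, fit_cluster_diameter
from segdyn.synthetic import generate_sphere_field

# A 3D two-channel stack of fluorescent cell clusters with known geometry:
# spheres of true diameter 40 um, 10 um z-step, 1 um pixels.
stack, truth = generate_sphere_field(
    true_diameter=40.0, fill_fraction=0.05,
    grid_shape=(64, 160, 160), spacing=(10.0, 1.0, 1.0), seed=1,
)

mask = binarize_channel(stack, "A", method="otsu")
curve = two_point_correlation(mask, r_max=100.0, bin_width=2.0)
fit = fit_cluster_diameter(curve)

print(f"true diameter : {truth.true_R0:.1f} um")
print(f"estimated R0  : {fit.R0:.1f} um  (fit window 0-{fit.fit_range[1]:.0f} um)")
print(f"occupied frac : {mask.occupied_fraction:.3f}")
```

Output:

```
true diameter : 40.0 um
estimated R0  : 33.5 um  (fit window 0-36 um)
occupied frac : 0.052
```

The ~0.84 recovery ratio is a documented property of the quadratic estimator on
spherical clusters (it is the small-r disk-overlap expansion); it is
scale-stable, so orderings and growth *slopes* are unaffected. See
`docs/methods.md` §1.

## Worked example: the collective growth exponent

```python
import numpy as np
from scipy import stats

from segdyn.synthetic import simulate_ballistic_segregation, mean_cluster_size

n, r = 4096, 5.0
box = float(np.sqrt(n * np.pi * r**2 / 0.15))   # packing fraction 0.15
states = simulate_ballistic_segregation(
    n_cells=n, cell_radius=r, speed=30.0, box=box,
    snapshot_times=tuple(np.geomspace(0.25, 40.0, 24)), seed=1,
)
t = [s.time for s in states if 16 <= s.n_clusters <= n // 4]
L = [mean_cluster_size(s) for s in states if 16 <= s.n_clusters <= n // 4]
z = stats.linregress(np.log(t), np.log(L)).slope
print(f"clusters: {states[0].n_clusters} -> {states[-1].n_clusters}")
print(f"growth exponent z = {z:.2f}  (ballistic theory: 1)")
```

Output:

```
clusters: 3317 -> 2
growth exponent z = 1.03  (ballistic theory: 1)
```

## Command line

Every pipeline is also a `segdyn` subcommand that writes CSV/JSON artifacts and
a structured run log:

```bash
$ segdyn synth dpa --seed 1 --out demo     # synthetic pressure-step record
wrote dpa dataset to demo
$ segdyn dpa demo/dpa.csv --out demo       # separation force in SI units
F_s = 1.732e-10 N (0.173 nN)
```

Subcommands: `synth` (sphere_field, coarsening, ballistic, spheroid, doublet,
dpa), `clusters` (diameter time series from stack TIFFs), `spheroid`
(perimeter-compaction trace), `doublet` (contact angle from a segmented image),
`dpa` (separation force), `exponent` (growth exponent from a series CSV).

Image stacks are plain multi-page TIFFs with a JSON sidecar declaring voxel
spacing, channel names and timestamp; spacing is never silently assumed.

## Package layout

| module | contents |
| --- | --- |
| `segdyn.correlation` | FFT two-point correlation, brute-force oracle, quadratic diameter fit, thresholding, time series |
| `segdyn.morphometry` | Sobel→Gaussian→IsoData spheroid segmentation, sub-pixel perimeter, compaction traces |
| `segdyn.doublet_mechanics` | DPA separation force, two-circle contact angles, image-side circle fitting, TST balance |
| `segdyn.dynamics_stats` | growth exponents with CIs, hourly resampling, Welch t-test, five-number summaries, envelopment index |
| `segdyn.synthetic` | lattice exchange simulator, ballistic merge simulator, sphere-field / spheroid / doublet / DPA generators, microscopy renderer |
| `segdyn.io` | TIFF+sidecar stacks, tidy CSVs, run configs and logs |
| `segdyn.cli` | the `segdyn` command group |

## Reproduction

Run the full test suite (includes the acceptance suite; ≈5 min on one CPU —
the two simulator-based exponent tests dominate):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Recompute the collective growth exponent from scratch (≈15 s):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# seed 1835504127: z = 0.9601
# ...
# pooled z = 0.9780  95% CI [0.9473, 1.0088]
cat results/acceptance.json
# {"t2": {"value": 0.9780417912573389, "n": 4096}}
```

All study conditions (lattice sizes, temperatures, populations, seeds, fit
windows) are frozen and justified in `docs/methods.md`, together with the
estimator-bias and simulator-transient caveats that a careful reader should
know before interpreting absolute numbers.
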