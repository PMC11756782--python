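# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic phantoms do and do not emulate, and the design
decisions taken where the design was genuinely open.

## Geometry and containers

All grids are axis-aligned regular lattices with per-axis spacing in mm and
a voxel-center convention: the center of voxel `(i,j,k)` is at
`origin + (index + 0.5)·spacing`. A voxel belongs to a structure iff its
center lies inside the defining surface. Volumes are voxel counts times the
voxel volume (1 cc = 1000 mm³) with no partial-volume weighting; the
tolerance budgets below absorb that convention.

## Dose phantom

The phantom emulates a single-target SRS dose distribution as a monotone
radial profile around the target surface:

```
D(x) = PD · g(s(x) + a(x))
g(s) = 1 + (P−1)·tanh(−s/(2w))     s ≤ 0       (interior escalation)
g(s) = 2^(−s/h)                     s > 0       (exterior falloff)
```

* `s(x)` — signed distance to the target surface (mm, negative inside);
  exact for spheres and unions of spheres, first-order for ellipsoids.
* `P = 100/interior_ratio` — deep-interior plateau relative to the boundary
  dose. Default `interior_ratio = 80` (%): a moderately hot center typical
  of boundary-prescribed SRS; the near-maximum dose sits ~25% above PD.
* `w = 3 mm` — interior ramp scale (fixed).
* `h = falloff_half_distance` — distance outside the surface at which dose
  halves. Default 6 mm, a realistic falloff for single-target arcs.
* `a(x)` — deterministic direction-dependent displacement of the isodose
  surfaces, `anisotropy · sin²θ·cos2φ` (the real sectoral l=2 spherical
  harmonic, |a| ≤ anisotropy mm). It deforms the dose cloud but never the
  target mask, so lamellarity coverages fall below 100% by a controlled
  amount. Default 0 for the bare generator; the experiment cohort uses
  0.5 mm.
* Default boundary dose 43 Gy, a typical multi-fraction SRS prescription
  magnitude; every reported %-of-PD metric is scale-invariant to it.

Two factors emulate Monte-Carlo calculation settings:

* **Calculation grid spacing** (`gs_factor`, mm): the dose is sampled on a
  lattice of this spacing and trilinearly resampled to the evaluation grid
  (default 1 mm); a coarse grid blurs gradients and under-resolves
  irregular target shapes. When the two spacings coincide the analytic dose
  is sampled directly (no interpolation error).
* **Statistical uncertainty** (`su_factor`, %): multiplicative Gaussian
  noise drawn per *calculation-grid* voxel and resampled with the dose.
  The resampled noise field is divided by the separable trilinear variance
  attenuation `∏ₐ(uₐ² + (1−uₐ)²)^½` so the per-voxel uncertainty of the
  final dose equals `su_factor` regardless of the calculation grid; what
  changes with the grid is the *correlation length* of the noise, which is
  what displaces isodose surfaces coherently. This mapping is an emulation
  choice: the clinical quantity is a planner-internal stopping criterion
  whose per-voxel meaning is not published, and no claim is made that the
  emulation reproduces any engine's noise structure.

Target centers default to a fixed sub-voxel offset (0.37, 0.203, 0.489
voxel) from the lattice. Centering an integer-radius sphere exactly on a
voxel center places large shells of lattice points at exactly integer
distances from the surface, making every voxel count a knife-edge function
of thresholds; a generic off-lattice center restores the smooth behaviour
real anatomy has.

For spherical, noise-free, isotropic phantoms the object carries a truth
record with the closed-form isodose radii `r + g⁻¹(d/PD)` and isodose
volumes, used as the analytic oracle in tests.

**What the phantom does not emulate:** beam/arc transport, MLC leaf
sequencing, optimizer behaviour, tissue heterogeneity, or any planner's
cost functions. Passing tests therefore demonstrate correctness of the
*evaluation machinery* and directional sensitivity of the metrics to
resolution and noise — not magnitudes of any clinical system's plan-quality
differences, which depend on the optimizer itself.

## Margins (isotropic expansion/contraction)

A margin is `{x : signed_distance_to_surface(x) ≤ m}` (closed threshold,
matching the inclusive eligibility rules). Voxel-to-voxel Euclidean
distance transforms are lattice-quantized (all distances are √k·spacing)
and biased by ~0.3 voxel near the surface; at 1–4 mm margins on a 1 mm grid
this produces 7–18% volume errors against analytic spheres. The
implementation therefore estimates the surface at subvoxel accuracy:

1. marching-cubes midpoint isosurface of the binary mask (level 0.5, mask
   padded by one voxel);
2. Taubin λ/μ smoothing (λ=0.5, μ=−0.53, 50 iterations, uniform Laplacian)
   — removes the ±½-voxel staircase jitter with negligible shrink;
3. dense barycentric sampling of every triangle (order 3) into a surface
   point cloud; signed distances are exact point-to-cloud distances via a
   KD-tree, with the sign taken from mask membership;
4. a coarse signed EDT pre-decides voxels farther than 2 voxels from the
   threshold, so only a thin band is ever queried.

Because the refined distance always lies within the band half-width of the
coarse one, thresholding the hybrid field is monotone in `m`. Measured on
voxelized spheres (r = 10 mm, 1 mm grid), margin volumes agree with the
analytic values to better than 2% for +2/−2/−4 mm and +20 mm.

Interior shells are only evaluated above minimum meaningful volumes
(−2 mm: GTV ≥ 0.72 cc; −4 mm: GTV ≥ 2.20 cc, both inclusive, applied to the
voxelized volume — the quantity the pipeline actually possesses). The
evaluation region is the GTV expanded 10–30 mm (default 20 mm), clipped to
the grid; it must contain the 50% isodose for spillage volumes to be
complete.

## DVH and lookups

The cumulative DVH is the exact sorted multiset of voxel doses — no
binning, since every downstream metric is a near-extreme quantile that
binning distorts. `dose_at_volume` interpolates linearly between adjacent
step points; volumes below one voxel return the maximum voxel dose
(limiting behaviour); `volume_at_dose` uses the closed threshold `≥ d`.
The "more than" vs "at least" distinction is measure-zero for continuous
dose and the closed form matches DVH convention; round-trip consistency is
guaranteed to within one voxel volume.

## Metric panel conventions

* Prescription: D_{V−0.01cc} for V > 0.20 cc (implied coverage
  `100·(V−0.01)/V`, reported rounded half-up to 2 decimals), D_95% at or
  below 0.20 cc (coverage 95.00). Near-maximum: D_0.01cc for V ≥ 0.20 cc,
  D_5% strictly below — the two boundary conventions differ by design at
  exactly 0.20 cc and are implemented exactly as stated.
* Rescaling: ratio = PD / metric, applied multiplicatively; the recomputed
  metric equals PD to 1e−9 relative. Reported to 3 decimals; statistics use
  the unrounded value.
* Spillage is the *set-difference* volume (voxels ≥ threshold AND outside
  the GTV), not arithmetic IIV − V_GTV: always ≥ 0 and identical to the
  arithmetic form whenever the GTV is fully covered at that level.
* All IIV-based quantities are computed on the evaluation-region DVH.
* Reporting precision: %-of-PD and coverages 1 decimal, ratios 3 decimals,
  volumes 2 decimals (half-up).

## Statistical stack

* **Friedman**: within-subject mid-ranks, tie-corrected chi-square
  statistic `(k−1)·Σ(R_j − n(k+1)/2)² / (A − C)` referred to χ²_{k−1};
  fully tied panels return p = 1. The chi-square reference is accurate in
  the decision tail (measured type-I error 4.4% at α = 0.05, n = 12,
  k = 4) but runs conservative at mid-range p — an inherent property of
  the approximation, shared with standard software.
* **Scheffé-type post hoc** on Friedman rank sums:
  `S_ij = (R_i − R_j)²/(n·k(k+1)/6)` vs χ²_{k−1} — the standard
  simultaneous (hence conservative) nonparametric multiple comparison.
* **Conditional Wilcoxon rule**: pairs with post hoc `0.05 ≤ p < 0.9` are
  re-tested with the paired Wilcoxon signed-rank test; already-significant
  or clearly null pairs are not.
* **Wilcoxon signed-rank**: zeros dropped (classical convention —
  switchable to Pratt was considered and rejected to keep one documented
  behaviour), mid-ranks for ties; exact two-sided p for n ≤ 25 by dynamic
  program over doubled ranks (handles ties, unlike textbook tables);
  tie-corrected normal approximation with continuity correction above.
* **Jonckheere–Terpstra** across the a-priori group order, Mann–Whitney
  counts with ties as ½ and the three-term tie-corrected variance; applied
  to group columns as independent samples (the test has no paired form).
  Measured type-I error 5.0% at the study design size.
* Stars: strict `<` at 0.05/0.01/0.001. Box-whisker summaries: linearly
  interpolated quartiles, whiskers at the nearest data within 1.5·IQR.

## Experiment orchestration

Per-subject geometry is fixed across groups (paired design); only the two
calculation factors vary. Per-plan randomness derives from SHA-256 of
(master seed, subject id, group label), below 2³¹, so results are
independent of iteration order and byte-identical across runs. Metrics with
ineligible shells are censored listwise per metric, mirroring reduced-n
analyses. Two-group designs use the Wilcoxon test alone; k ≥ 3 runs the
full stack. A single-subject cohort skips statistics with a warning but
still emits the metric panel. Calculation time is not modeled and no
placeholder column is emitted.

The default cohort is 12 ellipsoidal targets (cycled axis ratios between
1:0.9:0.8 and 1:0.7:0.55) spanning 0.08–48.09 cc with median 17.4 cc, plus
0.5 mm dose anisotropy: irregular targets with conformal ideal dose, so a
calculation grid too coarse to resolve the shape measurably degrades
lamellarity. Tests use smaller sub-cohorts (sub-cc to few-cc targets on
compact grids) to keep runtimes in seconds; problem sizes in each test are
stated in the test itself.

## Known limitations

* Ellipsoid signed distance is first-order (exact on the axes); margin
  accuracy on extreme aspect ratios degrades gracefully but is untested
  beyond ~2:1.
* DICOM ingest supports axial identity orientation and uniform slice
  spacing only.
* The emulated factors reproduce directions, not magnitudes: nothing here
  substitutes for a planning-system study when absolute differences matter.
* Coverage/spillage values on small structures (≲0.1 cc) are quantized by
  the voxel count and should be read with that granularity in mind.
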