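# Methods

This note documents the models, defaults, and numerical choices behind
`metconn`, and what the synthetic-data validation does and does not show.

## Coordinate frame and data model

All volumes live on a shared lattice with anisotropic spacing, in the
×10-scaled millimeter frame conventional for rodent PET (raw
0.3875 × 0.3875 × 0.775 mm voxels become 3.875 × 3.875 × 7.75 mm), so that
human-calibrated defaults such as 12 mm smoothing apply. World axes are
x = medial–lateral (+right), y = anterior–posterior (+anterior),
z = dorsal–ventral stored as *positive depth* below bregma; stereotaxic
atlas coordinates are multiplied by 10 when addressing the grid. The atlas
table does not state the sign convention of its DV column; positive depth
was chosen and applied consistently, which only fixes the z-orientation of
the frame and does not affect any statistic.

## Preprocessing

- `scale_voxels` is metadata-only: spacing and origin are multiplied,
  values untouched.
- `gaussian_smooth` uses per-axis sigma = FWHM / √(8 ln 2) / spacing with
  zero-padding outside the grid (the common neuroimaging convention; the
  boundary choice is visible only within ~2 FWHM of the edge). For the
  12 mm default, sigma = 5.095931 mm.
- `global_normalize` divides by the arithmetic mean over the binary brain
  mask, so the in-mask mean is exactly 1 afterwards and the operation is
  idempotent. "Global uptake" is interpreted as this mean; a proportional
  scaling to another reference value would differ only by a constant factor
  and cancels from every correlation downstream.
- Order of operations in the pipeline: smooth, then mask/normalize.

## Synthetic cohorts

Each subject volume is

    background + Σ_j ℓ_ij · support_j + ε,   then smoothed,

with a fixed ellipsoidal "brain-shaped" background (peak 100, center
(0, −12, 28) mm, semi-axes (70, 85, 45) mm — this also defines the brain
mask), spherical supports of radius 12 mm at the eight VOI centers
(1.5× the 8 mm extraction radius so extraction reads the support interior),
per-subject loadings ℓ_i ~ N(μ_g, Σ_g) for age group g, i.i.d. voxel noise
ε with sd 1.0, and generation smoothing of 6 mm FWHM emulating scanner
resolution (distinct from the 12 mm analysis smoothing). One
`SeedSequence` per cohort is split per subject by (group, subject) index,
so volumes are bit-reproducible independent of generation order.

Defaults encode the study conditions: group sizes 30/30/28; anterior
regions gain mean uptake with age (+0, +1.0, +1.5 on a baseline of 10)
while posterior regions lose (−0, −0.5, −1.0); the loading correlation has
base 0.2, bilateral homotopic pairs 0.6, and anterior–posterior coupling
that matures with age — midline MedF–Rsp 0.1 → 0.5 → 0.8 and
midline-to-sensorimotor 0.2 → 0.35 → 0.5 — with loading sd 3. The noise sd
is a free parameter of the design (inter-subject uptake variance is not
constrained by the emulated study); 1.0 (1% of background peak,
one third of the loading sd) keeps planted effects recoverable at the
study's sample sizes without making recovery trivial.

Known fidelity limit: dividing by the per-subject global mean introduces a
small common-mode coupling, so a planted loading correlation of 0.8 is
observed at ≈ 0.78 after the full preprocessing chain, independent of grid
resolution. This attenuation is a property of global normalization itself
(it would affect real data equally) and is deliberately not corrected.

What the generator does **not** emulate: PET physics (attenuation,
scatter, reconstruction artifacts), anatomy beyond an ellipsoid,
registration error, or anesthesia effects. Passing tests therefore
validate the *statistical machinery* under the study's design, not
robustness to acquisition artifacts.

## Voxelwise contrasts

Paired t on within-subject differences (subjects are scanned at every
age; pairing is by animal ID, unmatched animals dropped — with 30/30/28
animals the 10 vs 15 week contrast uses the 28 common animals).
Zero-variance voxels get t = 0, p = 1 rather than infinities. FDR is
Benjamini–Hochberg over in-mask voxels only; cluster extent filtering
uses 18-connectivity (faces + edges, the SPM convention) by default, with
6/26 available.

## Group ICA

Model order: minimum description length on the eigenspectrum of the
subject covariance, with the effective sample count N′ = voxels ×
`sample_correction` exposed because spatial smoothness makes voxels
non-i.i.d. (default 1.0; lower it for heavily smoothed data). The estimate
is clipped to [1, subjects − 1] and the full eigenspectrum remains
available rather than trusting a point estimate.

Unmixing: PCA whitening to k dimensions, then infomax with the logistic
nonlinearity and natural-gradient block updates (block 512 voxels,
shuffled per pass from the run seed). The learning rate anneals by ×0.9
whenever successive pass-level weight updates point more than 60° apart
(the signature of jitter around an optimum), converges when the
max-abs weight change in a pass drops below 1e-6, caps at 500 passes
(non-convergence is flagged on the result, never silent), and restarts at
half the rate after a numerical blowup. Maps are z-scored over in-mask
voxels with the scale folded into the mixing columns; sign is fixed by
orienting each map's extreme voxel positive; components are ordered by
mixing-column energy. Matching to reference maps uses optimal assignment
(Hungarian) on |spatial Pearson r|.

## Connectivity and efficiency inference

Edge statistic: Δz = atanh(r_B) − atanh(r_A) per edge, |r| clamped to
1 − 1e-7 before atanh. Null: pool both groups' subjects, reshuffle labels
preserving group sizes, recompute both pseudo-groups' correlation matrices
(vectorized over permutations). P-values use the add-one estimator
p = (1 + #{|Δz_perm| ≥ |Δz_obs|}) / (n_perm + 1), which cannot return 0
and is exact under exchangeability; tests are two-sided by default
(one-sided available). FDR is applied over the 28 edges of each group-pair
comparison separately.

Efficiency: S_i sums positive incident correlations (negative links
excluded by definition; an |r| option exists but is off), u_i is the group
mean of per-subject VOI means after global normalization (efficiency is a
group-level quantity), E_i = S_i / u_i. The permutation statistic is ΔE_i
with *both* S and u recomputed per pseudo-group, so the null reflects the
full statistic; significance is Bonferroni at family α / 8 = 0.00625.

## Orchestration

`run_pipeline` drives all stages from a single validated config whose
defaults equal the study parameters (12 mm FWHM, q = 0.05, extent 100,
10,000 permutations, z > 1.5, VOI radius 8 mm). The JSON report is
schema-validated (pydantic model), records every seed and per-group input
hash, rounds floats to 10 decimals, and serializes with sorted keys, so
identical configs give byte-identical reports.

## Validation problem sizes

The simulation studies run on a 20 × 24 × 8 grid at doubled spacing
(7.75 × 7.75 × 15.5 mm) covering the same field of view — coarse enough
that a full cohort generates in ~0.1 s while every VOI still contains
multiple voxels. Calibration uses 500 null cohorts at 1,000 permutations;
power 200 cohorts; efficiency direction 100 cohorts; ICA recovery 10
seeds. Measured under these conditions: null per-edge rejection ≈ 0.05 at
α = 0.05, planted-edge detection ≈ 0.93, efficiency direction ≈ 0.96, ICA
matched |r| > 0.99, deterministic kernels at float precision vs brute
force.

## Known limitations

- Spatial normalization/registration is out of scope; inputs must be
  co-registered.
- The permutation scheme pools subjects across groups; a within-pair
  scheme for longitudinal designs is not implemented.
- MDL model order is reported alongside the eigenspectrum but is known to
  be sensitive to the effective-sample correction on smoothed data.
- "Efficiency" here is the strength/uptake ratio, not graph-theoretic
  (shortest-path) efficiency.
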