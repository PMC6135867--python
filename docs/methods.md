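# Methods

This note records the models, conventions and numerical choices behind
`mseval`, the points where the design was genuinely open, and what the
synthetic phantom experiments do and do not establish.

## Grids and masks

All volumes of a case must share dimensions and voxel spacing (relative
spacing tolerance 1e-5); nothing is ever resampled, because interpolating
a binary mask would alter the overlap quantities being measured. Any
nonzero voxel value counts as lesion, which makes reading robust to
annotation tools that save labels other than 1. Physical units are mm
throughout; voxel volume is the product of the spacings.

## Overlap metrics and the evaluation region

Dice, PPV and sensitivity need no reference region, but specificity does:
against a whole head or an arbitrary padded grid the count of true
negatives dwarfs everything and every specificity saturates near 1. The
region `B` is therefore the union of all available segmentations of the
case, dilated three successive times with the 6-connectivity cross (three
applications of the face-neighbour kernel, not one application of a
radius-3 ball — the two differ on corners). When only a single pair is
evaluated outside a challenge context, `B` defaults to the dilated union
of that pair; specificity values are then not comparable across performers
evaluated with different companions, which is why the pipeline always
builds `B` once per case from every mask.

Empty-mask conventions: `A = G = ∅` scores Dice 1.0 with a `both_empty`
flag (agreement on nothing, routed to the no-consensus path at pipeline
level); empty `A` flags PPV undefined (NaN); empty `G` flags sensitivity
and specificity undefined and routes the case to the no-consensus report.
Flagged NaNs are excluded from every cohort average.

## Surface distance

The average symmetric surface distance averages, over both boundary point
sets, the minimal Euclidean distance to the other boundary. "Boundary" is
not uniquely defined on a voxel grid; here a foreground voxel is boundary
iff one of its six face neighbours is background or it touches the grid
edge, and distances are measured between voxel centers in physical mm (the
spacing is folded into an exact Euclidean distance transform, so
anisotropic grids are handled correctly). Voxel centers rather than mesh
faces is a choice, not a theorem: sub-voxel surface models would give
slightly different values, but the voxel-center definition matches the
resolution of the per-point sums and is what the all-pairs oracle in the
test suite verifies to 1e-9 mm.

## Lesion identification and detection matching

Lesions are 18-connected components (faces and edges, not corners) after
removing components below a minimum physical volume, 3 mm³ by default. The
size rule is applied as *keep ≥ 3 mm³* everywhere, with a `strict_size`
switch for *keep > 3 mm³*; both readings appear in the field and the
toolkit uses one consistent default rather than different rules in
different reports. Surviving lesions are renumbered in decreasing volume
order, which also fixes tie-breaking downstream.

The matcher works on the joint histogram `H` of the two label maps
(background row/column included). For each reference lesion `j`:

1. coverage rule — `Σ_{i≥1} H[i,j] / |G̃_j| ≥ α/100`;
2. contributor rule — contributors are taken in decreasing `H[i,j]` order
   (ties toward the smaller label, i.e. the larger lesion) until their
   cumulative overlap reaches γ/100 of the total overlap on `j`; each
   selected contributor must satisfy `(|Ã_i| − H[i,j])/|Ã_i| ≤ β/100`.

Whether the β bound applies to each contributor individually or to the
contributors' union is ambiguous in prose descriptions of this rule; both
are implemented (`beta_on_union`), per-contributor being the default as
the stricter and more local reading. `TP_A` uses the same procedure with
the two maps' roles reversed (the transposed histogram). Fractions are
compared in integer voxel counts cross-multiplied against the percentage,
so no float round-off can flip a boundary case. Degenerate conventions:
`N = 0` with `M > 0` gives `P_L = 0`; `Se_L + P_L = 0` gives `F1 = 0`;
`M = 0` routes to the no-consensus path. Defaults α = 10 %, γ = 65 %,
β = 70 %, which on phantoms tolerate sub-voxel boundary jitter while
rejecting sprawling overlaps.

## Consensus fusion

Binary STAPLE: latent voxelwise truth `T`, each rater a binary channel
with sensitivity `p_r` and specificity `q_r`. E-step computes
`W_v = P(T_v = 1 | D)` from a spatially varying prior and the rater
likelihoods; M-step re-estimates `(p_r, q_r)` from `W`. In `lop_staple`
mode the per-rater likelihood factors are pooled as a normalized weighted
geometric mean before the prior is applied — equal weights 1/R by default,
a `weights` argument exposed — which softens the penalty a single
deviating rater pays and is the log-opinion-pool reading of
performance-weighted fusion. The classical mode is the standard STAPLE
contract and is the mode verified against a scalar reference EM and for
per-iteration monotonicity of the observed-data log-likelihood; the LOP
pool is a tempered E-step whose objective is tracked but not guaranteed
monotone.

Numerical choices: initialization `p_r = q_r = 0.9`; prior = voxelwise
mean of the input masks clipped to [0.01, 0.99]; probabilities clipped at
1e-7 from {0, 1} inside logs; convergence when the largest parameter
change drops below 1e-6, at most 100 iterations; consensus threshold 0.5.
The EM runs only inside an evaluation region (union of inputs dilated 3×
by default, or a caller-supplied region) — on a full grid the
all-background exterior saturates every `q_r` at 1 and washes out the
performance estimates. Callers that know the generative support of rater
noise (e.g. simulation studies) should pass that region explicitly so the
estimated parameters refer to the intended domain.

Fusing all-empty inputs returns an empty consensus with NaN performance
parameters and a degeneracy flag rather than an error.

## Cohort analytics

*Ranking.* Within each case performers are ranked 1..N on one metric
(average ranks on ties, so each case's ranks sum to N(N+1)/2) and ranks
are averaged over cases. Rank-then-average is robust to a performer buying
a good mean with a few extreme cases. Cases missing any performer are
dropped with a warning rather than imputed.

*Performer clustering.* Each performer is summarized as a bivariate
Gaussian (mean and covariance of a metric pair over cases — the
covariance matters because a performer with the same mean but huge
case-to-case scatter is a different animal). Distances are the closed-form
2-Wasserstein (Bures) metric,
`d² = ‖μ₁−μ₂‖² + tr(Σ₁+Σ₂ − 2(Σ₂^½Σ₁Σ₂^½)^½)`,
chosen because it is a true metric with exact limits (Euclidean for point
masses, `√2|σ₁−σ₂|` for equal-mean isotropic Gaussians) that the tests
pin down. Clustering is normalized spectral clustering implemented
directly: affinity `exp(−d²/2σ²)` with σ the median nonzero pairwise
distance, embedding on the k smallest eigenvectors of the symmetric
normalized Laplacian, rows normalized, k-means with fixed seed 12345. The
embedding is written out rather than delegated because the library
diffusion-map variant proved unstable on small performer sets (11 points)
where this formulation is not. k = 3 by default, exposed. Labels are
renumbered so cluster 1 has the highest mean on the first metric.

*Regressions.* Score-vs-burden fits a least-squares line on log10(burden)
for the slope but reports R² as the squared Spearman rank correlation —
monotone association, insensitive to the log transform. The
detection-rate-vs-size curve bins lesion volumes into log-spaced bins
(10 by default), averages the rate per nonempty bin, and regresses the
binned means on log10 of the geometric bin center; patients (and lesions
within bins) are weighted equally. Constant scores or a degenerate curve
flag R² as undefined rather than reporting 0 or 1.

*Paired comparison.* Two performers' per-case scores are compared with the
two-sided Wilcoxon signed-rank test (scipy); identical samples return
p = 1 with a degeneracy flag.

## Phantom simulator

Ground truth is a union of digitized spheres with rejection-sampled
centers: every sphere fits inside the grid and any two sphere surfaces are
at least `min_separation` mm apart, so lesions are distinct components
under any connectivity and the per-lesion metadata (center, radius,
realized voxel volume) is exact. Spheres are deliberately unrealistic:
every property the toolkit tests is shape-agnostic, and spheres give
analytic control of count, volume and separation.

Defaults: 64³ grid at 1 mm isotropic, radii 1.5–6 mm (volumes ≈ 14–900
mm³, spanning the range where detection transitions from hard to easy),
lesion counts 3–12 per case in the challenge generator (variable lesion
burden), separation 3 mm. Simulated raters apply three independent error
modes — per-lesion radius jitter within ±`boundary_jitter_mm` (clamped so
a lesion never vanishes unless missed), per-lesion deletion with
`miss_prob`, and Poisson(`fp_rate`) false-positive spheres placed at least
`min_separation` from every true lesion so each is unambiguously a
detection false positive. Jitter degrades only overlap scores while the
detection rules tolerate it (until it breaches the α/β/size regime);
misses degrade only detection scores while surviving contours stay exact.
This separation is the fixture on which the two metric families are shown
to measure different things.

The default expert profile (jitter 0.2 mm, miss 1 %, FP rate 0.1) and the
graded algorithm profiles (jitter 0.8 + 0.4k mm, miss 10 + 7k %, FP rate
1.0 + 0.75k) emulate a challenge in which trained raters clearly
outperform every automatic method on both metric families — the structure
the clustering and ranking analyses are designed to resolve. What the
phantoms do *not* emulate: MRI intensities, anisotropic lesion shapes,
confluent lesions, rater bias correlated across raters, or
scanner effects. Passing tests therefore demonstrate the correctness of
the evaluation machinery under controlled error structure, not the
behaviour of any segmentation algorithm on real FLAIR images.

All randomness flows from explicit seeds through `numpy` generators
(`SeedSequence.spawn` per case and rater), and mask construction uses
integer-grid geometry, so outputs are bit-identical across runs and
platforms.

## Known limitations

* The LOP pool uses equal weights; performance-derived weights are
  possible via the `weights` argument but no claim is made that the fused
  consensus reproduces any specific challenge's consensus volumes.
* Fusing a *small* number of algorithms (e.g. four) of clearly unequal
  quality improves markedly on their average but does not reliably beat
  the single best algorithm case-by-case; the win fraction over the best
  individual varies with the random realization. Pooling many performers
  is what makes the composite dominate.
* Specificity depends on the region-construction convention; values are
  comparable only within one convention.
* Surface distances assume the affine is an axis-aligned scaling; oblique
  orientations would need the full affine folded into the transform.
* The problem sizes used by the test suite and acceptance script (32–64³
  grids, 10-case challenges, 50–100 random phantoms per oracle sweep) were
  chosen to exercise every code path at desk scale.
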