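# Methods

## Statistical model

Each fiber cluster (parcel) *c* summarizes a subject *s* by the mean of a
per-point diffusion scalar — FA (unitless, [0,1]) or MD (mm²/s) — pooled
over all points of all streamlines assigned to the parcel.  Pooling points
rather than averaging per-streamline means weights long streamlines
proportionally to their sampled length; a per-streamline variant would be a
one-line change in `mean_scalar_per_cluster` and is deliberately not a
second code path.

The per-parcel group comparison is ordinary least squares on

    y_sc = b0 + b1 * sex_s + b2 * (age_s - mean age) + e_sc

with sex coded female = 1 / male = 0 (fixing the sign convention "positive
effect = higher in females" everywhere) and a two-sided t-test on b1.
Centering age keeps the intercept interpretable and the design well
conditioned.  If age has zero variance the column is dropped and the test
reduces exactly to the two-sample t-test.  Subjects missing a parcel
(no streamlines) are dropped listwise for that parcel only — imputation
would manufacture precision where the data carry none.  Parcels with one
group entirely missing, fewer than 4 usable subjects, or zero residual
variance are flagged and assigned p = 1 rather than raising mid-analysis.

## Suprathreshold fiber clusters

Parcels with uncorrected p strictly below `alpha_unc` (default 0.05) are
merged into connected components of the k-nearest-neighbor geometry graph,
restricted to suprathreshold nodes; these components are the STFCs and
their **size** (member count) is the test statistic.  Three deliberate
readings of the procedure:

- **Members are suprathreshold only.**  "Combined with their neighbors" is
  implemented as merging neighboring *suprathreshold* parcels, not as
  absorbing sub-threshold neighbors — absorbing would inflate observed and
  permuted sizes asymmetrically and bias the corrected p.  The absorbing
  variant was considered and rejected.
- **Components split by effect direction** (default `split_by_sign`): an
  edge between a female>male parcel and a male>female parcel does not merge
  them, so each STFC carries one direction, as group-difference tables
  report.  `ignore_sign` is available.
- **Max-size null.**  Each permutation shuffles sex labels across subjects
  (each subject keeps its own age and features — the exchangeability-
  respecting scheme for a GLM with a covariate under the strong null of no
  group difference anywhere), reruns GLM → threshold → components, and
  records the maximum STFC size.  Comparing every observed STFC against the
  *maximum* gives strong family-wise error control in the classic
  suprathreshold-cluster sense.

Monte Carlo p-values use (1 + b)/(1 + N), which is never zero and keeps the
test valid at any N.  When the requested N reaches the number of distinct
label assignments C(n, n_F) (and that number is below 5·10⁵), the test
switches to exhaustive enumeration and reports the exact permutation
p-value b/N over all assignments, the identity included.  Inside the
permutation loop, "p < alpha" is decided as |t| > t_crit with t_crit
precomputed from the fixed residual degrees of freedom — identical to
thresholding p, without evaluating the t CDF per shuffle.

The family-wise type-I error of this construction sits at or slightly below
the nominal alpha (the suprathreshold set is sparse and discrete under the
null); the calibration experiment in `stfckit.validation` measures it
directly.

## Neighborhood graph

Cluster-to-cluster distance is the symmetrized mean-closest-point distance
between representative polylines: mean over a's points of the distance to
the nearest point of b, averaged with the b→a direction.  This is the
standard fiber distance of the fiber-clustering literature; it is symmetric
and non-negative but not a metric (no triangle inequality), which the graph
construction never relies on.  Each parcel is linked to its k nearest
parcels (default k = 10 — the neighborhood size is not dictated by the
method and 10 keeps ~1500-node graphs sparse yet connected); the edge set
is the symmetric closure, so degrees may exceed k.  For real data the same
machinery accepts pooled streamline point sets per cluster in place of
centroids.

Hemisphere bookkeeping: an atlas with n_b bilateral and n_c commissural
clusters yields 2·n_b + n_c per-subject parcels (716/84 → 1516).  Sides are
assigned by the sign of the mean x coordinate in RAS millimeters; |mean x|
below 0.1 mm is treated as midline and handled as commissural.

## Canonical correlation against behavior

CCA between the significant STFCs' member-cluster means (X) and a
behavioral battery (Y) is solved via the SVD of Qx'Qy, where Qx, Qy are QR
factors of the column-standardized (and optionally PCA-reduced) sides; the
singular values are the canonical r's, sorted non-increasing, and the first
is the major mode.  Rank deficiency after reduction and n ≤ retained
dimensions are hard errors naming the offending side, not warnings.

The permutation test shuffles Y's rows and refits the entire
standardize/PCA/CCA pipeline per shuffle; since column standardization and
PCA are invariant to row order, this is computed as re-orthogonalization of
the row-permuted prepared side — mathematically identical to a full refit.
The test is one-sided (r_perm ≥ r_obs): canonical correlations are
non-negative by construction.  Default 100,000 permutations; the
calibration experiments use 500, which is ample to decide p < 0.05.

PCA-before-CCA defaults to keeping 80% variance per side, following the
common practice for wide imaging/behavior matrices, with `None` switching
it off.  The calibration experiments run with PCA off because their
generative model is already low-dimensional: with independent feature
columns, PCA axes are arbitrary rotations and truncation would discard part
of the planted latent, attenuating r for reasons that have nothing to do
with the estimator under test.  Benjamini–Hochberg q-values (via
statsmodels) correct across an analysis family (e.g. 2 measures × 2
groups for one behavioral category).

## Synthetic cohorts

The generator works at the per-parcel feature level — it emulates the
objects the statistics consume, not the physics upstream.  Per cluster and
subject:

    y_sc = mu_c + delta_c * sex_s + gamma * (age_s - mean age) + e_sc

with mu_c ~ Normal(0.5, 0.05) (FA-like baselines), e_sc ~ Normal(0, sigma²)
homoscedastic by default (per-cluster sigmas available; real FA variances
are cluster-specific, but homoscedasticity is what the pooled calibration
band assumes), delta_c equal to `effect_size` on a planted region and 0
elsewhere.  Defaults mirror a large young-adult cohort: 340 F / 367 M (707
subjects), one shared truncated-normal age distribution 28.1 ± 3.4 y in
[22, 37] for both sexes (the emulated cohort is age-matched between groups),
sigma = 0.02 (a typical between-subject SD of parcel-mean FA), and 1516
parcels.

Geometry is a jittered 3D lattice (10 mm spacing, 0.5 mm jitter) of short
smooth arcs, so lattice neighbors are the polyline nearest neighbors and
the k-NN graph is non-trivial but predictable; a `line` layout exists for
worked examples.  The planted region must induce a connected subgraph of
that graph — enforced at generation — so recovered STFCs can be scored
against truth by Jaccard overlap.

Behavior with a known population canonical correlation rho is built by
shared-latent mixing: the latent z is the standardized mean of the planted
parcels' standardized columns (an exact linear combination of X), and each
of m behavior columns is c·z plus independent unit-variance noise with
c = rho / sqrt(m(1 − rho²)).  The optimal behavior combination then
correlates exactly rho with z, and no X combination can beat it because all
cross-covariance flows through z.

What the generator does **not** emulate: streamline-level tracking noise,
spatially varying FA along tracts, cross-parcel residual correlation beyond
the planted effect, non-Gaussian tails, missing parcels, or realistic
behavioral covariance.  Passing calibrations therefore certify the
statistical machinery under its own assumptions — not performance on real
tractography, where residual correlation between neighboring parcels will
make the max-size null heavier and the test more conservative.

## Reproducibility and numerics

All randomness flows from explicit integer seeds (`numpy.random.
default_rng`); the pipeline driver derives per-stage seeds as
sha256(global_seed, stage) mod 2³¹ and writes a manifest with config,
seeds and output digests — identical config + seed reproduces byte-identical
outputs.  Tables are TSV with `%.17g` floats and round-trip parsing, so
write→read is exact.  Degenerate GLM fits are detected by residual sum of
squares below 10⁻²⁴ of the response's scale.  Ties at the uncorrected
threshold use strict inequality (p < alpha).  Calibration experiment sizes
(200 null cohorts of 40 × 200; 25 recovery seeds of 100 × 200; 50 + 100 CCA
repeats at 500 permutations) were chosen so each binomial band is decisive
while a full run stays around a minute on one CPU.

## Known limitations

- The exhaustive permutation mode enumerates label assignments serially;
  it is intended for n ≲ 12 subjects (oracle checks), not production.
- Mean-closest-point distance between *centroids* is a proxy for
  streamline-set similarity; for real bundles, pass pooled point sets or
  precomputed distances to `build_neighborhood_graph`.
- The CCA stage assumes complete rows; behavioral missingness is handled by
  listwise deletion upstream of the call.
- Only ASCII VTK encodings are read or written; binary/appended polydata is
  out of scope.
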