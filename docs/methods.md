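# Methods

This note records the models implemented, the conventions chosen where
the literature allows more than one, and what the synthetic studies do
and do not establish.

## Patch identification and landscape metrics

Patches are maximal 4-connected components of equal nonzero species codes
(an 8-connectivity switch exists but is not the reference behaviour).
Perimeter counts every unit cell edge between a patch cell and anything
outside the patch: bare substrate, another species, or the plot boundary.
Boundary edges count (no torus wrap); a boundary between two
different-species patches is counted once *per patch*, so TE (the sum of
patch perimeters) double-counts shared edges — the self-consistent choice
given that MSI is built from the same per-patch perimeters.

* **Shape index**: the raster square-normalised form P/(4√A) in cell
  units, so any solid square scores exactly 1 and the index is invariant
  to the physical cell size.  The vector circle-normalised alternative
  would give a square ≈ 1.128 and is not used.
* **PSCV** uses the population standard deviation (so a single patch
  gives 0 exactly, and "all patches equal" gives 0).
* **SHDI** proportions are over vegetated (patch) area only; bare
  substrate is not a patch type.  This makes SHDI = 0 whenever exactly
  one species is present, regardless of cover, and bounds SHDI by ln PR.
* **Species-level aggregation** reports the sample standard deviation of
  patch areas and shape indices (NaN for a single patch); frequency is
  the percentage of plots occupied.
* **Distribution summaries** use moment skewness g1 and type-7 (linear
  interpolation) quartiles.

Degenerate inputs: an empty plot yields NP = 0 with all other metrics
NaN; `distribution_summary` flags sd and skewness NaN below two
observations; correlations with a constant column are NaN.

## Clustering and ANOVA

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on raw
abundances; Ward agglomeration in two variants.  `"D"` (default) applies
the Lance–Williams Ward update to the unsquared dissimilarities, `"D2"`
to their squares.  Only the D2 recurrence is available in scipy, but the
two are the same recursion on different scales, so Ward.D is computed
exactly as Ward.D2 on the square roots of the input with the merge
heights squared afterwards; both variants are verified against R's
`hclust` in the test suite.  The tree is cut at k = 3 by default (the
cluster count is a parameter; no optimality criterion is implied).
Cluster labels are canonicalised by each cluster's *characteristic
species* — the species whose within-cluster mean abundance is most
inflated over its overall mean — ordering clusters by that species'
within-cluster abundance, which makes labels stable under plot
reordering.  ANOVA is the classical one-way decomposition with t-based
95% confidence intervals per group; zero within-group variance with
distinct means is reported as F = ∞, p = 0.

## RLQ

With P = L/L··, row weights r, column weights c, and R̃, Q̃ the
weighted centred-and-normed tables (weighted second moment about the
weighted mean; no small-sample correction), the crossed matrix
X = R̃ᵀ P Q̃ is decomposed by SVD — numerically safer than an
eigendecomposition of XᵀX, which the tests use as the independent oracle.
Eigenvalues are squared singular values; singular values below 1e-12
relative to the largest are treated as zero rank.  Ordinal traits (the
1–6 lateral-spread classes) enter as quantitative scores.  Axis signs
from an SVD are arbitrary: each axis is oriented so that the variable
(metric or trait) with the largest absolute loading on it loads positive,
and left/right vectors flip together so X is unchanged.  Variable–axis
correlations are weighted Pearson correlations of the raw variables with
the axis scores (weights r for metrics/plots, c for traits/species).
Per-axis inertia contributions are 100 × squared loadings (summing to
100 per axis); the two-axis totals therefore sum to 200 across a variable
set.

## Partial RLQ

The covariate partitions the plots.  The default conditioning centres
each R column to weighted mean zero *within every class* (class weights =
CA row weights renormalised within the class) and re-norms columns to
weighted variance 1; Q and L are untouched, since the covariate
partitions samples, not species.  A column with no residual within-class
variance is set to exactly zero rather than renormed — renorming the
float residue of the class means would amplify rounding noise to full
amplitude.  An alternative scheme that additionally conditions L
(replacing the global expected profile r cᵀ by class-conditional
profiles r c_gᵀ) is available via `condition_l=True`; with a single
class both schemes reduce exactly to the basic RLQ.  The diagnostic is
the comparison of the axis-1 co-inertia share with the basic analysis: a
much higher partial share would mean the covariate was masking the
trait–configuration gradient.

## Fourth-corner tests

X's entries are weighted Pearson-type fourth-corner correlations, so
Σλ = ΣX² ties the modules together (asserted to 1e-10).  Model 2
permutes plot rows of L, model 4 species columns.  The implementation
permutes rows of R (resp. Q) instead, keeping the CA weights attached to
L's rows: permuting L by σ pairs (R row standardised under r∘σ, L row
σ(i)), which is the same pairing-with-weights as permuting R by σ⁻¹ and
standardising under r — the tests verify the equivalence against a
literal permute-L implementation.  Per cell, two-sided p-values on |X|
with the (b+1)/(B+1) estimator (never 0); ties are counted with a 1e-12
absolute guard so the identity permutation always yields p = 1.  The
global statistic is ΣX² under the same permutation schemes.  The
combined per-cell p is max(p₂, p₄) — the sequential rule that rejects the
overall null (trait and metric associated) only when both component
nulls are rejected — flagged at both α = √0.05 and α = 0.05.
A Benjamini–Hochberg adjustment across cells is available behind a flag
and off by default.  The variable–axis association tests hold the
observed axis scores fixed and permute the variable's rows (model 2 for
metrics, model 4 for traits); the statistic is the weighted correlation
(the quantitative–quantitative reduction of the squared-association D²
statistic, reported alongside as its square).

**Level of the combined test.**  The max-p combination *controls* α but
does not attain it under the complete null: when both component nulls
hold, the rejection probability lies between α² and α (the two p-values
share the same observed statistic and are therefore positively
dependent, which is why the rate is well above α²).  Measured on
synthetic null studies the per-cell combined rate is ≈ 0.02 at α = 0.05,
while the individual models are exact-level.  The test suite asserts the
α band for the individually null models and conservatism for the
combination.

## Synthetic studies

The generator emulates the field design: 46 plots of 100 × 100 one-cm
cells, 16 species, 9 traits (one ordinal 1–6 column), 7 metrics, and two
three-class covariates assigned independently of everything (their null
effect is the reference scenario; an optional `covariate_effect` shifts
the plot environment by terrain-age class for partial-RLQ exercises).
Patch counts per plot default to 30 with lognormal target areas
(σ = 1, mean ≈ 47 cm², areas clipped to [1, 400] cells), i.e., ≈ 15%
vegetated cover — matching the published species totals (≈ 1,530 cm² of
cover per plot).  Patches grow by Eden accretion (uniformly random
frontier-cell occupation) which yields shape indices in the ≈ 1.0–1.7
range and positively skewed area distributions; overlaps are first-come.

The built-in truth is one latent axis: species scores z, plot scores e.
Traits are noisy loadings on z.  The coupling β acts twice, mirroring
the idea that patch geometry is a species attribute:

* **composition**: per-plot species rates ∝ base_s · exp(β·tanh(z_s e_i)),
  renormalised within each plot (the tanh bound prevents single-species
  takeover, keeping the co-inertia signal monotone in β);
* **geometry**: a species' log expected patch area is shifted by
  β/2 · z_s (mean-corrected), everywhere it occurs.

R is computed from the emitted rasters via the metrics module and L is
the rasters' per-species cell count, so the tables are exactly
reproducible from the grids and everything is bit-deterministic in the
seed.

What the synthetic studies do *not* emulate: spatial autocorrelation
between plots, mechanistic succession (dispersal, competition kernels),
covariate-structured environments (except via the optional effect), and
the multi-gradient trait structure of real floras — a single latent axis
drives everything, which is why synthetic RLQ axis-1 shares (≈ 98%) run
higher than in real communities.  Two consequences for interpreting
passing tests: (i) power and recovery results speak to a one-gradient
world; (ii) because R derives from the same realised mosaic as L, the
L↔R link is mildly non-null even at β = 0 (an abundant species inflates
both its cover and the plot's patch counts), so β = 0 is a strict null
only for the trait side (model 4 and the combined trait–metric flag) —
complete-null level checks use tables with R drawn independently.
Relatedly, since all traits load on z, the species' trait-axis scores
correlate with z even at β = 0; the *signed* correlation is
symmetrically distributed around zero there, and only at β > 0 does the
axis align with z reproducibly.

## Problem sizes and tolerances

Null-level simulations use 500 replicates of a reduced study (12 plots,
8 species, 5 traits, 30 × 30 grids, 199 permutations): the
(b+1)/(B+1) estimator is exact-level at any permutation count, so the
reduction does not bias the level check, and 199 permutations make the
achievable rejection rate at α = 0.05 equal 9/200 = 0.045.  Power,
monotonicity and recovery checks run at the full design size with 6–10
replicates per β.  Rank tolerance 1e-12 (relative) for the spectrum;
float-residue guard 1e-24 (relative variance) for conditioned-away
columns; permutation tie guard 1e-12.
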