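# Methods

## The question and the estimand

Species richness of tropical tree communities rises with rainfall, but the
*evolutionary* diversity of a community need not follow. The quantity of
interest here is lineage diversity (LD): the standardized effect size of
Faith's phylogenetic diversity, i.e. how much evolutionary history a
community contains relative to what its genus count alone would predict.
The package asks how LD varies along a mean-annual-precipitation (MAP)
gradient and whether its maximum sits at intermediate rainfall — the
environmental-crossroads expectation, under which communities at the
wet/dry transition mix deeply divergent lineages adapted to either extreme.

## Lineage diversity

Faith's PD of a community is the summed branch length of the minimal
subtree spanning its taxa. By default the subtree includes the path to the
root (the common convention in community-phylogenetics software); a flag
restricts it to the MRCA. The null model shuffles the tip labels of the
whole phylogeny — the taxon pool is all tree tips, not a richness-matched
resample of the matrix — and LD is the z-score of observed PD against
`n_null` such shuffles (default 999; the headline analyses here use 199
and the calibration run 499). One permutation per iteration is shared by
all sites, which makes the exhaustive-enumeration oracle well defined and
halves the cost; an independent-per-site mode exists behind a flag. The
null sd uses the n−1 estimator for sampled nulls and the exact population
sd when the permutation set is enumerated exhaustively. Sites whose null
is permutation-invariant (`degenerate_null`) or with fewer than two genera
(`low_richness`) carry missing LD and are excluded from regression input.

Computation is vectorized: PD for all sites under one permutation is a
single sparse matrix product between the site-by-tip indicator and the
edge-by-tip incidence of the tree, so a 200-site × 920-tip analysis with
999 permutations takes seconds.

## Phylogenetic signal

Pagel's λ multiplies the off-diagonal entries of the Brownian covariance
(shared root-to-MRCA path lengths); the diagonal is untouched. The branch
-length version of the transform (internal branches × λ, terminal branches
stretched to preserve tip depths) is provided for ultrametric trees; the
covariance version backs the likelihood. Given λ, the root state and rate
σ² have closed-form GLS/ML solutions, so the profile likelihood is
one-dimensional; it is maximised on [0, 1] (the interpretable range; no
extension above 1) from a five-point grid with bounded refinement.
Significance is a likelihood-ratio test against λ = 0 referred to χ²₁.
Because λ = 0 is a boundary of the parameter space, the χ²₁ reference is
conservative: in null simulations ~80% of fits land exactly at λ̂ = 0
(LRT = 0, p = 1), and the type-I error at α = 0.05 is at or below nominal.
A 50:50 boundary-mixture p-value is exposed alongside the primary χ²₁ one.

## Missing genera, rarefaction, tree sets

Genera present in the community matrix but absent from the tree are
attached inside their most derived consensus clade (MDCC): an edge of the
clade's subtree (stem included) is drawn with probability proportional to
its length — interpreting "random position" as uniform over positions, not
over edges — the attachment time is uniform along the edge, and the new
terminal branch runs to the present, preserving ultrametricity.
Zero-length edges are accepted on input but never chosen as graft targets.
The richness control subsamples every site at or above a target genus
count (a quarter of the maximum richness among wet sites, following the
convention that motivated the design) without replacement, prunes the tree
to each subsample's pooled genera, and averages LD over repetitions;
per-site subsampling was chosen over global matrix rarefaction, whose
reading is also defensible. LD over a set of trees (posterior-style
uncertainty) averages per-tree sesPD runs with split seeds.

## Model competition

Three mean structures for LD vs MAP are compared by AIC under a Gaussian
likelihood with every estimated parameter counted (linear k = 3, quadratic
k = 4, piecewise k = 6: two slopes, two intercepts, the break point, the
residual variance; ties < 1e−9 go to the smaller k). The piecewise model
fits two *independent* lines — no continuity constraint, so the mean may
jump at the break — with the break point found by exhaustive search over
observed MAP values leaving at least `min_segment` (default 5) points on
each side; exhaustive search is transparent, deterministic, and exactly
checkable against a brute-force oracle. The break point is located on the
pooled OLS fit first, and spatial GLS is then fit separately on each side
(a GLS-first break search sits behind a flag).

Spatial GLS uses great-circle (haversine, Earth radius 6,371 km) distances
and four correlation kernels — exponential exp(−d/r), Gaussian
exp(−(d/r)²), linear and spherical with compact support at r — without a
nugget unless requested. The range r is estimated by profile maximum
likelihood over [1 km, 2 × max distance] (coarse geometric grid, then
bounded refinement); β̂ is the usual (XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹y. AIC counts β, σ²
and r (full ML, not REML, so models with different fixed effects remain
comparable); ΔAIC is reported against the same design with no spatial
structure. Since no standard r² exists for GLS, the squared Pearson
correlation between fitted and observed values is reported. Confidence
bands for the mean response come from the delta method on the coefficient
covariance with t quantiles, per segment for the piecewise model; break
-point uncertainty is deliberately excluded from the band.

## The synthetic-data generator

The generator exists so that every stage has ground truth. Defaults are
one synthetic "study": a 300-tip constant-rate birth–death genus tree
(birth 1.0, death 0.2 events/Myr, conditioned on the tip count; retried on
extinction), niches drawn MVN with λ_true = 0.5 and σ² = 8,000
(mm/yr)²/Myr, truncated at 1 mm (MAP is physically nonnegative; the clip
count is recorded), 200 sites with MAP on a jittered uniform grid over
300–3,500 mm, a stored unit-variance Gaussian noise field with exponential
spatial correlation (range 300 km) that the pipeline adds to the
regression response scaled by `noise_sd` = 0.3, a 21% protection rate, and
Bernoulli niche-filtered assembly through a Gaussian kernel (breadth
250 mm) scaled to an expected richness of 40 genera.

The `ech` preset gives the niche means a three-pool structure: the
youngest clade holding ~15% of the tips becomes the dry pool (mean
800 mm), the youngest disjoint clade of ~30% the wet-specialist pool
(3,200 mm), and the dispersed remainder sits at 1,900 mm. Both extremes
being phylogenetically compact is essential: with a single dry clade
nested in an otherwise-wet pool, crossroads communities never exceed the
tip-shuffling null (swapping unique deep branches for redundant young ones
lowers PD), the wet flank of the LD profile stays flat, and the site of
maximum LD wanders to the wettest extreme. With both extremes clustered
and the background dispersed, the LD maximum falls between the pool means
in ≥ 18 of 20 replicates and the decile profile peaks interior — and the
asymmetry (small, very young dry clade vs larger wet clade) reproduces the
steep-rise/shallow-decline shape that favors the piecewise model over the
quadratic. The `null` preset assembles communities with no filtering and
calibrates the machinery: LD there has mean ≈ 0 and sd ≈ 1.

What the generator does *not* emulate: real trees are not constant-rate
birth–death; real assembly includes dispersal limitation, abundance
structure and richness gradients beyond niche filtering; protection status
is spatially random rather than policy-shaped; and the spatial noise field
enters the regression stage only, not community assembly itself. Passing
tests therefore show the *inference machinery* is correct and calibrated
under the assumed structure, not that any real flora behaves this way.
One consequence worth noting: the preset's regression residuals are
dominated by spatially unstructured assembly and permutation noise, so the
GLS stage usually (correctly) selects "none" there; detection of genuine
spatial structure is exercised separately on explicitly
exponential-correlated simulations, where the exponential kernel beats the
non-spatial model in every run and recovers the range within a factor of
two.

## Numerical choices and degenerate inputs

Ultrametricity is asserted to a relative tip-depth spread of 1e−6 and
preserved to 1e−9 by grafting. Near-singular phylogenetic covariances
(nearly simultaneous divergences) get a single proportional jitter of
1e−10 × mean diagonal before failing with a duplicated-tip-depth
diagnosis; GLS correlation matrices get one 1e−10 ridge attempt. Every
stochastic stage draws its generator from the user seed plus a fixed stage
key (CRC-split `SeedSequence`), so stages are independently reproducible
and identical configurations produce byte-identical output files. The
conservation top set uses the ceiling of fraction × unprotected-valid
sites (an all-sites denominator is available), descending LD with
lexicographic site-id tie-break.

## Known limitations

λ is not estimated above 1 and its LRT is conservative near the boundary.
The piecewise model fits a single break only. GLS assumes stationary,
isotropic correlation in great-circle distance with no nugget. The
problem sizes used by the shipped analyses (300 genera, 200 sites,
199–499 permutations, 50–100 graft seeds) were chosen as the smallest
sizes at which the estimators' sampling noise is clearly below the effects
being demonstrated.
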