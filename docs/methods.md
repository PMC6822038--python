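# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## Data model and filtering

Trees are plain Newick with branch lengths in Ma; node support
annotations are ignored.  Ultrametricity is checked with a relative
tolerance of 1e-6 on the root-to-tip depth spread — beyond that the tree
is accepted with a warning and a flag, because time-calibrated trees
written to file routinely carry rounding noise.  Coordinates are assumed
WGS84 decimal degrees; longitudes are normalized to [−180, 180] and no
antimeridian wrapping is attempted (the motivating fauna is
Northern-Hemisphere continental).  Duplicates are exact
(species, lon, lat) triples after float parsing; no grid-based spatial
thinning is performed.  Species with fewer than `min_n = 5` usable
records are removed from the table and pruned from the tree
(degree-2 nodes suppressed, branch lengths summed), so downstream
analyses always see label-aligned inputs.

Rasters are single-band geographic grids (ESRI ASCII or GeoTIFF with
the standard pixel-scale/tiepoint tags); projected rasters are rejected
rather than reprojected.  Extraction is nearest-cell with half-open
cells [x, x + res) — a point on an interior edge belongs to the
higher-coordinate cell — and no interpolation: bioclim layers are
climatologies at fixed resolution, and smoothing them would manufacture
precision.  Temperature units follow the input rasters; no ×10 rescaling
is applied, so users mixing WorldClim versions must harmonize units
themselves.  BIO17 is taken in its standard definition (precipitation of
the driest quarter).

## Pagel's λ

The phylogenetic covariance C has C[i,j] = MRCA depth and tip depths on
the diagonal.  λ multiplies the off-diagonal only.  For a trait vector x,
the mean is profiled by GLS (μ̂ = 1ᵀC⁻¹x / 1ᵀC⁻¹1) and the rate by ML
(σ̂² with denominator n), leaving a one-dimensional profile likelihood
in λ.  It is maximized on [0, 1] by evaluating a 21-point grid and
refining the bracketing interval with bounded Brent search
(xatol = 1e-8); the hard boundaries 0 and 1 are always candidates.  The
upper bound is fixed at 1 rather than the tree-dependent maximum because
the definition used here caps λ at 1.  λ = 0 is evaluated exactly for
the likelihood-ratio test, which uses the χ²₁ upper tail; since λ = 0
lies on the boundary of the parameter space this reference is
conservative (simulated type-I error ≈ 0.015 at α = 0.05), which is the
standard practice for this test.  Degenerate inputs fail loudly: a
zero-variance trait raises an error, and a profile flat to within 1e-10
(e.g. a star tree, where λ is unidentifiable) resolves to λ̂ = 0 with an
`unidentifiable` flag.  Each of the median, min and max summaries gets
its own fit per variable; all three use the same LRT procedure.
Standardization (for disparity) uses the sample (n−1) standard
deviation.

## Disparity through time

Disparity is the mean pairwise **Euclidean** distance between
standardized trait rows — not the mean squared distance some
implementations default to; a `metric="squared"` switch provides the
other convention.  The curve walks internal nodes from the root in order
of depth.  A lineage (edge p→c) is alive at time t iff
depth(p) ≤ t < depth(c) ("just after" the divergence); exactly tied
divergences therefore split simultaneously and share one lineage set —
a fixed, deterministic convention for a measure-zero situation on real
trees.  Singleton (tip-only) lineages count as zero-disparity clades in
the average.  The root point is 1 by definition (the single root lineage
is the whole clade).  Times are reported relative to tree height.

The null envelope estimates the trait rate matrix Σ̂ from
phylogenetically independent contrasts (cross-product of contrasts over
n−1; multifurcations resolved by sequential zero-length pairing),
simulates trait matrices with tip covariance C ⊗ Σ̂ and root state 0,
re-standardizes every replicate — so simulated and observed disparities
share the per-variable scale — and takes pointwise 2.5/50/97.5%
quantiles at the observed node times.  Under Brownian truth the observed
curve falls inside the 95% band at ≈ 94% of time points on average.

## Niche equivalency

Backgrounds are occurrence bounding boxes buffered by 10° on all sides
and clipped to the raster extent and to |lat| ≤ 90; their pixel values
come from every valid cell center.  One PCA (variables centered and
scaled to unit sample variance) is calibrated per insect–host pair on
the pooled background pixels of the two entities — the per-pair choice
matches the per-species backgrounds, and a global PCA would leak
information across pairs.  Occurrences and backgrounds are projected on
the first two axes; the grid extent is the range of the pooled
background scores, evaluated at R × R cell centers (R = 100).

Densities use a separable Gaussian product kernel with the per-axis
normal-reference bandwidth h = σ·n^(−1/6) (the 2-D Scott/Silverman
rule), computed from the occurrence scores for o and the background
scores for e.  Corrected occupancy is o/e, normalized to sum 1.  Cells
whose availability is **at or below 5% of the modal availability** are
treated as absent from the study area and get z = 0.  This guard is
deliberately much stronger than a pure numerical-underflow cutoff:
Gaussian kernel tails mean o and e are both positive everywhere, and
with a looser guard a fifth or more of the occupancy mass can end up in
climates that barely exist in the background, which both distorts D and
destroys the power of the permutation test.  Occupancy is a preference
measure and is only meaningful where the environment actually occurs.

The permutation test freezes backgrounds, PCA, grid extent and the
availability surfaces (including their bandwidths), pools the two
entities' occurrence scores, and resplits them at the original sizes
100 times, recomputing the occurrence bandwidths per split (subset
compositions differ).  The p-value is (#{D_null ≤ D_obs} + 1)/(reps+1),
one-sided — a low observed D rejects equivalency; a `two_sided` option
doubles the smaller tail.  Simulations with both entities drawn from
one niche put the empirical type-I rate at ≈ 0.056 over 1,000 runs,
against the exact permutation level 5/101 ≈ 0.0495.

## Synthetic data

The generators produce every input class with known truth and are pure
functions of (parameters, seed).  Climate rasters are latitudinal
gradients plus optionally correlated Gaussian cell noise at roughly
temperate-zone magnitudes (e.g. BIO6 = 22 − 0.9·|lat| °C).  Occurrences
are drawn cell-wise proportionally to Gaussian suitability around a
per-variable optimum, with optional hard one-sided truncation, and
placed uniformly within the chosen cell.  The desk-scale defaults —
60 × 120 cells at 0.5°, 40 tips, 30 occurrences per species, 50 per
entity in pair scenarios — keep every simulation-based check on a
single CPU in minutes.

The pair scenarios fix the qualitative contrast of interest: the host
pool is a climate generalist (niche breadths twice the single-species
defaults, so its realized range spans a wide climatic band, as the union
of several tree species' ranges does), and the insect either shares the
host niche exactly ("equivalent") or has suitability hard-zeroed above
the BIO5 optimum ("truncated" — confined to the colder half).  The
clade scenario evolves a latitudinal optimum along a Yule tree under
λ-transformed Brownian motion and centers each species' niche on the
gradient climate at its optimum, so phylogenetic signal propagates into
the realized climate summaries.

What the synthetic data do **not** emulate: spatial autocorrelation of
occurrences beyond climate suitability (no dispersal limitation, no
biotic interactions), sampling bias, georeferencing error, coastlines or
topography, and observational host-association noise.  Passing tests
therefore show that the estimators and tests behave correctly when their
assumptions hold — not that real occurrence databases meet those
assumptions.  County-centroid detection in particular is not
implemented: there is no reproducible rule for it, so curation of real
records remains the user's responsibility.

## Known limitations

- λ fits are univariate; no joint multivariate λ, and no alternative
  signal statistics (Blomberg's K, Moran's I).
- The DTT envelope is descriptive; no MDI significance test and no
  OU/early-burst nulls.
- Multi-tree (posterior) DTT overlays accept a multi-tree Newick file;
  generating posterior samples is out of scope.
- Niche analyses stop at equivalency: no similarity/background tests,
  no expansion/stability/unfilling decomposition, no SDM fitting.
- Loess smoothing seen in typical DTT figures is a display concern; all
  outputs carry raw curves.
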