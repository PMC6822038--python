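# phyloniche

Climatic-niche evolution on phylogenies, for comparative ecologists
studying host-specialized herbivores (and anyone else with a
time-calibrated tree, occurrence points and a bioclimatic raster stack).
The package answers two questions about a clade such as the
conifer-feeding aphids and their pine hosts:

1. **Is climate tolerance phylogenetically conserved?**  Per-species
   climate summaries (median/min/max of BIO5, BIO6, BIO10, BIO11, BIO17
   at the occurrence points) are tested for phylogenetic signal with
   maximum-likelihood **Pagel's λ** and tracked through time with a
   multivariate **disparity-through-time (DTT)** curve against a
   Brownian-motion null envelope.
2. **Does the insect occupy its hosts' full climatic niche?**  A
   kernel-density **niche-equivalency test** in environmental PCA space
   compares each insect with the pooled occurrences of its host plants
   via **Schoener's D** and a pooled-split permutation null.

## The statistics

*Pagel's λ.*  Under Brownian motion on a time-calibrated tree, the trait
covariance of species *i*, *j* is C<sub>ij</sub> = depth of their MRCA.
λ multiplies the off-diagonal of **C**: the likelihood of the tip vector
**x** ~ N(μ**1**, σ²**C**(λ)) is profiled over λ ∈ [0, 1] (GLS mean, ML
rate), and λ = 0 is tested with a χ²₁ likelihood-ratio test.

*DTT.*  Disparity is the mean pairwise Euclidean distance between
standardized climate vectors.  Starting at the root, each divergence
event records the mean relative disparity (subclade/whole-clade) of all
lineages alive at that time; the null envelope is the pointwise 2.5–97.5%
band of curves from multivariate BM simulated with the rate matrix
estimated from independent contrasts.

*Equivalency.*  Per entity pair: background = occurrence bounding box
buffered 10° and clipped to the rasters; one PCA over the pooled
background pixels; occurrence and background scores gridded at R × R
(R = 100) with Gaussian kernels; occupancy z ∝ o/e (occurrence density
over availability) normalized to 1.  D = 1 − ½·Σ|z₁ − z₂|; the null
pools both occurrence sets and resplits them at the original sizes 100
times; p = (#{D<sub>null</sub> ≤ D<sub>obs</sub>} + 1)/(reps + 1).

## Worked example

Everything below runs on synthetic data generated by the package itself
(`phyloniche.synth`), so it works offline:

```python
import numpy as np
from phyloniche import synth, signal, climate, core_io, overlap

# a 40-species clade whose latitudinal optima evolved with lambda = 1
tree, occ, rasters, truth = synth.make_clade_scenario(lam=1.0, seed=9)
occ, tree = core_io.filter_min_occurrences(occ, tree, min_n=5)
values = climate.extract_at_points(rasters, occ)
tm = climate.trait_matrix(climate.summarize_species(values))
for res in signal.fit_all(tree, tm):
    print(f"{res.variable_id:>6}  lambda={res.lambda_hat:.3f}  "
          f"p={res.p_value:.3g}")

# an insect confined to the colder half of its hosts' niche
ins, host, rasters, _ = synth.make_pair_scenario("truncated", seed=3)
res = overlap.equivalency_test(ins, host, rasters, reps=100, seed=5)
print(f"D_obs={res.d_obs:.3f}  p={res.p_value:.3f}")
```

Output:

```
  BIO5  lambda=0.904  p=0.00121
  BIO6  lambda=1.000  p=5.73e-05
 BIO10  lambda=0.878  p=0.00142
 BIO11  lambda=0.908  p=0.000555
 BIO17  lambda=0.896  p=0.00024
D_obs=0.633  p=0.010
```

High λ with small p-values on every variable: the simulated niches are
about as heritable as the generating model says.  The truncated insect
overlaps its hosts at D ≈ 0.63 but the permutation test still rejects
equivalency (p = 0.01) — the "narrower, colder than the host" pattern.

The same analyses are available from the shell (`phyloniche simulate`,
`extract`, `signal`, `dtt`, `equivalency`), each as a thin wrapper over
the functions above.

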