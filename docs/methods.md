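# Methods

This note documents the models implemented in `flyscreen`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Ommatidial disorder score

**Model.** A wild-type compound eye packs ommatidia on a hexagonal lattice;
rough-eye phenotypes perturb facet positions, remove facets, or fuse
adjacent ones. The phenotypic score summarises local lattice disorder. For
each ommatidium the k = min(6, N−1) nearest neighbours define local
vectors; ties in distance (exact on square lattices) are broken by smaller
azimuth, then index, so results are deterministic. The per-ommatidium
disorder is

    d_i = w_L * (SD of vector lengths / mean length)
        + w_A * mean_j |Δθ_j − 60°| / 60°,

with the angular gaps Δθ_j taken between azimuth-sorted neighbour vectors
(they sum to 360°). The score is S = 100 × mean(d_i) over interior
ommatidia. Defaults w_L = w_A = 1 weight metric and angular disorder
equally; both ingredients are dimensionless, so S is invariant under rigid
motions and uniform scaling, and S = 0 exactly on any perfect hexagonal
lattice. The number of detected ommatidia enters through the interior-count
normalisation only: missing or fused facets raise S through the distorted
neighbour geometry they leave behind, not through an explicit count
penalty. This is a deliberate simplification; no numeric parity with any
particular published eye-scoring tool is claimed — the score is validated
by its zero point, invariances, and monotone response to planted disorder.

**Boundary handling.** Ommatidia on the convex hull of the center set have
boundary-truncated neighbour rings and are excluded. On a staggered
hexagonal edge, some points strictly inside the hull are still truncated
(the hull passes through the protruding rows only), so points within 0.75×
the median nearest-neighbour distance of the hull boundary are excluded as
well. The 0.75 collar sits between the staggered-edge offset (0.5× spacing)
and the row pitch (√3/2 ≈ 0.87× spacing), so on a clean lattice it removes
exactly the outermost ring; being expressed in units of the median
nearest-neighbour distance keeps it scale- and rotation-invariant.
Degenerate center sets (collinear) have no interior and are rejected by the
scorer with a clear message.

**Detection.** Centers are local maxima of a difference-of-Gaussians
band-pass at 0.2× and 0.6× the expected spacing (robust to illumination
gradients), kept if separated by ≥ 0.6× spacing and above the
`threshold_quantile` (default 0.9) of the filtered image, then refined by
an iterated intensity-weighted centroid whose window re-centers on the
running estimate — at convergence the window is centered on the weighted
center of mass, which removes the truncation bias a fixed window would
have. On noise-free synthetic lattices the residual center error is a few
hundredths of a pixel and the detect-then-score pipeline returns S < 1.
A constant image yields zero detections (not an error). At high jitter
(σ ≳ 0.25× spacing) facets genuinely overlap and the minimum-separation
rule merges them; the score saturates rather than growing linearly, which
matches how severely rough eyes lose countable facets.

**Rank concordance.** `percentile_ranks` uses the midrank formula
100·(#strictly below + 0.5·#ties)/n per condition and reports the Pearson
correlation of the rank vectors across two scoring conditions; intended
for comparing severity orderings of the same lines scored under two
protocols (e.g. with and without an RNAi amplifier).

## Two-hit interaction model

The screen compares four genotypes per pair (control, A, B, AB) with
replicate severity scores; higher score = more severe (this direction
matters: negating scores swaps suppressor and enhancer calls, which is
covered by a test). The 2×2 factorial ANOVA uses the classical cell-mean
decomposition for balanced designs and type-II sums of squares (nested
least squares) otherwise — type II because the two knockdown factors have
no a-priori ordering. The interaction always has one degree of freedom.
Zero residual variance (all scores identical) is reported as an undefined
F with a flag, not an exception. The statsmodels `anova_lm` decomposition
serves as an independent oracle in the tests (agreement to 1e-6 relative
on random balanced and unbalanced tables).

Classification: if the interaction p < α, the sign of the contrast
Δ₁ − Δ₂ = [mean(AB) − mean(A)] − [mean(B) − mean(control)] decides
suppressor (negative) vs enhancer (positive); otherwise a significant B
main effect calls an additive relationship; otherwise none. Full rescue is
flagged for suppressors whose AB-vs-control Mann-Whitney comparison is
non-significant while A-vs-control is significant. Mann-Whitney tests are
two-sided by default with a one-sided option. Per-pair tests are reported
without cross-pair correction by default (validation in a real screen
comes from independent RNAi lines); Benjamini-Hochberg across interaction
p-values is available as an option and re-gates the calls on adjusted
values. No fixed F cutoff is hard-coded: F and p are reported with their
degrees of freedom, since a critical F is meaningless without the residual
df of the particular design.

Under the additive null the interaction test's type-I error is calibrated:
the acceptance suite simulates 2000 null pairs (n = 12, normal noise) and
requires a rejection rate within [0.035, 0.065] at α = 0.05.

## Gene-set enrichment and overlap

**DE filter.** |log₂FC| > 1 AND FDR < 0.05, both strict: a gene exactly on
either threshold is excluded.

**Parametric Z-scores.** Z = (S_m − μ)·√m/δ, where S_m is the mean log₂FC
of the m measured member genes and μ, δ the mean and sample standard
deviation (n−1) of all measured log₂FC values. The √m factor is the
classic parametric-enrichment convention and the default; a flag drops it
for the literal set-mean-vs-population reading. δ uses the sample SD
because that is the convention of the procedure's reference
implementations. Terms with fewer than 2 or at least 500 measured members
are excluded (the cap removes very general terms; `max_set_size=None`
lifts it). Two-sided normal p-values are BH-corrected across retained
terms with a 0.01 significance cut by default. Under permuted fold-changes
the Z-scores are standard normal (KS-checked in the acceptance suite).

**Overlap permutation test.** The statistic counts universe genes
differentially expressed in ≥ k models (k ∈ {2, 3} by default). The null
resamples each model's set uniformly without replacement from the
annotation universe at its observed size — the universe is the resampling
pool because the statistic counts universe genes. The empirical p uses the
add-one estimator (b+1)/(n_perm+1), which never returns zero. Note the
statistic is not monotone in set similarity when sets are large relative
to the universe: random sets spread coverage across more distinct genes,
so planted sharing is detectable only when the universe is much larger
than the sets. The k-fold intersection of all models *is* maximised by
identical sets, which is how the minimal-p contract is exercised.

**Homolog mapping.** Many-to-many mapping tables are resolved by policy:
keep all partners (default) or best score only (ties broken
lexicographically). Unmapped genes are dropped and counted in a report.

**Set-score t-test.** A one-sided Welch t-test comparing a user-supplied
per-gene score between set members and non-members is provided as an
optional helper and is not wired into the pipeline, because the choice of
gene-level score is analysis-specific.

## Connector genes

Edges below the configurable weight cutoff (default: keep all) are
dropped, and the thresholded graph is treated as unweighted — geodesics
are hop-count shortest paths, which makes "number of critical paths using
an edge" well-defined. Per seed one BFS produces distances and
Brandes-style geodesic counts σ; for a pair (s, t) at distance d a node v
lies on a geodesic iff dist(s,v) + dist(v,t) = d and carries
σ_s(v)·σ_t(v) of the pair's geodesics; an edge (u,v) carries
σ_s(u)·σ_t(v) iff dist(s,u) + 1 + dist(v,t) = d. Connectors are the
non-seed interior nodes over all pairs; seeds lying on other pairs'
geodesics are never reported as connectors. Total edge criticality equals
Σ over pairs of (geodesic length × geodesic count), an identity the tests
check, and the whole procedure is validated against exhaustive enumeration
of simple paths of geodesic length on random graphs up to n = 30.

Annotation enrichment uses the one-sided (greater) hypergeometric tail
with the non-seed network nodes as the default background — the network is
the frame connectors are drawn from, so genome-wide backgrounds would
overstate enrichment. Random-seed controls rerun the full analysis for
random k-subsets of a user-chosen pool and report per-draw odds ratios and
p-values with summary quantiles; draws with no connectors are recorded,
not silently dropped.

## Synthetic data: what it emulates and what it does not

* **Eye images** are offset-row hexagonal lattices (odd rows shifted half a
  spacing, row pitch √3/2 × spacing) of isotropic Gaussian blobs
  (SD = radius/2, truncated at 3 SD), with per-site Gaussian jitter,
  independent dropout, nearest-neighbour fusion at blob midpoints, and
  additive Gaussian pixel noise clipped to [0, 1]. Defaults: 20×20 sites,
  spacing 10 px, radius 3 px, noise SD 0.05 — a moderate noise level at
  which detection is still near-perfect, chosen once as the study
  condition. Not emulated: necrotic patches, glossiness, pigment loss,
  eye-size differences, illumination fields, or realistic facet texture.
  Passing tests therefore show the scorer responds correctly to
  *geometric* disorder, not that it handles every real imaging artefact.
* **Score tables** draw i.i.d. normal replicates around planted cell
  means; the full-rescue class pins the two-hit mean to control (its
  interaction shift is derived as −(effect_a + effect_b)). Real screens
  have heteroscedastic, sometimes skewed scores; the Mann-Whitney rescue
  test does not assume normality but the planted recovery rates do.
* **Expression studies** assign FDR values consistently with the planted
  fold-changes (FDR < 0.05 iff |log₂FC| > 1) instead of fitting a DE
  model, since count modelling is out of scope; each model carries one
  knockdown gene with log₂FC drawn in [−1.3, −1.05] (≈50% expression
  drop, safely past the strict filter). Cross-model sharing is controlled
  by the shared fraction of each model's DE genes (default 0.4, n_de 100,
  10,000 genes, 6 models).
* **Networks** are Erdős–Rényi or Watts–Strogatz graphs with U(0,1]
  weights; if disconnected, the giant component is used and flagged.
  Real interaction networks are heavy-tailed and modular; the generator
  supports correctness checks (known geodesics), not topological realism.

All generators take explicit seeds; a master seed is fanned out through
`child_seeds` (NumPy `SeedSequence.spawn`), so adding a generator never
perturbs the draws of another, and identical seeds give byte-identical
outputs.

## Numerical and I/O choices

* Tables are tab-delimited UTF-8 with floats at 6 significant digits, so
  repeated seeded runs are byte-identical across platforms at the recorded
  precision.
* Length dispersion inside d_i uses the population SD (the per-ommatidium
  neighbour set is the full population of its ring); δ in the enrichment
  Z uses the sample SD (a population estimate). Both are documented here
  because either convention is defensible.
* The pipeline config is YAML with strict unknown-key rejection at every
  nesting level; the demo study sizes (14×14 lattices, 2 images per jitter
  level, 10 pairs, 4 expression models of 4000 genes, 150-node network,
  999 permutations) are chosen so the full run finishes in a few seconds
  while still exercising every stage.
* Acceptance-scale simulation sizes (50 images per jitter level, 2000
  null ANOVA pairs, 1000 null terms, 500 permutation replications, 100
  oracle graphs) keep the whole suite around two minutes on one CPU.

## Known limitations

* The disorder score saturates once jitter makes neighbouring facets
  unresolvable; it orders mild-to-severe phenotypes but does not separate
  "very severe" from "extremely severe".
* The detector assumes roughly uniform facet spacing given as a parameter;
  strongly anisotropic or multi-scale lattices would need a spacing map.
* Geodesic enumeration cost grows with the number of seed pairs times
  edges near geodesics; on very large dense networks with hundreds of
  seeds the per-seed BFS strategy is the right asymptotic choice but has
  not been profiled beyond synthetic sizes.
* The overlap test's power depends strongly on the universe/set-size
  ratio (see above); with sets comparable to the universe the statistic
  carries little signal and the test is honest about that (p near 1).
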