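# Methods

## The problem

Kinship inference from ancient or otherwise degraded genomes must cope with
three compounding difficulties: genome coverage varies over two orders of
magnitude between samples (0.05-3x is typical), post-mortem damage and
contamination corrupt a few percent of calls, and the reference populations
needed to separate identity-by-descent (IBD, familial) from
identity-by-state (IBS, population) sharing are often poorly known.  The
field's standard answer to coverage heterogeneity is pseudo-haploid calling:
one read-sampled allele per site, rendered as a homozygous call, which
equalizes the information content per typed site across coverages.  This
package estimates pairwise kinship coefficients from such data, corrects
them for partial marker overlap, and separates relatives (up to the 4th
degree) from unrelated pairs with an empirical Z-score error model.

## The estimator

Genotypes are minor-allele dosages g in {0, 1, 2} on a fixed biallelic panel
(pseudo-haploid calls contribute {0, 2}).  Markers with cohort minor-allele
frequency below `maf_min` (default 0.05) are pruned.  Population structure
is captured by the top K principal components of the standardized,
mean-imputed genotype matrix; each marker's genotypes are regressed on an
affine basis (intercept + components) to give individual-specific allele
frequencies mu_si, clipped to [eps, 1-eps] with eps = 1/(2n) bounded to
[1e-4, 0.01].  The raw kinship coefficient is the residual covariance

    phi_ij = sum_s (g_si - 2 mu_si)(g_sj - 2 mu_sj)
             / (4 sum_s sqrt(mu_si(1-mu_si) mu_sj(1-mu_sj)))

This reproduces the PC-Relate family of estimators: with no structure
(K = 0) mu reduces to the cohort frequency, and E[phi] equals the pedigree
kinship coefficient for both diploid and pseudo-haploid data (the covariance
of single sampled alleles between two individuals is phi * p(1-p), which the
{0,2} coding scales back onto the diploid normalization).

**Missing data.** Missing genotypes contribute a zero residual to the
numerator while the denominator always sums over all kept markers.  This
mean-imputation convention is deliberate and load-bearing: the numerator of
a partially typed pair accumulates signal only at jointly typed markers, so
the raw coefficient scales linearly with the pairwise overlapping-marker
fraction — which is exactly the attenuation the downstream correction
divides out.  Replacing it with pairwise-complete sums would break the
linear law and with it the correction.

**Choice of K.** The widely quoted eigenvalue-above-the-mean (Kaiser) rule
fails at these matrix shapes: for n samples and m markers with n/m ~ 0.01
the Marchenko-Pastur noise bulk places roughly half of all eigenvalues
above the mean, and regressing on ~n/2 components absorbs the relatedness
signal itself.  The default (`K="auto"`) therefore keeps components whose
eigenvalue exceeds the MP bulk edge, sigma^2 (1 + sqrt(n/m))^2, with the
noise scale sigma^2 estimated by the median eigenvalue and a 1.25 safety
margin against edge fluctuations.  Two refinements matter in practice:

* *Missingness rescaling.*  Mean-imputed rows of sparsely typed samples have
  shrunken norms, which spreads the bulk spectrum and would masquerade as
  structure; rows are divided by the square root of their typed fraction
  before the eigendecision.
* *Localization filter.*  A close relative pair creates its own eigenvalue
  above the bulk edge, but its eigenvector is concentrated on the two
  samples involved.  Components whose two largest squared loadings exceed
  0.5 are skipped: they are relatedness, not population structure, and
  regressing on them would cancel the signal being measured (the same
  problem PC-AiR solves by computing PCs on an unrelated subset).

K remains user-overridable; misspecifying the reference population (or
omitting ancestral components) inflates coefficients, a limitation inherent
to the approach rather than to this implementation.

**Inbreeding.** With `inbreed=True` (default) a per-sample coefficient F is
estimated from the excess residual variance relative to 2 mu (1 - mu) by an
alternating mu/F update (max 50 iterations, tolerance 1e-4; in this
formulation mu does not depend on F, so convergence is immediate).  F feeds
the self-kinship diagonal only — for pseudo-haploid data F converges to ~1
by construction, since a single sampled allele looks fully inbred, and
scaling pairwise denominators by it would be wrong.

## Overlap correction and the error model

The overlapping-marker fraction f_ij divides the count of markers typed in
both members of a pair by the full panel size M (all loaded autosomal
markers, not the post-MAF-pruned count: pruning happens inside the
estimator, and random missingness affects kept and pruned markers alike).
The corrected coefficient is phi* = phi / f, off-diagonal, with f = 0 pairs
flagged uncomputable.

The variance of phi* grows as the overlapping-marker count n shrinks —
empirically and theoretically close to sd(n) = a + b/sqrt(n), with b ~ 0.7
for diploid and ~1.2-1.4 for pseudo-haploid data.  The error model estimates
this curve from the analyzed cohort itself: pairs above the conventional
hard threshold (0.046875) are provisionally excluded; the remaining pairs
are binned into 10 log-spaced bins of n (bins under 20 pairs merge upward);
each bin contributes a 5%-trimmed mean and a trimmed SD rescaled by the
normal-consistency factor for the trim fraction (without the rescaling a
5% trim shrinks a normal SD by ~21% and a nominal Z = 6 would behave like
Z ~ 4.7); sd(n) = a + b/sqrt(n) is fitted by occupancy-weighted least
squares on the bin SDs; pairs above mean(n) + Z sd(n) are re-excluded and
the fit repeated once.  If the fit comes out increasing in n, isotonic
regression of the bin SDs replaces it, with a warning.  A pair is called
related when its Z score exceeds the multiplier (default Z = 6, conservative
against unmodeled reference mismatch) and/or when phi* exceeds the hard
threshold; the workflow default is the either/or combination, and every call
records which rule produced it.

Degree classes use arithmetic midpoints between the expected coefficients
0.5 / 0.25 / 0.125 / 0.0625 / 0.03125 (sample match, 1st-4th degree):
boundaries 0.375, 0.1875, 0.09375, 0.046875 — the last one doubling as the
hard filter — extended one step to 0.0234375 = midpoint(0.03125, 0.015625)
below which a pair is labeled "distant"; without that extension the class
"fourth" would be unreachable.  Pairs with fewer than 17,000 overlapping
markers are reported but flagged low-confidence, the regime where
4th-degree calls stop being reliable.  Kin groups are connected components
of the called-pair graph, labeled deterministically by smallest member id.

## Simulators and the fixture generator

`deplete_markers` removes markers from one pair's overlap until the overlap
count equals round(f M) exactly, assigning each discarded marker to one
randomly chosen member (keeping marginal typed counts realistic);
`deplete_indivs` draws per-sample typed counts uniformly on [min, max].

`apply_errors` models three aDNA error channels on pseudo-haploid data, at
per-sample rates drawn uniformly on [0, max_rate] (default max 5%, dataset
mean ~2.5% — roughly double a typical ancient-DNA error rate, the
deliberate stress condition), realized counts exact:

* *post-mortem damage* (cytosine deamination, C->T / G->A): markers whose
  allele pair is C/T or G/A have their homozygous state flipped; markers
  containing C or G with any other partner become missing, because the
  damage product matches neither allele and a biallelic format cannot
  represent it; A/T markers are immune.  The rule operates at marker level
  (the state, not the underlying strand, is simulated).
* *exogenous contamination* (microbial DNA): hit sites are set to the
  homozygous-major state.
* *endogenous contamination*: hit sites copy the state of a designated
  contaminant sample, missing included (whether a real contaminant read
  could restore a missing call is unknowable at state level; copying is the
  conservative choice).  The contaminant sample itself is never
  self-contaminated.

In mixed mode one combined site set is drawn without replacement and split
equally across the channels (applied PMD, endogenous, exogenous in fixed
order), so channels never collide on a site.

The fixture generator draws founder genotypes per marker from
Balding-Nichols population frequencies (ancestral frequency uniform on
[0.05, 0.95], population frequency Beta-distributed at a given F_ST) and
produces descendants by independent-locus Mendelian gene dropping.  Exact
pedigree kinship coefficients come from the standard recursion and serve as
ground truth.  What this emulates — and what it does not: allele-frequency
structure, coverage heterogeneity and aDNA error channels are represented;
linkage and recombination are not (no genetic map), so realized IBD
fractions have far less between-pair variance than in real genomes, and all
assertions on fixtures are about means, never about IBD-sharing variance.
LD between panel markers, reference-population misspecification and
alignment artifacts are likewise outside the generator, so passing tests
demonstrate correctness of the estimator and correction under the modeled
conditions, not robustness to everything real data can do.

## Validation experiment design and problem sizes

The validation suite scales the published experimental designs to desk size:
20k-marker panels with 200-sample single-population reference cohorts for
the linearity and expectation experiments (the "own reference population"
setting), 100-sample cohorts plus an F_ST = 0.15 contaminant for the error
channels, and 100k-marker, 300-sample cohorts for filter performance.

Two scaling choices deserve explanation:

* The overlap-fraction sweep averages 10 pseudo-haploidization/depletion
  randomizations per overlap fraction, mirroring the original design (which
  averaged 100): a single draw at 5% of a 20k panel (n = 1000 overlapping
  markers) has sd(phi*) ~ 1.2/sqrt(1000) ~ 0.04, so the flatness of the
  corrected coefficient is a statement about means.  Across the same sweep
  the between-replicate SD of phi* grows like the square root of the
  correction factor — pure sampling noise — and not like the factor itself;
  note that the f = 1 baseline carries only het-resolution randomness (the
  marker subset is fixed there), which makes the observed SD ratio at a 20x
  correction a bit above sqrt(20), ~5.5 for this frequency spectrum.
* Detectability at Z = 6 depends on the absolute overlap count, not the
  fraction: 4th degree needs on the order of 85k overlapping markers in
  pseudo-haploid data — more than any desk-scale panel holds.  The filter
  experiment therefore plants 1st-3rd-degree relatives at typed fractions
  uniform on [0.6, 1.0] of the panel (minimum pairwise overlap 36k markers,
  inside the detection envelope), while background samples span the scaled
  analogue of the 100k-marker inclusion threshold ([0.087, 1.0] of the
  panel) and 4th-degree pairs span the full range, so some of them fall
  below the ~10%-overlap bound and exercise the "reported, not required"
  regime.

Numerical conventions throughout: seeds are explicit everywhere randomness
exists (Philox counter-based generation for pseudo-haploidization, so
results are traversal-order independent); matrices are float64; the
estimator is deterministic given its input; tie-breaks in degree
classification are lower-inclusive on the class boundaries.

## Known limitations

* Estimates carry the small-sample bias of frequency estimation from the
  analyzed cohort itself (mean off-diagonal shift ~ -phi_self/(n-1), i.e.
  ~-0.005 for a 200-sample pseudo-haploid cohort); the same 2-4% downward
  bias is visible in the published diploid analyses and is inherent to the
  estimator family, not introduced by the correction.
* Numerical equality with any particular external PCA-based kinship tool is
  not promised; the contract is expectation recovery, the linear overlap
  law, and printed-table arithmetic.
* No parent/offspring vs sibling disambiguation: that needs IBD-state
  fractions, which pseudo-haploid single-allele data does not provide.
* Populations absent from the reference set inflate small coefficients;
  distant (3rd-4th degree) calls in poorly referenced cohorts should be
  treated as provisional.
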