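# Methods

`cophylochem` re-implements, as a tested pipeline over synthetic data, a
set of analyses linking the diversification of specialist herbivores to
the phylogeny and defensive chemistry of their host plants: DNA-barcode
species delimitation, metabolome-based species similarity, phylogenetic
signal statistics, cophylogenetic permutation tests, and Bayesian
variance partitioning of host-use incidence.  This note records the
models, the defaults and why they were chosen, what the synthetic data
do and do not emulate, and the numerical choices a maintainer would
want to know.

## Barcode distances and MOTU delimitation

Pairwise divergence between aligned COI barcodes uses the Kimura
two-parameter correction,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q),

with P and Q the transition and transversion proportions over sites
where both sequences carry an unambiguous base (complete-pair deletion
of gaps and N; the estimator needs no ts/tv ratio input).  Arguments of
the logarithms at or below zero raise a saturation error.  A cap of
0.35 substitutions/site on any pairwise distance stands in for an
identity prefilter against off-locus sequences.

Two delimitation routes:

* **Threshold scan** (`motu_scan`): single-linkage clustering at
  base-pair cutoffs 1..65; the molecular unit count M(t) is
  non-increasing in t, and the *plateau* — the longest run of constant
  M(t) of length >= 3, ties to the smallest threshold, preferring
  multi-cluster counts over the terminal all-merged count — gives the
  reported MOTU number.  Single linkage matches the
  connectivity-based cluster definition of threshold delimitation
  tools.
* **Gap partition** (`gap_partition`): a simplified automatic
  barcode-gap procedure.  For each of 30 log-spaced prior
  intraspecific divergences P in [0.3%, 6%], ranked pairwise distances
  are scanned for the first step that ends above P, exceeds 1.5x the
  mean preceding step, and is itself wider than P (a discontinuity
  narrower than the assumed intraspecific scale is noise, not a
  barcode gap); sequences are split by connectivity below the gap and
  the procedure recurses within groups.  The reported partition is the
  one at the dominant (longest) run of constant group count across the
  prior ladder, excluding the trivial one-group collapse when any
  multi-group partition exists.  The original tool's theoretical
  model of intraspecific divergence is not reproduced; only the
  partition counts and the level-off choice matter downstream.

Mitochondrial MOTUs are consolidated against nuclear-locus partitions:
a split between two MOTUs is kept iff at least one nuclear partition
separates the same individuals; pairs that every informative nuclear
partition merges are unioned (never increasing the MOTU count).
Divergences convert to ages as d / (2r), with r = 0.0115
subs/site/Myr per lineage (the classic arthropod COI calibration;
2.3% pairwise per Myr) or the faster alternative 0.0177.

## Chemical similarity

Compound classes follow the chromatographic rule: saponin iff RT > 18
min **and** precursor m/z > 580 (strict inequalities); otherwise
phenolic.  Tyrosine overexpression is carried separately as percent
leaf dry weight.

Compound-pair structural similarity is the **modified cosine** of their
MS/MS spectra: square-root intensities are L2-normalized and fragment
pairs may match directly (|dm/z| <= 0.02 Da) or shifted by the
precursor mass difference; candidate pairs are accepted greedily by
descending intensity product, each peak used once.  Scores below a 0.2
floor are zeroed (the molecular-network edge threshold); compounds
without spectra score zero against everything.  Default tolerances
(m/z 0.01 Da, RT 0.25 min for feature matching, fragment 0.02 Da,
floor 0.2) are instrument-realistic conventions and configurable.

Species-pair similarity credits unshared but structurally similar
compounds (CSCS-style): with per-species abundances a normalized to
sum to one and compound similarities eps,

    raw(A, B) = sum_ij a_iA a_jB eps_ij
    S(A, B)   = raw(A, B) / max(raw(A, A), raw(B, B)).

This score is invariant to splitting a compound into identical halves
and non-decreasing in any cross-species eps entry.  Class-wise
matrices (phenolics, saponins) are combined as an equally weighted
mean; when any species overexpresses tyrosine, a third matrix
1 - |t_A - t_B| / max|t_A - t_B| joins at equal weight.  Whether
tyrosine belongs in the combined matrix at all is an open design
point; it is exposed as an optional argument and omitted by default in
the analysis scripts.

The **chemogram** is UPGMA on 1 - S.  Cluster support is the ordinary
bootstrap proportion over compound-resampled similarity matrices (not
a multiscale/AU correction, which would be out of proportion to its
role here).  Cophenetic distance between species is the merge height
recorded as-is; the permutation tests that consume it are invariant to
that scale convention.

## Phylogenetic statistics

Blomberg's K compares the observed ratio of raw to
phylogenetically-corrected mean squared error with its Brownian
expectation; K = 1 under Brownian motion on the tree (exactly 1 on a
star phylogeny, where the correction is the identity), K -> 0 as
signal disappears.  The randomization p-value shuffles tip values with
the add-one rule p = (1 + #{K_perm >= K_obs}) / (reps + 1), so p is
never exactly zero.  K is invariant to rescaling all branch lengths.

PCoA is classical metric scaling: Gower double-centering of -D^2/2,
eigendecomposition, axes with eigenvalue > 1e-8 x the largest
retained.  Negative eigenvalues are dropped without correction;
percent variance is over the positive spectrum, and a flag is raised
when the most negative eigenvalue exceeds 5% of the largest.

Accumulation curves report the across-permutation mean and standard
deviation of cumulative richness over random host orderings.
Individual-based rarefaction is the hypergeometric closed form

    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)),

with the matching variance including pairwise co-absence terms,
computed through log-gamma for stability.  The worked sampling-depth
number divides printed totals, rounding half away from zero
(1286 individuals / 34 host taxa -> 38).

## ParaFit

With B and C the principal coordinates of the host and parasite
distance matrices and A the binary parasite x host link matrix, the
global statistic is ||C' A B||^2.  The null permutes each parasite's
host associations independently; p-values use the add-one rule.
Per-link F1 is the drop in the global statistic when the link is
removed (computed in closed form from the cross-product matrix), F2 is
F1 scaled by the remaining statistic, and link p-values follow the
same permutation scheme with the link tracking its parasite's
permutation.  Substituting the chemogram's cophenetic matrix for the
host phylogeny turns the same test toward host chemistry.  Only
positive PCoA axes are used; the original method's negative-eigenvalue
corrections are not exposed.

## Variance partitioning

Incidence cells y over (sawfly s, host h, region r) follow a
probit-link Bernoulli mixed model.  Twelve covariance structures are
built from the sawfly tip correlation S (Brownian covariance scaled to
unit diagonal), host tip correlation H, and chemical similarity C
(eigenvalue-clipped to the nearest PSD matrix and rescaled to unit
diagonal), as Kronecker products over sawfly x host cells: S(x)J,
J(x)H, J(x)C, I(x)H, I(x)C, S(x)I, S(x)H (coevolution), S(x)C
(defense tracking), I(x)J, J(x)I, I(x)I, plus a region block effect.
All factors have unit diagonal, so each component's sigma^2 is a
per-cell latent variance and the posterior proportions
sigma^2_k / sum_k sigma^2_k are comparable across terms; proportions
are computed per draw (they sum to one exactly) and summarized by the
posterior mean and 2.5/97.5% quantiles.  The residual probit variance
is fixed at 1 (binary non-identifiability) and excluded from the
proportions.

Sampling is Albert-Chib latent-variable Gibbs with parameter
expansion: each component's effect is alpha_k * Q Lambda^(1/2) v_k in
the eigenbasis of its Kronecker factors, with v_k ~ N(0, psi_k I),
alpha_k ~ N(0, scale^2) and psi_k ~ InvGamma(1/2, 1/2), inducing a
half-Cauchy(scale) prior on sigma_k = |alpha_k| sqrt(psi_k); the
default scale is 1.  Because the design is a balanced grid, every
conditional precision is diagonal in the eigenbasis and an iteration
costs a few small matrix products per term; a batched runner carries
independent replicate datasets through the same sweep, which is how
the simulation studies stay cheap.  Fixed effects (intercept, and
standardized log effort when effort is controlled) have N(0, 100)
priors.  Effective sample sizes are reported per component with
warnings below 100 (hard warnings below 10).  The default chain is
50,000 iterations, 5,000 burn-in, thinning 45 — a desk-scale tenth of
a full production chain (500k/50k/450), selectable through
`VarpartSpec`.

The 2 x 2 model grid crosses the region term with effort control.  In
the without-region variants the unstructured interaction term I(x)I is
dropped: with a single observation per sawfly x host cell it is
confounded with the residual.

A logit-link reference implementation would differ in link scale but
not materially in proportions of variance; the probit choice buys the
conjugate latent update.

## Occurrence models

Per-host occurrence counts (distinct herbivore species on the host,
out of the species-pool size as trials, zero-richness hosts included)
are fitted by maximum-likelihood binomial regression on host traits
and ordination axes, with sampling effort as a covariate and Wald 95%
intervals; exp(beta) is reported as a proportional odds.  Candidate
models are ranked by AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1).
Detected separation (diverging coefficients or fitted probabilities at
the boundary) triggers a Firth-penalized refit with a warning.

## Synthetic data: what it emulates, and what it does not

* **Trees**: constant-rate birth-death trees with exactly n extant
  tips; tip edges are extended by the waiting time to the next event
  so the newest cherry has positive length.  Time trees are rescaled
  to substitutions/site where needed.
* **Traits**: Brownian motion along branches — the exact null of the
  K statistic.
* **Barcodes**: a K2P substitution process (ts/tv rate ratio 1.47, a
  typical model-selection estimate for this marker) along the species tree,
  plus a star radiation within species (expected intraspecific
  divergence 0.3%, interspecific 5%, 645 bp).  No within-species
  coalescent, no gene-tree discordance: only the gap structure
  matters to the delimitation tests.
* **Chemistry**: compounds gained at rate 12 per unit branch length
  and lost per compound at rate 0.4 (stationary richness 30); a
  gained compound inherits 70% of a present parent compound's
  fragments, so cosine similarity decays with divergence time.
  Abundances are Dirichlet(5).  These defaults give species similarity
  spanning roughly 0-0.9 with strong phylogenetic structure —
  realistic contrast for a defensive metabolome — but no real
  fragmentation chemistry, adducts, or peak-detection noise.
* **Incidence**: the generative twin of the variance-partition model —
  latent Gaussian effects with covariances sigma^2_k A_k plus unit
  probit noise, thresholded at 1.5 (null prevalence ~7%, matching the
  sparsity of real host-herbivore records).  Host-switch behavior,
  abundance, and biogeographic range evolution are not modeled.

Because the data generator and the variance-partition model share one
covariance algebra, parameter-recovery tests show the estimator is
correct and identifiable under the stated conditions; they cannot show
that the model is well specified for field data.

### Fixture design for the recovery studies

Recovering the defense-tracking component S(x)C requires C to be
distinguishable from both the identity and the all-ones matrix, and
from H.  Chemistry simulated on the host tree is strongly collinear
with host phylogeny (the study system's own confounding), so the
recovery fixtures instead use four discrete chemotype guilds
(similarity 0.8 within, 0.05 between) assigned independently of both
phylogenies — mirroring the handful of chemotype classes real hosts
fall into.  With 20 sawflies x 20 hosts x 2 regions, a dominant
defense-tracking variance (1.0 vs 0.01 elsewhere) is ranked first in
about 85% of replicate datasets at the default chain; the occasional
misranking goes to the region term, whose two-level variance is
prior-dominated (its wide credible intervals are a property the full
field analysis shares).

## Problem sizes in the tests and the acceptance script

Simulation-based checks run at deliberately modest sizes chosen to
keep the whole suite interactive: 50 replicate barcode sets for MOTU
recovery; 200 Brownian replicates for the K expectation and 200
shuffled datasets (99 permutations each) for p-uniformity; 2000 null
datasets for the ParaFit size check and 50 for each power check;
500 bootstrap replicates for chemogram support; 20 replicate
communities (10 for the null calibration, 10 in the acceptance script)
for the mixed-model recovery at the 50k-iteration chain.  All
stochastic steps take explicit seeds and are bitwise reproducible.

## Known limitations

* The gap-partition procedure is a deliberately simplified reading of
  automatic barcode-gap discovery; on data without a clear gap its
  level-off choice can differ from the original tool's.
* Greedy one-to-one feature matching is order-dependent in principle;
  on tolerance-sparse data it coincides with the optimal assignment
  (tested against brute force on small tables).
* The region variance is weakly identified with few regions; its
  posterior reflects the half-Cauchy prior more than the data.
* Bootstrap chemogram support resamples compounds, not biological
  replicates; it measures stability of the similarity matrix to
  compound sampling only.
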