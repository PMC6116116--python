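# cophylochem

Tools for asking whether a radiation of specialist herbivores tracks
the **phylogeny** of its host plants or their **defensive chemistry** —
the question behind studies of neotropical sawflies feeding on *Inga*
trees, where the candidate explanations for congruent plant and
herbivore trees are codiversification and delayed host tracking of
conserved chemical defenses.

The package is organised as an analysis pipeline over synthetic
communities (no field data ship with it): numbered drivers under
`analysis/` run each stage and write tables under `results/`, and all
computation lives in the library `src/cophylochem/`, where it is unit-
and property-tested.

## What it computes

* **`barcode_motu`** — Kimura two-parameter distances
  (`d = -½ln(1-2P-Q) - ¼ln(1-2Q)` with pairwise deletion), MOTU
  delimitation by single-linkage threshold scan with barcode-gap
  plateau detection and by recursive gap partitioning over a ladder of
  prior intraspecific divergences, nuclear-concordance consolidation,
  and age calibration at 0.0115 or 0.0177 subs/site/Myr.
* **`chem_similarity`** — modified-cosine MS/MS similarity, the
  saponin/phenolic retention-time x m/z rule, abundance-weighted
  species similarity `S(A,B) = Σ a_i a_j ε_ij / max(raw(A,A), raw(B,B))`
  crediting unshared but structurally similar compounds, equal-weight
  class combination with optional tyrosine, and a bootstrap-supported
  UPGMA chemogram.
* **`phylo_stats`** — Blomberg's K with randomization p-values,
  principal coordinates analysis, patristic distances,
  species-accumulation and hypergeometric rarefaction curves.
* **`cophylogeny`** — ParaFit global and per-link permutation tests of
  tree-tree congruence, against either the host phylogeny or the host
  chemogram.
* **`association_models`** — binomial ML occurrence models with AICc,
  and a Bernoulli-probit mixed model that partitions incidence
  variance into twelve named components (phylogenetic and defense main
  effects and interactions, including the coevolution term S⊗H and the
  defense-tracking term S⊗C) by parameter-expanded Gibbs sampling.
* **`synthetic_data`** — generators for all of the above: birth-death
  trees, Brownian traits, gain/loss metabolomes with heritable MS/MS
  fragments, K2P barcode sets with a controllable barcode gap, and
  incidence drawn from known variance components.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```sh
python analysis/01_simulate_community.py --seed 1
python analysis/02_delimit_motus.py
python analysis/03_chemical_similarity.py --seed 1 --n-boot 200
python analysis/04_phylogenetic_signal.py --seed 1
python analysis/06_cophylogeny.py --seed 1
```

prints, among other things:

```
threshold scan: 8 MOTUs on the plateau 4-22 bp; gap partition: 8 MOTUs
(methods agree at Rand 1.00); deepest divergence 0.084 subs/site ~ 3.64 Myr
at the slow calibration
```

— both delimitation routes recover the eight simulated species exactly
and agree with each other, and the deepest split converts to an age of
a few million years under the slow mitochondrial calibration;

```
                            trait     K     p
             chemistry PCO1 (32%) 1.844 0.001
             chemistry PCO2 (22%) 1.677 0.001
       Brownian trait (simulated) 0.965 0.001
shuffled trait (signal destroyed) 0.351 0.136
```

— the leading axes of chemical similarity carry strong phylogenetic
signal (chemistry was simulated evolving on the host tree), a Brownian
trait sits at K ≈ 1 as theory demands, and shuffling destroys both the
statistic and its significance;

```
70 links; congruence with host phylogeny p = 0.0010, with host
chemistry p = 0.0020 (999 permutations)
```

— with incidence simulated under a dominant defense-tracking
component, both ParaFit tests detect non-independence.  Finally
`analysis/07_variance_partition.py` fits the 2 × 2 grid of mixed-model
variants and writes a four-column table of posterior variance
proportions with credible intervals (`results/variance_partition.csv`);
on this fixture the defense-related interaction terms dominate, with
the caveat — printed by the script — that chemistry simulated on the
host tree is collinear with host phylogeny, so the coevolution and
defense-tracking terms share the credit.

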