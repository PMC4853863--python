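# Methods

`markerrank` asks a question about marker-gene choice in prokaryotic
comparative genomics: **which marker genes best predict genome-wide sequence
similarity — measured as average amino-acid identity (AAI) — between closely
related strains?** The well-known answer for distant relatives is the 16S
rRNA gene; for closely related strains the useful markers turn out to be the
ones *least* conserved within the lineage of interest. The package provides
(1) an analysis pipeline that quantifies this on any cohort of genomes
following its input layout, and (2) a genome-evolution simulator that
generates cohorts with known genealogy and known per-gene rates, so every
pipeline statistic can be validated against generative truth.

## The analysis pipeline

Given per-genome marker nucleotide sequences, proteomes, a marker annotation
table and lineage assignments, the pipeline computes:

1. **Marker identity table.** For every genome pair and marker, the percent
   identity of a Needleman-Wunsch global alignment (affine gaps; identity =
   identical columns / all alignment columns). Multi-copy genes (the
   16S-like marker may have several copies per genome) use the maximal
   identity over all copy pairs. 16S-like copies outside 1000-1800 nt are
   ignored as spurious annotations.
2. **AAI.** For pairs whose 16S-like identity is at least
   `min_16s_identity_percent` (default 80), homologs are reciprocal best
   hits between the two proteomes under Smith-Waterman score, re-aligned
   with Smith-Waterman; a pair of proteins counts as homologous when aligned
   over >= 70% of the shorter protein with identity strictly > 30%. AAI is
   the unweighted mean homolog identity, reported only when at least
   `min_homologs` homologs survive (200 by default, following genome-scale
   practice; desk-scale simulated cohorts use 100 of 200 background genes).
   The BLAST search of classical AAI implementations is replaced by an exact
   Smith-Waterman ranking with a k-mer seed prefilter (subjects sharing a
   5-mer with the query, ranked by distinct shared 5-mers, falling back to
   4-mers when none; top 4 candidates aligned). `prefilter=False` restores
   the exhaustive all-vs-all search; on small proteomes both routes are
   verified to agree.
3. **Conservation ranks.** Within every genome pair that carries the
   complete marker set, markers are ranked by identity (1 = most similar,
   M = least similar, fractional ranks on ties, so each row sums to
   M(M+1)/2); lineage-average ranks are unweighted means over the lineage's
   complete pairs.
4. **Trees.** UPGMA (size-weighted average linkage, merge height = half the
   cluster distance, smallest-label tie-breaking, zero-length internal edges
   collapsed into multifurcations) on distances 1 - identity/100, per marker
   and for AAI, per lineage, restricted to genomes with the complete marker
   set and full AAI coverage. Marker trees are compared with the AAI tree by
   Robinson-Foulds split distance, reported raw and normalized by the total
   number of non-trivial splits in both trees (two stars count as
   identical). Rooted trees are compared as unrooted.
5. **Statistics.** Per-marker Spearman correlations between marker identity
   and AAI, split at AAI = 95% into a "distant" and a "close" side; binned
   95% confidence intervals of AAI per 2%-wide bin of 16S-like identity,
   from 20 genome-disjoint resamplings (greedy: shuffle, accept pairs
   introducing no already-used genome); and Spearman correlation between
   lineage-average rank and normalized split distance (per lineage and
   pooled across lineages — the pooled value is the headline statistic
   because the per-lineage point count is small at desk scale).

All stages are deterministic given config and seed; re-running on the same
output directory reuses cached stage outputs when the configuration hash
matches.

## The simulator

Sequences evolve by a K-state Jukes-Cantor process (uniform exchange among
K = 4 nucleotides or K = 20 amino acids), with the closed-form identity

    P(identical site) = 1/K + (K-1)/K * exp(-K/(K-1) * d)

at branch length `d` (expected substitutions per site) available as an exact
oracle. No indels are simulated, so alignments of simulated sequences are
colinear — the pipeline still runs its full affine-gap aligners on them.
An optional relaxed clock multiplies each (gene, branch) rate by an
independent mean-one lognormal draw (`rate_jitter_sigma`); the default is a
strict clock.

The cohort genealogy has three levels, mirroring how real strain cohorts are
structured:

* **strain clusters** — small groups of near-identical genomes whose crown
  depths are drawn log-uniformly from `cluster_depth_range` and whose
  internal splits sit a small absolute height gap below the cluster root;
* **lineages** — clusters joined at `lineage_crown_frac * tree_depth`;
* a **backbone** — a Yule topology over lineages whose internal nodes are
  spread over 0.55-0.95 of `tree_depth`, so between-lineage divergences vary.

`sample_tree` itself is a plain Yule tree rescaled so every root-to-leaf
path equals `depth`; the hierarchical structure is assembled in
`generate_dataset`. Every per-gene, per-branch substitution stream is
derived from the master seed by hashing (seed, purpose, gene, branch), so
adding a gene never perturbs other genes' sequences, and identical configs
produce byte-identical output files.

## Default study conditions and why

The defaults define a "desk-scale" cohort that runs in well under a minute
per replicate on one CPU while exhibiting the three qualitative patterns the
pipeline is designed to measure. They were chosen by analyzing the
signal-to-noise structure of each statistic (closed-form geometry pilots and
a direct Monte Carlo of the UPGMA cherry decision), not to mimic any
particular real dataset:

* **15 genomes in lineages of 6, 5, 4; strain clusters packed greedily in
  threes ([3,3], [3,2], [3,1]).** All three lineages keep >= 4 tree-capable
  genomes, and each full cluster of three contributes one contested cherry
  split, so the rank-versus-tree-distance statistic pools 3 x 133 = 399
  (lineage, gene) points over four contested splits.
* **133 markers, 300 nt, rate multipliers log-spaced 0.6-10; one 16S-like
  marker, 1200 nt, multiplier 0.035, 2 copies (second copy diverged by
  0.005 subs/site).** The 16S-like marker is both much slower and longer,
  as in real genomes. The wide, dense multiplier ladder does two jobs:
  the fastest markers saturate at between-lineage depths (the mechanism
  that makes poorly conserved genes unreliable for distant comparisons),
  and the many markers give the pooled rank/tree-distance correlation its
  statistical power — only markers slower than the pooled proteome's own
  resolving power can be graded by tree distance, so the point count, not
  the per-marker signal, carries the p-value.
* **200 background genes, 70 aa, multipliers 0.25-0.40.** Amino-acid
  divergence accumulates several-fold slower than marker nucleotide
  divergence, as in real coding sequences; with `tree_depth = 1.2` the AAI
  of the deepest pairs lands near 50%, spanning the 40-100% range over
  which AAI-based comparisons are typically reported. The pooled proteome
  (14 000 aa sites) also makes the AAI-based UPGMA tree the most reliable
  tree in the cohort, which is what lets it serve as the reference
  topology.
* **Cluster depths 0.015-0.045 (log-uniform per cluster) with cherries an
  absolute 0.0055-0.0075 subs/site below the cluster root.** The absolute
  height gap places every cherry in the window where the AAI tree still
  resolves it but slow markers cannot: by direct Monte Carlo of the UPGMA
  decision, the probability of mis-resolving a cherry falls from ~0.5
  (16S-like) through ~0.2 (multiplier 0.6) to ~0.02 (multiplier 10), while
  the AAI reference errs in under 2% of cherries. Shallower gaps corrupt
  the AAI reference itself (penalizing all markers jointly); deeper gaps
  are resolved by every marker and carry no signal. The wide spread of
  cluster ages, by contrast, supplies the close-side (AAI > 95%) variation
  against which per-marker correlations are measured.
* **`presence_prob = 0.9999`.** Gene absence is supported and occasionally
  exercised at the defaults, but kept rare: at desk scale a single absent
  marker disqualifies a genome from ranking and trees, and losing one
  genome costs a fifth of a lineage (dedicated tests use much lower
  presence probabilities to exercise the >90% presence filter and
  missing-data paths).

## What the simulation does and does not show

Passing the replicated synthetic analyses shows that the pipeline's
statistics recover known generative structure under a neutral substitution
model with clock-like rates, strain-cluster genealogies and no gene flow.
Real prokaryotic data add horizontal gene transfer, indels and alignment
error, codon structure, rRNA secondary-structure constraints, annotation
noise, and taxon sampling far from any clean design — none of which the
generator emulates (indels, HGT, recombination and site-rate heterogeneity
are explicit non-goals). Conclusions about real cohorts should rest on the
pipeline's behavior on real inputs; the synthetic results validate the
machinery, the conventions and the statistics, not biology.

Two deliberate consequences of the strict clock are worth noting. First,
16S-like identity is then an almost noiseless proxy for genealogical depth,
so the confidence-interval broadening seen in real data at high 16S identity
(near-identical 16S spanning a wide AAI range) cannot appear under the
default conditions; the property is exercised on cohorts with
`rate_jitter_sigma = 0.5` and strain clusters of widely varying age, where
lineage-to-lineage rate drift produces exactly that pattern. Second, the
Jukes-Cantor closed form is an exact per-gene oracle only under the strict
clock, which is why the identity/divergence agreement checks disable the
jitter.

## Numerical conventions

* Gap costs: a gap of length k costs `gap_open + (k-1) * gap_extend`
  (so `gap_extend = gap_open` is linear gap costs); end gaps are penalized
  in global mode. Defaults: nucleotide +5/-4, open 10, extend 0.5;
  protein BLOSUM62, open 11, extend 1.
* Percent-identity denominators: all columns (global), aligned columns
  (local).
* Best-hit ties break toward the lexicographically smallest subject id;
  UPGMA ties toward the smallest merged-label pair; both are arbitrary but
  fixed, for reproducibility.
* UPGMA internal edges shorter than 1e-12 are collapsed, so an all-equal
  distance matrix yields a star tree rather than an arbitrary resolution.
* Normalized split distance with zero non-trivial splits on both sides is
  defined as 0.
* Spearman p-values use the t-distribution approximation; no
  multiple-testing correction is applied anywhere.
* TSV outputs are written with %.12g floats; re-reading reproduces values
  to better than 1e-9.

## Known limitations

* Inputs are assumed coding-strand and whole-gene; there is no
  reverse-complement search and no coordinate handling.
* The homolog search is score-ranked RBH, not e-value-ranked BLAST; homolog
  sets on real data will differ in detail from BLAST-based AAI tools.
* The genome-disjoint resampling is greedy, not a maximum matching; bins
  whose pair graph is unfavorable may under-fill and are flagged.
* Lineages with fewer than four usable genomes are skipped for tree-based
  statistics (a 3-leaf unrooted tree has no non-trivial splits).
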