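# markerrank

Which marker genes best predict genome-wide similarity between closely
related prokaryotic strains?

The 16S rRNA gene is the standard prokaryotic marker: universally present,
slowly evolving, easy to amplify. Those same properties make it a blunt
instrument at fine taxonomic scales — strains that have diverged across
their whole genome can still carry near-identical 16S sequences.
`markerrank` implements an analysis that quantifies this directly. Genome-wide
similarity of a pair of genomes is measured as **average amino-acid identity
(AAI)**: the unweighted mean percent identity over all reciprocal-best-hit
homologs shared by the two proteomes (homologs must align over ≥ 70% of the
shorter protein at > 30% identity; pairs with < 200 homologs are discarded).
Each candidate marker gene is then judged by

* the Spearman correlation between its percent identity (Needleman-Wunsch,
  nucleotide level) and AAI, computed separately for distantly related pairs
  (AAI < 95%) and closely related pairs (AAI > 95%);
* its **conservation rank** within each genome pair (1 = most conserved of
  the M markers, M = least conserved; fractional ranks on ties), averaged
  within a lineage;
* the Robinson-Foulds split distance between the UPGMA tree built from its
  identities and the UPGMA tree built from AAI, per lineage (distances are
  1 − identity/100).

On real genome cohorts the pattern is that slow markers (16S-like) predict
AAI well only for distant pairs, while the markers *least* conserved within
a lineage both track AAI best among close relatives and reconstruct the
AAI tree most faithfully. The package ships a genome-evolution simulator
(Jukes-Cantor substitution on strain-cluster genealogies with known
per-gene rates) that reproduces these patterns with known ground truth, so
every statistic is testable end to end. It is intended for method
development and teaching as much as for re-analysis of cohorts that follow
its input layout.

## Worked example

Simulate a default desk-scale cohort (15 genomes in 3 lineages of strain
clusters, one slow multi-copy 16S-like marker plus 132 protein-coding
markers spanning a 16-fold rate range, 200 background genes) and run the
full analysis:

```bash
markerrank simulate --out cohort --seed 7
markerrank run --input cohort --out results --seed 7 --min-homologs 100
markerrank report results
```

The `run` step prints the filter accounting:

```
n_genomes: 15
pairs_in: 105
pairs_passing_16s_filter: 105
pairs_rejected_16s: 0
aai_retained: 105
aai_discarded: 0
```

(105 = all genome pairs of 15 genomes; at this simulation depth every pair
clears the 80% 16S-identity prefilter and the homolog minimum.) The report
then summarizes the headline statistics:

```
genomes: 15
genome pairs with marker identities: 105
pairs with AAI computed (16s >= 80%): 105
pairs discarded by min_homologs=100: 0
close-side (AAI > 95%) correlation ordering: slow16s is 108 of 133
lineage lin1: rank vs split-distance rho = -0.258 (p = 0.0028, n = 133)
lineage lin2: rank vs split-distance rho = -0.342 (p = 5.5e-05, n = 133)
lineage lin3: rank vs split-distance rho = -0.293 (p = 0.00062, n = 133)
combined: rank vs split-distance rho = -0.292 (p = 2.9e-09, n = 399)
lineages: lin1, lin2, lin3
```

Reading this: among closely related pairs the slow 16S-like marker is one
of the worst predictors of AAI (rank 108 of 133 by close-side correlation),
and lineage-average conservation rank is negatively correlated with the
split distance to the AAI tree — less conserved markers reconstruct the
genome-wide tree better (pooled rho −0.29, p ≈ 3e-9).
Per-pair tables (`marker_identity.tsv`, `aai.tsv`, `correlations.tsv`,
`ranks.tsv`, `split_distances.tsv`, `binned_ci.tsv`) and all trees
(`trees/*.nwk`) are written to the output directory.

The same machinery is available as a library:

```python
from markerrank import SimulationConfig, generate_dataset, PipelineConfig, run_all

truth = generate_dataset(SimulationConfig(seed=7), "cohort")
res = run_all(PipelineConfig(input_dir="cohort", out_dir="results",
                             min_homologs=100, seed=7))
print(res.correlations.head())
```

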