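# beedelim

Integrative species delimitation and community phylogenetics for
two-locus insect inventories — built for the situation a tropical bee
survey presents: hundreds of Malaise-trap specimens sorted only to
morphospecies, a fast mitochondrial barcode (COI) sequenced for some
specimens, a slow nuclear marker (28S) for others, and downstream
ecological questions that need defensible species units.

The pipeline reconciles three sources of evidence:

1. **Supervised phenetic clustering.** Per-locus genetic distances (K2P
   closed form, closed-form GTR, or maximum-likelihood GTR+I+Γ) are
   combined by alignment-length weighting with single-locus fallback,
   clustered by single linkage, and the clustering threshold *t\** is
   chosen to maximize the Hubert–Arabie adjusted Rand index (ARI) against
   the morphospecies labels, with taxonomic must-link constraints.
2. **Independent DNA-taxonomy delineators.** The barcode gap (the longest
   plateau of the OTU-count-vs-threshold curve), a two-rate Poisson tree
   process (within- vs between-species exponential branch-length classes
   on a neighbor-joining tree), and the conservative COI rule that flags
   conspecific pairs at K2P distance > 9 %.
3. **Consensus resolution.** Remaining morphology/DNA incongruences are
   overridden only where every delineator with data agrees on the same
   alternative grouping; otherwise morphology stands.

On the resulting OTU-by-plot table the package computes Gini–Simpson
diversity, Faith's PD, MPD/MNTD and their standardized effect sizes
NRI/NTI (tip-shuffle null; > 1.96 indicates phylogenetic clustering),
Bray–Curtis dissimilarity with UPGMA, beta diversity partitioned into
replacement and richness components (β<sub>total</sub> = β<sub>repl</sub> +
β<sub>rich</sub>, with rarefaction), Mantel / ANOSIM / PERMANOVA
permutation tests, and the abundance-weighted between-community
phylogenetic distance (comdist). Every phylogeny-derived index can be
computed both on a tree of the sampled OTUs only and on a
reference-augmented tree (nearest-neighbor grafting onto a backbone), to
quantify how much reference context changes the indices.

A seeded synthetic-data generator (`beedelim.simulate`) produces full
inventories with known truth — a Yule species tree, GTR+I+Γ sequences at
two loci with contrasting rates, star-shaped intraspecific variation
below a controlled barcode gap, specimens missing one locus, corrupted
morphospecies labels, and habitat-filtered communities — so every stage
of the pipeline is testable against ground truth.

## Worked example

Simulate a 30-species inventory under the default (noisy) study
conditions, run the whole pipeline, and compare against truth:

```
$ beedelim run-all --seed 1 --n-species 30 --out-dir demo
final OTUs: 27 (truth 30); ARI vs truth = 0.887
```

`demo/summary.json` records the stage counts:

```json
{
 "stages": {
  "specimens": 136,
  "otus_scan": 31,
  "otus_constrained": 31,
  "incongruences": 16,
  "otus_disjunct": 5,
  "otus_ptp": 39,
  "otus_final": 27
 },
 "t_star": 0.0052,
 "final_ari_vs_truth": 0.887,
 "beta": {"btotal": 0.944, "brepl": 0.712, "brich": 0.232}
}
```

Reading this: 136 specimens of 30 true species were clustered at the
most label-congruent threshold *t\** = 0.0052 into 31 OTUs (ARI 0.99
against truth at this stage); 16 incongruences with the (deliberately
corrupted) morphospecies labels were contested against the DNA
delineators, and the consensus rule — which retains morphology unless the
DNA evidence is unanimous — settled on 27 final OTUs. The final ARI of
0.887 is *lower* than the scan's because under these error rates the
retained morphology is itself sometimes wrong: the pipeline is
deliberately conservative, exactly like the field protocol it
implements. With clean labels and no missing loci the same pipeline
returns the true species exactly (ARI = 1.0; see the test suite).

Individual stages are available as subcommands (`simulate`, `distances`,
`delineate scan`, `delineate resolve`, `tree build`, `tree graft`,
`diversity`, `beta`, `ordtest`) and as library functions
(`beedelim.run_delineation`, `beedelim.run_community`).

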