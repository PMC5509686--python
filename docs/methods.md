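# Methods

## The delimitation model

Specimens are points in a two-locus genetic-distance space. Within a
species, pairwise distances are small and unimodal; between species they
are larger, and in favorable data the two modes are separated by an empty
interval (the barcode gap). Delimitation exploits three different
formalizations of that structure:

**Supervised threshold clustering.** Single-linkage clustering at
threshold *t* is equivalent to taking connected components of the graph
with edges where d(i,j) ≤ *t*; the partition is therefore nested and the
OTU count non-increasing in *t*. The threshold is chosen by scanning a
grid (default 0–0.05 in steps of 0.0001, fine enough to express
thresholds such as 0.0033 or 0.0055 exactly) and maximizing the
Hubert–Arabie adjusted Rand index against morphospecies labels,
restricted to labeled specimens. Ties break toward the **smallest**
threshold: over-splitting is the cheaper error, because residual splits
are visible to the downstream DNA delineators while residual lumps are
not. Taxonomic must-link constraints are applied afterwards by
union-find; they can only merge, never split.

**Distances.** K2P and the closed-form GTR estimator
d = −tr(Π log(Π⁻¹F̂)) are computed with pairwise deletion of columns
containing gaps, N, or IUPAC ambiguity codes (preserved on disk, ignored
at distance time). Saturated pairs — where the logarithm argument is
non-positive or the matrix logarithm is non-real — are flagged and left
NaN, never clamped. The ML estimator maximizes the pairwise GTR+I+Γ
likelihood over the branch length by bounded Brent search (|Δt| < 1e−8,
≤ 200 iterations); the discrete gamma uses four equal-probability
categories with category-mean rates, rescaled by 1/(1−p_inv) so the
overall site-rate mean is one and branch lengths read as expected
substitutions per site. Two-locus combination is the
alignment-length-weighted mean over loci where the pair is comparable,
with single-locus fallback; a pair comparable nowhere is missing and
contributes no clustering edge (components can still form through
intermediaries, mirroring single-linkage chaining). Where a complete
matrix is required (neighbor joining for the PTP tree), missing pairs are
filled by shortest-path metric completion.

**Barcode-gap detection.** The disjunct is the longest maximal run of
constant OTU count along the threshold grid (ties to the earliest run);
its smallest threshold is reported, with the plateau length and flanking
drops. A plateau is parameter-free and matches the idea of a *stable*
switch to species-level grouping better than a largest-single-drop rule.
A strictly decreasing curve raises "no disjunct".

**Poisson tree process.** Branch lengths are modeled as i.i.d.
exponential with one rate on between-species edges and another on
within-species edges; a delimitation marks, per species, the edges of its
spanning subtree as within. Rates are profiled out analytically
(λ̂ = n/Σx per class). The search is a deterministic greedy over species
boundaries (split a species at its root node, or merge sibling species
into their parent), run from both the one-species and the all-singletons
start, better end returned. Because a free two-rate fit can never have
lower likelihood than a one-rate fit, pure likelihood always favors
splitting; moves are therefore accepted on the penalized score
log L − c·k with k the species count and c = 3.0 per species, an
AIC-type complexity charge (≈ 2Δlog L > 6 per added boundary, the χ²₁
~1.4 % critical value — conservative under the implicit multiple testing
across candidate boundaries). At this penalty, trees whose edges come
from a single exponential are returned as one species ~97 % of the time,
while clean multi-species structure is recovered exactly; c = 0 gives
the pure-ML search, whose log-likelihood is monotone along the greedy
path. Non-positive edge lengths are perturbed upward; the pipeline uses
half a substitution over the total alignment length (the data's
branch-length resolution) rather than a fixed epsilon, because clusters
of identical sequences otherwise form a degenerate, infinitely likely
within-species class. Species whose mean within-edge length exceeds ten
times the within-class mean are flagged: a long branch nested among
near-identical tips is the classic failure mode that inflates species
counts, and the flag is a diagnostic for the user, not an automatic
correction.

**The 9 % COI rule and consensus.** Within an OTU, any pair with COI K2P
distance strictly greater than 0.09 is flagged as almost certainly
heterospecific; at or below the bound the rule proposes connectivity
grouping at ≤ 0.09. For each remaining morphology/DNA incongruence the
three delineators (restricted to those with data for all the group's
specimens; the K2P rule requires COI for all of them) each propose a
grouping; the morphological grouping is overridden only when all
available proposals coincide and differ from it. This makes the pipeline
deliberately conservative: genuinely distinct species closer than 9 % at
COI cannot be split over morphology's objection, which is the intended
field behavior.

## Trees and community metrics

Neighbor joining is implemented with lexicographic tie-breaking on taxon
names (input-order invariance) and negative branch estimates clamped to
zero with the deficit moved to the sister edge. Reference grafting
attaches each query as a cherry at the midpoint of its nearest reference
tip's pendant edge (pendant max(d/2, 1e−6)); backbone topology and path
lengths are untouched, so community-tip patristic distances are
invariant — the with/without-reference contrast therefore acts through
Faith's PD pruning and through the enlarged null pool of the NRI/NTI
randomization, not through pairwise distances.

Faith's PD is the total branch length of the minimal spanning subtree
*including the root path* (pruning keeps the original root even at
degree one). MPD averages patristic distances over distinct unordered
pairs (abundance products as weights when weighted); MNTD averages each
taxon's distance to its nearest *other* community member — self-distances
are excluded but distinct taxa at distance zero still count. NRI/NTI are
the negated z-scores of MPD/MNTD against a tip-shuffle null: each of the
default 999 iterations draws an equal-size taxon set uniformly from the
whole supplied phylogeny's tips and reassigns the observed abundances.
Positive values mean clustering; the sign convention is pinned by test.
A community equal to the entire pool has a constant null and raises a
degenerate-null error.

Beta diversity uses the replacement/richness partition
β_total = (b+c)/(a+b+c), β_repl = 2·min(b,c)/(a+b+c),
β_rich = |b−c|/(a+b+c) (incidence: shared/unique species counts;
abundance: Σmin and unilateral surpluses), averaged over plot pairs; the
identity β_total = β_repl + β_rich is exact and asserted to 1e−12.
Default rarefaction resamples each plot without replacement to the
smallest plot total, 100 times, excluding plots below the target.
Mantel, ANOSIM and PERMANOVA use the permutation conventions
p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm); PERMANOVA partitions the
Gower-centered squared-distance matrix and permutes raw observations,
single-term designs (one factor or one continuous covariate) only. Their
type-I error is calibrated at 0.05 by simulation in the acceptance
suite, and their statistics are cross-checked against an independent
implementation in the tests.

## The synthetic-data generator

The generator emulates the statistical structure of a two-locus tropical
bee inventory; its defaults are the package's study conditions.

* **Species tree.** Pure-birth (Yule): waiting times Exp(k·λ) while k
  lineages exist, uniform choice of the splitting lineage, one final
  Exp(n·λ) pendant extension, depth normalized to 1.
* **Scaling and the gap.** The tree is scaled to 0.15 expected fast-locus
  substitutions per site root-to-tip, then every internal node is floored
  so the smallest interspecific distance is `min_interspecific` (default
  0.03) in combined (length-weighted) units — flooring is monotone, so
  the tree stays ultrametric, at the cost of zero-length internal edges
  between stacked nodes. Intraspecific variation is a star genealogy of
  pendant length `within_species_scale`/2 (default total 0.002) hanging
  from each species' sequence: the delineators depend only on the gap,
  not on coalescent genealogy shape. Generating distances are thus
  exactly bimodal with an empty (0.002, 0.03) interval; *estimated*
  distances blur its edges at barcode alignment lengths, and pairs
  comparable only at the slow locus fall genuinely inside it (see below).
* **Loci.** COI-like: 585 bp, AT-rich frequencies, transition bias 4,
  p_inv 0.2, α = 1.0, relative rate 1. 28S-like: 450 bp, milder bias,
  relative rate 0.25. Sequences evolve by transition matrices
  exp(Q·b·rate) per branch with per-site rate categories fixed across
  the tree (invariant sites stay invariant); alignments are gapless (no
  indel process).
* **Missing loci.** Each specimen loses each locus independently at rate
  0.15 but never both (a lost pair keeps one at random), so
  P(single-locus specimen) = 2r(1−r) + r². Pairs without a shared locus
  fall back to the other locus' distance — which for interspecific pairs
  near the floor lies *inside* the combined gap. This reproduces a real
  failure mode of two-locus surveys (sister species identical at the
  slow locus lumped when the fast locus is missing), and it is why the
  unsupervised gap/disjunct benchmarks run the generator with
  `missing_locus_rate = 0`: they characterize the method, the noisy
  default characterizes the protocol.
* **Morphospecies error.** Lump (merge a species' label into another's,
  rate 0.1/species), split (bipartition a species' specimens into two
  labels, 0.1/species), mislabel (0.02/specimen).
* **Communities.** Twelve plots in five habitats (young/old rubber,
  forest edge, river bank, forest ×4). Each habitat draws a focal clade
  (an internal node covering between a fifth and half of the species);
  species enter a plot's pool with probability
  0.5 · richness_multiplier · ((1−φ) + φ·clade_membership). Forest has
  the strongest filter (φ = 0.8) and lower richness; included species
  get log-normal(1, 1) abundances rounded up to ≥ 1 individual
  (range ≈ 1–70). Species absent from every plot are seeded with one
  individual at a random plot so that every sequenced species was caught
  somewhere. Covariates (habitat, altitude, temperature, an NDMI-like
  vegetation index) are drawn from per-habitat normals. Specimen plot
  membership follows the community abundances.

What passing tests on these data do **not** show: robustness to
alignment error or indels, coalescent gene-tree discordance,
contamination, or real morphological characters — the generator's label
errors are random, not correlated with phylogeny as real misidentifications
are.

## Numerical and degenerate-input conventions

Distance saturation is flagged, never clamped. ARI restricted to the
label intersection; both-trivial partitions (single class vs single
class) return 1. Plots with one OTU get NaN for MPD/MNTD/NRI/NTI and are
dropped from paired correlations. The stochastic stages all derive their
streams from one master seed plus fixed stage indices; reruns are
byte-identical. Rounding of the per-plot sampling means is half-toward-zero
at one decimal, matching the printed precision conventions of the survey
tables the summary op reproduces.

## Known limitations

The PTP search is greedy with two starts, not exhaustive or annealed;
on specimen-level NJ trees it tends to oversplit species with internal
structure (reported honestly by the benchmark). Reference grafting is a
stand-in for a constrained likelihood tree search, so with/without-
reference contrasts in pairwise-distance-based indices are driven by the
null pool only. PERMANOVA handles single-term designs; there is no
variance partitioning over multiple covariates, no NMDS, and no
coordinate-based spatial Mantel (the environment Mantel uses
standardized covariate distances).
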