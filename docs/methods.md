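# Methods notes

This note records the models, conventions and numerical choices behind
`corephylo`, in the places where the underlying procedure left genuine design
freedom, and what the synthetic-data tests do and do not demonstrate.

## The synthetic clade generator

`corephylo.simulate` produces a clade of `n_groups` groups ×
`species_per_group` species × `genomes_per_species` genomes with known ground
truth. Its defaults describe the study conditions the package is validated
under:

| parameter | default | meaning |
|---|---|---|
| `core_panel_size` | 300 | single-copy genes shared by all genomes |
| `accessory_pool_size` | 600 | genes subject to gain/loss |
| `within_species_divergence` | 0.005 | expected pairwise substitutions/site inside a species (~99.5% identity) |
| `between_species_divergence` | 0.05 | between species in a group (~95%) — straddling the 97% species threshold from below |
| `between_group_divergence` | 0.15 | between groups |
| `gene_gain_rate`, `gene_loss_rate` | 8 | Poisson events per branch of the group/species/genome hierarchy |
| `rearrangement_rate` | 2 | inversions + block translocations per branch |
| `mean_gene_length_codons` | 300 | Poisson mean gene length |
| `draft_fraction` | 0.5 | genomes fragmented into 4–12 scaffolds |
| `gene_split_probability` | 0.05 | chance a draft carries one gene split across a breakpoint |
| `noise_annotation_rates` | 0.08/0.01/0.005 | hypothetical / mobile-element / repeat rows per coding call |

**Substitution model.** Independent-site substitution with a uniform rate
(Jukes–Cantor-like): each site flips with the branch's divergence probability
to one of the other three bases. Divergence is structured hierarchically —
root → group ancestor → species ancestor → genome, with each branch carrying
half the configured pairwise divergence of its level — so two genomes of
different species differ by about `between_species + within_species`
substitutions per site. One deliberate departure from a neutral model: a
substitution that would create an internal stop codon is redirected to
another base. Core genes are overwhelmingly under purifying selection
against nonsense mutations, and without this constraint essentially every
gene acquires premature stops at realistic divergences, which would make the
translate–align–back-translate stage discard most of the data. The terminal
codon drifts freely. The redirection leaves the per-site substitution
probability exact and perturbs only the (already tiny) probability that two
independent substitutions coincide, which the calibration test accounts for.

**Gene content and architecture.** Accessory presence evolves by Poisson
gain/loss per branch over a fixed pool; every pool gene's *sequence* evolves
along every branch whether or not it is currently present, so regained genes
carry lineage-specific divergence (important: otherwise high-occupancy
accessory genes would enter the core panel with identical sequences and
inflate PNS). Gene order is a circular permutation of the present genes;
each branch applies Poisson-many events, each an inversion (segment
reversed in place, strands flipped) or a block translocation, with segment
length uniform up to a quarter of the chromosome. Genomes are laid out
gene-by-gene with no intergenic sequence (a declared non-goal), the origin of
the linear representation rotated randomly per genome.

**Species tree shape.** The hierarchy is star-like within each level (all
species of a group radiate from the group ancestor). The written truth tree
reflects this with polytomies. A ladderized alternative was considered and
rejected: the star keeps all same-level pairwise divergences equal, which is
what the threshold-straddling recovery tests need, and no test depends on
within-group branching order.

**Draft assemblies.** Fragmentation cuts the circular gene order at random
gene boundaries, then shuffles and randomly reverses the resulting scaffolds.
With `split_genes`, one cut lands inside a gene at a uniform interior
position (kept ≥ 10% from either end so both partials are called), producing
two partial calls whose lengths sum exactly to the original.

**What passing tests do not show.** The generator has no sequencing error,
no assembly chimerism or contamination, no annotation-string drift between
runs of an annotation server, no paralogy beyond exact duplications, and no
HGT (gene trees equal the species tree, so concordance tests on synthetic
data exercise machinery, not biology). Recovery results on synthetic data
therefore validate the *rules* — thresholds, filters, orderings — not the
robustness of those rules to real-data pathologies.

## Core-panel filters

Filters run in the order: duplicate removal, per-copy size filters,
missing-data cutoff. Conventions where the rule composition is ambiguous:

* the duplicate rule requires ≥ 2 copies each with normalized size strictly
  > 0.75; a genome with one full copy plus sub-0.7 fragments is *present*,
  not duplicated (the fragments are assembly artefacts by construction);
* two surviving copies both in (0.7, 0.75] are irreducibly ambiguous and
  scored missing for that genome (conservative), logged at debug level;
* normalized size exactly 0.7 survives the fragment filter, exactly 1.3
  survives the oversize filter, exactly 0.75 escapes the duplicate rule —
  all boundary comparisons are strict per the rule wording;
* `max_missing_genomes` counts genomes scored missing *after* the size
  filters, and a gene is removed when that count reaches the cutoff (≥ 4 by
  default).

The "complete genome" N50 cutoff (3 Mb) applies to real bacterial
assemblies; the pipeline takes the complete-genome set explicitly, and for
synthetic data uses the generator's draft flag, since simulated chromosomes
are deliberately small.

## Alignment

Gene alignment is translate–align–back-translate with a pluggable protein
aligner. The bundled `CenterStarAligner` (center star over Biopython's
pairwise aligner: match 2, mismatch −1, gap open −5, extend −0.5) is
deterministic plumbing that is exact for the no-indel and isolated-indel
cases the synthetic data produces; `MafftAligner` adapts an external MAFFT
for real data, and the test suite cross-checks the two on an indel fixture.
Equal-length protein inputs short-circuit to the gap-free alignment, which
is optimal under these affine costs. Terminal stop codons are stripped
before translation and never re-enter; an internal stop flags the
genome-gene pair missing.

End trimming removes terminal codon columns whose missing fraction (a row's
codon counts as missing when all three characters are gap or N — gaps and Ns
count jointly) strictly exceeds 0.90; exact-0.90 columns stay. Trimming is
idempotent and never touches interior columns. Concatenation N-fills missing
genes over exactly their partition.

## Species delimitation

PNS excludes any position where either row carries a non-ACGT character;
ambiguity codes are treated as missing, like N. Clustering is by connected
components of the PNS ≥ 97% graph (single linkage): it is the only rule
under which the stated pairwise criterion is both necessary and sufficient
for cluster membership, and it reproduces published type-strain merges.
Non-transitive triples are therefore merged by closure. Candidate numbering
is blocked by group (caller-supplied order, alphabetical by default) and by
smallest member genome id within a group; both are configurable because the
numbering is presentation, not inference.

## Gene content

Species profiles round mean occurrence with breaks < 0.5 → 0,
[0.5, 1.5) → 1, ≥ 1.5 → 2 (the upper break closes the gap the stated rule
leaves at [1.5, 2)). Hellinger normalization is applied per row over the
non-excluded gene universe; Bray–Curtis comes from
`scipy.spatial.distance.braycurtis`. Rarefaction replicates draw a fresh
species order and one random genome per species, accumulating nested subsets
so each replicate's pan curve is non-decreasing and core curve
non-increasing; means are therefore comparable with exhaustive enumeration
over subsets, which the tests perform on toy groups. Venn overlaps use
rounded species profiles (not raw genome counts) at a fixed species depth,
consistent with the species-averaged occurrence display.

## Synteny

Scaffold scoring treats the reference chromosome as the circle it is: each
scaffold is scored by the circular (directional) mean of its core genes'
positions, which keeps arcs that straddle the arbitrary origin of the
reference's linear representation next to their true neighbours. A plain
linear mean rank would misplace exactly those arcs and forfeit the
recovery guarantee below. Ties break by scaffold id.

Orientation is chosen to maximise junction adjacencies (edge-gene pairs
between consecutive scaffolds, plus the circular closure) present in the
reference link set. Because this objective decomposes over consecutive
scaffold pairs, a two-state dynamic program (both orientations of the first
scaffold enumerated to close the circle) finds the exact optimum in linear
time — no greedy approximation is needed. Ties resolve to forward.

With those two choices, any fragmentation of a pool genome without
rearrangement or gene splitting is provably restored to SI = 1: the true
arrangement attains the maximal junction score, and any co-optimal
arrangement's links are all reference links, giving |A∩B| = |A| = |B|.

SI uses max(|A|,|B|) as denominator so SI(x,x) = 1 and missing genes in
drafts can only lower, never inflate, similarity. Drafts are processed in
decreasing completeness (descending N50, ties by fewer scaffolds, then id),
each accepted configuration joining the reference pool. A draft's final link
set includes junction and circular-closure links of its inferred
configuration, so complete and reordered genomes are accounted identically.
A link counts as present in a species when any member genome carries it; the
consensus network keeps links whose species frequency strictly exceeds 50%
in at least one group. All remaining ties (best reference, reference-genome
choice for the conserved-link profile) break lexicographically.

## Tree comparison

Normalized RF divides the count of bipartitions unique to either tree by the
total number of nontrivial bipartitions in both trees, which remains well
defined after polytomy-inducing collapses. Support scale is auto-detected
(values ≤ 1 read as proportions); unlabeled internal nodes are never
collapsed. The bootstrap-null test flags an observed distance as exceeding
when it is strictly greater than the null maximum and reports its empirical
percentile; with a degenerate all-equal null, a value numerically equal to
the maximum is not an exceedance. Neighbor joining is scikit-bio's; it is
deliberately the package's only tree *builder* — ML and coalescent engines
are external contracts whose inputs (partition files, reformatted gene
trees, NEXUS with taxon partitions) this package prepares.

## Problem sizes

The validation suite runs the full pipeline on a 4-group × 5-species ×
2-genome clade with a 300-gene core panel (the scale at which every stage's
behaviour is distinguishable), and unit fixtures on 2-group clades with
40–120 core genes; scaffold-reordering recovery is exercised on 50 genomes ×
300 genes. These sizes keep the whole suite and the acceptance script within
a few minutes on a single CPU while leaving every threshold decision
observable.

## Known limitations

* Gene identity is annotation-string identity; no orthology inference.
* The center-star aligner is not a general MSA tool; plug in MAFFT (or any
  protein MSA executable honouring the contract) for real data.
* The rf-null machinery takes replicate trees as input; it does not run
  bootstrap searches itself.
* Consensus-network and conserved-link outputs are tables/graphs; rendering
  is out of scope.
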