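# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `slowfast` package — an audit of the "slow–fast"
alignment-trimming practice in deep microbial phylogenetics.

## The question

Slow–fast analysis removes the fastest-evolving alignment sites before tree
inference, on the premise that substitution saturation destroys their
phylogenetic signal. The audit asks the converse question: how much signal
do slow sites actually carry for *short* internal branches? A site evolving
at rate multiplier r contributes `(L/k) · t · r` expected substitutions
along a branch of length t in an L-site alignment with k equiprobable rate
categories — a share `r/k` of the branch total, independent of t. For the
slowest of 12 categories under a gamma shape of 0.803 (r ≈ 0.023) this is
~0.2% of the substitutions on any branch: slow sites are almost guaranteed
to be silent across short branches, however many of them are kept.

## Substitution model

Amino-acid evolution follows a reversible CTMC: `Q_ij = S_ij π_j` with a
symmetric exchangeability matrix S and equilibrium frequencies π, rescaled
to unit mean rate (`−Σ π_i Q_ii = 1`) so branch lengths are expected
substitutions per site. The empirical LG, WAG, Dayhoff and JTT tables ship
as PAML-layout `.dat` files. Transition matrices use the spectral form of
the symmetrised generator (reversibility gives a real spectrum), cached per
model.

Rate heterogeneity uses the discrete-gamma approximation: k = 12
equal-probability categories, each carrying the conditional mean of a
mean-1 Gamma(α, α) within its quantile bin (the mean variant of the Yang
discretisation; the 12 rates average to exactly 1). At α = 0.803 the
endpoints are 0.02337 and 3.8233. Published tables for this dataset print
0.02332 and 3.8243, which correspond to a shape of ≈0.8025 rounded to
0.803 in print; the ~0.2% discrepancy is the rounding of α, not a
discretisation difference.

## Synthetic data

The generator emulates the simulation design of ribosomal-protein
Tree-of-Life studies:

- **Topology** — sequential random attachment: each new leaf grafts onto a
  uniformly chosen existing edge, starting from the 3-leaf star. The
  default study uses 100 leaves (a deliberate scale-down of the 1000-leaf
  design; see *Problem sizes*).
- **Branch lengths** — internal and terminal edges draw from separate gamma
  distributions with shapes 0.7581720 and 1.509421 (values fitted to a
  published 3083-taxon ribosomal phylogeny). The scales are not published;
  they are calibrated so the internal median is 0.05 substitutions/site —
  the median reported for that reference phylogeny — and the terminal
  median is 0.20, a realistic figure for densely sampled ribosomal trees.
  Both are config fields, chosen once and not tuned.
- **Sequences** — root drawn from the model equilibrium; each site draws
  its category uniformly from the k equiprobable categories (recorded as
  ground truth) and propagates down every branch with the category-specific
  transition matrix. No indels, no invariant class, no heterotachy, no
  compositional drift — deliberately, because the study's point is what
  happens *without* alignment error or model violation.

Everything is bit-reproducible from one master seed, fanned out through
`SeedSequence([master, replicate, stage, category])` with a fixed stage
numbering (0 topology, 1 branch lengths, 2 evolution, 3 bootstrap,
4 subsampling).

## Site-rate assignment and partitions

Invariant columns (≤1 distinct non-gap residue; gaps ignored) are removed
first. Variable sites get per-category likelihoods by Felsenstein pruning
(gaps and ambiguity codes are fully missing data; per-node rescaling keeps
1000-taxon likelihoods in range) and are hard-binned to the
maximum-posterior category under equal 1/k priors; ties resolve to the
slower category. On simulated data the guide tree is the true tree by
default (config flag); on real data a supplied Newick or the pipeline's own
estimate. A bounded 1-D search (`α ∈ [0.05, 20]`) maximises the
discrete-gamma mixture likelihood when the shape must be estimated.

Each rate category's sites form an RSAP (rate-specific alignment
partition): the sites are tandem-replicated cyclically to the full
alignment length, so every partition presents the same number of columns to
the estimator. Replication changes column multiplicity only, never
residues. Trimming schemes drop categories 1–4 (`slow_trim`), 10–12
(`fast_trim`) or both, the category boundaries used in the source analyses.
Gap-context labels classify each column by its flanking columns' gap counts
(defaults 2000/500 absolute, scalable as taxa fractions; window = 1 column
per side, configurable because "flanked by" is not further specified).

## Tree estimation (the UFBoot stand-in)

IQTree's UltraFast Bootstrap is replaced by machinery that runs at desk
scale while preserving the object the statistics consume — a sample of
trees per partition:

1. **Pairwise ML distances.** The branch length t maximising
   `Σ_sites log Σ_c (1/k) π_a P_ab(r_c t)`, bounded in (0, 10]; pairs at
   the cap are flagged saturated, not errored. The matrix/bootstrap path
   shares one precomputed log-likelihood grid (160 log-spaced distances,
   parabolic refinement around the per-pair optimum), so a bootstrap
   replicate costs two matrix products.
2. **Neighbor joining** with lowest-index tie-breaking and negative branch
   estimates clamped to zero.
3. **Balanced-NNI refinement.** NJ topologies are hill-climbed under the
   balanced minimum-evolution criterion (subtree averages weight each
   bifurcation's sides 1/2, the Desper–Gascuel convention); the quartet
   pairing with the smallest summed average distance is kept at every
   internal edge until no interchange improves. On pilot replicates this
   cuts RF distance to the true tree by 25–40% on fast partitions at
   ~0.1 s per 100-taxon tree. `refine=False` recovers plain NJ.
4. **Nonparametric bootstrap**: columns resampled with replacement, the
   full distance + NJ + NNI estimation redone per replicate. An adapter
   ingests externally produced multi-tree Newick samples instead.

Within a single RSAP the sites are rate-pure by construction, so
within-partition distances use the homogeneous (single-rate) model, in the
partition's own substitution units — the desk-scale analogue of a
per-partition LG+G refit, which converges to the homogeneous limit on
single-rate data. (Fitting the 12-category mixture to a rate-pure fast
partition grossly inflates distances: in pilots, 90% of RSAP12 pairs hit
the saturation cap and the recovery orderings inverted.) The heterogeneous
mixture is used whenever a rate-heterogeneous alignment is analysed.

Fixed-tree model scoring (the Table-1-style comparison) evaluates each
model with bundled or empirical (+F, 19 extra parameters, small
pseudocount) frequencies at a homogeneous rate; BIC with n = alignment
length selects the winner. Taxon-subsampling profiles re-estimate trees on
random leaf subsets per fraction (or prune the reference tree, as a config
mode) and report mean branch lengths.

## Statistics

Bipartitions are canonical splits (the side holding the smallest taxon
label); RF distance is the symmetric-difference count, normalised variants
divide by the total split count. A reference bipartition is *recovered*
("compatible") when ≥80% of a partition's bootstrap trees contain it.
Recovery summaries use only internal branches: the below-median and
top-quartile cutoffs come from the reference tree's internal branch-length
distribution. Spearman correlations use the large-sample t approximation,
switching to exact permutation below 10 pairs; replicate-level p-values are
Benjamini–Hochberg corrected (the source analyses report q-values without
naming a procedure; BH is the standard default). Tree-space pictures use
classical (Torgerson) MDS on double-centred squared RF distances with a
fixed axis-sign convention. Compositional bias is the sum over 20 residues
of squared frequency deviations from the whole (variable-site) alignment,
computed on unique source sites by default (replication multiplies counts,
not information; configurable).

## Problem sizes

The published simulation design is 1000 taxa × 100 replicate alignments ×
1000 bootstrap samples per partition with full ML tree search. The
package's default study — its own choice of a desk-scale working point —
is 100 leaves × 2596 sites × 3 replicates × 100 bootstrap trees per
partition, which completes in roughly ten minutes on one core. All scale
parameters are ordinary config fields.

## What the desk-scale study does and does not show

Reproduced qualitatively at the default scale (seeded runs):

- RF distance to the true tree is worst for the slowest partition and best
  in the mid-to-fast range, with a mild deterioration at the fastest
  partitions.
- The fastest partition recovers about three times the share of
  below-median-branch-length true bipartitions that the slowest does.
- Top-quartile longest-branch bipartitions are recovered at ≥90% by every
  partition except the slowest.
- The rate-vs-recovered-branch-length correlation is negative.

Not reproduced quantitatively — and important to understand why:

- The published short-branch recovery contrast (73% vs 18%) and
  replicate-average correlation (−0.69), and near-universal (~99%)
  long-branch recovery *including the slowest partition*, all rest on full
  ML tree search over 1000 taxa. A two-stage distance estimator dilutes
  the per-branch signal across noisy pairwise distances: the slowest
  partition's ~100–200 unique variable sites put even long branches below
  the pairwise noise floor, and classical bootstrap support is known to run
  more conservative than UFBoot support at the same threshold. The
  package reports what its estimator computes; closing this gap requires
  likelihood-based tree search, which is outside this artifact's scope.

Passing tests therefore certify the machinery (models, simulator, binning,
partitions, bootstrap, statistics) and the qualitative orderings, not the
full-scale effect sizes. Nothing in this note states a number the test
suite or `scripts/acceptance.py` does not itself compute.

## Numerical details

- Residues: uint8 codes in PAML order; gaps and B/Z/X are missing data.
- Pruning rescales partial likelihoods per node (max-normalisation) and
  accumulates log scales.
- The distance grid spans [5×10⁻⁴, 10] substitutions/site; identical
  sequences short-circuit to 0; grid-edge optima are capped/flagged.
- NJ resolves ties to the lowest-index pair; the final 3-star uses the
  closed-form lengths; negative estimates clamp to 0.
- MDS clips negative eigenvalues at zero and fixes axis signs by making
  each axis's largest-magnitude coordinate positive.
- Empirical (+F) frequencies add a 0.5 pseudocount per residue so absent
  residues keep the generator reversible and irreducible.
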