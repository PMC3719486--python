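# Methods

This note records the models, estimators and design choices behind
famwave, in the package's own words: what is simulated, how each quantity
is estimated, which knobs matter, and what the tests do and do not
establish.

## Gene-family birth–death simulation

A family starts as a single gene at the root of a species tree and each
gene lineage evolves independently along every branch under a duplication
rate λ and a loss rate μ (events per gene per unit branch time).  Event
times are drawn by the Gillespie algorithm (exponential waiting times at
total rate λ+μ, event type chosen proportionally).  An *expansion wave*
multiplies λ over the leading fraction of a named branch — the minimal
mechanism for lineage-specific bursts of duplication.  λ and μ may be
scalars or per-branch dictionaries keyed by the child node of each branch
(with a `default` entry).

Bookkeeping: the simulator records every event per branch and the number
of live lineages at each node, so the invariant
`lineages(child) = lineages(parent) + duplications − losses` is checkable
directly.  A family whose lineages all die is returned as an explicit
empty result, not an error.

Ground-truth labels.  Each duplication starts a new *lineage clade*: the
continuing copy keeps its clade label, the new copy gets a fresh one.
These fine-grained clades (at most one gene per species each) are what
Dollo reconstruction is scored against: with μ = 0 each clade spans
exactly the leaves below its birth branch, so reconstructed gains equal
true duplication counts branch by branch.  Category truth is coarser and
family-level: a family spanning ≥ 2 species is *stable* for all its
members, a single-species family of ≥ 2 genes is *unstable*, a lone gene
is a *singleton* — the same semantics the classifier applies to inferred
clades, evaluated on the realised species span.

The bundled species tree has eight leaves (one alga `Cocc`, bryophyte
`Ppat`, lycophyte `Smoe`, monocots `Osat`/`Sbic`, eudicots
`Vvin`/`Ptri`/`Atha`) with ancestors N0 (Chloroplastida), N1 (land
plants), NV (vascular plants), N2 (angiosperms), N3 (monocots), N4
(eudicots), ND (rosid crown); it is ultrametric with root-to-tip height
1.05 time units.

## Codon sequence evolution

Sequences evolve under an MG94-style model on the 61 sense codons:
single-nucleotide exchanges only, transition/transversion bias κ
(default 2), nonsynonymous rates multiplied by a per-region ω, and rates
into stop codons set to zero — stops are outside the state space, so no
in-frame stop can ever appear.  The generator is normalised so that one
unit of branch length equals one expected substitution per nucleotide
site at neutrality (ω = 1) with the given κ.  Substitution along a branch
is sampled exactly by exponentiating the 61×61 generator per (branch
length, region-ω) pair and drawing child codons from the parent rows;
matrices are cached, which makes replicate Monte-Carlo studies cheap.
Regions are codon intervals with their own ω (defaults: a conserved
N-terminal domain, ω = 0.1, and a diversifying C-terminal domain,
ω = 1.5, over a 200-codon CDS).  No indels and no among-site rate
variation are simulated; rows are therefore pre-aligned.

Randomness discipline: every operation derives its generator from the
single `SimParams.seed` through fixed stream ids (family history 0,
sequences 1, loci 2, expression 3), so identical parameters reproduce
byte-identical outputs regardless of call order.

## JTT distances and tree inference

Pairwise protein distances are maximum-likelihood times under the
Jones–Taylor–Thornton empirical model: Q = S·diag(π) normalised to one
expected substitution per site, joint likelihood
L(t) = Σ c_ij · log(π_i P_ij(t)) over residue-pair counts after pairwise
deletion of gap columns (reversibility makes the estimate symmetric).
The optimum is found by bounded Brent search on [0, 10] to tolerance
1e-6; estimates at the cap of 10 substitutions/site are flagged
saturated.  A Poisson-corrected fallback (−ln(1−p)) is available by
flag.  Inside the bootstrap loop, distances instead use a 160-point
log-spaced likelihood grid with one parabolic refinement in log-time
(≈ 0.1 % accuracy) — far below what topology estimation can resolve, and
an order of magnitude faster; the public single-pair function keeps the
Brent contract.

Neighbor joining follows Saitou–Nei; negative intermediate branch lengths
are clamped to zero with the deficit shifted to the sister edge
(a documented necessity for Newick output), and ties in the Q criterion
break on the lexicographically smallest pair of sorted-leaf-label cluster
keys, so results are invariant under input permutation.  Bootstrap
consensus resamples alignment columns with replacement, runs NJ per
replicate, and keeps bipartitions with frequency ≥ 0.5 (majority rule at
≥, not >); supports are round(100·frequency).  If a pair of rows shares
no sampled columns in a replicate the error is raised rather than
guessed.  Outgroup rooting bisects the outgroup's pendant edge; supports
are re-attached per unrooted bipartition afterwards, so rerooting never
migrates a support to the wrong split.

Reciprocal best hits score all cross pairs by global alignment (BLOSUM62;
affine gaps where a run of k gap positions costs 11 + k) and keep a pair
iff each sequence is the other's unique best hit; ties break
lexicographically and are flagged.

## Clade classification

On a rooted tree with supports as internal-node labels, a preorder walk
takes the first node on any root-to-leaf path with support strictly
greater than `min_support` (default 40; missing support counts 0) and at
least two leaves as a maximal clade; its descendants are not split
further, and uncovered leaves are singletons.  The outgroup is pruned
before extraction and reported as its own singleton row.  Clades spanning
≥ 2 species are stable, single-species clades unstable.  A curator
override table (gene → clade id) can re-assign genes where a single
support rule cannot reproduce externally curated groupings.  Raising the
threshold can only move genes out of clades, so the singleton count is
monotone in `min_support` (tested).

## Dollo gain/loss reconstruction

Each clade is a character gained exactly once at the MRCA of the species
retaining it, present with one ancestral copy on every node of the paths
from that origin to its retaining leaves, and lost on any branch where it
disappears.  Node counts are the number of clades present; terminal
branches absorb within-species copy-number expansion
(`gains = extant − inherited clades`), which places, e.g., a 20-fold
single-species amplification entirely on that species' terminal branch.
The one-copy-per-ancestral-clade reading is the parsimony-minimal one;
an alternative "maximum copies" reading cannot be reproduced from clade
spans alone and is not attempted.  Reconstruction asserts the
conservation identity on every branch and rejects extant counts smaller
than the clades containing the species.

## NG86 Ka/Ks

Synonymous sites per codon are Σ over positions of (#synonymous
single-base changes)/(#changes not creating a stop); nonsynonymous sites
are 3 − s.  Differences between two codons average the per-step
synonymous/nonsynonymous counts over all orderings of the minimal
mutation path, excluding orderings that pass through a stop (falling back
to all orderings when every path is blocked).  Site counts are averaged
between the two sequences; codons containing gaps or ambiguous bases in
either row are deleted pairwise; a shared terminal stop is tolerated,
an internal stop is an error.  Proportions are Jukes–Cantor corrected;
p ≥ 3/4 sets a saturated flag with an undefined distance, and Ks = 0
yields an undefined ratio flag rather than infinity arithmetic.  A
table-driven vectorised path (precomputed 61×61 difference tables) serves
the Monte-Carlo studies; unit tests verify both paths against an exact
rational-arithmetic enumeration oracle over all 3 721 ordered sense-codon
pairs.  Sliding windows (150 bp window, 9 bp step, both multiples of 3)
report 1-based bp coordinates with midpoints at window centres; the
window count is ⌊(L−w)/step⌋+1.  Group contrasts use the tie-corrected
Kruskal–Wallis H with a χ² p-value (df = k−1), dropping undefined ratios
with a logged count; all-identical input returns H = 0, p = 1.

In the neutral calibration the summary statistic is the ratio of mean Ka
to mean Ks across replicates, not the mean of per-replicate ratios — the
latter is inflated by Jensen's inequality at finite Ks counts — with a
delta-method standard error.

## Tandem clusters

Per chromosome, loci sorted by start are chained whenever the intergenic
gap (next start − previous end, floored at 0 for overlaps) is strictly
below 10 kb; chains of ≥ 2 genes are clusters (single linkage, so A–B–C
chain even when A and C are far apart).  The strict-< boundary and the
gap convention are configurable since the measuring points are a
convention, not a law.  The simulator's placement uses species-scoped
chromosome names so pooled multi-species locus sets never collide.

## Expression

Intensities are log2-transformed once (a flag prevents double
transformation; nonpositive cells are reported by gene and sample).
UPGMA uses scipy average linkage on euclidean or correlation (1 − r)
distance; genes are label-sorted first so tie-breaking is deterministic,
and two genes at distance d join at ultrametric height d/2.  The
stable-vs-unstable contrast is a pooled-variance Student t-test on
per-gene means (Welch by flag).  Concordance between sequence clades and
a k-cluster flat cut (k defaults to the number of clades) is the adjusted
Rand index plus per-clade co-clustered pair fractions; single-clade or
single-cluster comparisons are flagged degenerate with ARI = NaN.

## The recovery study generator

`famwave.pipeline.simulate_study` builds the scenario on which the whole
pipeline is scored: 15 independent families on the default species tree —
seven conserved single-copy families (stable), four species-specific
expansions on terminal branches (unstable; duplication rate 6 on the host
branch, extinction elsewhere via heavy per-branch loss), three lone genes
and one algal outgroup gene.  Sequence structure mimics a multi-domain
superfamily alignment: all families share a homologous 40-codon
N-terminal domain evolved from one ancestral domain along equal stems of
1.2 nt substitutions/site at ω = 0.4, while each family's 110-codon
C-terminal block occupies its own alignment columns (gaps elsewhere).
Within-family divergence accrues at 0.12 substitutions per unit of
species-tree time.  Two properties follow, and they are the point:
within-family distances stay well below the cross-family floor, so each
family is a crisply supported clade; and cross-family distances rest only
on the short clock-like common domain, so they are nearly equal and the
deep backbone is an unresolved star that earns little bootstrap support.
This reproduces the regime the analysis assumes — strong shallow signal,
no deep signal — the regime in which stable/unstable/singleton categories
are identifiable at all.  With fully independent random families instead,
chance sequence affinity between unrelated saturated sequences is
consistent under column resampling and routinely produces spuriously
supported deep joins; the domain-structured design removes that failure
mode, and the many-small-families layout bounds the damage of any
residual join.  Category recovery was ≥ 0.92 on every one of 28
consecutive seeds at this design point.

What passing does not show: the generator has no indels, no rate
variation among sites, no alignment error, no gene conversion, and its
"unalignable domain" structure is imposed rather than inferred by an
aligner — so recovery rates here bound what the pipeline can do under its
own assumptions, not on real proteomes.

## Problem sizes and tolerances

The test suite and the acceptance script use: all 3 721 ordered codon
pairs for the NG86 oracle; 200 random additive matrices (≤ 8 leaves,
1e-9 additivity tolerance); 100 simulated histories for Dollo
conservation plus 40–50 loss-free histories for gain equality; 500
replicates for the two-region ω ordering (≥ 95 % ordered) and the
neutral calibration (99 % CI covers 1); 1 000 simulated datasets for the
expression type-I rate (5 % ± 2 %); 1 000 bootstrap replicates and the
default 15-family study for category recovery (≥ 90 %).  These sizes keep
each check statistically meaningful at interactive runtimes.

## Known limitations

JTT-ML distances saturate near 10 substitutions/site and are flagged, but
trees built from heavily saturated matrices are unreliable at depth by
nature; the classifier relies on that unreliability staying *unsupported*
rather than resolving it.  The Dollo reconstruction cannot distinguish a
root-present-then-lost clade from a later origin (it reports the MRCA of
surviving species).  NG86 is an approximate counting method: with strong
transition bias its site counts are biased relative to ML codon models;
it is used here as a consistent, fast estimator, not as the best
available one.
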