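# Methods

## The inference problem

Given a rooted species tree, a collection of per-family gene trees, and
optionally a graph-based orthogroup clustering, the pipeline decides, for a
curated set of named genes, in which species each gene is still present —
and then screens genome-wide for orthogroups whose loss pattern tracks a
convergently evolved trait: absent in every focal (trait-bearing) species,
present in every background species.  The scientific setting is gene-loss
phyloprofiling: traits such as arbuscular mycorrhizal symbiosis leave a
diagnostic footprint of co-eliminated genes, and carnivorous lineages that
abandoned the symbiosis are expected to show convergent absence of that gene
set while close noncarnivorous relatives retain it.

## Duplication–loss reconciliation and rooting

Reconciliation uses the classical LCA mapping.  Each gene-tree leaf maps to
the species-tree leaf of its species; each internal node maps to the LCA of
its children's images.  A node is a duplication exactly when it shares its
image with at least one child; otherwise a speciation.  Losses are counted
per gene-tree edge u→v from the number d of species-tree edges between the
images of u and v: d−1 losses below a speciation, d below a duplication.
This is the standard parsimony count for the duplication-loss model; the
total cost is w_dup·dups + w_loss·losses with unit weights by default (the
weighting is configurable because published pipelines rarely state it).

Unrooted gene trees are rooted by exhaustive search: every edge of the
unrooted tree (2n−3 for a binary tree) is tried as a root position, the edge
being split at its midpoint, and the minimal-cost rooting kept.  The full
edge→cost table and the set of minimal-cost ties are part of the result so
rootings can be audited.  Ties are broken deterministically: prefer the
candidate whose root image is closest to the species-tree root (smallest
depth of M(root)), then the lexicographically smallest edge identifier (the
sorted leaf labels of the smaller bipartition side).  Nothing in the DL
model distinguishes tied edges, so the tie-break is a reporting convention,
not an inference.

Numerical/structural choices:

* Non-binary gene-tree nodes are resolved deterministically before
  reconciliation (children ordered by smallest descendant label, combined
  left-deep with zero-length edges) and the result is flagged; DL counting
  is defined on binary trees and ML gene trees are binary in practice.
* Species-tree polytomies are left as-is; a polytomy contributes one edge to
  the loss path, which under-counts rather than over-counts losses
  (conservative).
* Gene-tree leaves whose species is absent from the species tree are pruned
  at ingest with a logged warning, mirroring upstream contamination
  filtering; reconciliation refuses unmapped species outright.

The implementation is verified against an independent brute-force oracle
(naive ancestor-walk LCA, adjacency-map re-rooting, written separately in
the test suite) on hundreds of simulated families: the per-edge cost tables
agree exactly, and the zero-cost characterization (cost 0 ⇔ one copy per
species of the root-image clade, congruent topology) is tested in both
directions.

## Orthogroup extraction

A named gene is located in a rooted family tree via its anchor ids — known
orthologs in reference species.  The orthogroup is the smallest clade that
(a) contains the anchor and (b) has a child subtree consisting exclusively
of outgroup-species leaves; that child is the basalmost lineage of the
clade, which is the weakest structural reading of "outgroup as basalmost
ortholog" that can be checked mechanically.  All leaves of the clade are
members, including lineage-specific duplicates.  When no such clade exists
(typical when the outgroup is missing from a transcriptome-derived tree) the
extraction returns the largest clade around the anchor that avoids other
genes' anchors and flags `outgroup_found=False`; presence is still scored,
since dropping such families would bias the profile toward absence.  With
several anchors in one tree the union of their clades is taken — consistent
with the union-style consensus downstream.  Anchor ids match by exact string
comparison; no fuzzy matching.

Graph-based clusters are a second, independent evidence channel: each
cluster containing an anchor of a gene yields one call, so one cluster
shared by two genes and one gene split across clusters are both
representable; downstream presence takes the union over a gene's calls.

## Consensus occurrence and retention

A gene is present in a species if either evidence source recovers it —
union, not intersection — because the two channels fail independently and
the analysis cares about presence trends, not per-copy certainty.  Each cell
records provenance (`tree`, `graph`, `both`, `none`), with the invariant
that `none` coincides exactly with absence.  Species absent from a
particular gene tree contribute "absent" for that source (detected vs
undetected is the dichotomy; there is no missing-data state by default, an
optional mask supports sensitivity analyses).  Retention of a gene set in a
species is k present of n; group summaries report per-species values with
group n, mean, and min–max range.

## The convergent-loss screen

Set logic on the occurrence matrix: hits = rows present in every background
species ∩ rows absent in every focal species, with the universe, the two
marginal counts, and the hit list all reported.  Focal species are pooled by
default; an optional per-lineage mode requires each focal group to be
all-absent independently.  Target-list overlap is reported as a count plus
ids, and enrichment as the exact one-sided hypergeometric tail
P(X ≥ k) computed by rational summation of C(K,i)C(N−K,n−i)/C(N,n) —
exact integer arithmetic, so the test-suite comparison against full
enumeration holds to 1e-12 and large universes lose no precision.  No
multiple-testing correction is applied for a single screen; a
Benjamini–Hochberg helper exists for multi-list use.

## The simulator and what it does (not) show

The generator emulates the statistical structure of a gene-loss study, not
sequences: species trees are Yule (pure birth, rate 1/unit time, ultrametric
by construction); one gene lineage enters the species-tree root and each
copy evolves an independent linear birth–death process along every branch
(duplication rate λ, loss rate μ per unit branch length); trait-linked
families (a fraction `frac_trait_linked`) are additionally forced-lost with
probability `p_forced_loss` per designated trait branch — all copies
terminated at the branch midpoint, no regain below (Dollo-like
irreversibility, reflecting how hard multi-gene pathways are to
re-evolve).  Detection dropout thins true presence per species with
completeness c_s; presets 0.90/0.77 correspond to typical genome and
transcriptome gene-set completeness.

Scenario defaults are the package's reference study conditions: 500
families on a 16-taxon tree, λ = μ = 0.1, 15% trait-linked families,
certain forced loss on two cherries (4 focal species), perfect detection
unless stated.  The duplication/loss rates are implementer-chosen realistic
magnitudes — empirical per-family DL rates are not identifiable from a
presence/absence study — and are deliberately critical (λ = μ) so family
size drifts without exploding; the birth–death mean E[N(T)] = e^{(λ−μ)T} is
verified by Monte Carlo against the closed form.

What passing simulation tests show: the algorithmic chain (rooting →
extraction → consensus → screen) is internally correct and recovers planted
signal exactly under perfect detection, and degrades as binomial theory
predicts under dropout.  What they do not show: robustness to gene-tree
estimation error (topological noise from alignment/inference is not
simulated), to horizontal transfer, to rate heterogeneity across branches
beyond the trait mechanism, or to annotation artifacts in real assemblies.
Real-data conclusions still require the caution the field applies to
presence/absence calls from transcriptomes.

## Determinism

All randomness flows through numpy Generators seeded from user seeds;
per-family streams derive from (seed, family_index) so families regenerate
independently; forced-loss decisions are pre-drawn in a fixed branch order
so the stream does not depend on which branches surviving copies reach.
Serialized datasets regenerate byte-identically from the same scenario.

## Known limitations

* Rooting is exhaustive per edge, O(n²·depth) per family — intended for the
  ≤ a-few-hundred-leaf trees of anchored families, not 5000-leaf homolog
  sets.
* The DL model ignores branch lengths and transfer; likelihood-aware
  rooting/NNI correction (as done by species-tree-aware ML refiners) is out
  of scope, and results feeding from such tools are consumed, not
  reproduced.
* Graph-based clustering itself is an input (TSV), never recomputed.
* The occurrence model has no explicit missing-data state by default; the
  optional mask is the escape hatch for completeness-aware sensitivity
  analyses.
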