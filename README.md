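# symscreen

Phylogenomic screening for convergent gene loss across species — the kind of
analysis used to ask whether a functionally coherent gene set (for instance
the genes supporting arbuscular mycorrhizal symbiosis) has been repeatedly
discarded in lineages that evolved an alternative lifestyle (for instance
carnivorous plants).

The package is aimed at comparative genomicists who already have a rooted
species tree, per-family gene trees from standard ML tools, and optionally a
graph-based orthogroup table, and who want a tested, scriptable
implementation of the inference chain in between:

1. **treeio** — newick and TSV ingest with an enforced `species|gene_id`
   leaf-label convention linking every gene to a species-tree leaf.
2. **reconcile** — duplication–loss (DL) reconciliation by LCA mapping, and
   rooting of unrooted gene trees by exhaustive minimal-DL search over all
   edges.  For a gene-tree edge $u \to v$ with images $M(u), M(v)$ in the
   species tree, losses are counted as $d-1$ ($d$ = path length from $M(u)$
   to $M(v)$) below a speciation and $d$ below a duplication; the root is
   placed on the edge minimising $w_D \cdot \#\text{dup} + w_L \cdot
   \#\text{loss}$, with the full per-edge cost table and the tie set
   reported.
3. **orthogroup** — anchor-based extraction: the orthogroup of a named gene
   is the smallest clade containing a reference-species anchor ortholog with
   the outgroup species (by default *Amborella trichopoda*) as the basalmost
   lineage; lineage-specific duplicates are members.  Graph-based cluster
   tables are ingested as a second, independent evidence source.
4. **occurrence** — consensus presence/absence: a gene is present in a
   species if *either* evidence source recovers an ortholog there, with
   per-cell provenance (`tree`/`graph`/`both`/`none`) and retention
   statistics (k present of n, per species and per species group).
5. **screen** — the convergent-loss screen: orthogroups absent in **all**
   focal species and present in **all** background species, with target-list
   overlap and an exact hypergeometric enrichment p-value,
   $P(X \ge k),\ X \sim \mathrm{Hypergeom}(N, K, n)$.
6. **simulate** — a fully ground-truthed generator: Yule species trees, gene
   families evolving by a per-copy linear birth–death process (duplication
   rate λ, loss rate μ per unit branch length), trait-linked forced losses
   on designated branches, and per-species detection dropout emulating
   incomplete genome (c ≈ 0.90) or transcriptome (c ≈ 0.77) assemblies.

## Worked example

```python
from symscreen import read_species_tree, read_gene_tree, root_gene_tree
from symscreen.simulate import (convergent_loss_scenario, simulate_gene_family,
                                apply_detection_noise)
from symscreen.screen import (ScreenSpec, convergent_loss_screen,
                              hypergeometric_enrichment)

# --- minimal-DL rooting of an unrooted gene tree -------------------------
stree = read_species_tree("((A,B),(C,D));")
gtree = read_gene_tree("(A|a1,B|b1,(C|c1,D|d1));")   # basal trifurcation
result = root_gene_tree(gtree, stree)
print(f"root edge: {result.root_edge}, cost={result.cost}, "
      f"dup={result.dup_count}, loss={result.loss_count}, ties={result.tie_edges}")

# --- synthetic convergent-loss study -------------------------------------
scenario, focal, background = convergent_loss_scenario(seed=1, n_families=200)
sp = scenario.resolved_species_tree()
truths = [simulate_gene_family(scenario, i, species_tree=sp) for i in range(200)]
matrix = apply_detection_noise(truths, 1.0, seed=1, species=sp.leaf_names)
res = convergent_loss_screen(matrix, ScreenSpec(focal, background))
print(f"universe={res.n_universe} background_present={res.n_background_present} "
      f"focal_absent={res.n_focal_absent} hits={res.n_hits}")
trait = {t.family_name for t in truths if t.trait_linked}
k = len(set(res.hits) & trait)
p = hypergeometric_enrichment(k, len(trait), res.n_hits, res.n_universe)
print(f"{k}/{res.n_hits} hits are trait-linked families "
      f"(exact hypergeometric p = {p:.3g})")
```

prints

```
root edge: ('A|a1', 'B|b1'), cost=0.0, dup=0, loss=0, ties=[('A|a1', 'B|b1')]
universe=200 background_present=69 focal_absent=32 hits=8
8/8 hits are trait-linked families (exact hypergeometric p = 1.06e-07)
```

The congruent quartet roots at zero cost on the edge separating {A,B} from
{C,D} — the species-root bipartition — with no ties.  In the synthetic
study, 200 gene families evolve on a 16-species tree where four "focal"
species (two independent cherries) force-lose every trait-linked family; the
screen recovers 8 hits, all of them genuinely trait-linked, and the
enrichment against the trait-linked list is decisive.

A `symscreen` console command wraps the same stages for shell pipelines
(`symscreen simulate | root | extract | occur | screen | validate |
convert`); run `symscreen --help` for details.

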