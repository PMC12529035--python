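import pytest

from symscreen import read_gene_tree, read_species_tree
from symscreen.simulate import SimScenario, simulate_gene_family, simulate_species_tree


@pytest.fixture
def quartet_species_tree():
    return read_species_tree("((A,B),(C,D));")


@pytest.fixture
def gene_tree():
    def make(newick, **kwargs):
        return read_gene_tree(newick, **kwargs)

    return make


@pytest.fixture(scope="session")
def yule20():
    """The 20-taxon reference species tree used by the simulation-based checks."""
    return simulate_species_tree(20, 1.0, seed=11)


def simulated_families(species_tree, n, seed, min_leaves=3, max_leaves=None,
                       dup_rate=0.1, loss_rate=0.1, max_scan=20000):
    """Yield up to n simulated families whose gene trees fall in a leaf window."""
    scenario = SimScenario(
        n_families=max_scan,
        species_tree=species_tree,
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        frac_trait_linked=0.0,
        seed=seed,
    )
    found = []
    for i in range(max_scan):
        truth = simulate_gene_family(scenario, i, species_tree=species_tree)
        if truth.gene_tree is None:
            continue
        size = truth.gene_tree.n_leaves
        if size < min_leaves or (max_leaves is not None and size > max_leaves):
            continue
        found.append(truth)
        if len(found) == n:
            break
    return found
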