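"""Generator contracts: determinism, birth-death sanity, forced losses, dropout."""

import filecmp
import math

import numpy as np
import pytest

from symscreen import read_species_tree
from symscreen.simulate import (
    FORCED_LOSS,
    SimScenario,
    apply_detection_noise,
    sample_branch_copy_number,
    simulate_dataset,
    simulate_gene_family,
    simulate_species_tree,
)


class TestSpeciesTreeSimulation:
    def test_two_taxon_cherry(self):
        tree = simulate_species_tree(2, 1.0, seed=4)
        assert tree.leaf_names == ["S1", "S2"]
        assert all(leaf.length > 0 for leaf in tree.root.leaves())

    def test_determinism(self):
        a = simulate_species_tree(10, 1.0, seed=42)
        b = simulate_species_tree(10, 1.0, seed=42)
        assert a.to_newick() == b.to_newick()
        c = simulate_species_tree(10, 1.0, seed=43)
        assert c.to_newick() != a.to_newick()

    def test_ultrametric_and_binary(self):
        tree = simulate_species_tree(50, 1.0, seed=1)

        def tip_depths(node, acc=0.0):
            acc += node.length or 0.0
            if node.is_leaf():
                return [acc]
            assert len(node.children) == 2
            return [d for c in node.children for d in tip_depths(c, acc)]

        depths = tip_depths(tree.root)
        assert len(depths) == 50
        assert max(depths) - min(depths) < 1e-9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, seed=0)


class TestGeneFamilySimulation:
    def test_no_events_yields_congruent_one_copy_family(self):
        scenario = SimScenario(
            n_families=1, n_taxa=8, dup_rate=0.0, loss_rate=0.0,
            frac_trait_linked=0.0, seed=6,
        )
        stree = scenario.resolved_species_tree()
        truth = simulate_gene_family(scenario, 0, species_tree=stree)
        assert all(truth.true_presence.values())
        assert all(c == 1 for c in truth.n_copies.values())
        gene_clades = {
            frozenset(n.split("|")[0] for n in node.leaf_names())
            for node in truth.gene_tree.root.postorder()
        }
        species_clades = {
            frozenset(node.leaf_names()) for node in stree.root.postorder()
        }
        assert gene_clades == species_clades

    def test_forced_terminal_loss(self):
        stree = read_species_tree("((S1:1,S2:1):1,(S3:1,S4:1):1);")
        scenario = SimScenario(
            n_families=1, species_tree=stree, dup_rate=0.0, loss_rate=0.0,
            trait_loss_branches=("S3",), p_forced_loss=1.0,
            frac_trait_linked=1.0, seed=0,
        )
        truth = simulate_gene_family(scenario, 0, species_tree=stree)
        assert truth.trait_linked
        assert truth.true_presence == {"S1": True, "S2": True, "S3": False, "S4": True}
        forced = [e for e in truth.events if e.event == FORCED_LOSS]
        assert [e.branch for e in forced] == ["S3"]
        assert forced[0].time == pytest.approx(0.5)

    def test_forced_clade_loss_via_mrca_spec(self):
        stree = read_species_tree("((S1:1,S2:1):1,(S3:1,S4:1):1);")
        scenario = SimScenario(
            n_families=1, species_tree=stree, dup_rate=0.0, loss_rate=0.0,
            trait_loss_branches=(("S3", "S4"),), p_forced_loss=1.0,
            frac_trait_linked=1.0, seed=0,
        )
        truth = simulate_gene_family(scenario, 0, species_tree=stree)
        assert truth.true_presence == {"S1": True, "S2": True, "S3": False, "S4": False}

    def test_no_forced_events_without_trait_linkage(self):
        scenario = SimScenario(
            n_families=40, n_taxa=8, trait_loss_branches=("S1", "S5"),
            frac_trait_linked=0.0, p_forced_loss=1.0, seed=8,
        )
        stree = scenario.resolved_species_tree()
        for i in range(40):
            truth = simulate_gene_family(scenario, i, species_tree=stree)
            assert not truth.trait_linked
            assert all(e.event != FORCED_LOSS for e in truth.events)

    def test_forced_events_confined_to_trait_branches(self):
        scenario = SimScenario(
            n_families=60, n_taxa=8, trait_loss_branches=("S2",),
            frac_trait_linked=0.5, p_forced_loss=0.5, seed=9,
        )
        stree = scenario.resolved_species_tree()
        saw_forced = False
        for i in range(60):
            truth = simulate_gene_family(scenario, i, species_tree=stree)
            for e in truth.events:
                if e.event == FORCED_LOSS:
                    saw_forced = True
                    assert e.branch == "S2"
                    assert truth.trait_linked
        assert saw_forced

    def test_presence_consistent_with_gene_tree(self):
        scenario = SimScenario(n_families=30, n_taxa=10, seed=10)
        stree = scenario.resolved_species_tree()
        for i in range(30):
            truth = simulate_gene_family(scenario, i, species_tree=stree)
            from_tree = {s: 0 for s in stree.leaf_names}
            if truth.gene_tree is not None:
                for leaf in truth.gene_tree.leaves:
                    from_tree[leaf.species_id] += 1
            assert truth.n_copies == from_tree
            assert truth.true_presence == {s: c > 0 for s, c in from_tree.items()}

    def test_pure_birth_never_loses_and_pure_death_never_gains(self):
        stree = simulate_species_tree(8, 1.0, seed=3)
        birth_only = SimScenario(
            n_families=25, species_tree=stree, dup_rate=0.3, loss_rate=0.0,
            frac_trait_linked=0.0, seed=14,
        )
        for i in range(25):
            truth = simulate_gene_family(birth_only, i, species_tree=stree)
            assert all(c >= 1 for c in truth.n_copies.values())
        death_only = SimScenario(
            n_families=25, species_tree=stree, dup_rate=0.0, loss_rate=0.3,
            frac_trait_linked=0.0, seed=15,
        )
        for i in range(25):
            truth = simulate_gene_family(death_only, i, species_tree=stree)
            assert all(c <= 1 for c in truth.n_copies.values())

    def test_family_regenerable_independently(self):
        scenario = SimScenario(n_families=5, n_taxa=6, seed=19)
        stree = scenario.resolved_species_tree()
        full = [simulate_gene_family(scenario, i, species_tree=stree) for i in range(5)]
        alone = simulate_gene_family(scenario, 3, species_tree=stree)
        assert alone.true_presence == full[3].true_presence
        assert (alone.gene_tree.to_newick() == full[3].gene_tree.to_newick()
                if alone.gene_tree else full[3].gene_tree is None)


class TestBirthDeathExpectation:
    def test_mean_copy_number_matches_closed_form_small(self):
        lam, mu, T = 0.2, 0.1, 3.0
        counts = sample_branch_copy_number(lam, mu, T, n_samples=3000, seed=23)
        expected = math.exp((lam - mu) * T)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) <= 3 * se


class TestDetectionNoise:
    def _truths(self, n=40, seed=16):
        scenario = SimScenario(n_families=n, n_taxa=6, seed=seed)
        stree = scenario.resolved_species_tree()
        return [simulate_gene_family(scenario, i, species_tree=stree) for i in range(n)], stree

    def test_perfect_completeness_reproduces_truth(self):
        truths, stree = self._truths()
        matrix = apply_detection_noise(truths, 1.0, seed=0, species=stree.leaf_names)
        for t in truths:
            for s in stree.leaf_names:
                assert matrix.presence.loc[t.family_name, s] == t.true_presence[s]

    def test_zero_completeness_blanks_everything(self):
        truths, stree = self._truths()
        matrix = apply_detection_noise(truths, 0.0, seed=0, species=stree.leaf_names)
        assert not matrix.presence.to_numpy().any()
        assert (matrix.provenance.to_numpy() == "none").all()

    def test_dropout_count_is_binomial(self):
        truths, stree = self._truths(n=300, seed=17)
        n_true = sum(sum(t.true_presence.values()) for t in truths)
        c = 0.9
        matrix = apply_detection_noise(truths, c, seed=1, species=stree.leaf_names)
        observed = int(matrix.presence.to_numpy().sum())
        sigma = math.sqrt(n_true * c * (1 - c))
        assert abs(observed - n_true * c) <= 3 * sigma

    def test_invalid_probability_rejected(self):
        truths, stree = self._truths(n=2)
        with pytest.raises(ValueError):
            apply_detection_noise(truths, 1.5, seed=0, species=stree.leaf_names)

    def test_per_species_completeness_requires_full_coverage(self):
        truths, stree = self._truths(n=2)
        with pytest.raises(ValueError, match="undefined"):
            apply_detection_noise(truths, {"S1": 0.9}, seed=0, species=stree.leaf_names)


class TestDatasetOrchestration:
    def test_byte_identical_regeneration(self, tmp_path):
        scenario = SimScenario(
            n_families=12, n_taxa=6, trait_loss_branches=("S2",),
            frac_trait_linked=0.3, detection_completeness=0.9, seed=33,
        )
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        simulate_dataset(scenario, dir_a)
        simulate_dataset(scenario, dir_b)
        files_a = sorted(p.name for p in dir_a.iterdir())
        assert files_a == sorted(p.name for p in dir_b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(dir_a, dir_b, files_a, shallow=False)
        assert mismatch == [] and errors == []
        assert "manifest.json" in files_a and "truth.tsv" in files_a

    def test_empty_scenario_writes_valid_files(self, tmp_path):
        scenario = SimScenario(n_families=0, n_taxa=4, seed=0)
        truths, gene_trees, matrix, manifest = simulate_dataset(scenario, tmp_path)
        assert truths == [] and gene_trees == []
        assert matrix.shape[0] == 0
        assert (tmp_path / "observed.tsv").exists()
        assert manifest["n_families_with_survivors"] == 0
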