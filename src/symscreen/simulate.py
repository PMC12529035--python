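"""Synthetic gene families evolving by duplication and loss on a species tree.

The generator produces the three layers the inference pipeline consumes, with
full ground truth:

* a rooted ultrametric species tree (pure-birth / Yule), or a user tree;
* per-family gene trees: one lineage enters the species-tree root and each
  copy independently duplicates at rate ``dup_rate`` and dies at rate
  ``loss_rate`` per unit branch length (a linear birth-death process per
  copy).  Families flagged *trait-linked* can additionally suffer a forced
  whole-family loss on designated "trait" branches (the carnivorous
  lineages): on entering such a branch, with probability ``p_forced_loss``
  every copy is terminated at the branch midpoint, and — Dollo-like — never
  regained below it;
* an observed presence/absence matrix obtained by thinning the true presence
  with per-species detection completeness (the analogue of imperfect genome
  or transcriptome assemblies; presets 0.90 for genomes and 0.77 for
  transcriptomes, matching typical Busco-style completeness means).

Everything is reproducible: random streams are split per family from
``(seed, family_index)``, so any family can be regenerated on its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .occurrence import OccurrenceMatrix
from .treeio import (
    DEFAULT_CONVENTION,
    GeneLeaf,
    GeneTree,
    LabelConvention,
    SpeciesTree,
    TreeNode,
    read_species_tree,
    write_newick,
    write_occurrence_table,
)

__all__ = [
    "SimScenario",
    "SimTruth",
    "SimEvent",
    "COMPLETENESS_GENOME",
    "COMPLETENESS_TRANSCRIPTOME",
    "simulate_species_tree",
    "simulate_gene_family",
    "apply_detection_noise",
    "simulate_dataset",
    "sample_branch_copy_number",
]

# Detection-completeness presets: typical gene-set completeness of assembled
# genomes (~0.90) and transcriptomes (~0.77).
COMPLETENESS_GENOME = 0.90
COMPLETENESS_TRANSCRIPTOME = 0.77

DUP = "dup"
LOSS = "loss"
FORCED_LOSS = "forced_loss"


def _seed32(seed: int) -> int:
    return int(seed) % (2**32)


@dataclass
class SimScenario:
    """Parameters of one simulated study.

    ``trait_loss_branches`` designates species-tree branches by their child
    end: a bare string names a terminal branch (the leaf), an iterable of
    leaf names means the branch above the MRCA of those leaves.
    ``detection_completeness`` is a single probability applied to every
    species or a per-species mapping.
    """

    n_families: int = 500
    species_tree: SpeciesTree | None = None
    n_taxa: int = 16
    birth_rate: float = 1.0
    dup_rate: float = 0.1
    loss_rate: float = 0.1
    trait_loss_branches: tuple = ()
    p_forced_loss: float = 1.0
    frac_trait_linked: float = 0.15
    detection_completeness: float | Mapping[str, float] = 1.0
    seed: int = 0
    family_prefix: str = "fam"
    convention: LabelConvention = field(default=DEFAULT_CONVENTION)

    def validate(self) -> None:
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication and loss rates must be >= 0")
        for p, label in (
            (self.p_forced_loss, "p_forced_loss"),
            (self.frac_trait_linked, "frac_trait_linked"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.species_tree is None:
            if self.n_taxa < 2:
                raise ValueError("n_taxa must be >= 2")
            if self.birth_rate <= 0:
                raise ValueError("birth_rate must be > 0")

    def resolved_species_tree(self) -> SpeciesTree:
        if self.species_tree is not None:
            return self.species_tree
        return simulate_species_tree(self.n_taxa, self.birth_rate, self.seed)

    def to_manifest(self) -> dict:
        tree = self.resolved_species_tree()
        completeness = self.detection_completeness
        if isinstance(completeness, Mapping):
            completeness = dict(completeness)
        return {
            "n_families": self.n_families,
            "n_taxa": len(tree.leaf_names),
            "species": tree.leaf_names,
            "species_tree_newick": tree.to_newick(),
            "birth_rate": self.birth_rate,
            "dup_rate": self.dup_rate,
            "loss_rate": self.loss_rate,
            "trait_loss_branches": [
                [spec] if isinstance(spec, str) else sorted(spec)
                for spec in self.trait_loss_branches
            ],
            "p_forced_loss": self.p_forced_loss,
            "frac_trait_linked": self.frac_trait_linked,
            "detection_completeness": completeness,
            "seed": self.seed,
            "family_prefix": self.family_prefix,
            "leaf_label_separator": self.convention.separator,
        }


@dataclass
class SimEvent:
    """One recorded event: the species-tree branch (by child end), the event
    type (dup / loss / forced_loss) and the time from the branch start."""

    branch: str
    event: str
    time: float


@dataclass
class SimTruth:
    """Ground truth for one simulated family."""

    family_name: str
    trait_linked: bool
    true_presence: dict[str, bool]
    n_copies: dict[str, int]
    events: list[SimEvent]
    gene_tree: GeneTree | None

    @property
    def extinct(self) -> bool:
        return not any(self.true_presence.values())


# ---------------------------------------------------------------------------
# species-tree simulation (Yule)
# ---------------------------------------------------------------------------


def simulate_species_tree(n_taxa: int, birth_rate: float, seed: int) -> SpeciesTree:
    """Simulate a rooted binary ultrametric Yule tree with leaves S1..Sn.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears one more exponential waiting time is added so terminal branches
    have positive length.  Deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(_seed32(seed))
    root = TreeNode()
    birth_time: dict[int, float] = {id(root): 0.0}
    active: list[TreeNode] = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.length = None  # set below once children exist
        left, right = TreeNode(), TreeNode()
        node.add_child(left)
        node.add_child(right)
        birth_time[id(left)] = birth_time[id(right)] = t
        # record split time on the parent via closure of birth_time
        birth_time[(id(node), "split")] = t  # type: ignore[index]
        active.extend([left, right])
    t_end = t + rng.exponential(1.0 / (n_taxa * birth_rate))
    for node in root.preorder():
        if node.is_leaf():
            node.length = t_end - birth_time[id(node)]
        else:
            split = birth_time[(id(node), "split")]  # type: ignore[index]
            node.length = None if node.parent is None else split - birth_time[id(node)]
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"S{i}"
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# gene-family simulation
# ---------------------------------------------------------------------------


def _branch_id(node: TreeNode) -> str:
    if node.name:
        return node.name
    return ",".join(sorted(node.leaf_names()))


def resolve_trait_branches(
    species_tree: SpeciesTree, specs: Iterable
) -> dict[int, TreeNode]:
    """Map branch specifications to species-tree nodes (the child end)."""
    resolved: dict[int, TreeNode] = {}
    for spec in specs:
        if isinstance(spec, str):
            node = species_tree.leaf(spec)
        else:
            node = species_tree.mrca(spec)
        if node is species_tree.root:
            raise ValueError("the species-tree root has no branch above it")
        resolved[id(node)] = node
    return resolved


def simulate_gene_family(
    scenario: SimScenario,
    family_index: int,
    species_tree: SpeciesTree | None = None,
) -> SimTruth:
    """Simulate one gene family with full ground truth.

    One gene lineage enters the species-tree root; copies evolve by
    independent birth-death along every branch; trait-linked families may be
    forced-lost (all copies, branch midpoint) on each trait branch.  The
    returned gene tree contains exactly the surviving copies.  Reproducible
    from ``(scenario.seed, family_index)`` alone.
    """
    scenario.validate()
    stree = species_tree or scenario.resolved_species_tree()
    trait_nodes = resolve_trait_branches(stree, scenario.trait_loss_branches)
    rng = np.random.default_rng([_seed32(scenario.seed), int(family_index)])
    family = f"{scenario.family_prefix}{family_index:04d}"

    trait_linked = bool(rng.random() < scenario.frac_trait_linked)
    # Pre-draw forced-loss decisions in a fixed branch order so the stream
    # does not depend on which branches copies happen to reach.
    forced: dict[int, bool] = {}
    if trait_linked and scenario.p_forced_loss > 0:
        for key in sorted(trait_nodes, key=lambda k: _branch_id(trait_nodes[k])):
            forced[key] = bool(rng.random() < scenario.p_forced_loss)

    lam, mu = scenario.dup_rate, scenario.loss_rate
    total_rate = lam + mu
    events: list[SimEvent] = []
    forced_logged: set[int] = set()
    counter = 0

    def next_gene_label(species: str) -> str:
        nonlocal counter
        counter += 1
        return scenario.convention.format(
            GeneLeaf(gene_id=f"{family}_g{counter}", species_id=species)
        )

    def enter_branch(snode: TreeNode) -> TreeNode | None:
        length = snode.length if snode.length is not None else 1.0
        if id(snode) in forced and forced[id(snode)]:
            if id(snode) not in forced_logged:
                events.append(SimEvent(_branch_id(snode), FORCED_LOSS, length / 2.0))
                forced_logged.add(id(snode))
            return None
        return evolve_copy(snode, length, 0.0)

    def evolve_copy(snode: TreeNode, remaining: float, elapsed: float) -> TreeNode | None:
        """One copy on the branch above ``snode``; returns its surviving
        gene subtree (root length = time from this point to its first node)."""
        wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
        if wait >= remaining:
            sub = at_species_node(snode)
            if sub is not None:
                sub.length = (sub.length or 0.0) + remaining
            return sub
        when = elapsed + wait
        if rng.random() < (lam / total_rate if total_rate > 0 else 0.0):
            events.append(SimEvent(_branch_id(snode), DUP, when))
            left = evolve_copy(snode, remaining - wait, when)
            right = evolve_copy(snode, remaining - wait, when)
            survivors = [s for s in (left, right) if s is not None]
            if not survivors:
                return None
            if len(survivors) == 1:
                survivors[0].length = (survivors[0].length or 0.0) + wait
                return survivors[0]
            return TreeNode(length=wait, children=survivors)
        events.append(SimEvent(_branch_id(snode), LOSS, when))
        return None

    def at_species_node(snode: TreeNode) -> TreeNode | None:
        if snode.is_leaf():
            return TreeNode(name=next_gene_label(snode.name or ""), length=0.0)
        kids = [k for k in (enter_branch(c) for c in snode.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return TreeNode(length=0.0, children=kids)

    gene_root = at_species_node(stree.root)

    n_copies = {name: 0 for name in stree.leaf_names}
    if gene_root is not None:
        gene_root.length = None
        for node in gene_root.leaves():
            leaf = scenario.convention.parse(node.name or "")
            n_copies[leaf.species_id] += 1
    presence = {name: count > 0 for name, count in n_copies.items()}

    gene_tree = None
    if gene_root is not None:
        gene_tree = GeneTree(
            gene_root,
            rooted=True,
            family_name=family,
            convention=scenario.convention,
            validate=False,
        )
    return SimTruth(
        family_name=family,
        trait_linked=trait_linked,
        true_presence=presence,
        n_copies=n_copies,
        events=events,
        gene_tree=gene_tree,
    )


# ---------------------------------------------------------------------------
# detection noise and dataset orchestration
# ---------------------------------------------------------------------------


def _completeness_vector(
    c_s: float | Mapping[str, float], species: Sequence[str]
) -> np.ndarray:
    if isinstance(c_s, Mapping):
        missing = [s for s in species if s not in c_s]
        if missing:
            raise ValueError(f"detection completeness undefined for species {missing}")
        vec = np.array([float(c_s[s]) for s in species])
    else:
        vec = np.full(len(species), float(c_s))
    if ((vec < 0) | (vec > 1)).any():
        raise ValueError("detection completeness must be in [0, 1]")
    return vec


def apply_detection_noise(
    truths: Sequence[SimTruth],
    c_s: float | Mapping[str, float],
    seed: int,
    species: Sequence[str] | None = None,
) -> OccurrenceMatrix:
    """Thin true presence with per-species detection completeness.

    ``observed[f][s] = true_presence[f][s] AND Bernoulli(c_s[s])``.  Each
    observed-present cell carries provenance ``tree`` (the single simulated
    evidence source).
    """
    import pandas as pd

    if species is None:
        species = list(truths[0].true_presence) if truths else []
    truth = pd.DataFrame(
        [[t.true_presence[s] for s in species] for t in truths],
        index=[t.family_name for t in truths],
        columns=list(species),
        dtype=bool,
    )
    vec = _completeness_vector(c_s, species)
    rng = np.random.default_rng(_seed32(seed))
    detected = rng.random(truth.shape) < vec[None, :] if truth.size else truth.to_numpy()
    observed = truth & detected
    return OccurrenceMatrix(observed)


def simulate_dataset(
    scenario: SimScenario,
    out_dir: str | Path | None = None,
) -> tuple[list[SimTruth], list[GeneTree], OccurrenceMatrix, dict]:
    """Run a full scenario: families, gene trees, observed matrix, manifest.

    With ``out_dir`` the dataset is serialized (``species.nwk``,
    ``fam_*.nwk`` for families with surviving copies, ``truth.tsv``,
    ``events.tsv``, ``observed.tsv`` + provenance, ``manifest.json``);
    regenerating from the same scenario and seed is byte-identical.
    """
    import pandas as pd

    scenario.validate()
    stree = scenario.resolved_species_tree()
    truths = [
        simulate_gene_family(scenario, i, species_tree=stree)
        for i in range(scenario.n_families)
    ]
    noise_seed = (_seed32(scenario.seed) * 2654435761 + scenario.n_families + 1) % (2**31)
    matrix = apply_detection_noise(
        truths, scenario.detection_completeness, seed=noise_seed, species=stree.leaf_names
    )
    gene_trees = [t.gene_tree for t in truths if t.gene_tree is not None]
    manifest = scenario.to_manifest()
    manifest["n_families_with_survivors"] = len(gene_trees)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species.nwk").write_text(stree.to_newick() + "\n")
        for truth in truths:
            if truth.gene_tree is not None and truth.gene_tree.n_leaves >= 2:
                path = out / f"{truth.family_name}.nwk"
                path.write_text(truth.gene_tree.to_newick() + "\n")
        truth_rows = []
        for t in truths:
            row = {"family_name": t.family_name, "trait_linked": int(t.trait_linked)}
            row.update({s: int(t.true_presence[s]) for s in stree.leaf_names})
            truth_rows.append(row)
        pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
        event_rows = [
            {"family_name": t.family_name, "branch": e.branch, "event": e.event,
             "time": f"{e.time:.10g}"}
            for t in truths
            for e in t.events
        ]
        pd.DataFrame(
            event_rows, columns=["family_name", "branch", "event", "time"]
        ).to_csv(out / "events.tsv", sep="\t", index=False)
        write_occurrence_table(matrix, out / "observed.tsv")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return truths, gene_trees, matrix, manifest


def convergent_loss_scenario(
    seed: int,
    n_families: int = 500,
    n_taxa: int = 16,
    frac_trait_linked: float = 0.15,
    p_forced_loss: float = 1.0,
    detection_completeness: float | Mapping[str, float] = 1.0,
) -> tuple[SimScenario, set[str], set[str]]:
    """The canonical convergent-loss study setup on a simulated species tree.

    Picks the first two disjoint cherries (in postorder) of a Yule tree as
    the trait-loss branches, so a fraction of families is forced-lost in the
    four "carnivorous" focal species those cherries subtend; all remaining
    species form the noncarnivorous background.  Returns the scenario plus
    the focal and background species sets.
    """
    stree = simulate_species_tree(n_taxa, 1.0, seed)
    cherries: list[tuple[str, str]] = []
    taken: set[str] = set()
    for node in stree.root.postorder():
        if len(node.children) == 2 and all(c.is_leaf() for c in node.children):
            names = (node.children[0].name or "", node.children[1].name or "")
            if not taken & set(names):
                cherries.append(names)
                taken |= set(names)
        if len(cherries) == 2:
            break
    if len(cherries) < 2:  # pragma: no cover - a binary tree always has >= 2
        raise RuntimeError("species tree has fewer than two disjoint cherries")
    scenario = SimScenario(
        n_families=n_families,
        species_tree=stree,
        trait_loss_branches=tuple(cherries),
        p_forced_loss=p_forced_loss,
        frac_trait_linked=frac_trait_linked,
        detection_completeness=detection_completeness,
        seed=seed,
    )
    focal = set(taken)
    background = set(stree.leaf_names) - focal
    return scenario, focal, background


def sample_branch_copy_number(
    dup_rate: float, loss_rate: float, length: float, n_samples: int, seed: int
) -> np.ndarray:
    """Surviving copy counts of one entering copy after one branch of the
    given length — Monte-Carlo samples of the linear birth-death process,
    whose mean is ``exp((dup_rate - loss_rate) * length)``.

    Runs the ordinary family simulator on a two-leaf species tree whose two
    terminal branches both have the requested length; the two per-leaf counts
    of each family are independent draws, so ``ceil(n/2)`` families suffice.
    """
    stree = read_species_tree(f"(A:{length:.10g},B:{length:.10g});")
    scenario = SimScenario(
        n_families=(n_samples + 1) // 2,
        species_tree=stree,
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        trait_loss_branches=(),
        frac_trait_linked=0.0,
        seed=seed,
    )
    counts: list[int] = []
    for i in range(scenario.n_families):
        truth = simulate_gene_family(scenario, i, species_tree=stree)
        counts.extend([truth.n_copies["A"], truth.n_copies["B"]])
    return np.asarray(counts[:n_samples], dtype=int)
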