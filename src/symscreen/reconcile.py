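"""Duplication-loss reconciliation and species-tree-guided gene-tree rooting.

A rooted gene tree is reconciled against the species tree by the classical
LCA mapping: every gene-tree leaf maps to its species' leaf, and every
internal node maps to the last common ancestor of its children's images.  An
internal node is a *duplication* when it maps to the same species-tree node
as one of its children, otherwise a *speciation*.  Losses are counted per
gene-tree edge (u -> v) from the species-tree path length d between M(u) and
M(v):

    losses(u -> v) = d - 1   if u is a speciation
                   = d       if u is a duplication

The total cost is ``w_dup * duplications + w_loss * losses`` (unit weights by
default).  An unrooted gene tree is rooted by exhaustively re-rooting on
every edge and keeping the minimal-cost root; ties are reported and resolved
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .treeio import GeneTree, SpeciesTree, TreeNode, unroot

__all__ = [
    "Reconciliation",
    "RootingResult",
    "ReconciliationError",
    "lca_map",
    "label_events_and_count",
    "reconcile",
    "root_gene_tree",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


class ReconciliationError(ValueError):
    """Gene tree cannot be reconciled (e.g. a species missing from the tree)."""


@dataclass
class Reconciliation:
    """LCA mapping of a rooted gene tree onto the species tree.

    ``gene_root`` is the (possibly deterministically binarized) working copy
    of the gene tree that ``mapping`` and ``events`` are keyed on.
    """

    gene_tree: GeneTree
    species_tree: SpeciesTree
    gene_root: TreeNode
    mapping: dict[int, TreeNode]
    events: dict[int, str] = field(default_factory=dict)
    dup_count: int | None = None
    loss_count: int | None = None
    cost: float | None = None
    w_dup: float = 1.0
    w_loss: float = 1.0
    binarized: bool = False

    def map_of(self, node: TreeNode) -> TreeNode:
        return self.mapping[id(node)]

    def event_of(self, node: TreeNode) -> str:
        return self.events[id(node)]


# ---------------------------------------------------------------------------
# LCA mapping and event counting
# ---------------------------------------------------------------------------


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaf_names())


def _binarize(node: TreeNode) -> TreeNode:
    """Resolve polytomies deterministically (children sorted by smallest leaf
    label, combined left-deep with zero-length edges)."""
    if node.is_leaf():
        return TreeNode(node.name, node.length)
    kids = sorted((_binarize(c) for c in node.children), key=_min_leaf)
    while len(kids) > 2:
        a = kids.pop(0)
        b = kids.pop(0)
        kids.insert(0, TreeNode(length=0.0, children=[a, b]))
    return TreeNode(node.name, node.length, children=kids)


def _has_polytomy(root: TreeNode) -> bool:
    return any(len(n.children) > 2 for n in root.preorder())


def lca_map(gene_tree: GeneTree, species_tree: SpeciesTree) -> Reconciliation:
    """Compute the LCA mapping of a rooted gene tree onto the species tree.

    Non-binary gene-tree nodes are resolved deterministically first (the DL
    count is defined on binary trees); the result records ``binarized=True``
    when that happened.
    """
    if not gene_tree.rooted:
        raise ReconciliationError("LCA mapping needs a rooted gene tree; root it first")
    root = gene_tree.root
    binarized = _has_polytomy(root)
    if binarized:
        root = _binarize(root)
    mapping: dict[int, TreeNode] = {}
    for node in root.postorder():
        if node.is_leaf():
            leaf = gene_tree.convention.parse(node.name or "")
            if leaf.species_id not in species_tree:
                raise ReconciliationError(
                    f"gene leaf {node.name!r}: species {leaf.species_id!r} is not "
                    "in the species tree (should have been pruned at ingest)"
                )
            mapping[id(node)] = species_tree.leaf(leaf.species_id)
        else:
            image = mapping[id(node.children[0])]
            for child in node.children[1:]:
                image = species_tree.lca(image, mapping[id(child)])
            mapping[id(node)] = image
    return Reconciliation(
        gene_tree=gene_tree,
        species_tree=species_tree,
        gene_root=root,
        mapping=mapping,
        binarized=binarized,
    )


def label_events_and_count(
    rec: Reconciliation, w_dup: float = 1.0, w_loss: float = 1.0
) -> Reconciliation:
    """Fill in speciation/duplication labels, loss counts and the DL cost."""
    stree = rec.species_tree
    events: dict[int, str] = {}
    dups = 0
    for node in rec.gene_root.postorder():
        if node.is_leaf():
            continue
        image = rec.mapping[id(node)]
        if any(rec.mapping[id(child)] is image for child in node.children):
            events[id(node)] = DUPLICATION
            dups += 1
        else:
            events[id(node)] = SPECIATION
    losses = 0
    for node in rec.gene_root.preorder():
        if node.parent is None:
            continue
        d = stree.depth(rec.mapping[id(node)]) - stree.depth(rec.mapping[id(node.parent)])
        losses += d if events[id(node.parent)] == DUPLICATION else d - 1
    rec.events = events
    rec.dup_count = dups
    rec.loss_count = losses
    rec.w_dup = w_dup
    rec.w_loss = w_loss
    rec.cost = w_dup * dups + w_loss * losses
    return rec


def reconcile(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    w_dup: float = 1.0,
    w_loss: float = 1.0,
) -> Reconciliation:
    """LCA-map a rooted gene tree and count duplications, losses and cost."""
    return label_events_and_count(lca_map(gene_tree, species_tree), w_dup, w_loss)


# ---------------------------------------------------------------------------
# minimal-DL rooting
# ---------------------------------------------------------------------------


@dataclass
class RootingResult:
    """Outcome of exhaustive minimal-DL rooting of an unrooted gene tree.

    Edges are identified by the sorted leaf labels of the smaller side of the
    bipartition they induce (ties between equal-size sides broken
    lexicographically), so the cost table can be audited against any other
    implementation.
    """

    rooted_tree: GeneTree
    root_edge: tuple[str, ...]
    cost: float
    dup_count: int
    loss_count: int
    cost_table: dict[tuple[str, ...], float]
    tie_edges: list[tuple[str, ...]]
    reconciliation: Reconciliation


def edge_key(side_labels: set[str], all_labels: set[str]) -> tuple[str, ...]:
    """Canonical id of an unrooted-tree edge from one side of its bipartition."""
    other = all_labels - side_labels
    a, b = sorted(side_labels), sorted(other)
    if (len(a), a) <= (len(b), b):
        return tuple(a)
    return tuple(b)


def _orient(node: TreeNode, came_from: TreeNode | None) -> TreeNode:
    """Rebuild the subtree seen from ``node`` looking away from ``came_from``."""
    new = TreeNode(node.name)
    neighbors: list[tuple[TreeNode, float | None]] = [
        (child, child.length) for child in node.children
    ]
    if node.parent is not None:
        neighbors.append((node.parent, node.length))
    for neighbor, length in neighbors:
        if neighbor is came_from:
            continue
        sub = _orient(neighbor, node)
        sub.length = length
        new.add_child(sub)
    return new


def _rooted_at_edge(u: TreeNode, v: TreeNode) -> TreeNode:
    """Root the (unrooted) tree at the midpoint of the edge between u and v."""
    half = v.length / 2.0 if v.length is not None else None
    side_v = _orient(v, u)
    side_v.length = half
    side_u = _orient(u, v)
    side_u.length = half
    return TreeNode(children=[side_v, side_u])


def root_gene_tree(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    w_dup: float = 1.0,
    w_loss: float = 1.0,
) -> RootingResult:
    """Root an unrooted gene tree on its minimal duplication+loss edge.

    Every edge of the unrooted tree is tried as a root position and its DL
    cost computed; the full edge -> cost table and the set of minimal-cost
    ties are returned.  Ties are resolved deterministically: prefer the edge
    whose root maps closest to the species-tree root (smallest depth of
    M(root)), then the lexicographically smallest smaller-side leaf set.

    A rooted input is first unrooted so the search covers all edges.
    """
    if gene_tree.n_leaves < 3:
        raise ReconciliationError("rooting needs an unrooted tree with >= 3 leaves")
    root = gene_tree.root.copy() if not gene_tree.rooted else unroot(gene_tree.root)

    all_labels = set(root.leaf_names())
    edges: list[tuple[TreeNode, TreeNode]] = [
        (node, child) for node in root.preorder() for child in node.children
    ]

    cost_table: dict[tuple[str, ...], float] = {}
    candidates: dict[tuple[str, ...], tuple[GeneTree, Reconciliation]] = {}
    for u, v in edges:
        key = edge_key(set(v.leaf_names()), all_labels)
        rooted = GeneTree(
            _rooted_at_edge(u, v),
            rooted=True,
            family_name=gene_tree.family_name,
            convention=gene_tree.convention,
            validate=False,
        )
        rec = reconcile(rooted, species_tree, w_dup, w_loss)
        cost_table[key] = rec.cost  # type: ignore[assignment]
        candidates[key] = (rooted, rec)

    best = min(cost_table.values())
    ties = sorted(k for k, c in cost_table.items() if c == best)

    def tiebreak(key: tuple[str, ...]) -> tuple[int, tuple[str, ...]]:
        _, rec = candidates[key]
        root_depth = species_tree.depth(rec.map_of(rec.gene_root))
        return (root_depth, key)

    chosen = min(ties, key=tiebreak)
    rooted_tree, rec = candidates[chosen]
    return RootingResult(
        rooted_tree=rooted_tree,
        root_edge=chosen,
        cost=rec.cost,  # type: ignore[arg-type]
        dup_count=rec.dup_count,  # type: ignore[arg-type]
        loss_count=rec.loss_count,  # type: ignore[arg-type]
        cost_table=cost_table,
        tie_edges=ties,
        reconciliation=rec,
    )
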