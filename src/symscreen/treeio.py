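"""Tree and table I/O for the gene-loss screening pipeline.

Trees are exchanged as newick text (parsed with dendropy, so quoted labels,
internal-node labels and comments from external tree tools are tolerated) and
held in a deliberately small mutable node structure that the reconciliation,
rooting and simulation code can rearrange freely.

Gene-tree leaves pack a species id and a gene id into one newick label.  The
convention defaults to ``species|gene_id`` and is enforced at ingest: a single
unambiguous mapping from every gene to a species-tree leaf is what makes the
downstream presence/absence calls well defined across hundreds of
heterogeneously named sequence sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "GeneLeaf",
    "GeneTree",
    "LabelConvention",
    "DEFAULT_CONVENTION",
    "NewickError",
    "LabelError",
    "read_newick",
    "write_newick",
    "read_species_tree",
    "read_gene_tree",
    "parse_leaf_label",
    "format_leaf_label",
    "write_occurrence_table",
    "read_occurrence_table",
    "unroot",
]


class NewickError(ValueError):
    """Malformed newick text or a tree violating a structural invariant."""


class LabelError(ValueError):
    """A leaf label that does not follow the species/gene packing convention."""


# ---------------------------------------------------------------------------
# core tree structure
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a rooted tree: name, branch length above it, children.

    ``length`` is the length of the edge between this node and its parent
    (``None`` when absent, e.g. at the root).
    """

    __slots__ = ("name", "length", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        children: list["TreeNode"] | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        for child in children or ():
            self.add_child(child)

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def copy(self) -> "TreeNode":
        new = TreeNode(self.name, self.length)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or '(internal)'} n_children={len(self.children)}>"


# ---------------------------------------------------------------------------
# leaf-label convention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLeaf:
    """A gene-tree leaf: the gene id and the species the gene belongs to."""

    gene_id: str
    species_id: str


@dataclass(frozen=True)
class LabelConvention:
    """How a species id and a gene id are packed into one newick leaf label.

    The species id may not contain the separator; the split is taken at the
    first occurrence, so gene ids containing the separator round-trip.
    """

    separator: str = "|"

    def parse(self, label: str) -> GeneLeaf:
        species, sep, gene = label.partition(self.separator)
        if not sep or not species or not gene:
            raise LabelError(
                f"leaf label {label!r} does not match the "
                f"'<species>{self.separator}<gene_id>' convention"
            )
        return GeneLeaf(gene_id=gene, species_id=species)

    def format(self, leaf: GeneLeaf) -> str:
        if self.separator in leaf.species_id:
            raise LabelError(
                f"species id {leaf.species_id!r} contains the separator "
                f"{self.separator!r}"
            )
        return f"{leaf.species_id}{self.separator}{leaf.gene_id}"


DEFAULT_CONVENTION = LabelConvention()


def parse_leaf_label(label: str, convention: LabelConvention = DEFAULT_CONVENTION) -> GeneLeaf:
    """Split a packed leaf label into ``(species_id, gene_id)``."""
    return convention.parse(label)


def format_leaf_label(leaf: GeneLeaf, convention: LabelConvention = DEFAULT_CONVENTION) -> str:
    """Inverse of :func:`parse_leaf_label`."""
    return convention.format(leaf)


# ---------------------------------------------------------------------------
# domain trees
# ---------------------------------------------------------------------------


class SpeciesTree:
    """A rooted species tree over unique taxon ids.

    The reference frame for reconciliation: provides LCA queries, node depths
    and the tree-ordered species list used to lay out occurrence matrices.
    Polytomies are permitted (the LCA stays well defined); branch lengths, if
    present, must be non-negative.
    """

    def __init__(self, root: TreeNode, validate: bool = True) -> None:
        self.root = root
        self._index()
        if validate:
            self._validate()

    def _index(self) -> None:
        self._leaf_by_name: dict[str, TreeNode] = {}
        self._depth: dict[int, int] = {}
        for node in self.root.preorder():
            self._depth[id(node)] = (
                0 if node.parent is None else self._depth[id(node.parent)] + 1
            )
            if node.is_leaf():
                name = node.name or ""
                if name in self._leaf_by_name:
                    raise NewickError(f"duplicate species-tree leaf name {name!r}")
                self._leaf_by_name[name] = node

    def _validate(self) -> None:
        if len(self._leaf_by_name) < 2:
            raise NewickError("a species tree needs at least 2 leaves")
        if "" in self._leaf_by_name:
            raise NewickError("species-tree leaves must be named")
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise NewickError("negative branch length in species tree")

    # -- queries -----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        """Leaf names in tree (left-to-right postorder) order."""
        return self.root.leaf_names()

    def leaf(self, name: str) -> TreeNode:
        try:
            return self._leaf_by_name[name]
        except KeyError:
            raise KeyError(f"species {name!r} is not a leaf of the species tree") from None

    def __contains__(self, name: str) -> bool:
        return name in self._leaf_by_name

    def depth(self, node: TreeNode) -> int:
        return self._depth[id(node)]

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        """Last common ancestor of two nodes (depth-lifting walk)."""
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = a.parent  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = b.parent  # type: ignore[assignment]
            db -= 1
        while a is not b:
            a = a.parent  # type: ignore[assignment]
            b = b.parent  # type: ignore[assignment]
        return a

    def mrca(self, names: Iterable[str]) -> TreeNode:
        nodes = [self.leaf(n) for n in names]
        if not nodes:
            raise ValueError("mrca() of an empty set of names")
        node = nodes[0]
        for other in nodes[1:]:
            node = self.lca(node, other)
        return node

    def clade_leaves(self, node: TreeNode) -> list[str]:
        return node.leaf_names()

    def to_newick(self) -> str:
        return write_newick(self.root)


class GeneTree:
    """A per-family gene tree whose leaves carry ``(species, gene id)``.

    May be rooted or unrooted; an unrooted tree is stored with a basal
    multifurcation of degree >= 3.  ``validate=False`` relaxes the >= 2 leaf
    requirement so simulated families that went extinct (or survive as a
    single copy) can still be carried with their truth records.
    """

    def __init__(
        self,
        root: TreeNode,
        rooted: bool = True,
        family_name: str = "",
        convention: LabelConvention = DEFAULT_CONVENTION,
        validate: bool = True,
    ) -> None:
        self.root = root
        self.rooted = rooted
        self.family_name = family_name
        self.convention = convention
        if validate:
            self._validate()

    def _validate(self) -> None:
        leaves = self.root.leaves()
        if len(leaves) < 2:
            raise NewickError("a gene tree needs at least 2 leaves")
        if not self.rooted and len(self.root.children) < 3:
            raise NewickError("an unrooted gene tree must have a basal multifurcation")
        seen: set[str] = set()
        for node in leaves:
            leaf = self.convention.parse(node.name or "")
            if leaf.gene_id in seen:
                raise NewickError(f"duplicate gene id {leaf.gene_id!r} in gene tree")
            seen.add(leaf.gene_id)

    # -- queries -----------------------------------------------------------

    @property
    def leaves(self) -> list[GeneLeaf]:
        return [self.convention.parse(n.name or "") for n in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    @property
    def species(self) -> set[str]:
        return {leaf.species_id for leaf in self.leaves}

    @property
    def gene_ids(self) -> list[str]:
        return [leaf.gene_id for leaf in self.leaves]

    def leaf_node(self, gene_id: str) -> TreeNode:
        for node in self.root.leaves():
            if self.convention.parse(node.name or "").gene_id == gene_id:
                return node
        raise KeyError(f"gene id {gene_id!r} is not a leaf of this tree")

    def prune_to_species(self, known_species: Iterable[str]) -> "GeneTree":
        """Drop leaves whose species is unknown; mirrors contamination removal.

        Returns a new tree; removed leaves are reported with a logged warning.
        """
        known = set(known_species)
        root = self.root.copy()
        removed = [
            n.name
            for n in root.leaves()
            if self.convention.parse(n.name or "").species_id not in known
        ]
        if removed:
            logger.warning(
                "gene tree %s: pruning %d leaves with species absent from the "
                "species tree: %s",
                self.family_name or "(unnamed)",
                len(removed),
                ", ".join(str(r) for r in removed[:10]),
            )
            root = _prune_leaves(root, set(removed))
            if root is None:
                raise NewickError(
                    f"gene tree {self.family_name!r}: no leaf maps to the species tree"
                )
        return GeneTree(
            root,
            rooted=self.rooted,
            family_name=self.family_name,
            convention=self.convention,
            validate=False,
        )

    def to_newick(self) -> str:
        return write_newick(self.root)


def _prune_leaves(root: TreeNode, drop_names: set[str]) -> TreeNode | None:
    """Remove named leaves and suppress the resulting unifurcations."""

    def rebuild(node: TreeNode) -> TreeNode | None:
        if node.is_leaf():
            if node.name in drop_names:
                return None
            return TreeNode(node.name, node.length)
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            if node.length is not None or only.length is not None:
                only.length = (node.length or 0.0) + (only.length or 0.0)
            return only
        new = TreeNode(node.name, node.length)
        for k in kids:
            new.add_child(k)
        return new

    return rebuild(root)


def unroot(root: TreeNode) -> TreeNode:
    """Collapse a degree-2 root into a basal multifurcation (degree >= 3).

    The two root-adjacent edge lengths are merged onto one child so total
    path lengths are preserved.
    """
    if len(root.children) != 2:
        return root.copy()
    new = root.copy()
    a, b = new.children
    donor = a if not a.is_leaf() else b
    other = b if donor is a else a
    if donor.is_leaf():
        raise NewickError("cannot unroot a 2-leaf tree")
    merged = TreeNode(new.name, new.length)
    for grandchild in donor.children:
        merged.add_child(grandchild)
    if other.length is not None or donor.length is not None:
        other.length = (other.length or 0.0) + (donor.length or 0.0)
    merged.add_child(other)
    return merged


# ---------------------------------------------------------------------------
# newick reading / writing
# ---------------------------------------------------------------------------


def read_newick(text: str, rootedness_hint: str = "auto") -> tuple[TreeNode, bool]:
    """Parse newick text into a :class:`TreeNode` plus a rooted flag.

    ``rootedness_hint``: ``auto`` classifies a basal node of degree >= 3 as
    unrooted; ``rooted``/``unrooted`` force the flag.  Quoted labels and
    internal-node labels are accepted; comments (including NHX) are ignored.
    """
    if rootedness_hint not in ("auto", "rooted", "unrooted"):
        raise ValueError(f"unknown rootedness hint {rootedness_hint!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse newick: {exc}") from exc

    def convert(dnode: "dendropy.Node") -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            name = dnode.label
        node = TreeNode(name=name, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf():
        raise NewickError("newick describes a single leaf, not a tree")
    if rootedness_hint == "auto":
        rooted = len(root.children) == 2
    else:
        rooted = rootedness_hint == "rooted"
    return root, rooted


_NEEDS_QUOTING = set("()[]{}:;,'\" \t\n")


def _format_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_node(node: TreeNode) -> str:
    if node.is_leaf():
        out = _format_label(node.name or "")
    else:
        out = "(" + ",".join(_format_node(c) for c in node.children) + ")"
        if node.name:
            out += _format_label(node.name)
    if node.length is not None:
        out += f":{node.length:.10g}"
    return out


def write_newick(root: TreeNode) -> str:
    """Serialize a tree to a newick string (round-trips through the reader)."""
    return _format_node(root) + ";"


def read_species_tree(source: str | Path) -> SpeciesTree:
    """Read a rooted species tree from newick text or a file path."""
    text = _slurp(source)
    root, _ = read_newick(text, rootedness_hint="rooted")
    return SpeciesTree(root)


def read_gene_tree(
    source: str | Path,
    family_name: str = "",
    convention: LabelConvention = DEFAULT_CONVENTION,
    rootedness_hint: str = "auto",
    species_tree: SpeciesTree | None = None,
) -> GeneTree:
    """Read a gene tree; optionally prune leaves unknown to the species tree."""
    text = _slurp(source)
    root, rooted = read_newick(text, rootedness_hint=rootedness_hint)
    tree = GeneTree(root, rooted=rooted, family_name=family_name, convention=convention)
    if species_tree is not None:
        tree = tree.prune_to_species(species_tree.leaf_names)
    return tree


def _slurp(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "(" in text or ";" in text:
        return text
    path = Path(text)
    if path.exists():
        return path.read_text()
    raise NewickError(f"{source!r} is neither newick text nor an existing file")


# ---------------------------------------------------------------------------
# occurrence-matrix tables
# ---------------------------------------------------------------------------


def _provenance_path(path: Path) -> Path:
    return path.with_name(path.stem + ".provenance" + path.suffix)


def write_occurrence_table(
    matrix: "OccurrenceMatrix",
    path: str | Path,
    provenance_path: str | Path | None = None,
) -> Path:
    """Write a gene x species occurrence matrix as TSV (cells 1/0).

    A companion table with per-cell evidence provenance (``tree`` / ``graph``
    / ``both`` / ``none``) is written next to it.  Round-trips exactly through
    :func:`read_occurrence_table`.
    """
    path = Path(path)
    prov_path = Path(provenance_path) if provenance_path else _provenance_path(path)
    matrix.presence.astype(int).to_csv(path, sep="\t", index_label="gene_name")
    matrix.provenance.to_csv(prov_path, sep="\t", index_label="gene_name")
    return path


def read_occurrence_table(
    path: str | Path,
    provenance_path: str | Path | None = None,
) -> "OccurrenceMatrix":
    """Read a TSV occurrence matrix (and its provenance companion if present)."""
    from .occurrence import OccurrenceMatrix  # local import: avoids a cycle

    path = Path(path)
    presence = pd.read_csv(path, sep="\t", index_col="gene_name").astype(bool)
    presence.index = presence.index.astype(str)
    prov_path = Path(provenance_path) if provenance_path else _provenance_path(path)
    provenance = None
    if prov_path.exists():
        provenance = pd.read_csv(prov_path, sep="\t", index_col="gene_name", dtype=str)
        provenance.index = provenance.index.astype(str)
    return OccurrenceMatrix(presence, provenance)
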