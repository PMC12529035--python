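"""Orthogroup delimitation from rooted gene trees and from cluster tables.

A named gene (e.g. *CCaMK*) is located in a rooted gene tree through its
anchor gene ids — the known orthologs in reference species.  The orthogroup
is the smallest clade that contains the anchor and has the outgroup species
(*Amborella trichopoda* by default, the basal angiosperm) as its basalmost
lineage, operationalized as: one child subtree of the clade root consists
exclusively of outgroup-species leaves.  Every leaf of that clade is a
member, lineage-specific duplicates included.  When no outgroup-anchored
clade exists (common for transcriptome-derived trees missing the outgroup),
the extraction falls back to the largest clade around the anchor that avoids
other genes' anchors and flags ``outgroup_found=False`` — presence is still
scored rather than silently biasing toward absence.

Graph-based clusters (e.g. a SonicParanoid orthogroup table) are ingested as
a second, independent evidence source: every cluster containing an anchor of
a gene yields one call for that gene, so clusters shared by two genes and
genes split across clusters are both representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .treeio import GeneTree, TreeNode

__all__ = [
    "AnchorSet",
    "OrthogroupCall",
    "DEFAULT_OUTGROUP",
    "extract_orthogroup",
    "ingest_graph_clusters",
    "species_presence",
    "read_anchor_table",
    "read_cluster_table",
    "validate_cluster_table",
]

DEFAULT_OUTGROUP = "Amborella_trichopoda"


@dataclass
class AnchorSet:
    """Named genes mapped to their anchor gene ids in reference species."""

    anchors: dict[str, list[str]]
    reference_species: list[str] = field(default_factory=list)
    outgroup_species: str = DEFAULT_OUTGROUP

    def __post_init__(self) -> None:
        for gene_name, ids in self.anchors.items():
            if not ids:
                raise ValueError(f"gene {gene_name!r} has no anchor ids")

    @property
    def gene_names(self) -> list[str]:
        return list(self.anchors)

    def anchors_of_others(self, gene_name: str) -> set[str]:
        return {
            aid
            for other, ids in self.anchors.items()
            if other != gene_name
            for aid in ids
        }


@dataclass
class OrthogroupCall:
    """One orthogroup membership call for a named gene from one evidence source."""

    gene_name: str
    source: str  # "tree" or "graph"
    member_gene_ids: list[str]
    member_species: set[str]
    subtree_root: TreeNode | None = None
    outgroup_found: bool | None = None
    cluster_id: str | None = None


# ---------------------------------------------------------------------------
# tree-based extraction
# ---------------------------------------------------------------------------


def _is_all_outgroup(node: TreeNode, tree: GeneTree, outgroup_species: str) -> bool:
    return all(
        tree.convention.parse(leaf.name or "").species_id == outgroup_species
        for leaf in node.leaves()
    )


def _clade_for_anchor(
    tree: GeneTree,
    anchor_node: TreeNode,
    outgroup_species: str,
    exclude_anchors: set[str],
) -> tuple[TreeNode, bool]:
    """Smallest outgroup-anchored clade above the anchor, or the fallback."""
    node = anchor_node
    while node is not None:
        if not node.is_leaf():
            for child in node.children:
                if _is_all_outgroup(child, tree, outgroup_species):
                    return node, True
        node = node.parent
    # Fallback: highest ancestor whose clade avoids other genes' anchors.
    node = anchor_node
    best = anchor_node
    while node is not None:
        gene_ids = {
            tree.convention.parse(leaf.name or "").gene_id for leaf in node.leaves()
        }
        if gene_ids & exclude_anchors:
            break
        best = node
        node = node.parent
    return best, False


def extract_orthogroup(
    rooted_gtree: GeneTree,
    anchors: Sequence[str],
    outgroup_species: str = DEFAULT_OUTGROUP,
    gene_name: str = "",
    exclude_anchors: Iterable[str] = (),
) -> OrthogroupCall | None:
    """Extract the orthogroup clade containing the anchor gene(s).

    Returns ``None`` when no anchor id occurs among the tree's leaves — the
    gene is simply undetected by this evidence source, not an error.  With
    several anchors present, the union of their clades is taken.  Anchor ids
    are matched by exact string comparison against parsed gene ids.
    """
    if not rooted_gtree.rooted:
        raise ValueError("orthogroup extraction needs a rooted gene tree")
    anchor_ids = set(anchors)
    exclude = set(exclude_anchors) - anchor_ids
    anchor_nodes = [
        node
        for node in rooted_gtree.root.leaves()
        if rooted_gtree.convention.parse(node.name or "").gene_id in anchor_ids
    ]
    if not anchor_nodes:
        return None

    member_nodes: dict[int, TreeNode] = {}
    subtree_roots: list[TreeNode] = []
    outgroup_found = False
    for anchor_node in anchor_nodes:
        clade, found = _clade_for_anchor(
            rooted_gtree, anchor_node, outgroup_species, exclude
        )
        outgroup_found = outgroup_found or found
        subtree_roots.append(clade)
        for leaf in clade.leaves():
            member_nodes[id(leaf)] = leaf

    leaves = [member_nodes[key] for key in member_nodes]
    parsed = [rooted_gtree.convention.parse(n.name or "") for n in leaves]
    return OrthogroupCall(
        gene_name=gene_name,
        source="tree",
        member_gene_ids=sorted(p.gene_id for p in parsed),
        member_species={p.species_id for p in parsed},
        subtree_root=subtree_roots[0] if len(subtree_roots) == 1 else None,
        outgroup_found=outgroup_found,
    )


# ---------------------------------------------------------------------------
# graph-based clusters
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = ("orthogroup_id", "gene_id", "species_id")


def validate_cluster_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (orthogroup_id, gene_id, species_id) table invariants."""
    missing = [c for c in CLUSTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cluster table is missing columns {missing}")
    per_gene = table.groupby("gene_id")["orthogroup_id"].nunique()
    conflicted = per_gene[per_gene > 1]
    if len(conflicted):
        raise ValueError(
            "gene ids assigned to more than one orthogroup: "
            + ", ".join(conflicted.index[:5])
        )
    return table


def ingest_graph_clusters(
    table: pd.DataFrame, anchors: AnchorSet
) -> list[OrthogroupCall]:
    """Turn a graph-based cluster table into per-gene orthogroup calls.

    Every cluster containing at least one anchor id of a gene yields one
    call (source ``graph``).  One cluster holding anchors of two genes gives
    both genes a call with identical membership; one gene split across
    clusters gives multiple calls whose union is taken downstream.
    """
    validate_cluster_table(table)
    cluster_of = dict(zip(table["gene_id"], table["orthogroup_id"]))
    calls: list[OrthogroupCall] = []
    grouped = dict(tuple(table.groupby("orthogroup_id")))
    for gene_name, anchor_ids in anchors.anchors.items():
        hit_clusters = sorted(
            {cluster_of[a] for a in anchor_ids if a in cluster_of}
        )
        for cid in hit_clusters:
            members = grouped[cid]
            calls.append(
                OrthogroupCall(
                    gene_name=gene_name,
                    source="graph",
                    member_gene_ids=sorted(members["gene_id"]),
                    member_species=set(members["species_id"]),
                    cluster_id=str(cid),
                )
            )
    return calls


def species_presence(
    call: OrthogroupCall | None, all_species: Sequence[str]
) -> pd.Series:
    """Boolean presence vector over ``all_species`` for one call."""
    present = call.member_species if call is not None else set()
    return pd.Series(
        [sp in present for sp in all_species], index=list(all_species), dtype=bool
    )


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------


def read_anchor_table(
    path: str | Path, outgroup_species: str = DEFAULT_OUTGROUP
) -> AnchorSet:
    """Read a TSV with columns gene_name, anchor_id, reference_species."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_name", "anchor_id"}
    if not required <= set(table.columns):
        raise ValueError("anchor table needs columns gene_name and anchor_id")
    anchors: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        anchors.setdefault(row["gene_name"], []).append(row["anchor_id"])
    reference = (
        sorted(set(table["reference_species"].dropna()))
        if "reference_species" in table.columns
        else []
    )
    return AnchorSet(anchors, reference_species=reference, outgroup_species=outgroup_species)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a graph-based orthogroup cluster table (TSV)."""
    return validate_cluster_table(pd.read_csv(path, sep="\t", dtype=str))
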