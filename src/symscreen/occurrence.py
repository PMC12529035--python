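"""Consensus presence/absence matrices and retention statistics.

A gene is scored *present* in a species if either evidence source — the
tree-based orthogroup extraction or the graph-based cluster table — recovers
at least one ortholog there; the per-cell provenance records which source(s)
contributed (``tree`` / ``graph`` / ``both`` / ``none``).  Retention of a
gene set in a species is simply the fraction of genes present; its
complement is the loss rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "RetentionRate",
    "consensus_presence",
    "retention_rate",
    "summarize_by_group",
]

PROVENANCE_VALUES = ("tree", "graph", "both", "none")


class OccurrenceMatrix:
    """Genes (rows) x species (columns) boolean matrix with evidence provenance.

    Invariant: ``provenance == "none"`` exactly where the cell is absent.
    Row order follows the anchor/gene list it was built from; column order is
    the species-tree order handed in by the caller.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        provenance: pd.DataFrame | None = None,
        species_meta: pd.DataFrame | None = None,
        validate: bool = True,
    ) -> None:
        self.presence = presence.astype(bool)
        if provenance is None:
            provenance = pd.DataFrame(
                np.where(self.presence.to_numpy(), "tree", "none"),
                index=self.presence.index,
                columns=self.presence.columns,
            )
        self.provenance = provenance
        self.species_meta = species_meta
        if validate:
            self._validate()

    def _validate(self) -> None:
        if not self.presence.index.equals(self.provenance.index) or not (
            self.presence.columns.equals(self.provenance.columns)
        ):
            raise ValueError("presence and provenance must share row/column labels")
        prov = self.provenance.to_numpy()
        if self.presence.size:
            bad = ~np.isin(prov, PROVENANCE_VALUES)
            if bad.any():
                raise ValueError(f"invalid provenance values: {set(prov[bad])}")
            if ((prov == "none") != ~self.presence.to_numpy()).any():
                raise ValueError(
                    "provenance 'none' must coincide exactly with absent cells"
                )

    # -- queries -----------------------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def equals(self, other: "OccurrenceMatrix") -> bool:
        return self.presence.equals(other.presence) and self.provenance.equals(
            other.provenance
        )

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"<OccurrenceMatrix {g} genes x {s} species>"


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------


def _presence_from_calls(
    calls: Iterable,
    gene_names: Sequence[str],
    all_species: Sequence[str],
) -> pd.DataFrame:
    frame = pd.DataFrame(False, index=list(gene_names), columns=list(all_species))
    known_species = set(all_species)
    known_genes = set(gene_names)
    for call in calls:
        if call is None:
            continue
        if call.gene_name not in known_genes:
            raise ValueError(f"call references unknown gene name {call.gene_name!r}")
        unknown = set(call.member_species) - known_species
        if unknown:
            raise ValueError(
                f"call for {call.gene_name!r} references unknown species {sorted(unknown)}"
            )
        for sp in call.member_species:
            frame.loc[call.gene_name, sp] = True
    return frame


def consensus_presence(
    tree_calls: Iterable,
    graph_calls: Iterable,
    all_species: Sequence[str],
    gene_names: Sequence[str],
    species_meta: pd.DataFrame | None = None,
) -> OccurrenceMatrix:
    """Union the two evidence sources into one occurrence matrix.

    A gene is present in a species if *either* the tree-based or the
    graph-based evidence places an ortholog there; multiple calls for one
    gene (split orthogroups, multiple anchors) union naturally.
    """
    tree_p = _presence_from_calls(tree_calls, gene_names, all_species)
    graph_p = _presence_from_calls(graph_calls, gene_names, all_species)
    presence = tree_p | graph_p
    t, g = tree_p.to_numpy(), graph_p.to_numpy()
    prov = np.where(
        t & g, "both", np.where(t, "tree", np.where(g, "graph", "none"))
    )
    provenance = pd.DataFrame(prov, index=presence.index, columns=presence.columns)
    return OccurrenceMatrix(presence, provenance, species_meta=species_meta)


# ---------------------------------------------------------------------------
# retention statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionRate:
    """Present / total counts for one species with derived rates."""

    species: str
    present: int
    total: int

    @property
    def retention(self) -> float:
        return self.present / self.total

    @property
    def loss(self) -> float:
        return 1.0 - self.retention


def retention_rate(
    matrix: OccurrenceMatrix,
    species_id: str,
    gene_subset: Sequence[str] | None = None,
) -> RetentionRate:
    """Fraction of the gene set present in one species (k present of n)."""
    if species_id not in matrix.presence.columns:
        raise KeyError(f"species {species_id!r} is not a column of the matrix")
    genes = list(gene_subset) if gene_subset is not None else matrix.gene_names
    if not genes:
        raise ValueError("gene_subset must not be empty")
    missing = set(genes) - set(matrix.gene_names)
    if missing:
        raise KeyError(f"gene_subset contains unknown genes: {sorted(missing)}")
    column = matrix.presence.loc[genes, species_id]
    return RetentionRate(species=species_id, present=int(column.sum()), total=len(genes))


def summarize_by_group(
    matrix: OccurrenceMatrix,
    species_groups: Mapping[str, Sequence[str]],
    gene_subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species retention plus per-group n / mean / min-max range.

    Groups must be disjoint, non-empty subsets of the matrix columns.
    """
    seen: set[str] = set()
    for name, members in species_groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"species group {name!r} is empty")
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"species groups overlap on {sorted(overlap)}")
        seen |= set(members)
    per_species_rows = []
    group_rows = []
    for name, members in species_groups.items():
        rates = [retention_rate(matrix, sp, gene_subset) for sp in members]
        for r in rates:
            per_species_rows.append(
                {
                    "group": name,
                    "species": r.species,
                    "present": r.present,
                    "total": r.total,
                    "retention": r.retention,
                }
            )
        values = [r.retention for r in rates]
        group_rows.append(
            {
                "group": name,
                "n_species": len(values),
                "mean": float(np.mean(values)),
                "min": float(np.min(values)),
                "max": float(np.max(values)),
            }
        )
    return pd.DataFrame(per_species_rows), pd.DataFrame(group_rows)
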