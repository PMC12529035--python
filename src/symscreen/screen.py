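"""Genome-wide convergent-loss screen.

Given an orthogroup x species occurrence matrix, find the orthogroups that
are absent in *every* focal species (the carnivorous lineages) while present
in *every* background species (the noncarnivorous relatives).  The screen
reports the three counts it is built from — the universe size, the
background-present set and the focal-absent set — plus the intersection
(the hits), the overlap with a target gene list, and an optional exact
hypergeometric enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import pandas as pd

from .occurrence import OccurrenceMatrix

__all__ = [
    "ScreenSpec",
    "ScreenResult",
    "convergent_loss_screen",
    "overlap_with_target",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
]


@dataclass
class ScreenSpec:
    """Focal (all-absent) and background (all-present) species sets.

    ``focal_groups`` optionally splits the focal species into independent
    lineages that must *each* be all-absent; by default the focal species
    are pooled into a single all-absent condition.
    """

    focal_species: set[str]
    background_species: set[str]
    focal_groups: list[set[str]] | None = None

    def __post_init__(self) -> None:
        self.focal_species = set(self.focal_species)
        self.background_species = set(self.background_species)
        if not self.focal_species or not self.background_species:
            raise ValueError("focal and background species sets must be non-empty")
        overlap = self.focal_species & self.background_species
        if overlap:
            raise ValueError(f"focal and background overlap on {sorted(overlap)}")
        if self.focal_groups is not None:
            pooled = set().union(*self.focal_groups) if self.focal_groups else set()
            if pooled != self.focal_species:
                raise ValueError("focal_groups must cover exactly focal_species")


@dataclass
class ScreenResult:
    """Counts and hit list of one convergent-loss screen."""

    n_universe: int
    n_background_present: int
    n_focal_absent: int
    hits: list[str]
    n_masked_excluded: int = 0
    spec: ScreenSpec | None = None

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _presence_frame(matrix: OccurrenceMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, OccurrenceMatrix):
        return matrix.presence
    return matrix.astype(bool)


def convergent_loss_screen(
    matrix: OccurrenceMatrix | pd.DataFrame,
    spec: ScreenSpec,
    mask: pd.DataFrame | None = None,
) -> ScreenResult:
    """Orthogroups absent in all focal and present in all background species.

    The universe is the set of matrix rows; rows with any masked
    (missing-data) cell among the spec's species are excluded from the
    universe and counted separately.  Undetected cells count as absent.
    """
    presence = _presence_frame(matrix)
    missing = (spec.focal_species | spec.background_species) - set(presence.columns)
    if missing:
        raise KeyError(f"species missing from the matrix: {sorted(missing)}")

    n_masked = 0
    if mask is not None:
        used = sorted(spec.focal_species | spec.background_species)
        excluded = mask.reindex(
            index=presence.index, columns=used, fill_value=False
        ).any(axis=1)
        n_masked = int(excluded.sum())
        presence = presence.loc[~excluded]

    background = sorted(spec.background_species)
    background_present = presence[background].all(axis=1)
    groups = spec.focal_groups or [spec.focal_species]
    focal_absent = pd.Series(True, index=presence.index)
    for group in groups:
        focal_absent &= ~presence[sorted(group)].any(axis=1)

    hits = sorted(presence.index[background_present & focal_absent])
    return ScreenResult(
        n_universe=len(presence),
        n_background_present=int(background_present.sum()),
        n_focal_absent=int(focal_absent.sum()),
        hits=hits,
        n_masked_excluded=n_masked,
        spec=spec,
    )


def overlap_with_target(
    result: ScreenResult, target_ids: Iterable[str]
) -> tuple[int, list[str]]:
    """How many screen hits fall in a target list (e.g. known symbiosis genes)."""
    targets = set(target_ids)
    ids = sorted(set(result.hits) & targets)
    return len(ids), ids


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p-value, P(X >= k), X ~ Hypergeom(N, K, n).

    Exact rational tail summation of C(K,i) C(N-K,n-i) / C(N,n): drawing n
    orthogroups from a universe of N containing K targets, the chance of at
    least the observed k targets among the draws.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(tail, total))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (for multi-target-list screens)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
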