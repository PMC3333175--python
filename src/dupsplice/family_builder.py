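"""Paralog-pair qualification and single-linkage gene-family construction.

A paralog pair qualifies at a percent-identity criterion when at least one
of its two directional identities is strictly larger than the criterion;
qualified pairs are then clustered single-linkage ("at least one gene in
common") into gene families — i.e. families are the connected components of
the qualified-pair graph.  Sweeping the criterion from high to low moves the
analysis from recent duplications toward increasingly ancient ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_tables import ParalogPair, RunConfig, _bin_label

__all__ = [
    "FamilyPartition",
    "qualify_pairs",
    "build_families",
    "sweep_partitions",
    "bin_family_size",
    "membership_table",
]


@dataclass
class FamilyPartition:
    """Disjoint partition of the gene universe at one identity criterion.

    ``families`` maps family_id (the lexicographically smallest member) to
    its member set; every family has at least two members.  All other genes
    are ``singletons``.
    """

    criterion: float
    families: dict[str, frozenset[str]]
    singletons: frozenset[str]
    _size_of: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for fid, members in self.families.items():
            if len(members) < 2:
                raise ValueError(f"family {fid} has fewer than 2 members")
            if fid != min(members):
                raise ValueError(f"family id {fid} is not its smallest member")
            for g in members:
                self._size_of[g] = len(members)
        for g in self.singletons:
            if g in self._size_of:
                raise ValueError(f"gene {g} is both singleton and family member")
            self._size_of[g] = 1

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self._size_of)

    def duplicates(self) -> frozenset[str]:
        """All genes belonging to some family at this criterion."""
        return frozenset(g for fam in self.families.values() for g in fam)

    def family_size(self, gene_id: str) -> int:
        """Observed family size of a gene (1 for singletons)."""
        return self._size_of[gene_id]


def qualify_pairs(pairs: Iterable[ParalogPair], criterion: float) -> set[tuple[str, str]]:
    """Pairs whose maximum directional identity strictly exceeds ``criterion``.

    Strict ">" — a pair whose best identity equals the criterion does not
    qualify.  Returns canonical (smaller-id, larger-id) tuples.
    """
    if not (0.0 < criterion < 100.0):
        raise ValueError(f"criterion {criterion} outside (0,100)")
    return {p.key for p in pairs if p.max_identity > criterion}


def build_families(
    qualified: Iterable[tuple[str, str]], universe: Iterable[str], criterion: float = float("nan")
) -> FamilyPartition:
    """Single-linkage clustering: connected components of the qualified graph.

    Components of size ≥ 2 become families (id = smallest member); all
    degree-zero genes are singletons.  Deterministic regardless of input
    order.
    """
    universe = frozenset(universe)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for a, b in qualified:
        for g in (a, b):
            if g not in universe:
                raise ValueError(f"qualified pair references gene outside universe: {g}")
        graph.add_edge(a, b)
    families: dict[str, frozenset[str]] = {}
    singletons: set[str] = set()
    for comp in nx.connected_components(graph):
        if len(comp) >= 2:
            families[min(comp)] = frozenset(comp)
        else:
            singletons.update(comp)
    return FamilyPartition(
        criterion=criterion, families=families, singletons=frozenset(singletons)
    )


def sweep_partitions(
    pairs: Iterable[ParalogPair],
    universe: Iterable[str],
    config: RunConfig,
) -> dict[float, FamilyPartition]:
    """One :class:`FamilyPartition` per configured identity criterion.

    Because qualification is monotone in the criterion, the duplicate set at
    a higher criterion nests inside the duplicate set at a lower one, and
    each low-criterion family is a union of high-criterion families plus
    singletons.
    """
    pairs = list(pairs)
    universe = frozenset(universe)
    return {
        crit: build_families(qualify_pairs(pairs, crit), universe, crit)
        for crit in config.identity_criteria
    }


def bin_family_size(size: int, config: RunConfig) -> str:
    """Map an observed family size to its stratum label (e.g. "2-4", "8+")."""
    if size < 1:
        raise ValueError(f"family size must be >= 1, got {size}")
    for lo, hi in config.family_size_bins:
        if size >= lo and (hi is None or size <= hi):
            return _bin_label(lo, hi)
    raise AssertionError("bins do not cover all positive integers")


def membership_table(
    partitions: Mapping[float, FamilyPartition], config: RunConfig
) -> pd.DataFrame:
    """Long-format per-criterion membership: gene, family id, size, size bin."""
    rows = []
    for crit in sorted(partitions):
        part = partitions[crit]
        for fid in sorted(part.families):
            for g in sorted(part.families[fid]):
                size = len(part.families[fid])
                rows.append((g, crit, fid, size, bin_family_size(size, config)))
        for g in sorted(part.singletons):
            rows.append((g, crit, "", 1, bin_family_size(1, config)))
    return pd.DataFrame(
        rows, columns=["gene_id", "criterion", "family_id", "family_size", "size_bin"]
    )
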