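"""AS status per gene and the four-group labels per gene per criterion.

A gene "has AS" when it carries more than one counted peptide (known
peptides in the main analysis).  AS status is a property of the gene and
does not change with the identity criterion; only the family context does.
Families where every member has AS are A_F, families where none does are
N_F, mixed families are MIXED_F, and singletons split into A_S / N_S.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .family_builder import FamilyPartition
from .io_tables import GeneRecord

__all__ = [
    "Group",
    "GroupAssignment",
    "classify_as",
    "as_status_map",
    "classify_groups",
    "group_table",
    "FOUR_GROUPS",
]


class Group(str, Enum):
    A_F = "A_F"        # family, all members AS
    N_F = "N_F"        # family, no member AS
    MIXED_F = "MIXED_F"  # family with both AS and no-AS members
    A_S = "A_S"        # AS singleton
    N_S = "N_S"        # no-AS singleton


#: the four groups compared for Ka/Ks, length, domains and GO (MIXED_F excluded)
FOUR_GROUPS = (Group.A_F, Group.N_F, Group.A_S, Group.N_S)


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    criterion: float
    as_status: bool
    group: Group


def classify_as(gene: GeneRecord, mode: str = "known_only") -> bool:
    """True iff the gene has more than one counted peptide under ``mode``."""
    count = gene.counted_peptides(mode)
    if count < 1:
        raise ValueError(
            f"gene {gene.gene_id} has no counted peptide under mode {mode!r}; "
            "it should have been excluded from the analyzed universe"
        )
    return count > 1


def as_status_map(
    records: Mapping[str, GeneRecord], mode: str = "known_only"
) -> dict[str, bool]:
    """AS status for every analyzable gene (≥1 counted peptide).

    Genes with zero counted peptides are omitted — the caller is expected to
    restrict the analysis universe to the returned keys.
    """
    return {
        gid: classify_as(rec, mode)
        for gid, rec in records.items()
        if rec.counted_peptides(mode) >= 1
    }


def classify_groups(
    partition: FamilyPartition, as_status: Mapping[str, bool]
) -> dict[str, GroupAssignment]:
    """One group label per gene in the partition's universe."""
    out: dict[str, GroupAssignment] = {}
    missing = partition.universe - set(as_status)
    if missing:
        raise ValueError(f"AS status missing for gene {sorted(missing)[0]}")
    for members in partition.families.values():
        statuses = {g: as_status[g] for g in members}
        if all(statuses.values()):
            group = Group.A_F
        elif not any(statuses.values()):
            group = Group.N_F
        else:
            group = Group.MIXED_F
        for g in members:
            out[g] = GroupAssignment(g, partition.criterion, statuses[g], group)
    for g in partition.singletons:
        group = Group.A_S if as_status[g] else Group.N_S
        out[g] = GroupAssignment(g, partition.criterion, as_status[g], group)
    return out


def group_table(
    assignments_by_criterion: Mapping[float, Mapping[str, GroupAssignment]]
) -> pd.DataFrame:
    """Long-format gene × criterion group table."""
    rows = [
        (a.gene_id, crit, a.as_status, a.group.value)
        for crit in sorted(assignments_by_criterion)
        for a in sorted(assignments_by_criterion[crit].values(), key=lambda a: a.gene_id)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "criterion", "as_status", "group"])
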