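"""EST filtering, best-match isoform assignment and per-group profiles.

ESTs serve as an expression proxy: each aligned EST is kept when the read
is at least 100 bp and the aligned region reaches 95% identity or higher
(both bounds inclusive), then assigned to its single best-matching isoform.
The per-group profile divides assigned ESTs by the number of transcripts of
the group's genes, transcripts with zero hits included — a low average for
no-AS groups flags that missing AS annotation may simply reflect shallow
expression sampling.

Alignment identity is matches/(matches+mismatches) over the aligned
columns; records with no aligned columns are skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .group_classifier import Group, GroupAssignment
from .io_tables import ESTAlignment, GeneRecord

__all__ = [
    "ESTAssignment",
    "alignment_identity",
    "filter_alignments",
    "assign_best_match",
    "est_profile",
    "MIN_EST_LENGTH",
    "MIN_IDENTITY",
]

logger = logging.getLogger(__name__)

MIN_EST_LENGTH = 100   # bp, inclusive
MIN_IDENTITY = 0.95    # fraction over the aligned region, inclusive


@dataclass(frozen=True)
class ESTAssignment:
    """The unique isoform an EST was attributed to, with its identity (%)."""

    est_id: str
    isoform_id: str
    identity: float


def alignment_identity(aln: ESTAlignment) -> float:
    """matches/(matches+mismatches); raises on an empty aligned region."""
    span = aln.matches + aln.mismatches
    if span == 0:
        raise ZeroDivisionError(f"EST {aln.est_id}: empty aligned region")
    return aln.matches / span


def filter_alignments(
    alignments: Iterable[ESTAlignment],
    min_length: int = MIN_EST_LENGTH,
    min_identity: float = MIN_IDENTITY,
) -> list[ESTAlignment]:
    """Keep alignments with EST length ≥ min_length and identity ≥ min_identity.

    Both bounds are inclusive ("at least 100 bp", "95% identity or higher").
    Alignments with zero aligned columns are skipped with a warning rather
    than failing the run.
    """
    kept = []
    for aln in alignments:
        if aln.matches + aln.mismatches == 0:
            logger.warning(
                "skipping EST %s vs %s: no aligned columns", aln.est_id, aln.isoform_id
            )
            continue
        if aln.est_length >= min_length and alignment_identity(aln) >= min_identity:
            kept.append(aln)
    return kept


def assign_best_match(filtered: Iterable[ESTAlignment]) -> dict[str, ESTAssignment]:
    """One assignment per EST: maximal identity, ties by matches then id.

    Ties on identity are broken by larger match count, then by the
    lexicographically smallest isoform id — a deterministic stand-in for an
    otherwise arbitrary choice among equally good matches.
    """
    best: dict[str, ESTAlignment] = {}
    for aln in filtered:
        cur = best.get(aln.est_id)
        if cur is None:
            best[aln.est_id] = aln
            continue
        key_new = (alignment_identity(aln), aln.matches)
        key_cur = (alignment_identity(cur), cur.matches)
        if key_new > key_cur or (key_new == key_cur and aln.isoform_id < cur.isoform_id):
            best[aln.est_id] = aln
    return {
        est_id: ESTAssignment(
            est_id, aln.isoform_id, 100.0 * alignment_identity(aln)
        )
        for est_id, aln in sorted(best.items())
    }


def est_profile(
    assignments: Mapping[str, ESTAssignment],
    isoform_to_gene: Mapping[str, str],
    assignments_by_criterion: Mapping[float, Mapping[str, GroupAssignment]],
    records: Mapping[str, GeneRecord],
    mode: str = "known_only",
) -> pd.DataFrame:
    """Average EST hits per transcript, per criterion × group.

    The denominator counts every transcript (counted peptide) of the
    group's genes, whether or not any EST hit it; the numerator counts
    assigned ESTs whose isoform maps to a gene of the group.  ESTs assigned
    to an isoform with no gene mapping are an error.
    """
    hits_per_gene: dict[str, int] = {}
    for a in assignments.values():
        gene = isoform_to_gene.get(a.isoform_id)
        if gene is None:
            raise ValueError(f"assigned isoform {a.isoform_id} has no gene mapping")
        hits_per_gene[gene] = hits_per_gene.get(gene, 0) + 1

    rows = []
    for crit in sorted(assignments_by_criterion):
        by_group: dict[Group, list[str]] = {}
        for gid, ga in assignments_by_criterion[crit].items():
            by_group.setdefault(ga.group, []).append(gid)
        for group in sorted(by_group, key=lambda g: g.value):
            genes = sorted(by_group[group])
            n_transcripts = sum(records[g].counted_peptides(mode) for g in genes)
            n_hits = sum(hits_per_gene.get(g, 0) for g in genes)
            rows.append(
                {
                    "criterion": crit,
                    "group": group.value,
                    "n_genes": len(genes),
                    "n_transcripts": n_transcripts,
                    "n_est_hits": n_hits,
                    "avg_hits_per_transcript": (
                        n_hits / n_transcripts if n_transcripts else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)
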