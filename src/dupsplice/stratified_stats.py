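"""Stratified summaries and tests over the criterion sweep.

Computes, per identity criterion: AS proportions and mean isoform counts by
family-size stratum, duplicate-vs-singleton 2×2 Pearson chi-squared tests,
Ka/Ks ratio summaries per group, protein-length and domain-count summaries
per group, and flat GO-category share tables with a "<=1% → others" merge.

Quantile convention: linear interpolation between order statistics (numpy's
default, the classic "type 7"), used for every boxplot-style export.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .family_builder import FamilyPartition, bin_family_size
from .group_classifier import FOUR_GROUPS, Group, GroupAssignment
from .io_tables import GeneRecord, RunConfig

__all__ = [
    "as_proportion",
    "mean_isoform_count",
    "pearson_chisq",
    "proportion_sweep",
    "ka_ks_summary",
    "feature_summary",
    "go_distribution",
]


def as_proportion(genes: Iterable[str], as_status: Mapping[str, bool]) -> float:
    """Fraction of the gene set with AS; errors on an empty set."""
    genes = list(genes)
    if not genes:
        raise ValueError("as_proportion of an empty gene set is undefined")
    return sum(bool(as_status[g]) for g in genes) / len(genes)


def mean_isoform_count(
    genes: Iterable[str],
    records: Mapping[str, GeneRecord],
    mode: str = "known_only",
    over: str = "all",
) -> float:
    """Mean counted-peptide (isoform) count over a gene set.

    ``over="all"`` averages over every gene in the set, so a gene without AS
    contributes its single isoform; ``over="as_only"`` restricts the average
    to genes with more than one isoform.
    """
    counts = [records[g].counted_peptides(mode) for g in genes]
    if over == "as_only":
        counts = [c for c in counts if c > 1]
    elif over != "all":
        raise ValueError(f"unknown averaging mode {over!r}")
    if not counts:
        raise ValueError("mean_isoform_count over an empty gene set")
    return float(np.mean(counts))


def pearson_chisq(
    table: Sequence[Sequence[float]], correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2×2 table.

    Rows are duplicate/singleton, columns AS/no-AS.  With ``correction``,
    the Yates continuity correction (|O−E|−0.5, floored at 0) is applied —
    matching R's ``chisq.test`` default for 2×2 tables.  Returns
    (statistic, p-value) with 1 degree of freedom.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative count in contingency table")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def _quartiles(values: np.ndarray) -> dict[str, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])  # linear / "type 7"
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
    }


_NULL_STATS = {"min": math.nan, "q1": math.nan, "median": math.nan,
               "q3": math.nan, "max": math.nan, "mean": math.nan}


def proportion_sweep(
    partitions: Mapping[float, FamilyPartition],
    as_status: Mapping[str, bool],
    records: Mapping[str, GeneRecord],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AS proportion and mean isoform count per criterion × size stratum.

    Returns ``(strata, chisq)``: ``strata`` has one row per (criterion,
    size-bin) plus pooled "duplicate" and "singleton" rows; ``chisq`` holds
    the per-criterion duplicate-vs-singleton 2×2 test.  Empty strata are
    emitted with n_genes=0 and null statistics.
    """
    mode = config.peptide_status_mode
    strata_rows = []
    chisq_rows = []
    for crit in sorted(partitions):
        part = partitions[crit]
        by_bin: dict[str, list[str]] = {label: [] for label in config.bin_labels()}
        for g in part.universe:
            by_bin[bin_family_size(part.family_size(g), config)].append(g)
        # the pooled singleton row coincides with the size-1 bin; only the
        # pooled duplicate row adds information
        pooled = {"duplicate": sorted(part.duplicates())}
        for label, genes in list(by_bin.items()) + list(pooled.items()):
            if genes:
                n_as = sum(bool(as_status[g]) for g in genes)
                strata_rows.append(
                    {
                        "criterion": crit,
                        "stratum": label,
                        "n_genes": len(genes),
                        "n_as": n_as,
                        "as_proportion": n_as / len(genes),
                        "mean_isoform_count": mean_isoform_count(genes, records, mode),
                    }
                )
            else:
                strata_rows.append(
                    {
                        "criterion": crit,
                        "stratum": label,
                        "n_genes": 0,
                        "n_as": 0,
                        "as_proportion": math.nan,
                        "mean_isoform_count": math.nan,
                    }
                )
        dup, sing = pooled["duplicate"], sorted(part.singletons)
        dup_as = sum(bool(as_status[g]) for g in dup)
        sing_as = sum(bool(as_status[g]) for g in sing)
        table = [[dup_as, len(dup) - dup_as], [sing_as, len(sing) - sing_as]]
        try:
            stat, p = pearson_chisq(table, config.chisq_continuity_correction)
        except ValueError:
            stat, p = math.nan, math.nan
        chisq_rows.append(
            {
                "criterion": crit,
                "dup_as": dup_as,
                "dup_no_as": len(dup) - dup_as,
                "sing_as": sing_as,
                "sing_no_as": len(sing) - sing_as,
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(strata_rows), pd.DataFrame(chisq_rows)


def _four_group_genes(
    assignments: Mapping[str, GroupAssignment]
) -> dict[Group, list[str]]:
    """Genes per group, MIXED_F excluded, deterministic order."""
    out: dict[Group, list[str]] = {g: [] for g in FOUR_GROUPS}
    for gid in sorted(assignments):
        grp = assignments[gid].group
        if grp in out:
            out[grp].append(gid)
    return out


def ka_ks_summary(
    assignments_by_criterion: Mapping[float, Mapping[str, GroupAssignment]],
    records: Mapping[str, GeneRecord],
) -> pd.DataFrame:
    """Ka/Ks ratio five-number summaries per criterion × group.

    The ratio is computed per gene; genes with missing Ka or Ks, or Ks ≤ 0,
    are excluded and tallied in ``excluded_kaks_count``.  MIXED_F families
    are excluded from the four-group comparison.
    """
    rows = []
    for crit in sorted(assignments_by_criterion):
        for group, genes in _four_group_genes(assignments_by_criterion[crit]).items():
            ratios = []
            excluded = 0
            for g in genes:
                rec = records[g]
                if rec.ka is None or rec.ks is None or rec.ks <= 0:
                    excluded += 1
                else:
                    ratios.append(rec.ka / rec.ks)
            stats = _quartiles(np.asarray(ratios)) if ratios else dict(_NULL_STATS)
            rows.append(
                {
                    "criterion": crit,
                    "group": group.value,
                    "n_genes": len(genes),
                    "n_with_kaks": len(ratios),
                    "excluded_kaks_count": excluded,
                    **{f"kaks_{k}": v for k, v in stats.items()},
                }
            )
    return pd.DataFrame(rows)


def feature_summary(
    assignments_by_criterion: Mapping[float, Mapping[str, GroupAssignment]],
    records: Mapping[str, GeneRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-length summaries and domain-count histograms per group.

    Length uses the longest known peptide per gene.  The domain histogram
    reports raw frequency and log10 frequency per (criterion, group,
    domain_count); genes without a domain count are dropped from the
    histogram only.
    """
    length_rows = []
    domain_rows = []
    for crit in sorted(assignments_by_criterion):
        for group, genes in _four_group_genes(assignments_by_criterion[crit]).items():
            lengths = np.asarray(
                [
                    records[g].longest_known_peptide_length
                    for g in genes
                    if records[g].longest_known_peptide_length is not None
                ],
                dtype=float,
            )
            stats = _quartiles(lengths) if len(lengths) else dict(_NULL_STATS)
            length_rows.append(
                {
                    "criterion": crit,
                    "group": group.value,
                    "n_genes": len(genes),
                    "n_with_length": len(lengths),
                    **{f"length_{k}": v for k, v in stats.items()},
                }
            )
            counts: dict[int, int] = {}
            for g in genes:
                dc = records[g].domain_count
                if dc is not None:
                    counts[dc] = counts.get(dc, 0) + 1
            total = sum(counts.values())
            for dc in sorted(counts):
                freq = counts[dc] / total
                domain_rows.append(
                    {
                        "criterion": crit,
                        "group": group.value,
                        "domain_count": dc,
                        "n_genes": counts[dc],
                        "frequency": freq,
                        "log10_frequency": math.log10(freq),
                    }
                )
    return pd.DataFrame(length_rows), pd.DataFrame(domain_rows)


def go_distribution(
    assignments: Mapping[str, GroupAssignment],
    records: Mapping[str, GeneRecord],
    ontology: str,
    min_proportion: float = 0.01,
    counting: str = "annotation",
) -> pd.DataFrame:
    """Per-group GO category shares for one criterion's assignments.

    With ``counting="annotation"`` a gene annotated with k categories
    contributes k incidences (category shares of annotations); with
    ``"gene"`` each gene-category pair still counts once but shares are of
    annotated genes.  Categories whose share is not strictly larger than
    ``min_proportion`` are merged into "others".  Shares per group sum to 1.
    """
    if ontology not in ("MF", "BP"):
        raise ValueError(f"ontology must be MF or BP, got {ontology!r}")
    if counting not in ("annotation", "gene"):
        raise ValueError(f"unknown counting mode {counting!r}")
    rows = []
    for group, genes in _four_group_genes(assignments).items():
        incidences: dict[str, int] = {}
        n_annotated = 0
        for g in genes:
            cats = records[g].go_mf if ontology == "MF" else records[g].go_bp
            if cats:
                n_annotated += 1
            for cat in cats:
                incidences[cat] = incidences.get(cat, 0) + 1
        total = sum(incidences.values()) if counting == "annotation" else n_annotated
        if total == 0:
            continue  # group with no annotated genes: no rows (logged upstream)
        merged: dict[str, float] = {}
        for cat in sorted(incidences):
            share = incidences[cat] / total
            if share > min_proportion:
                merged[cat] = merged.get(cat, 0.0) + share
            else:
                merged["others"] = merged.get("others", 0.0) + share
        for cat in sorted(merged):
            rows.append(
                {
                    "group": group.value,
                    "ontology": ontology,
                    "category": cat,
                    "proportion": merged[cat],
                }
            )
    return pd.DataFrame(rows, columns=["group", "ontology", "category", "proportion"])
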