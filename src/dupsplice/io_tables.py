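"""Readers and writers for the pipeline's tabular inputs and outputs.

All gene-level inputs are plain TSV files with named header columns, the
dialect Ensembl BioMart exports reduce to once sequence retrieval is done
upstream.  EST alignments are accepted either as BLAT PSL (21 columns, with
or without the 5-line header) or as a minimal TSV.

Input tables
------------
genes        gene_id, species
peptides     gene_id, peptide_id, status (known|novel), length
pairs        gene_a, gene_b, identity_a, identity_b   (percent, directional)
kaks         gene_id, ka, ks          (blank cells allowed)
domains      gene_id, domain_count
go           gene_id, ontology (MF|BP), category
est          BLAT PSL, or TSV with est_id, isoform_id, est_length,
             matches, mismatches

Readers validate and normalise to immutable record types; output order is
deterministic and independent of input row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "GeneRecord",
    "ParalogPair",
    "ESTAlignment",
    "RunConfig",
    "read_gene_tables",
    "read_paralog_pairs",
    "read_psl",
    "read_est_tsv",
    "read_isoform_map",
    "write_gene_records",
    "read_gene_records",
    "write_paralog_pairs",
    "write_psl",
]

KNOWN = "known"
NOVEL = "novel"
VALID_STATUSES = (KNOWN, NOVEL)
VALID_ONTOLOGIES = ("MF", "BP")

PSL_COLUMNS = 21
# 0-based indices into a PSL row
_PSL_MATCHES = 0
_PSL_MISMATCHES = 1
_PSL_QNAME = 9
_PSL_QSIZE = 10
_PSL_TNAME = 13


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its peptide inventory summary and optional annotations.

    ``known_peptide_count``/``all_peptide_count`` summarise the peptide
    table; ``longest_known_peptide_length`` is ``None`` when the gene has no
    known peptide.  ``ka``/``ks`` come from an ortholog comparison and may be
    absent, as may ``domain_count``.
    """

    gene_id: str
    species: str
    known_peptide_count: int
    all_peptide_count: int
    longest_known_peptide_length: int | None = None
    domain_count: int | None = None
    ka: float | None = None
    ks: float | None = None
    go_mf: frozenset[str] = field(default_factory=frozenset)
    go_bp: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.known_peptide_count < 0 or self.all_peptide_count < 0:
            raise ValueError(f"negative peptide count for gene {self.gene_id}")
        if self.known_peptide_count > self.all_peptide_count:
            raise ValueError(
                f"gene {self.gene_id}: known_peptide_count "
                f"{self.known_peptide_count} exceeds all_peptide_count "
                f"{self.all_peptide_count}"
            )
        if self.known_peptide_count > 0 and self.longest_known_peptide_length is None:
            raise ValueError(
                f"gene {self.gene_id}: known peptides present but no longest length"
            )

    def counted_peptides(self, mode: str) -> int:
        """Peptide count under the given status mode (known_only or all)."""
        _check_mode(mode)
        return self.known_peptide_count if mode == "known_only" else self.all_peptide_count


@dataclass(frozen=True)
class ParalogPair:
    """An undirected paralog pair with two directional percent identities.

    ``identity_a`` is the alignment identity relative to ``gene_a``'s
    sequence, ``identity_b`` relative to ``gene_b``'s.  Pairs are stored in
    canonical order (``gene_a`` lexicographically smaller).
    """

    gene_a: str
    gene_b: str
    identity_a: float
    identity_b: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair for gene {self.gene_a}")
        for ident in (self.identity_a, self.identity_b):
            if not (0.0 <= ident <= 100.0):
                raise ValueError(
                    f"pair ({self.gene_a},{self.gene_b}): identity {ident} "
                    "outside [0,100]"
                )
        if self.gene_a > self.gene_b:
            # swap into canonical order, keeping identities attached to genes
            a, b = self.gene_a, self.gene_b
            ia, ib = self.identity_a, self.identity_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)
            object.__setattr__(self, "identity_a", ib)
            object.__setattr__(self, "identity_b", ia)

    @staticmethod
    def make(gene_a: str, gene_b: str, identity_a: float, identity_b: float) -> "ParalogPair":
        """Construct a pair in canonical gene-id order."""
        if gene_b < gene_a:
            gene_a, gene_b = gene_b, gene_a
            identity_a, identity_b = identity_b, identity_a
        return ParalogPair(gene_a, gene_b, identity_a, identity_b)

    @property
    def max_identity(self) -> float:
        return max(self.identity_a, self.identity_b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ESTAlignment:
    """One EST-to-isoform alignment (one PSL row).

    ``matches``/``mismatches`` count aligned columns; together they may be
    smaller than ``est_length`` for a partial alignment.
    """

    est_id: str
    isoform_id: str
    est_length: int
    matches: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.est_length <= 0:
            raise ValueError(f"EST {self.est_id}: non-positive length")
        if self.matches < 0 or self.mismatches < 0:
            raise ValueError(f"EST {self.est_id}: negative match counts")


def _check_mode(mode: str) -> None:
    if mode not in ("known_only", "all"):
        raise ValueError(f"unknown peptide_status_mode: {mode!r}")


@dataclass(frozen=True)
class RunConfig:
    """Sweep configuration.

    identity_criteria
        Percent-identity thresholds swept; a pair qualifies at a criterion
        when its maximum directional identity is strictly larger.  Higher
        criteria select younger duplications.
    peptide_status_mode
        ``known_only`` counts only Ensembl-status-known peptides (the main
        analysis); ``all`` also counts novel peptides.
    family_size_bins
        Inclusive (lo, hi) ranges; ``hi = None`` is open-ended.  Default
        strata: singletons, 2-4, 5-7, 8+.
    """

    identity_criteria: tuple[float, ...] = (10.0, 20.0, 30.0, 50.0, 70.0, 90.0)
    peptide_status_mode: str = "known_only"
    family_size_bins: tuple[tuple[int, int | None], ...] = (
        (1, 1),
        (2, 4),
        (5, 7),
        (8, None),
    )
    chisq_continuity_correction: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        _check_mode(self.peptide_status_mode)
        crits = tuple(float(c) for c in self.identity_criteria)
        if not crits:
            raise ValueError("identity_criteria must be non-empty")
        if any(not (0.0 < c < 100.0) for c in crits):
            raise ValueError("identity criteria must lie in (0,100)")
        if any(b <= a for a, b in zip(crits, crits[1:])):
            raise ValueError("identity criteria must be strictly increasing")
        object.__setattr__(self, "identity_criteria", crits)
        bins = tuple((int(lo), None if hi is None else int(hi)) for lo, hi in self.family_size_bins)
        # bins must tile the positive integers without gaps or overlap
        expect = 1
        for i, (lo, hi) in enumerate(bins):
            if lo != expect:
                raise ValueError(f"family_size_bins gap/overlap at size {expect}")
            if hi is None:
                if i != len(bins) - 1:
                    raise ValueError("open-ended bin must come last")
            else:
                if hi < lo:
                    raise ValueError(f"bin ({lo},{hi}) is empty")
                expect = hi + 1
        if bins[-1][1] is not None:
            raise ValueError("last family_size_bin must be open-ended")
        object.__setattr__(self, "family_size_bins", bins)

    def bin_labels(self) -> tuple[str, ...]:
        return tuple(_bin_label(lo, hi) for lo, hi in self.family_size_bins)

    def to_dict(self) -> dict:
        return {
            "identity_criteria": list(self.identity_criteria),
            "peptide_status_mode": self.peptide_status_mode,
            "family_size_bins": [list(b) for b in self.family_size_bins],
            "chisq_continuity_correction": self.chisq_continuity_correction,
            "random_seed": self.random_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kwargs = dict(d)
        if "family_size_bins" in kwargs:
            kwargs["family_size_bins"] = tuple(
                (int(lo), None if hi is None else int(hi))
                for lo, hi in kwargs["family_size_bins"]
            )
        if "identity_criteria" in kwargs:
            kwargs["identity_criteria"] = tuple(kwargs["identity_criteria"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _bin_label(lo: int, hi: int | None) -> str:
    if lo == 1 and hi == 1:
        return "singleton"
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def _to_int(series: pd.Series, what: str) -> pd.Series:
    try:
        return series.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer value in {what}: {exc}") from None


def read_gene_tables(
    gene_path: str | Path,
    peptide_path: str | Path,
    config: RunConfig | None = None,
    *,
    kaks_path: str | Path | None = None,
    domain_path: str | Path | None = None,
    go_path: str | Path | None = None,
) -> dict[str, GeneRecord]:
    """Read the gene + peptide tables (and optional annotations) into records.

    One :class:`GeneRecord` per distinct gene_id in the gene table.  Peptide
    counts are aggregated from the peptide table; genes absent from it get
    zero counts.  Annotation tables attach Ka/Ks, domain counts and GO labels
    to existing genes (rows for unknown genes raise).
    """
    genes = _read_tsv(gene_path, ("gene_id", "species"))
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in gene table: {dup}")
    species = dict(zip(genes["gene_id"], genes["species"]))

    peps = _read_tsv(peptide_path, ("gene_id", "peptide_id", "status", "length"))
    if len(peps):
        if peps["peptide_id"].duplicated().any():
            dup = peps.loc[peps["peptide_id"].duplicated(), "peptide_id"].iloc[0]
            raise ValueError(f"duplicate peptide_id: {dup}")
        bad = ~peps["status"].isin(VALID_STATUSES)
        if bad.any():
            raise ValueError(
                f"unknown peptide status token: {peps.loc[bad, 'status'].iloc[0]!r}"
            )
        unknown = set(peps["gene_id"]) - set(species)
        if unknown:
            raise ValueError(f"peptide row for unknown gene {sorted(unknown)[0]}")
        peps = peps.assign(length=_to_int(peps["length"], "peptide length"))
        if (peps["length"] <= 0).any():
            raise ValueError("non-positive peptide length")

    known_count: dict[str, int] = {}
    all_count: dict[str, int] = {}
    longest_known: dict[str, int] = {}
    if len(peps):
        grp_all = peps.groupby("gene_id").size()
        all_count = grp_all.to_dict()
        kn = peps[peps["status"] == KNOWN]
        if len(kn):
            known_count = kn.groupby("gene_id").size().to_dict()
            longest_known = kn.groupby("gene_id")["length"].max().to_dict()

    ka: dict[str, float] = {}
    ks: dict[str, float] = {}
    if kaks_path is not None:
        kk = _read_tsv(kaks_path, ("gene_id", "ka", "ks"))
        _check_known_genes(kk, species, "kaks")
        for _, row in kk.iterrows():
            gid = row["gene_id"]
            if _has_value(row["ka"]):
                ka[gid] = float(row["ka"])
            if _has_value(row["ks"]):
                ks[gid] = float(row["ks"])

    domains: dict[str, int] = {}
    if domain_path is not None:
        dm = _read_tsv(domain_path, ("gene_id", "domain_count"))
        _check_known_genes(dm, species, "domains")
        dm = dm.assign(domain_count=_to_int(dm["domain_count"], "domain_count"))
        domains = dict(zip(dm["gene_id"], dm["domain_count"]))

    go_mf: dict[str, set[str]] = {}
    go_bp: dict[str, set[str]] = {}
    if go_path is not None:
        go = _read_tsv(go_path, ("gene_id", "ontology", "category"))
        _check_known_genes(go, species, "go")
        bad = ~go["ontology"].isin(VALID_ONTOLOGIES)
        if bad.any():
            raise ValueError(
                f"unknown ontology token: {go.loc[bad, 'ontology'].iloc[0]!r}"
            )
        for _, row in go.iterrows():
            target = go_mf if row["ontology"] == "MF" else go_bp
            target.setdefault(row["gene_id"], set()).add(row["category"])

    records: dict[str, GeneRecord] = {}
    for gid in sorted(species):
        records[gid] = GeneRecord(
            gene_id=gid,
            species=species[gid],
            known_peptide_count=int(known_count.get(gid, 0)),
            all_peptide_count=int(all_count.get(gid, 0)),
            longest_known_peptide_length=(
                int(longest_known[gid]) if gid in longest_known else None
            ),
            domain_count=domains.get(gid),
            ka=ka.get(gid),
            ks=ks.get(gid),
            go_mf=frozenset(go_mf.get(gid, ())),
            go_bp=frozenset(go_bp.get(gid, ())),
        )
    return records


def _check_known_genes(df: pd.DataFrame, species: Mapping[str, str], what: str) -> None:
    unknown = set(df["gene_id"]) - set(species)
    if unknown:
        raise ValueError(f"{what} row for unknown gene {sorted(unknown)[0]}")


def _has_value(x) -> bool:
    if x is None:
        return False
    if isinstance(x, float) and math.isnan(x):
        return False
    return str(x).strip() != ""


def read_paralog_pairs(path: str | Path) -> list[ParalogPair]:
    """Read and validate the paralog-pair table.

    Mirrored rows (``(a,b)`` and ``(b,a)`` with identities swapped) collapse
    to one pair; the same unordered pair with conflicting identities is an
    error, as are self-pairs and out-of-range identities.
    """
    df = _read_tsv(path, ("gene_a", "gene_b", "identity_a", "identity_b"))
    seen: dict[tuple[str, str], ParalogPair] = {}
    for _, row in df.iterrows():
        pair = ParalogPair.make(
            str(row["gene_a"]), str(row["gene_b"]),
            float(row["identity_a"]), float(row["identity_b"]),
        )
        prev = seen.get(pair.key)
        if prev is None:
            seen[pair.key] = pair
        elif (prev.identity_a, prev.identity_b) != (pair.identity_a, pair.identity_b):
            raise ValueError(
                f"conflicting identities for pair {pair.key}: "
                f"{(prev.identity_a, prev.identity_b)} vs "
                f"{(pair.identity_a, pair.identity_b)}"
            )
    return [seen[k] for k in sorted(seen)]


def read_psl(path: str | Path) -> list[ESTAlignment]:
    """Read BLAT PSL alignments (21 columns, optional 5-line header)."""
    alignments: list[ESTAlignment] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        # standard header: version line, blank, two column-name lines, dashes
        start = 5
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("-"):
            continue
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise ValueError(
                f"{path}:{lineno}: expected {PSL_COLUMNS} PSL columns, "
                f"got {len(fields)}"
            )
        try:
            matches = int(fields[_PSL_MATCHES])
            mismatches = int(fields[_PSL_MISMATCHES])
            qsize = int(fields[_PSL_QSIZE])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric PSL numeric field") from None
        alignments.append(
            ESTAlignment(
                est_id=fields[_PSL_QNAME],
                isoform_id=fields[_PSL_TNAME],
                est_length=qsize,
                matches=matches,
                mismatches=mismatches,
            )
        )
    alignments.sort(key=lambda a: (a.est_id, a.isoform_id, -a.matches, a.mismatches))
    return alignments


def read_est_tsv(path: str | Path) -> list[ESTAlignment]:
    """Read EST alignments from the minimal TSV dialect."""
    df = _read_tsv(path, ("est_id", "isoform_id", "est_length", "matches", "mismatches"))
    out = [
        ESTAlignment(
            est_id=str(r["est_id"]),
            isoform_id=str(r["isoform_id"]),
            est_length=int(r["est_length"]),
            matches=int(r["matches"]),
            mismatches=int(r["mismatches"]),
        )
        for _, r in df.iterrows()
    ]
    out.sort(key=lambda a: (a.est_id, a.isoform_id, -a.matches, a.mismatches))
    return out


def read_isoform_map(path: str | Path) -> dict[str, str]:
    """Read the isoform→gene TSV (columns isoform_id, gene_id)."""
    df = _read_tsv(path, ("isoform_id", "gene_id"))
    if df["isoform_id"].duplicated().any():
        dup = df.loc[df["isoform_id"].duplicated(), "isoform_id"].iloc[0]
        raise ValueError(f"isoform {dup} mapped to more than one gene")
    return dict(zip(df["isoform_id"], df["gene_id"]))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GO_SEP = ";"


def write_gene_records(records: Mapping[str, GeneRecord], path: str | Path) -> None:
    """Write GeneRecords to the flat one-row-per-gene TSV dialect."""
    rows = []
    for gid in sorted(records):
        r = records[gid]
        rows.append(
            {
                "gene_id": r.gene_id,
                "species": r.species,
                "known_peptide_count": r.known_peptide_count,
                "all_peptide_count": r.all_peptide_count,
                "longest_known_peptide_length": (
                    "" if r.longest_known_peptide_length is None
                    else r.longest_known_peptide_length
                ),
                "domain_count": "" if r.domain_count is None else r.domain_count,
                "ka": "" if r.ka is None else repr(r.ka),
                "ks": "" if r.ks is None else repr(r.ks),
                "go_mf": _GO_SEP.join(sorted(r.go_mf)),
                "go_bp": _GO_SEP.join(sorted(r.go_bp)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_records(path: str | Path) -> dict[str, GeneRecord]:
    """Inverse of :func:`write_gene_records`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: dict[str, GeneRecord] = {}
    for _, r in df.iterrows():
        rec = GeneRecord(
            gene_id=r["gene_id"],
            species=r["species"],
            known_peptide_count=int(r["known_peptide_count"]),
            all_peptide_count=int(r["all_peptide_count"]),
            longest_known_peptide_length=(
                int(r["longest_known_peptide_length"])
                if r["longest_known_peptide_length"] != "" else None
            ),
            domain_count=int(r["domain_count"]) if r["domain_count"] != "" else None,
            ka=float(r["ka"]) if r["ka"] != "" else None,
            ks=float(r["ks"]) if r["ks"] != "" else None,
            go_mf=frozenset(x for x in r["go_mf"].split(_GO_SEP) if x),
            go_bp=frozenset(x for x in r["go_bp"].split(_GO_SEP) if x),
        )
        if rec.gene_id in records:
            raise ValueError(f"duplicate gene_id {rec.gene_id}")
        records[rec.gene_id] = rec
    return dict(sorted(records.items()))


def write_paralog_pairs(pairs: Iterable[ParalogPair], path: str | Path) -> None:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "identity_a": repr(p.identity_a),
            "identity_b": repr(p.identity_b),
        }
        for p in sorted(pairs, key=lambda p: p.key)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity_a", "identity_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_psl(alignments: Iterable[ESTAlignment], path: str | Path) -> None:
    """Write alignments as headerless 21-column PSL.

    Only the fields the pipeline consumes (matches, misMatches, qName, qSize,
    tName) are meaningful; the remaining columns are filled with neutral
    placeholder values so the file stays structurally valid PSL.
    """
    with open(path, "w") as fh:
        for a in sorted(alignments, key=lambda a: (a.est_id, a.isoform_id, -a.matches, a.mismatches)):
            span = a.matches + a.mismatches
            fields = [
                a.matches, a.mismatches, 0, 0, 0, 0, 0, 0, "+",
                a.est_id, a.est_length, 0, min(span, a.est_length),
                a.isoform_id, max(span, 1), 0, span,
                1, f"{span},", "0,", "0,",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")
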