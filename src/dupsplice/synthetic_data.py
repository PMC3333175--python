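"""Synthetic datasets with planted duplication/AS structure.

The generator emulates the statistical structure the pipeline is designed
to interrogate, without any sequence simulation:

* Gene "units" are singletons or paralog families (cliques) whose size is
  drawn from a unit-level distribution.  Each family has an age a ∈ (0,1]
  (0 = newest); every pair in the family draws its percent identity from a
  Gaussian centred on 100·(1−a), so the identity-criterion sweep slices
  families by age.  The two directional identities of a pair share the same
  maximum (the second direction gets a small non-negative deficit), so pair
  qualification depends only on the single planted identity draw.
* AS status is Bernoulli: P(AS | singleton) = p_s, and for a family gene
  logistic(β0 + β1·a + β2·1[size ≥ 8]).  The default preset plants the
  qualitative regime reported for mammalian genomes: young duplicates
  AS-poor, ancient duplicates AS-rich, large families AS-poor throughout.
* AS genes carry 2 + Poisson(λ) known peptides, others exactly one; novel
  peptides, Ka/Ks, domain counts, GO labels and per-transcript EST hit
  rates are drawn per (duplicate?, AS?) class with defaults encoding the
  planted group contrasts (e.g. no-AS families get the lowest EST rates).

``planted_expectations`` returns the *exact* expected AS proportion per
observed family-size stratum at each criterion.  Within a planted clique
the pairs qualify independently given the age, so the observed family of a
gene is its connected component in an Erdős–Rényi graph G(k, q(a,t)); the
component-size law is computed by the standard connected-graph recursion
and integrated over the age grid.  Partial family visibility (fragmentation
near a threshold) is therefore handled exactly, not approximately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .family_builder import bin_family_size
from .io_tables import ESTAlignment, ParalogPair, RunConfig, write_psl

__all__ = ["SyntheticParams", "SyntheticDataset", "generate", "planted_expectations"]

# (duplicate?, AS?) classes used for the per-group feature models
_CLASSES = ("F_AS", "F_NO", "S_AS", "S_NO")

MF_CATEGORIES = (
    "molecular transducer activity",
    "catalytic activity",
    "binding",
    "structural molecule activity",
    "enzyme regulator activity",
    "nucleic acid binding transcription factor activity",
    "transporter activity",
    "antioxidant activity",
)

BP_CATEGORIES = (
    "cellular process",
    "metabolic process",
    "multicellular organismal process",
    "signaling",
    "immune system process",
    "developmental process",
    "localization",
    "response to stimulus",
)

# category weights per class; no-AS families are tilted toward
# transducer/signalling roles, AS genes toward metabolic/catalytic ones
_GO_MF_WEIGHTS = {
    "F_AS": (0.04, 0.30, 0.28, 0.06, 0.06, 0.12, 0.10, 0.04),
    "F_NO": (0.30, 0.14, 0.20, 0.05, 0.10, 0.10, 0.08, 0.03),
    "S_AS": (0.03, 0.28, 0.30, 0.12, 0.05, 0.08, 0.10, 0.04),
    "S_NO": (0.05, 0.22, 0.26, 0.14, 0.10, 0.07, 0.12, 0.04),
}
_GO_BP_WEIGHTS = {
    "F_AS": (0.26, 0.24, 0.08, 0.10, 0.02, 0.12, 0.10, 0.08),
    "F_NO": (0.16, 0.14, 0.22, 0.24, 0.02, 0.08, 0.06, 0.08),
    "S_AS": (0.30, 0.28, 0.06, 0.08, 0.03, 0.08, 0.09, 0.08),
    "S_NO": (0.28, 0.26, 0.08, 0.10, 0.015, 0.09, 0.095, 0.08),
}


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the planted model; defaults are the "mammalian" preset."""

    n_genes: int = 10_000
    species: str = "synthspecies"
    #: unit-level probabilities for family sizes 1..S_max
    family_size_probs: tuple[float, ...] = (
        0.55, 0.18, 0.10, 0.06, 0.04, 0.025, 0.015, 0.010, 0.007, 0.005, 0.004, 0.004,
    )
    #: family age is uniform on (age_min, age_max]; mean pair identity is 100(1-a)
    age_min: float = 0.02
    age_max: float = 0.88
    identity_sd: float = 2.0           # per-pair Gaussian jitter, identity points
    directional_deficit_max: float = 4.0
    # AS model
    p_as_singleton: float = 0.65
    as_beta0: float = -0.405           # logit P(AS) for a family gene at age 0
    as_beta_age: float = 4.0
    as_beta_large: float = -2.0        # penalty for families of size >= large_family_min
    large_family_min: int = 8
    as_family_prob_override: float | None = None  # force P(AS|family) for degenerate tests
    # isoform / peptide model
    extra_isoform_lambda: float = 1.3  # AS genes carry 2 + Poisson(lambda) known peptides
    novel_peptide_lambda: float = 0.4
    # per-class feature models, keyed F_AS / F_NO / S_AS / S_NO
    length_median: Mapping[str, float] = field(
        default_factory=lambda: {"F_AS": 600.0, "F_NO": 420.0, "S_AS": 520.0, "S_NO": 450.0}
    )
    length_log_sd: float = 0.35
    domain_mean: Mapping[str, float] = field(
        default_factory=lambda: {"F_AS": 5.0, "F_NO": 2.0, "S_AS": 4.0, "S_NO": 3.0}
    )
    domain_dispersion: float = 3.0
    domain_missing_prob: float = 0.03
    kaks_present_prob: float = 0.92
    ks_zero_prob: float = 0.01
    ks_median: float = 0.45
    ks_log_sd: float = 0.35
    #: Ka/Ks ratio at age 1 per class; family classes gain exp(gamma*(1-a))
    kaks_ratio_base: Mapping[str, float] = field(
        default_factory=lambda: {"F_AS": 0.10, "F_NO": 0.16, "S_AS": 0.22, "S_NO": 0.22}
    )
    kaks_age_gamma: float = 1.2
    kaks_log_sd: float = 0.5
    go_extra_category_lambda: float = 0.8  # genes carry 1 + Poisson(lambda) categories (<=3)
    #: Poisson EST hits per transcript, per class
    est_rate: Mapping[str, float] = field(
        default_factory=lambda: {"F_AS": 3.0, "F_NO": 1.0, "S_AS": 2.5, "S_NO": 1.5}
    )
    est_good_prob: float = 0.85        # remainder split between low-identity and short reads
    est_low_identity_prob: float = 0.08
    est_decoy_prob: float = 0.20       # chance of an extra sub-threshold alignment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        probs = np.asarray(self.family_size_probs, dtype=float)
        if len(probs) < 1 or (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("family_size_probs must be a probability vector")
        if not (0.0 < self.age_min < self.age_max <= 1.0):
            raise ValueError("need 0 < age_min < age_max <= 1")
        if self.identity_sd < 0:
            raise ValueError("identity_sd must be >= 0")
        if not (0.0 <= self.p_as_singleton <= 1.0):
            raise ValueError("p_as_singleton must be a probability")

    @property
    def max_family_size(self) -> int:
        return len(self.family_size_probs)

    def family_as_prob(self, size: int, age: float) -> float:
        """P(AS) for a gene in a family of the given true size and age."""
        if self.as_family_prob_override is not None:
            return float(self.as_family_prob_override)
        z = self.as_beta0 + self.as_beta_age * age
        if size >= self.large_family_min:
            z += self.as_beta_large
        return float(expit(z))

    def to_dict(self) -> dict:
        d = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if isinstance(v, Mapping):
                v = dict(v)
            elif isinstance(v, tuple):
                v = list(v)
            d[f] = v
        return d


@dataclass
class SyntheticDataset:
    """All generated tables plus the planted-truth sidecar."""

    params: SyntheticParams
    genes: pd.DataFrame          # gene_id, species
    peptides: pd.DataFrame       # gene_id, peptide_id, status, length
    pairs: pd.DataFrame          # gene_a, gene_b, identity_a, identity_b
    kaks: pd.DataFrame           # gene_id, ka, ks
    domains: pd.DataFrame        # gene_id, domain_count
    go: pd.DataFrame             # gene_id, ontology, category
    est: list[ESTAlignment]
    isoform_map: pd.DataFrame    # isoform_id, gene_id
    truth: dict

    def paralog_pairs(self) -> list[ParalogPair]:
        return [
            ParalogPair.make(r.gene_a, r.gene_b, r.identity_a, r.identity_b)
            for r in self.pairs.itertuples()
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        self.peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        self.kaks.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        self.domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
        self.go.to_csv(outdir / "go.tsv", sep="\t", index=False)
        self.isoform_map.to_csv(outdir / "isoform_map.tsv", sep="\t", index=False)
        write_psl(self.est, outdir / "est.psl")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _gene_class(is_family: bool, as_status: bool) -> str:
    return ("F_" if is_family else "S_") + ("AS" if as_status else "NO")


def generate(params: SyntheticParams) -> SyntheticDataset:
    """Draw a complete dataset; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    sizes = np.arange(1, params.max_family_size + 1)
    probs = np.asarray(params.family_size_probs, dtype=float)
    probs = probs / probs.sum()

    # --- unit structure -------------------------------------------------
    unit_sizes: list[int] = []
    total = 0
    while total < params.n_genes:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, params.n_genes - total)  # last unit may be truncated
        unit_sizes.append(k)
        total += k

    gene_rows = []
    truth_genes: dict[str, dict] = {}
    units = []
    gid_counter = 0
    for unit_id, k in enumerate(unit_sizes):
        age = float(rng.uniform(params.age_min, params.age_max)) if k >= 2 else None
        members = []
        for _ in range(k):
            gid = f"g{gid_counter:06d}"
            gid_counter += 1
            members.append(gid)
            gene_rows.append({"gene_id": gid, "species": params.species})
        units.append((unit_id, members, age))
        for gid in members:
            p_as = (
                params.p_as_singleton
                if k == 1
                else params.family_as_prob(k, age)
            )
            truth_genes[gid] = {
                "unit_id": unit_id,
                "true_family_size": k,
                "age": age,
                "as_prob": p_as,
            }

    # --- AS status, peptides --------------------------------------------
    peptide_rows = []
    isoform_rows = []
    for gid in sorted(truth_genes):
        info = truth_genes[gid]
        as_status = bool(rng.random() < info["as_prob"])
        info["as_status"] = as_status
        cls = _gene_class(info["true_family_size"] >= 2, as_status)
        info["class"] = cls
        n_known = int(2 + rng.poisson(params.extra_isoform_lambda)) if as_status else 1
        n_novel = int(rng.poisson(params.novel_peptide_lambda))
        longest = max(50, int(rng.lognormal(math.log(params.length_median[cls]),
                                            params.length_log_sd)))
        lengths = [longest] + [
            max(30, int(longest * rng.uniform(0.3, 0.95)))
            for _ in range(n_known + n_novel - 1)
        ]
        for i, ln in enumerate(lengths):
            pid = f"{gid}.p{i}"
            status = "known" if i < n_known else "novel"
            peptide_rows.append(
                {"gene_id": gid, "peptide_id": pid, "status": status, "length": ln}
            )
            if status == "known":
                isoform_rows.append({"isoform_id": pid, "gene_id": gid})
        info["n_known_peptides"] = n_known

    # --- paralog pairs ---------------------------------------------------
    pair_rows = []
    for unit_id, members, age in units:
        if len(members) < 2:
            continue
        mean_identity = 100.0 * (1.0 - age)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = float(np.clip(rng.normal(mean_identity, params.identity_sd), 0.0, 100.0))
                deficit = float(rng.uniform(0.0, params.directional_deficit_max))
                other = max(ident - deficit, 0.0)
                if rng.random() < 0.5:
                    ia, ib = ident, other
                else:
                    ia, ib = other, ident
                pair_rows.append(
                    {
                        "gene_a": members[i],
                        "gene_b": members[j],
                        "identity_a": round(ia, 4),
                        "identity_b": round(ib, 4),
                    }
                )

    # --- Ka/Ks, domains, GO ----------------------------------------------
    kaks_rows = []
    domain_rows = []
    go_rows = []
    for gid in sorted(truth_genes):
        info = truth_genes[gid]
        cls = info["class"]
        if rng.random() < params.kaks_present_prob:
            if rng.random() < params.ks_zero_prob:
                ks = 0.0
                ka = 0.0
            else:
                ks = float(rng.lognormal(math.log(params.ks_median), params.ks_log_sd))
                log_ratio = math.log(params.kaks_ratio_base[cls])
                if info["true_family_size"] >= 2:
                    log_ratio += params.kaks_age_gamma * (1.0 - info["age"])
                ratio = float(np.exp(log_ratio + rng.normal(0.0, params.kaks_log_sd)))
                ka = ratio * ks
            kaks_rows.append({"gene_id": gid, "ka": round(ka, 6), "ks": round(ks, 6)})
        if rng.random() >= params.domain_missing_prob:
            mean = params.domain_mean[cls]
            n = params.domain_dispersion
            dc = int(rng.negative_binomial(n, n / (n + mean)))
            domain_rows.append({"gene_id": gid, "domain_count": dc})
        n_cats = min(3, 1 + int(rng.poisson(params.go_extra_category_lambda)))
        for ontology, cats, weights in (
            ("MF", MF_CATEGORIES, _GO_MF_WEIGHTS[cls]),
            ("BP", BP_CATEGORIES, _GO_BP_WEIGHTS[cls]),
        ):
            w = np.asarray(weights, dtype=float)
            chosen = rng.choice(len(cats), size=n_cats, replace=False, p=w / w.sum())
            for c in sorted(chosen):
                go_rows.append({"gene_id": gid, "ontology": ontology, "category": cats[c]})

    # --- ESTs -------------------------------------------------------------
    est_alignments: list[ESTAlignment] = []
    all_isoforms = [r["isoform_id"] for r in isoform_rows]
    est_counter = 0
    for row in isoform_rows:
        gid = row["gene_id"]
        cls = truth_genes[gid]["class"]
        n_hits = int(rng.poisson(params.est_rate[cls]))
        for _ in range(n_hits):
            est_id = f"E{est_counter:07d}"
            est_counter += 1
            roll = rng.random()
            if roll < params.est_good_prob:
                qsize = int(rng.integers(150, 701))
                identity = float(rng.uniform(0.955, 1.0))
            elif roll < params.est_good_prob + params.est_low_identity_prob:
                qsize = int(rng.integers(150, 701))
                identity = float(rng.uniform(0.80, 0.94))
            else:  # too short to pass the length filter
                qsize = int(rng.integers(40, 100))
                identity = float(rng.uniform(0.955, 1.0))
            span = max(30, int(qsize * rng.uniform(0.6, 1.0)))
            matches = int(round(span * identity))
            est_alignments.append(
                ESTAlignment(est_id, row["isoform_id"], qsize, matches, span - matches)
            )
            if rng.random() < params.est_decoy_prob and len(all_isoforms) > 1:
                decoy = all_isoforms[int(rng.integers(len(all_isoforms)))]
                if decoy != row["isoform_id"]:
                    d_span = max(30, int(qsize * rng.uniform(0.3, 0.8)))
                    d_ident = float(rng.uniform(0.70, 0.93))
                    d_matches = int(round(d_span * d_ident))
                    est_alignments.append(
                        ESTAlignment(est_id, decoy, qsize, d_matches, d_span - d_matches)
                    )

    truth = {
        "params": params.to_dict(),
        "genes": truth_genes,
        "n_units": len(units),
        "n_families": sum(1 for _, m, _ in units if len(m) >= 2),
    }
    return SyntheticDataset(
        params=params,
        genes=pd.DataFrame(gene_rows),
        peptides=pd.DataFrame(peptide_rows),
        pairs=pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "identity_a", "identity_b"]),
        kaks=pd.DataFrame(kaks_rows, columns=["gene_id", "ka", "ks"]),
        domains=pd.DataFrame(domain_rows, columns=["gene_id", "domain_count"]),
        go=pd.DataFrame(go_rows, columns=["gene_id", "ontology", "category"]),
        est=est_alignments,
        isoform_map=pd.DataFrame(isoform_rows, columns=["isoform_id", "gene_id"]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# closed-form planted expectations
# ---------------------------------------------------------------------------

def _component_size_law(k: int, q: np.ndarray) -> np.ndarray:
    """P(random vertex lies in a component of size j) in G(k, q).

    Returns an array of shape (k, len(q)); row j-1 is the probability of
    component size j, vectorized over the edge probabilities ``q``.
    Uses the standard connected-graph recursion
    P_conn(n) = 1 − Σ_{j<n} C(n−1, j−1) P_conn(j) (1−q)^{j(n−j)}.
    """
    one_minus = 1.0 - q
    conn = [None, np.ones_like(q)]  # conn[n] = P(G(n,q) connected)
    for n in range(2, k + 1):
        acc = np.zeros_like(q)
        for j in range(1, n):
            acc += math.comb(n - 1, j - 1) * conn[j] * one_minus ** (j * (n - j))
        conn.append(1.0 - acc)
    out = np.zeros((k, len(q)))
    for j in range(1, k + 1):
        out[j - 1] = math.comb(k - 1, j - 1) * conn[j] * one_minus ** (j * (k - j))
    return out


def planted_expectations(
    params: SyntheticParams,
    config: RunConfig | None = None,
    n_age_points: int = 400,
) -> pd.DataFrame:
    """Exact expected AS proportion per criterion × observed size stratum.

    A gene's observed family at criterion t is its connected component in
    the qualified subgraph of its planted clique; given the family age the
    pairs qualify independently with probability q(a,t) = P(identity > t),
    so the component-size law of G(k, q) applies.  Expectations marginalize
    the uniform age distribution on a midpoint grid and weight true sizes
    by their gene-level shares.  Strata are the configured size bins plus a
    pooled "duplicate" row (observed size ≥ 2).
    """
    if config is None:
        config = RunConfig()
    sizes = np.arange(1, params.max_family_size + 1)
    unit_probs = np.asarray(params.family_size_probs, dtype=float)
    unit_probs = unit_probs / unit_probs.sum()
    gene_w = sizes * unit_probs
    gene_w = gene_w / gene_w.sum()

    edges = np.linspace(params.age_min, params.age_max, n_age_points + 1)
    ages = 0.5 * (edges[:-1] + edges[1:])

    labels = list(config.bin_labels()) + ["duplicate"]
    rows = []
    for crit in config.identity_criteria:
        num = {lab: 0.0 for lab in labels}
        den = {lab: 0.0 for lab in labels}
        for idx, k in enumerate(sizes):
            if k == 1:
                lab = bin_family_size(1, config)
                num[lab] += gene_w[idx] * params.p_as_singleton
                den[lab] += gene_w[idx]
                continue
            mean_ident = 100.0 * (1.0 - ages)
            if params.identity_sd > 0:
                q = 1.0 - norm.cdf((crit - mean_ident) / params.identity_sd)
            else:
                q = (mean_ident > crit).astype(float)
            comp = _component_size_law(int(k), q)  # (k, n_age_points)
            pi = np.array([params.family_as_prob(int(k), float(a)) for a in ages])
            for j in range(1, int(k) + 1):
                lab = bin_family_size(j, config)
                mass = gene_w[idx] * comp[j - 1].mean()
                as_mass = gene_w[idx] * (comp[j - 1] * pi).mean()
                den[lab] += mass
                num[lab] += as_mass
                if j >= 2:
                    den["duplicate"] += mass
                    num["duplicate"] += as_mass
        for lab in labels:
            rows.append(
                {
                    "criterion": crit,
                    "stratum": lab,
                    "expected_as_proportion": (
                        num[lab] / den[lab] if den[lab] > 0 else math.nan
                    ),
                    "expected_gene_fraction": den[lab],
                }
            )
    return pd.DataFrame(rows)
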