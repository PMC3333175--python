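"""Stratified summaries: proportions, isoform means, chi-squared, Ka/Ks,
feature summaries and GO category shares."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupsplice.family_builder import build_families, sweep_partitions
from dupsplice.group_classifier import classify_groups
from dupsplice.io_tables import ParalogPair, RunConfig
from dupsplice.stratified_stats import (
    as_proportion,
    feature_summary,
    go_distribution,
    ka_ks_summary,
    mean_isoform_count,
    pearson_chisq,
    proportion_sweep,
)
from .conftest import make_record


class TestASProportion:
    def test_count_ratio(self):
        status = {"a": True, "b": True, "c": True, "d": False}
        assert as_proportion(status, status) == 0.75
        assert as_proportion(["a", "b"], status) == 1.0
        assert as_proportion(["d"], status) == 0.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            as_proportion([], {})

    def test_binomial_recovery_of_planted_rate(self):
        rng = np.random.default_rng(11)
        p = 0.65
        n = 5000
        status = {f"g{i}": bool(rng.random() < p) for i in range(n)}
        se = math.sqrt(p * (1 - p) / n)
        assert abs(as_proportion(status, status) - p) < 3 * se


class TestMeanIsoformCount:
    def test_averages_over_all_genes(self):
        records = {f"g{i}": make_record(f"g{i}", c) for i, c in enumerate([1, 2, 5])}
        assert mean_isoform_count(records, records) == pytest.approx(8 / 3)

    def test_single_peptide_cohort(self):
        records = {f"g{i}": make_record(f"g{i}", 1) for i in range(4)}
        assert mean_isoform_count(records, records) == 1.0

    def test_as_only_mode_drops_single_isoform_genes(self):
        records = {f"g{i}": make_record(f"g{i}", c) for i, c in enumerate([1, 2, 5])}
        assert mean_isoform_count(records, records, over="as_only") == 3.5

    def test_agreement_with_direct_resummation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.integers(1, 9, size=rng.integers(1, 30))
            records = {
                f"g{i}": make_record(f"g{i}", int(c)) for i, c in enumerate(counts)
            }
            assert mean_isoform_count(records, records) == pytest.approx(
                sum(counts) / len(counts)
            )


def chisq_oracle(table):
    """Textbook Pearson statistic computed from scratch."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestPearsonChisq:
    def test_perfect_independence(self):
        stat, p = pearson_chisq([[10, 10], [10, 10]], correction=False)
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_formula(self):
        table = [[30, 10], [10, 30]]
        stat, _ = pearson_chisq(table, correction=False)
        assert stat == pytest.approx(chisq_oracle(table), abs=1e-10)

    def test_correction_never_lowers_p(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            table = rng.integers(1, 100, size=(2, 2))
            _, p_corr = pearson_chisq(table, correction=True)
            _, p_raw = pearson_chisq(table, correction=False)
            assert p_corr >= p_raw - 1e-12

    @pytest.mark.parametrize("table", [[[0, 0], [5, 5]], [[0, 3], [0, 7]]])
    def test_degenerate_margins(self, table):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chisq(table)


class TestProportionSweep:
    def test_toy_duplicate_vs_singleton(self):
        # one family {a,b} both AS; singletons c (AS), d, e, f
        cfg = RunConfig(identity_criteria=(50.0,))
        records = {g: make_record(g, 2 if g in "abc" else 1) for g in "abcdef"}
        parts = sweep_partitions(
            [ParalogPair.make("a", "b", 95, 91)], list("abcdef"), cfg
        )
        as_status = {g: records[g].known_peptide_count > 1 for g in records}
        strata, chisq = proportion_sweep(parts, as_status, records, cfg)
        row = strata.set_index("stratum")
        assert row.loc["duplicate", "as_proportion"] == 1.0
        assert row.loc["singleton", "as_proportion"] == 0.25
        assert row.loc["2-4", "n_genes"] == 2
        assert chisq.iloc[0]["dup_as"] == 2 and chisq.iloc[0]["sing_as"] == 1

    def test_empty_bins_emit_null_rows(self):
        cfg = RunConfig(identity_criteria=(50.0,))
        records = {g: make_record(g, 1) for g in "ab"}
        parts = sweep_partitions([], list("ab"), cfg)
        strata, _ = proportion_sweep(parts, {g: False for g in "ab"}, records, cfg)
        empty = strata[strata["stratum"] == "8+"].iloc[0]
        assert empty["n_genes"] == 0 and math.isnan(empty["as_proportion"])

    def test_count_conservation_over_bins(self):
        cfg = RunConfig(identity_criteria=(30.0, 60.0))
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(40)]
        pairs = {}
        for _ in range(50):
            a, b = rng.choice(genes, 2, replace=False)
            p = ParalogPair.make(str(a), str(b), float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
            pairs.setdefault(p.key, p)
        records = {g: make_record(g, int(rng.integers(1, 4))) for g in genes}
        as_status = {g: records[g].known_peptide_count > 1 for g in genes}
        parts = sweep_partitions(list(pairs.values()), genes, cfg)
        strata, _ = proportion_sweep(parts, as_status, records, cfg)
        bins = strata[strata["stratum"] != "duplicate"]
        assert (bins.groupby("criterion")["n_genes"].sum() == len(genes)).all()


def _grouped_fixture(records):
    """One A_F family {a,b}, one N_F family {c,d}, singletons e (AS), f."""
    part = build_families({("a", "b"), ("c", "d")}, set("abcdef"), criterion=10)
    as_status = {g: records[g].known_peptide_count > 1 for g in records}
    return {10.0: classify_groups(part, as_status)}


class TestKaKsSummary:
    def test_ratio_and_exclusions(self):
        records = {
            "a": make_record("a", 2, ka=0.1, ks=0.2),
            "b": make_record("b", 2, ka=0.3, ks=0.0),   # ks=0 excluded
            "c": make_record("c", 1, ka=None, ks=None),  # missing excluded
            "d": make_record("d", 1, ka=0.2, ks=0.4),
            "e": make_record("e", 2, ka=0.5, ks=1.0),
            "f": make_record("f", 1),
        }
        df = ka_ks_summary(_grouped_fixture(records), records).set_index("group")
        assert df.loc["A_F", "kaks_mean"] == pytest.approx(0.5)
        assert df.loc["A_F", "excluded_kaks_count"] == 1
        assert df.loc["N_F", "excluded_kaks_count"] == 1
        assert df.loc["N_F", "kaks_mean"] == pytest.approx(0.5)
        assert df.loc["N_S", "n_with_kaks"] == 0

    def test_quantile_convention_linear_interpolation(self):
        ratios = [0.1, 0.2, 0.3, 0.4, 0.5]
        records = {
            g: make_record(g, 2, ka=r, ks=1.0)
            for g, r in zip("abcde", ratios)
        } | {"f": make_record("f", 1)}
        part = build_families(
            {("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}, set("abcdef"), criterion=10
        )
        groups = {10.0: classify_groups(part, {g: g != "f" for g in "abcdef"})}
        df = ka_ks_summary(groups, records).set_index("group")
        assert df.loc["A_F", "kaks_q1"] == pytest.approx(0.2)
        assert df.loc["A_F", "kaks_median"] == pytest.approx(0.3)
        assert df.loc["A_F", "kaks_q3"] == pytest.approx(0.4)


class TestFeatureSummary:
    def test_length_mean_and_domain_histogram(self):
        records = {
            "a": make_record("a", 2, length=100, domain_count=0),
            "b": make_record("b", 2, length=300, domain_count=0),
            "c": make_record("c", 1, length=200, domain_count=3),
            "d": make_record("d", 1, length=200),          # no domain count
            "e": make_record("e", 2, length=200, domain_count=2),
            "f": make_record("f", 1, length=200, domain_count=1),
        }
        lengths, domains = feature_summary(_grouped_fixture(records), records)
        lg = lengths.set_index("group")
        assert lg.loc["A_F", "length_mean"] == pytest.approx(200.0)
        af = domains[(domains["group"] == "A_F")]
        assert list(af["domain_count"]) == [0] and af.iloc[0]["frequency"] == 1.0
        nf = domains[domains["group"] == "N_F"]
        assert nf["n_genes"].sum() == 1  # gene d dropped from histogram only

    def test_planted_group_ordering_recovered(self):
        rng = np.random.default_rng(4)
        means = {"A_F": 600, "N_S": 400}
        records = {}
        fam, singles = [], []
        for i in range(60):
            gid = f"a{i:02d}"
            fam.append(gid)
            records[gid] = make_record(gid, 2, length=int(rng.normal(means["A_F"], 40)))
        for i in range(60):
            gid = f"s{i:02d}"
            singles.append(gid)
            records[gid] = make_record(gid, 1, length=int(rng.normal(means["N_S"], 40)))
        qualified = {(fam[0], g) for g in fam[1:]}
        part = build_families(qualified, fam + singles, criterion=10)
        groups = {10.0: classify_groups(part, {g: g.startswith("a") for g in records})}
        lengths, _ = feature_summary(groups, records)
        lg = lengths.set_index("group")
        assert lg.loc["A_F", "length_mean"] > lg.loc["N_S", "length_mean"]


class TestGODistribution:
    def test_exact_one_percent_goes_to_others(self):
        records = {
            "a": make_record("a", 2, go_mf=frozenset({"A", "B"})),
            "b": make_record("b", 2, go_mf=frozenset({"A", "B", "C"})),
            "c": make_record("c", 1),
            "d": make_record("d", 1),
            "e": make_record("e", 2),
            "f": make_record("f", 1),
        }
        groups = _grouped_fixture(records)[10.0]
        # direct construction of incidence boundary via min_proportion on counts:
        df = go_distribution(groups, records, "MF", min_proportion=1 / 5)
        af = df[df["group"] == "A_F"].set_index("category")["proportion"]
        # incidences: A:2, B:2, C:1 of 5; C at exactly 20% -> "others"
        assert set(af.index) == {"A", "B", "others"}
        assert af["others"] == pytest.approx(0.2)

    def test_single_category(self):
        records = {
            g: make_record(g, 2 if g in "abe" else 1,
                           go_mf=frozenset({"binding"}) if g in "ab" else frozenset())
            for g in "abcdef"
        }
        df = go_distribution(_grouped_fixture(records)[10.0], records, "MF")
        af = df[df["group"] == "A_F"]
        assert list(af["category"]) == ["binding"]
        assert af.iloc[0]["proportion"] == 1.0

    def test_unannotated_group_emits_no_rows(self):
        records = {
            g: make_record(g, 2 if g in "abe" else 1,
                           go_bp=frozenset({"signaling"}) if g == "a" else frozenset())
            for g in "abcdef"
        }
        df = go_distribution(_grouped_fixture(records)[10.0], records, "BP")
        assert set(df["group"]) == {"A_F"}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.dictionaries(
            st.sampled_from("abef"),
            st.sets(st.sampled_from("PQRSTUVW"), min_size=1, max_size=5),
            min_size=1,
        )
    )
    def test_proportions_sum_to_one(self, annotation):
        records = {
            g: make_record(
                g, 2 if g in "abe" else 1,
                go_mf=frozenset(annotation.get(g, ())),
            )
            for g in "abcdef"
        }
        df = go_distribution(_grouped_fixture(records)[10.0], records, "MF")
        for _, sub in df.groupby("group"):
            assert sub["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
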