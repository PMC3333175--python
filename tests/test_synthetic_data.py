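"""The planted-structure generator and its closed-form expectations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from dupsplice.cli_report import analyze
from dupsplice.io_tables import RunConfig, read_gene_tables, read_paralog_pairs
from dupsplice.synthetic_data import SyntheticParams, generate, planted_expectations


def small_params(**kw):
    defaults = dict(n_genes=800, seed=13)
    defaults.update(kw)
    return SyntheticParams(**defaults)


def records_from(dataset, tmp_path, config=None):
    dataset.write(tmp_path)
    records = read_gene_tables(
        tmp_path / "genes.tsv", tmp_path / "peptides.tsv", config,
        kaks_path=tmp_path / "kaks.tsv", domain_path=tmp_path / "domains.tsv",
        go_path=tmp_path / "go.tsv",
    )
    pairs = read_paralog_pairs(tmp_path / "pairs.tsv")
    return records, pairs


class TestGenerate:
    def test_deterministic_under_seed(self):
        d1 = generate(small_params(seed=7))
        d2 = generate(small_params(seed=7))
        for name in ("genes", "peptides", "pairs", "kaks", "domains", "go", "isoform_map"):
            pd.testing.assert_frame_equal(getattr(d1, name), getattr(d2, name))
        assert d1.est == d2.est
        assert d1.truth == d2.truth

    def test_different_seeds_differ(self):
        d1 = generate(small_params(seed=1))
        d2 = generate(small_params(seed=2))
        assert not d1.pairs.equals(d2.pairs)

    def test_requested_gene_count_and_id_uniqueness(self):
        d = generate(small_params())
        assert len(d.genes) == 800
        assert d.genes["gene_id"].is_unique

    def test_pairs_satisfy_table_invariants(self):
        # ParalogPair construction validates ranges and rejects self-pairs
        d = generate(small_params())
        pairs = d.paralog_pairs()
        assert len({p.key for p in pairs}) == len(pairs)
        assert all(0 <= p.identity_b <= p.identity_a <= 100 or
                   0 <= p.identity_a <= p.identity_b <= 100 for p in pairs)

    def test_known_peptide_counts_match_as_status(self, tmp_path):
        d = generate(small_params())
        records, _ = records_from(d, tmp_path)
        for gid, info in d.truth["genes"].items():
            expected = info["n_known_peptides"]
            assert records[gid].known_peptide_count == expected
            assert (expected > 1) == info["as_status"]

    def test_degenerate_planting_splits_cleanly(self, tmp_path):
        """All singletons AS, no family gene AS: the pipeline must report
        singleton AS proportion 1.0 and duplicate AS proportion 0.0 at every
        criterion (ages kept very young so every family is fully visible)."""
        params = small_params(
            p_as_singleton=1.0,
            as_family_prob_override=0.0,
            age_min=0.01,
            age_max=0.04,
            identity_sd=0.5,
        )
        d = generate(params)
        records, pairs = records_from(d, tmp_path)
        report = analyze(records, pairs, RunConfig())
        for entry in report.summary["by_criterion"].values():
            assert entry["singleton_as_proportion"] == 1.0
            assert entry["duplicate_as_proportion"] == 0.0


class TestPlantedExpectations:
    def test_flat_model_uniform_across_strata(self):
        p0 = 0.42
        params = small_params(
            p_as_singleton=p0,
            as_beta0=math.log(p0 / (1 - p0)),
            as_beta_age=0.0,
            as_beta_large=0.0,
        )
        exp = planted_expectations(params)
        assert np.allclose(exp["expected_as_proportion"], p0, atol=1e-12)

    def test_visibility_tail_for_pure_pairs(self):
        """Only size-2 families at a pinned age: the expected duplicate share
        is the gene-weighted family fraction times the Gaussian tail
        P(identity > criterion)."""
        params = SyntheticParams(
            n_genes=100,
            family_size_probs=(0.5, 0.5),
            age_min=0.0499,
            age_max=0.0501,
            identity_sd=2.0,
            seed=0,
        )
        cfg = RunConfig(identity_criteria=(90.0,))
        exp = planted_expectations(params, cfg).set_index("stratum")
        q = 1 - norm.cdf((90.0 - 95.0) / 2.0)
        gene_family_share = 2 * 0.5 / (1 * 0.5 + 2 * 0.5)
        assert exp.loc["duplicate", "expected_gene_fraction"] == pytest.approx(
            gene_family_share * q, abs=1e-6
        )

    def test_gene_mass_conserved(self):
        exp = planted_expectations(SyntheticParams())
        bins = exp[exp["stratum"] != "duplicate"]
        for _, sub in bins.groupby("criterion"):
            assert sub["expected_gene_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agrees_with_closed_form(self, tmp_path):
        """Pipeline estimates per (criterion × bin) track the closed form.

        Genes arrive in families sharing one age draw, so per-stratum counts
        are cluster-sampled and the binomial SE understates their spread at
        this cohort size; the allowance is 3 binomial SE for the bulk of the
        cells with a hard 4.5 SE guard on every cell.
        """
        z_all = []
        for seed in (0, 1, 2):
            params = SyntheticParams(n_genes=3000, seed=seed)
            d = generate(params)
            records, pairs = records_from(d, tmp_path / str(seed))
            report = analyze(records, pairs, RunConfig())
            obs = report.tables["proportions"]
            exp = planted_expectations(params)
            m = obs.merge(exp, on=["criterion", "stratum"])
            m = m[m["n_genes"] > 0]
            se = np.sqrt(
                m["expected_as_proportion"] * (1 - m["expected_as_proportion"]) / m["n_genes"]
            )
            z_all.extend(((m["as_proportion"] - m["expected_as_proportion"]) / se).tolist())
        z_all = np.asarray(z_all)
        assert (np.abs(z_all) < 4.5).all()
        assert (np.abs(z_all) > 3).mean() <= 0.10

    def test_family_as_prob_model(self):
        params = SyntheticParams()
        young_small = params.family_as_prob(3, 0.0)
        old_small = params.family_as_prob(3, 0.8)
        old_large = params.family_as_prob(9, 0.8)
        assert young_small == pytest.approx(float(expit(params.as_beta0)))
        assert old_small > young_small          # AS gained with duplication age
        assert old_large < old_small            # large-family penalty
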