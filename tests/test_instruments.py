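import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrsumstats.gwas_io import LdTable
from mrsumstats.instruments import (SelectionConfig, apply_exclusions,
                                    f_statistic, filter_maf,
                                    instrument_diagnostics, ld_clump,
                                    select_significant, steiger_test,
                                    variance_explained)
from mrsumstats.harmonize import harmonize, usable
from mrsumstats.synthetic import SimulationConfig, simulate_two_sample

from conftest import instrument_panel, make_instrument, make_record


class TestSelectSignificant:
    def test_threshold_is_strict(self):
        recs = [make_record("rs1", pval=1e-9), make_record("rs2", pval=5e-8),
                make_record("rs3", pval=1e-7)]
        assert [r.snp_id for r in select_significant(recs, 5e-8)] == ["rs1"]

    def test_threshold_one_keeps_everything(self):
        recs = [make_record(f"rs{i}", pval=0.99) for i in range(5)]
        assert select_significant(recs, 1.0) == recs

    def test_matches_brute_force_on_simulated_records(self):
        rng = np.random.default_rng(42)
        recs = [make_record(f"rs{i}", pval=float(p))
                for i, p in enumerate(10 ** rng.uniform(-12, 0, size=20))]
        survivors = select_significant(recs, 5e-8)
        assert [r.snp_id for r in survivors] == \
            [r.snp_id for r in recs if r.pval < 5e-8]


class TestFilterMaf:
    def test_boundary_is_strict_and_symmetric(self):
        recs = [make_record("rs1", eaf=0.05), make_record("rs2", eaf=0.96),
                make_record("rs3", eaf=0.051), make_record("rs4", eaf=0.5)]
        assert [r.snp_id for r in filter_maf(recs, 0.05)] == ["rs3", "rs4"]

    def test_missing_eaf_retained(self):
        recs = [make_record("rs1", eaf=None), make_record("rs2", eaf=0.01)]
        assert [r.snp_id for r in filter_maf(recs, 0.05)] == ["rs1"]

    def test_matches_hand_enumeration(self):
        eafs = [0.02, 0.06, 0.5, 0.94, 0.97, None]
        recs = [make_record(f"rs{i}", eaf=e) for i, e in enumerate(eafs)]
        kept = {r.snp_id for r in filter_maf(recs, 0.05)}
        assert kept == {"rs1", "rs2", "rs3", "rs5"}


class TestLdClump:
    def test_dominant_index_absorbs_neighbour(self):
        recs = [make_record("rs1", pos=1000, pval=1e-20),
                make_record("rs2", pos=2000, pval=1e-10)]
        ld = LdTable([("rs1", "rs2", 0.5)])
        assert [r.snp_id for r in ld_clump(recs, ld)] == ["rs1"]

    def test_different_chromosomes_both_survive(self):
        recs = [make_record("rs1", chrom="1", pval=1e-20),
                make_record("rs2", chrom="2", pval=1e-10)]
        ld = LdTable([("rs1", "rs2", 0.99)])
        assert len(ld_clump(recs, ld)) == 2

    def test_window_gate(self):
        cfg = SelectionConfig(clump_window_kb=10)
        far = [make_record("rs1", pos=1000, pval=1e-20),
               make_record("rs2", pos=1000 + 10_001, pval=1e-10)]
        ld = LdTable([("rs1", "rs2", 0.9)])
        assert len(ld_clump(far, ld, cfg)) == 2          # just outside
        near = [make_record("rs1", pos=1000, pval=1e-20),
                make_record("rs2", pos=1000 + 10_000, pval=1e-10)]
        assert len(ld_clump(near, ld, cfg)) == 1          # closed boundary

    def test_r2_threshold_is_strict(self):
        recs = [make_record("rs1", pos=1000, pval=1e-20),
                make_record("rs2", pos=2000, pval=1e-10)]
        ld = LdTable([("rs1", "rs2", 0.001)])
        assert len(ld_clump(recs, ld, SelectionConfig(clump_r2=0.001))) == 2

    def test_eight_snp_panel_matches_exhaustive_greedy(self):
        """Hand-simulated greedy recursion on a fully specified LD panel.

        Order of index picks by p: rs3 (1e-30) claims rs1, rs5; rs7 (1e-22)
        claims rs8; rs2 (1e-15) claims nothing in LD; rs4 (1e-12) claims rs6.
        """
        recs = [
            make_record("rs1", pos=1_000, pval=1e-10),
            make_record("rs2", pos=2_000, pval=1e-15),
            make_record("rs3", pos=3_000, pval=1e-30),
            make_record("rs4", pos=4_000, pval=1e-12),
            make_record("rs5", pos=5_000, pval=1e-20),
            make_record("rs6", pos=6_000, pval=1e-11),
            make_record("rs7", pos=7_000, pval=1e-22),
            make_record("rs8", pos=8_000, pval=1e-9),
        ]
        ld = LdTable([
            ("rs3", "rs1", 0.4), ("rs3", "rs5", 0.9), ("rs3", "rs2", 0.0005),
            ("rs7", "rs8", 0.3), ("rs7", "rs5", 0.8),
            ("rs4", "rs6", 0.2), ("rs2", "rs4", 0.0)])
        kept = {r.snp_id for r in ld_clump(recs, ld)}
        assert kept == {"rs3", "rs7", "rs2", "rs4"}

    def test_clumping_is_idempotent(self):
        rng = np.random.default_rng(3)
        recs = [make_record(f"rs{i}", pos=1000 * i,
                            pval=float(10 ** rng.uniform(-30, -8)))
                for i in range(30)]
        pairs = [(f"rs{i}", f"rs{j}", float(rng.uniform(0, 1)))
                 for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.2]
        ld = LdTable(pairs)
        once = ld_clump(recs, ld)
        assert ld_clump(once, ld) == once

    def test_matches_independent_greedy_oracle(self):
        """Brute-force greedy re-implementation agrees, and every displaced
        SNP has p >= its own clump's index SNP."""
        rng = np.random.default_rng(4)
        recs = [make_record(f"rs{i}", pos=1000 * i,
                            pval=float(10 ** rng.uniform(-30, -8)))
                for i in range(20)]
        ld = LdTable([(f"rs{i}", f"rs{j}", 0.8)
                      for i in range(20) for j in range(i + 1, 20)
                      if abs(i - j) <= 3])
        # independent oracle: repeated min-p scan over a shrinking pool
        pool = {r.snp_id: r for r in recs}
        oracle_kept, claimer = [], {}
        while pool:
            idx = min(pool.values(), key=lambda r: (r.pval, r.pos, r.snp_id))
            oracle_kept.append(idx.snp_id)
            del pool[idx.snp_id]
            for other in list(pool.values()):
                if (other.chrom == idx.chrom
                        and abs(other.pos - idx.pos) <= 10_000_000
                        and ld.r2(idx.snp_id, other.snp_id) > 0.001):
                    claimer[other.snp_id] = idx
                    del pool[other.snp_id]
        kept = ld_clump(recs, ld)
        assert {r.snp_id for r in kept} == set(oracle_kept)
        by_id = {r.snp_id: r for r in recs}
        for snp_id, idx in claimer.items():
            assert idx.pval <= by_id[snp_id].pval


class TestVarianceExplained:
    def test_maximal_heterozygosity(self):
        assert variance_explained(0.5, 1.0) == 0.5

    @pytest.mark.parametrize("eaf,beta", [(0.3, 0.0), (0.0, 1.0), (1.0, 1.0)])
    def test_degenerate_cases_are_zero(self, eaf, beta):
        assert variance_explained(eaf, beta) == 0.0

    def test_direct_arithmetic(self):
        assert variance_explained(0.3, 0.02) == pytest.approx(1.68e-4)

    def test_missing_eaf_returns_none(self):
        assert variance_explained(None, 0.5) is None


class TestFStatistic:
    def test_paper_scale_inputs(self):
        # N, K and total R² at the scale of a ~half-million-sample GWAS
        assert f_statistic(454_874, 462, 0.028955) == pytest.approx(29.3289,
                                                                    abs=0.01)

    def test_zero_r2_gives_zero(self):
        assert f_statistic(1000, 5, 0.0) == 0.0

    def test_direct_arithmetic(self):
        assert f_statistic(103, 1, 0.5) == pytest.approx(101.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(5, 4, 0.1)
        with pytest.raises(ValueError):
            f_statistic(100, 1, 1.0)

    @given(st.floats(0.001, 0.3), st.floats(0.001, 0.3),
           st.integers(1000, 10_000), st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_r2_and_n(self, r2a, r2b, n, k):
        lo, hi = sorted((r2a, r2b))
        if hi - lo > 1e-12:
            assert f_statistic(n, k, lo) < f_statistic(n, k, hi)
        assert f_statistic(n, k, lo) < f_statistic(n + 100, k, lo)


class TestSteiger:
    def test_dominant_exposure_direction(self):
        ins = instrument_panel(bx=[0.1] * 5, by=[0.001] * 5, sy=[0.01] * 5,
                               n_exp=100_000.0, n_out=100_000.0)
        res = steiger_test(ins)
        assert res.direction is True
        assert res.pval < 1e-6

    def test_equal_r2_gives_p_one(self):
        ins = instrument_panel(bx=[0.1, 0.2], by=[0.1, 0.2], sy=[0.01, 0.01])
        res = steiger_test(ins)
        assert res.direction is False  # strict comparison, tie is "not supported"
        assert res.pval == pytest.approx(1.0)

    def test_no_usable_snp_reports_undefined(self):
        ins = instrument_panel(bx=[0.1], by=[0.01], sy=[0.01], eaf_exp=None)
        res = steiger_test(ins)
        assert res.direction is None and res.pval is None

    def test_simulated_true_direction_recovered(self):
        hits = 0
        for rep in range(200):
            cfg = SimulationConfig(n_snps=30, theta=0.1, gamma_sd=0.05,
                                   n_exp=100_000, n_out=100_000, seed=900 + rep)
            exp, out, _, _ = simulate_two_sample(cfg)
            res = steiger_test(usable(harmonize(exp, out)))
            hits += bool(res.direction)
        assert hits >= 190  # >= 95% of replicates


class TestExclusionsAndDiagnostics:
    def test_flag_bookkeeping_counts(self):
        ins = [make_instrument(f"rs{i}") for i in range(5)]
        flagged, counts = apply_exclusions(ins, confounder_ids={"rs1", "rs3"})
        assert counts["excluded_confounder"] == 2
        assert len(usable(flagged)) == 3

    def test_empty_sets_identity(self):
        ins = [make_instrument(f"rs{i}") for i in range(4)]
        flagged, counts = apply_exclusions(ins)
        assert flagged == ins and sum(counts.values()) == 0

    def test_candidate_minus_exclusion_arithmetic(self):
        """Workflow audit: candidates − confounders − outliers = analysable."""
        ins = [make_instrument(f"rs{i}") for i in range(521)]
        conf = {f"rs{i}" for i in range(46)}
        flagged, counts = apply_exclusions(ins, confounder_ids=conf)
        assert len(usable(flagged)) == 521 - 46
        flagged2, counts2 = apply_exclusions(flagged,
                                             presso_outlier_ids={"rs100"})
        assert len(usable(flagged2)) == 521 - 46 - 1
        assert counts2["excluded_presso_outlier"] == 1

    def test_unknown_ids_ignored(self):
        ins = [make_instrument("rs1")]
        flagged, counts = apply_exclusions(ins, confounder_ids={"rs999"})
        assert usable(flagged) == ins

    def test_total_r2_additive_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        ins = instrument_panel(bx=rng.normal(0, 0.05, 10),
                               by=rng.normal(0, 0.01, 10),
                               sy=np.full(10, 0.01))
        d1 = instrument_diagnostics(ins, run_steiger=False)
        d2 = instrument_diagnostics(ins[::-1], run_steiger=False)
        assert d1.total_r2 == pytest.approx(sum(d1.per_snp_r2.values()))
        assert d1.total_r2 == pytest.approx(d2.total_r2)
        assert d1.f_statistic == pytest.approx(d2.f_statistic)

    def test_per_snp_f_uses_k_equal_one(self):
        ins = instrument_panel(bx=[0.1], by=[0.01], sy=[0.01],
                               eaf_exp=0.3, n_exp=10_000.0)
        d = instrument_diagnostics(ins, run_steiger=False)
        r2 = 2 * 0.3 * 0.7 * 0.1**2
        assert d.per_snp_f["rs1"] == pytest.approx(
            (10_000 - 2) / 1 * r2 / (1 - r2))
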