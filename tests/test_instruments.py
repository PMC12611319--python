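import numpy as np
import pytest

from medimr import io as gio
from medimr.instruments import (apply_blacklist, f_statistic, filter_by_pvalue,
                                ld_clump, select_instruments, snp_r2)
from medimr.records import LDReference
from medimr.simulate import fixture_config, simulate_mediation_gwas

from conftest import make_record, make_set


class TestPvalueFilter:
    def test_strict_threshold(self):
        s = make_set([make_record(snp_id="rs1", pvalue=1e-6, pos=1),
                      make_record(snp_id="rs2", pvalue=1e-4, pos=2),
                      make_record(snp_id="rs3", pvalue=0.2, pos=3)])
        assert filter_by_pvalue(s, 5e-5).snp_ids == ["rs1"]

    def test_threshold_one_keeps_all(self, small_stats):
        assert len(filter_by_pvalue(small_stats, 1.0)) == len(small_stats)

    def test_count_matches_truth_file_recount(self):
        cfg = fixture_config("strong_mediation")
        exposure, *_ = simulate_mediation_gwas(cfg)
        kept = filter_by_pvalue(exposure, 5e-5)
        hand = int((exposure.frame["pvalue"] < 5e-5).sum())
        assert len(kept) == hand

    @pytest.mark.parametrize("tight,loose", [(5e-6, 5e-5), (1e-8, 1e-3)])
    def test_tightening_never_increases_count(self, tight, loose):
        cfg = fixture_config("strong_mediation")
        exposure, *_ = simulate_mediation_gwas(cfg)
        assert len(filter_by_pvalue(exposure, tight)) <= \
            len(filter_by_pvalue(exposure, loose))


def one_block_stats(pvals, positions=None, chroms=None):
    positions = positions or [1000 + i for i in range(len(pvals))]
    chroms = chroms or ["1"] * len(pvals)
    recs = [make_record(snp_id=f"rs{i}", chrom=c, pos=p, pvalue=pv)
            for i, (pv, p, c) in enumerate(zip(pvals, positions, chroms))]
    return make_set(recs)


class TestClumping:
    def test_correlated_block_keeps_most_significant(self):
        s = one_block_stats([1e-8, 1e-7, 1e-6])
        mat = np.full((3, 3), np.sqrt(0.5))
        np.fill_diagonal(mat, 1.0)
        ld = LDReference([(["rs0", "rs1", "rs2"], mat)])
        assert ld_clump(s, ld).snp_ids == ["rs0"]

    def test_cross_chromosome_pairs_both_kept(self):
        s = one_block_stats([1e-8, 1e-7], chroms=["1", "2"])
        mat = np.array([[1.0, 0.95], [0.95, 1.0]])
        ld = LDReference([(["rs0", "rs1"], mat)])
        assert set(ld_clump(s, ld).snp_ids) == {"rs0", "rs1"}

    def test_outside_window_both_kept(self):
        s = one_block_stats([1e-8, 1e-7], positions=[1000, 1000 + 15_000_000])
        mat = np.array([[1.0, 0.95], [0.95, 1.0]])
        ld = LDReference([(["rs0", "rs1"], mat)])
        assert set(ld_clump(s, ld).snp_ids) == {"rs0", "rs1"}

    def test_idempotent_and_pairwise_r2_guarantee(self):
        cfg = fixture_config("strong_mediation")
        exposure, _, _, ld, _ = simulate_mediation_gwas(cfg)
        once = ld_clump(exposure, ld)
        twice = ld_clump(once, ld)
        assert once.snp_ids == twice.snp_ids
        ids = once.snp_ids
        frame = once.frame.set_index("snp_id")
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if frame.loc[a, "chrom"] != frame.loc[b, "chrom"]:
                    continue
                if abs(frame.loc[a, "pos"] - frame.loc[b, "pos"]) > 1e7:
                    continue
                assert ld.r2(a, b) < 0.001


class TestSnpR2AndF:
    def test_r2_zero_beta(self):
        assert snp_r2(make_record(eaf=0.5, beta=0.0)) == 0.0

    def test_r2_direct_evaluation(self):
        assert snp_r2(make_record(eaf=0.5, beta=0.2)) == pytest.approx(0.02)

    def test_r2_z_variant_for_missing_eaf(self):
        rec = make_record(eaf=None, beta=0.2, se=0.02, n_total=1000)
        expected = 0.04 / (0.04 + 1000 * 0.0004)
        assert snp_r2(rec, method="z") == pytest.approx(expected)
        with pytest.raises(ValueError, match="eaf"):
            snp_r2(rec)

    def test_f_statistic_printed_formula(self):
        assert f_statistic(0.01, 7174, 10) == pytest.approx(
            (0.01 / 0.99) * (7163 / 10), rel=1e-12)
        assert f_statistic(0.01, 7174, 10) == pytest.approx(7.235, abs=0.001)
        assert f_statistic(0.05, 8299, 20) == pytest.approx(21.78, abs=0.01)
        assert f_statistic(0.0, 7174, 10) == 0.0

    def test_f_requires_enough_samples(self):
        with pytest.raises(ValueError):
            f_statistic(0.01, 11, 10)

    def test_sum_r2_tracks_generated_variance(self):
        cfg = fixture_config("strong_mediation")
        exposure, *_, truth = simulate_mediation_gwas(cfg)
        t = truth.per_snp.set_index("snp_id")
        est = sum(snp_r2(r) for r in exposure.records())
        true_r2 = float(np.sum(2 * t["maf"] * (1 - t["maf"]) * t["gamma"] ** 2))
        noise_r2 = float(np.sum(2 * t["maf"] * (1 - t["maf"]) * t["se_exp"] ** 2))
        assert est == pytest.approx(true_r2 + noise_r2, rel=0.25)


class TestBlacklist:
    def test_empty_is_identity(self, small_stats):
        out = apply_blacklist(small_stats, set())
        assert out.snp_ids == small_stats.snp_ids

    def test_removes_listed_and_ignores_absent(self, small_stats):
        log = gio.ExclusionLog()
        out = apply_blacklist(small_stats, {"rs0", "rs2", "rs_absent"}, log=log)
        assert len(out) == len(small_stats) - 2
        assert all(r["reason"] == "confounder_blacklist" for r in log.rows)


class TestSelectInstruments:
    def test_weak_set_rejected_by_f_filter(self):
        # tiny effects: per-SNP R^2 so small that aggregate F <= 10
        recs = [make_record(snp_id=f"rs{i}", pos=1000 + i * 100, beta=0.01,
                            se=0.003, pvalue=1e-5, n_total=300)
                for i in range(10)]
        s = make_set(recs)
        ld = LDReference([])
        kept, inst = select_instruments(s, ld, p_threshold=5e-4)
        assert inst is None

    def test_flow_conservation_through_selection(self):
        cfg = fixture_config("strong_mediation")
        exposure, _, _, ld, _ = simulate_mediation_gwas(cfg)
        log = gio.ExclusionLog()
        kept, inst = select_instruments(exposure, ld, blacklist={"rs100000"},
                                        log=log)
        assert inst is not None
        assert len(kept) + len(log) == len(exposure)
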