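"""Instrument selection, clumping, strength filtering, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.instruments import (
    HarmonizedSet,
    clump,
    exclude_confounder_snps,
    f_statistic,
    filter_weak,
    harmonize,
    harmonize_multi,
    make_instruments,
    select_instruments,
)
from mrkit.simulate import ScenarioTruth, generate_pair
from mrkit.sumstats import LDTable, SummaryTable

from conftest import make_assoc


class TestSelect:
    def test_threshold_filters_and_preserves_order(self):
        rows = [make_assoc("a", pval=1e-9), make_assoc("b", pval=1e-7)]
        table = SummaryTable("t", "binary", rows)
        assert [r.variant_id
                for r in select_instruments(table, 5e-8)] == ["a"]
        assert [r.variant_id
                for r in select_instruments(table, 5e-6)] == ["a", "b"]

    def test_vacuous_threshold_keeps_everything(self, three_row_table):
        kept = select_instruments(three_row_table, 0.9999999)
        assert len(kept) == len(three_row_table)


class TestClump:
    def test_ld_partner_of_stronger_hit_removed(self):
        a = make_assoc("a", chrom="1", pos=1000, pval=1e-10)
        b = make_assoc("b", chrom="1", pos=2000, pval=1e-9)
        ld = LDTable({("a", "b"): 0.9})
        kept = clump([a, b], ld)
        assert [r.variant_id for r in kept] == ["a"]

    def test_same_ld_outside_window_kept(self):
        a = make_assoc("a", chrom="1", pos=1000, pval=1e-10)
        b = make_assoc("b", chrom="1", pos=20_001_000, pval=1e-9)
        ld = LDTable({("a", "b"): 0.9})
        assert len(clump([a, b], ld)) == 2

    def test_matches_greedy_oracle_on_random_block(self, rng):
        # 20 variants, random p and LD; re-evaluate every accept/reject
        # decision of the greedy definition independently
        n = 20
        cands = [make_assoc(f"v{i}", chrom="1", pos=1000 + i * 1000,
                            pval=float(rng.uniform(1e-12, 1e-6)))
                 for i in range(n)]
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    ld.set(f"v{i}", f"v{j}", float(rng.uniform(0, 1)))
        kept = {r.variant_id for r in clump(cands, ld, 0.001, 10_000_000)}

        accepted = []
        for cand in sorted(cands, key=lambda r: (r.pval, r.variant_id)):
            if all(not (k.chrom == cand.chrom
                        and abs(k.pos - cand.pos) <= 10_000_000
                        and ld.r2(k.variant_id, cand.variant_id) >= 0.001)
                   for k in accepted):
                accepted.append(cand)
        assert kept == {r.variant_id for r in accepted}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_is_independent_set(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        cands = [make_assoc(f"v{i}", chrom="1", pos=1000 + i * 500,
                            pval=float(rng.uniform(1e-12, 1e-6)))
                 for i in range(n)]
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    ld.set(f"v{i}", f"v{j}", float(rng.uniform(0, 0.05)))
        kept = clump(cands, ld, r2_max=0.001)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not (a.chrom == b.chrom
                            and abs(a.pos - b.pos) <= 10_000_000
                            and ld.r2(a.variant_id, b.variant_id) >= 0.001)


class TestFStatistic:
    def test_wald_square(self):
        assert f_statistic(make_assoc(beta=0.1, se=0.02)) == pytest.approx(25.0)
        assert f_statistic(make_assoc(beta=0.0, se=0.02, pval=1.0)) == 0.0

    def test_agrees_with_squared_z_from_pvalue(self, rng):
        # rows whose p was computed from beta/se: F should equal the
        # inverse-normal z squared to within numerical precision
        for _ in range(20):
            beta = rng.normal(0, 0.1)
            se = rng.uniform(0.005, 0.05)
            rec = make_assoc(beta=beta, se=se)
            z = stats.norm.isf(rec.pval / 2)
            assert f_statistic(rec) == pytest.approx(z ** 2, rel=0.05)


class TestFilterWeak:
    def test_weak_instruments_dropped_and_mean_reported(self):
        insts = make_instruments([
            make_assoc("a", beta=0.1, se=0.02),    # F = 25
            make_assoc("b", beta=0.03, se=0.01),   # F = 9
        ])
        kept, mean_f = filter_weak(insts, f_min=10)
        assert [i.variant_id for i in kept] == ["a"]
        assert mean_f == pytest.approx(25.0)

    def test_all_weak_gives_empty_set(self):
        insts = make_instruments([make_assoc("a", beta=0.03, se=0.01)])
        kept, mean_f = filter_weak(insts, f_min=10)
        assert kept == [] and np.isnan(mean_f)

    def test_zero_threshold_is_identity(self):
        insts = make_instruments([make_assoc("a"), make_assoc("b")])
        kept, _ = filter_weak(insts, f_min=0)
        assert len(kept) == 2


class TestConfounderExclusion:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "trait", "pval"])

    def test_genomewide_confounder_hit_removed(self):
        insts = make_instruments([make_assoc("a"), make_assoc("b")])
        conf = self._table([("a", "smoking", 1e-9)])
        kept, removed = exclude_confounder_snps(insts, conf)
        assert [i.variant_id for i in kept] == ["b"]
        assert removed == [("a", "confounder:smoking")]

    def test_subthreshold_hit_kept(self):
        insts = make_instruments([make_assoc("a")])
        conf = self._table([("a", "smoking", 1e-6)])
        kept, removed = exclude_confounder_snps(insts, conf)
        assert len(kept) == 1 and removed == []

    def test_empty_table_is_identity(self):
        insts = make_instruments([make_assoc("a")])
        kept, removed = exclude_confounder_snps(insts, self._table([]))
        assert len(kept) == 1 and removed == []


class TestHarmonize:
    def _outcome(self, rows):
        return SummaryTable("out", "binary", rows)

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = [make_assoc("v", ea="A", oa="G", beta=0.10)]
        out = self._outcome([make_assoc("v", ea="G", oa="A", beta=-0.05,
                                        eaf=0.7)])
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == pytest.approx(0.05)
        assert h.rows.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        exp = [make_assoc("v", ea="A", oa="T", eaf=0.50)]
        out = self._outcome([make_assoc("v", ea="A", oa="T", eaf=0.50)])
        h = harmonize(exp, out)
        assert len(h) == 0
        assert h.dropped == [("v", "palindromic_ambiguous")]

    def test_complement_then_swap(self):
        # outcome reported on the other strand with swapped allele roles
        exp = [make_assoc("v", ea="A", oa="G", beta=0.10)]
        out = self._outcome([make_assoc("v", ea="C", oa="T", beta=-0.05)])
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_informative_palindromic_oriented_by_frequency(self):
        # frequencies on opposite sides of 0.5 imply a strand flip
        exp = [make_assoc("v", ea="A", oa="T", eaf=0.10, beta=0.2)]
        out = self._outcome([make_assoc("v", ea="A", oa="T", eaf=0.88,
                                        beta=0.07)])
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == pytest.approx(-0.07)

    def test_missing_and_irreconcilable_variants_dropped(self):
        exp = [make_assoc("gone", ea="A", oa="G"),
               make_assoc("bad", ea="A", oa="G")]
        out = self._outcome([make_assoc("bad", ea="A", oa="C")])
        h = harmonize(exp, out)
        assert dict(h.dropped) == {"gone": "missing_in_outcome",
                                   "bad": "allele_mismatch"}

    def test_idempotent_on_already_harmonized_set(self):
        exp = [make_assoc("v1", ea="A", oa="G", beta=0.10, eaf=0.2),
               make_assoc("v2", ea="C", oa="G", beta=0.15, eaf=0.1)]
        out = self._outcome([
            make_assoc("v1", ea="G", oa="A", beta=-0.05, eaf=0.75),
            make_assoc("v2", ea="C", oa="G", beta=0.08, eaf=0.12)])
        h1 = harmonize(exp, out)
        # rebuild an outcome table from the harmonized rows (now expressed
        # on the exposure's alleles) and harmonize again
        re_rows = []
        for exp_rec in exp:
            row = h1.rows[h1.rows.variant_id == exp_rec.variant_id].iloc[0]
            re_rows.append(make_assoc(
                exp_rec.variant_id, ea=exp_rec.effect_allele,
                oa=exp_rec.other_allele, beta=float(row.beta_out),
                se=float(row.se_out), eaf=float(row.eaf_out)))
        h2 = harmonize(exp, self._outcome(re_rows))
        assert np.allclose(h1.rows.beta_out, h2.rows.beta_out)
        assert np.allclose(h1.rows.eaf_out, h2.rows.eaf_out)
        assert h2.dropped == []

    def test_multi_exposure_joint_harmonization_complete_case(self):
        e1 = SummaryTable("e1", "quantitative",
                          [make_assoc("v1", beta=0.1),
                           make_assoc("v2", beta=0.2)])
        e2 = SummaryTable("e2", "quantitative",
                          [make_assoc("v1", beta=0.05)])  # v2 missing
        out = self._outcome([make_assoc("v1", beta=0.02),
                             make_assoc("v2", beta=0.04)])
        mh = harmonize_multi(
            {"e1": list(e1), "e2": list(e2)}, {"e1": e1, "e2": e2}, out)
        assert mh.variant_ids == ["v1"]
        assert ("v2", "missing_in_e2") in mh.dropped
        assert mh.exposure_betas.shape == (1, 2)


class TestEndToEndSelection:
    def test_recovers_planted_instruments_from_generated_tables(self):
        truth = ScenarioTruth(theta=0.2, n_snp=30, seed=99)
        exposure, _, ld, info = generate_pair(truth)
        selected = select_instruments(exposure, 5e-8)
        kept = clump(selected, ld, 0.001, 10_000_000)
        kept_ids = {r.variant_id for r in kept}
        # exactly the planted index variants whose observed association
        # reaches the threshold; satellite tags are always weaker and
        # fillers are null
        expected = {r.variant_id for r in selected
                    if r.variant_id in info["instrument_ids"]}
        assert kept_ids == expected
        assert len(kept_ids) >= 25  # most planted instruments re-detected
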