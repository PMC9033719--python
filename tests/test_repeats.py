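"""Repeat genotyping, locus summary table, depth-based SV calls, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from haplocharter.cohort import CohortConfig, generate_cohort
from haplocharter import repeats as rp

from conftest import make_matrix


def pheno(samples, protein):
    return pd.DataFrame({
        "sample_id": samples,
        "protein": protein,
        "oil": [20.0] * len(samples),
        "dclass": ["landrace"] * len(samples),
    })


class TestClassifyInsertion:
    @pytest.mark.parametrize("seq,annot,copies", [
        ("CAACAACAA", rp.ANNOT_CIF, 3),     # 9 bp pure repeat
        ("CAACA", rp.ANNOT_FSV, 0),          # 5 bp: frameshift
        ("CAACAT", rp.ANNOT_DIF, 0),         # 6 bp, not a pure repeat
        ("CAA", rp.ANNOT_CIF, 1),
        ("TTTTTT", rp.ANNOT_DIF, 0),
    ])
    def test_annotation_cases(self, seq, annot, copies):
        a = rp.classify_insertion(seq)
        assert a.annotation == annot
        assert a.caa_copies_inserted == copies
        if copies:
            assert a.total_copies == 5 + copies

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_annotation_is_total_over_insertions(self, seq):
        a = rp.classify_insertion(seq)
        assert a.annotation in (rp.ANNOT_CIF, rp.ANNOT_DIF, rp.ANNOT_FSV)
        # frame rule: FSV iff length not divisible by 3
        assert (a.annotation == rp.ANNOT_FSV) == (len(seq) % 3 != 0)
        # pure repeat iff inserted length is 3 * copies
        if a.is_pure_repeat:
            assert len(seq) == 3 * a.caa_copies_inserted


class TestGenotypeRepeat:
    def _matrix(self):
        # alleles: 1 = +9bp CAAx3 (8 total), 2 = +6bp CAAx2, 3 = +5bp FSV
        return make_matrix([(
            31_727_019, "A", ["ACAACAACAA", "ACAACAA", "ACAACA"],
            [(1, 1), (0, 2), (1, 2), (0, 0), (-1, 1), (3, 3)],
        )])

    def test_category_assignment(self):
        geno = rp.genotype_repeat(self._matrix(), 31_727_019)
        cats = {g.sample: g.category for g in geno}
        assert cats == {
            "S1": rp.CAT_HOM_REPEAT,
            "S2": rp.CAT_SINGLE_REPEAT,
            "S3": rp.CAT_HET_REPEATS,
            "S4": rp.CAT_REFERENCE,
            "S5": rp.CAT_MISSING,
            "S6": rp.CAT_OTHER,
        }
        hom = next(g for g in geno if g.sample == "S1")
        assert hom.hom_copies == 8
        assert hom.alleles[0].annotation == rp.ANNOT_CIF

    def test_anchor_mismatch_rejected(self):
        m = make_matrix([(100, "A", ["GCAA"], [(0, 1)])])
        with pytest.raises(ValueError, match="anchor"):
            rp.genotype_repeat(m, 100)

    def test_absent_locus_rejected(self):
        m = make_matrix([(100, "A", ["G"], [(0, 1)])])
        with pytest.raises(ValueError, match="absent"):
            rp.genotype_repeat(m, 200)


class TestRepeatSummary:
    def test_reference_panel_rows_reaggregate_exactly(self):
        s = rp.aggregate_repeat_rows(rp.REFERENCE_PANEL_REPEAT_ROWS)
        assert s.total_n == 985
        assert s.total_mean == pytest.approx(44.54, abs=0.005)

    def test_reference_panel_percent_increase(self):
        s = rp.aggregate_repeat_rows(rp.REFERENCE_PANEL_REPEAT_ROWS)
        assert s.pct_increase == pytest.approx(7.9, abs=0.15)

    def test_include_other_toggle_changes_contrast(self):
        s0 = rp.aggregate_repeat_rows(rp.REFERENCE_PANEL_REPEAT_ROWS)
        s1 = rp.aggregate_repeat_rows(rp.REFERENCE_PANEL_REPEAT_ROWS,
                                      include_other_in_increase=True)
        assert s1.pct_increase < s0.pct_increase

    def test_all_reference_cohort_flagged(self):
        m = make_matrix([(100, "A", ["ACAA"], [(0, 0), (0, 0)])])
        geno = rp.genotype_repeat(m, 100)
        s = rp.repeat_summary(geno, pheno(["S1", "S2"], [44.0, 45.0]))
        assert s.pct_increase is None
        assert s.total_n == 2

    def test_synthetic_summary_counts_are_complete(self, default_cohort):
        geno = rp.genotype_repeat(
            default_cohort.matrix, default_cohort.config.repeat_locus
        )
        s = rp.repeat_summary(geno, default_cohort.phenotypes)
        assert s.total_n == default_cohort.matrix.n_samples
        assert int(s.table["n"].sum()) == s.total_n
        # carriers are protein-elevated, so the contrast is positive
        assert s.pct_increase > 0


class TestCallSV:
    def test_synthetic_deletion_recovered_exactly(self, default_cohort):
        cfg = default_cohort.config
        sv = rp.call_sv_from_depth(
            default_cohort.depth, (cfg.deletion_start, cfg.deletion_end)
        )
        assert (sv.start, sv.end) == (cfg.deletion_start, cfg.deletion_end)
        assert sv.length_bp == 304
        truth = dict(zip(default_cohort.truth.samples,
                         default_cohort.truth.deletion_present))
        called = {s: p for s, p in sv.presence.items() if p is not None}
        # precision = recall = 1 against the generator truth
        assert all(called[s] == bool(truth[s]) for s in called)
        assert sum(called.values()) == sum(truth.values())

    def test_flat_track_is_absent(self):
        t = rp.DepthTrack("S1", "Gm20", 900, np.full(1200, 30, dtype=np.int32))
        sv = rp.call_sv_from_depth([t], (1000, 1500))
        assert sv.presence["S1"] is False

    def test_low_background_is_uncallable_not_absent(self):
        t = rp.DepthTrack("S1", "Gm20", 900, np.full(1200, 3, dtype=np.int32))
        sv = rp.call_sv_from_depth([t], (1000, 1500))
        assert sv.presence["S1"] is None

    def test_short_track_rejected(self):
        t = rp.DepthTrack("S1", "Gm20", 1100, np.full(100, 30, dtype=np.int32))
        with pytest.raises(ValueError, match="cover"):
            rp.call_sv_from_depth([t], (1000, 1500))

    def test_depth_bed_roundtrip(self, tmp_path, default_cohort):
        tracks = default_cohort.depth[:5]
        path = rp.write_depth_bed(tracks, tmp_path / "d.bed")
        back = {t.sample: t for t in rp.read_depth_bed(path)}
        for t in tracks:
            np.testing.assert_array_equal(back[t.sample].depth, t.depth)
            assert back[t.sample].start == t.start

    def test_deletion_carrier_bed_rows_are_low_depth(self, tmp_path,
                                                     default_cohort):
        cfg = default_cohort.config
        truth = dict(zip(default_cohort.truth.samples,
                         default_cohort.truth.deletion_present))
        carriers = [t for t in default_cohort.depth if truth[t.sample]][:3]
        path = rp.write_depth_bed(carriers, tmp_path / "d.bed")
        rows = pd.read_csv(path, sep="\t", header=None,
                           names=["chrom", "s", "e", "depth", "sample"])
        inside = rows[(rows.s >= cfg.deletion_start - 1)
                      & (rows.e <= cfg.deletion_end - 1)]
        assert len(inside) > 0
        assert (inside.depth <= 1).all()


class TestConcordance:
    def test_perfect_coinheritance_gives_full_concordance(self):
        res = generate_cohort(CohortConfig(
            seed=14, missing_rate=0.0, repeat_resample_rate=0.0,
            n_wild=60, n_landrace=100, n_old_cultivar=5, n_modern_cultivar=15,
        ))
        geno = rp.genotype_repeat(res.matrix, res.config.repeat_locus)
        sv = rp.call_sv_from_depth(
            res.depth, (res.config.deletion_start, res.config.deletion_end)
        )
        table, frac = rp.concordance(geno, sv)
        # every hom-repeat sample is a hom carrier and hence deletion-present
        assert frac == pytest.approx(1.0)
        assert table.loc["All", "All"] == res.matrix.n_samples

    def test_decoupling_lowers_concordance(self):
        res = generate_cohort(CohortConfig(
            seed=15, missing_rate=0.0, repeat_resample_rate=0.0,
            sv_decouple_rate=0.05,
            n_wild=400, n_landrace=100, n_old_cultivar=5, n_modern_cultivar=15,
        ))
        geno = rp.genotype_repeat(res.matrix, res.config.repeat_locus)
        sv = rp.call_sv_from_depth(
            res.depth, (res.config.deletion_start, res.config.deletion_end)
        )
        _table, frac = rp.concordance(geno, sv)
        assert frac == pytest.approx(0.95, abs=0.04)

    def test_empty_intersection_warns(self):
        m = make_matrix([(100, "A", ["ACAA"], [(0, 0)])])
        geno = rp.genotype_repeat(m, 100)
        sv = rp.SVCall(100, 200, {"other": True}, {}, {})
        with pytest.warns(UserWarning, match="no samples"):
            table, frac = rp.concordance(geno, sv)
        assert len(table) == 0 and frac is None


class TestSVLinkage:
    def test_hom_cohort_gives_perfect_linkage(self):
        # all-or-nothing classes: every sample homozygous, so the proxy
        # recoding matches the focal haplotypes exactly
        res = generate_cohort(CohortConfig(
            seed=16, ld_leak=0.0, missing_rate=0.0,
            hap_freq_by_class={"wild": 1.0, "landrace": 0.0,
                               "old_cultivar": 0.0, "modern_cultivar": 1.0},
            n_wild=40, n_landrace=80, n_old_cultivar=0, n_modern_cultivar=20,
        ))
        sv = rp.call_sv_from_depth(
            res.depth, (res.config.deletion_start, res.config.deletion_end)
        )
        pair = rp.sv_linkage(sv, res.matrix, res.config.focal_pos)
        assert pair.r2 == pytest.approx(1.0)
        assert pair.dprime == pytest.approx(1.0)

    def test_decoupling_decreases_r2(self):
        r2s = []
        for eps in (0.0, 0.1, 0.25):
            res = generate_cohort(CohortConfig(
                seed=17, ld_leak=0.0, missing_rate=0.0, sv_decouple_rate=eps,
                hap_freq_by_class={"wild": 1.0, "landrace": 0.0,
                                   "old_cultivar": 0.0, "modern_cultivar": 1.0},
                n_wild=100, n_landrace=200, n_old_cultivar=0,
                n_modern_cultivar=100,
            ))
            sv = rp.call_sv_from_depth(
                res.depth, (res.config.deletion_start, res.config.deletion_end)
            )
            r2s.append(rp.sv_linkage(sv, res.matrix, res.config.focal_pos).r2)
        assert r2s[0] > r2s[1] > r2s[2]

    def test_monomorphic_presence_rejected(self):
        m = make_matrix([(100, "A", ["G"], [(0, 1)])])
        sv = rp.SVCall(100, 200, {"S1": True}, {}, {})
        with pytest.raises(ValueError, match="monomorphic"):
            rp.sv_linkage(sv, m, 100)
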