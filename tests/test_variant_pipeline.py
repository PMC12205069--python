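import numpy as np
import pandas as pd
import pytest

from clonaldyn import synthetic_data as sd
from clonaldyn import variant_pipeline as vp


class TestReaders:
    def test_ad_derived_vaf(self, tmp_path, two_sample_sheet):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\tA\tB\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tDP:AD\t100:100,0\t100:90,10\t60:30,30\n"
        )
        recs = vp.read_variants(vcf, two_sample_sheet)
        assert len(recs) == 1
        assert recs[0].vaf["A"] == pytest.approx(0.10)
        assert recs[0].vaf["B"] == pytest.approx(0.50)
        assert recs[0].seed_vaf == pytest.approx(0.0)

    def test_unknown_sample_rejected(self, tmp_path, two_sample_sheet):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\tA\tZZ\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tDP:AD\t9:9,0\t9:9,0\t9:9,0\n"
        )
        with pytest.raises(ValueError, match="ZZ"):
            vp.read_variants(vcf, two_sample_sheet)

    def test_tsv_and_vcf_encodings_agree(self, tmp_path):
        recs, sheet, _ = sd.gen_variants(seed=11, out_dir=tmp_path)
        sheet2 = vp.read_sample_sheet(tmp_path / "sheet.csv")
        a = {r.key: r for r in vp.read_variants(tmp_path / "variants.tsv", sheet2)}
        b = {r.key: r for r in vp.read_variants(tmp_path / "variants.vcf", sheet2)}
        assert set(a) == set(b)
        for k in a:
            for s in a[k].vaf:
                assert a[k].vaf[s] == pytest.approx(b[k].vaf[s], abs=1e-4)
                assert a[k].depth[s] == b[k].depth[s]

    def test_sample_sheet_validation(self):
        base = [
            {"sample_id": "S", "fbs_group": "none", "timepoint": "t0",
             "replicate": 0, "role": "seed"},
            {"sample_id": "A", "fbs_group": "1%", "timepoint": "w3",
             "replicate": 1, "role": "culture"},
        ]
        vp.SampleSheet(pd.DataFrame(base))
        with pytest.raises(ValueError, match="seed"):
            vp.SampleSheet(pd.DataFrame(base[1:]))
        dup = base + [dict(base[1], sample_id="B")]
        with pytest.raises(ValueError, match="duplicate"):
            vp.SampleSheet(pd.DataFrame(dup))


class TestFilters:
    def test_truth_table_strict(self, filter_truth_table, two_sample_sheet):
        records, strict_kept, _ = filter_truth_table
        out = vp.filter_variants(records, vp.FilterConfig(mode="strict"), two_sample_sheet)
        assert {(r.chrom, r.pos) for r in out} == strict_kept
        assert len(out) == 3

    def test_truth_table_relaxed(self, filter_truth_table, two_sample_sheet):
        records, _, relaxed_kept = filter_truth_table
        out = vp.filter_variants(records, vp.FilterConfig(mode="relaxed"), two_sample_sheet)
        assert {(r.chrom, r.pos) for r in out} == relaxed_kept

    def test_idempotent(self, filter_truth_table, two_sample_sheet):
        records, _, _ = filter_truth_table
        for mode in ("strict", "relaxed"):
            cfg = vp.FilterConfig(mode=mode)
            once = vp.filter_variants(records, cfg, two_sample_sheet)
            twice = vp.filter_variants(once, cfg, two_sample_sheet)
            assert twice == once

    def test_relaxed_superset_of_strict(self, filter_truth_table, two_sample_sheet):
        records, _, _ = filter_truth_table
        strict = vp.filter_variants(records, vp.FilterConfig(mode="strict"), two_sample_sheet)
        relaxed = vp.filter_variants(records, vp.FilterConfig(mode="relaxed"), two_sample_sheet)
        assert {r.key for r in strict} <= {r.key for r in relaxed}

    def test_relaxed_superset_on_generated_sets(self):
        for seed in (0, 5, 9):
            recs, sheet, _ = sd.gen_variants(seed=seed)
            strict = {r.key for r in vp.filter_variants(recs, vp.FilterConfig(mode="strict"), sheet)}
            relaxed = {r.key for r in vp.filter_variants(recs, vp.FilterConfig(mode="relaxed"), sheet)}
            assert strict <= relaxed


class TestCounts:
    def test_no_records_all_zero(self, two_sample_sheet):
        out = vp.count_novel_snvs([], two_sample_sheet)
        assert out["count"].tolist() == [0, 0]

    def test_single_record_counts_one_sample(self, filter_truth_table, two_sample_sheet):
        records, _, _ = filter_truth_table
        r3 = [records[2]]  # VAFs 0.30 / 0.20
        out = vp.count_novel_snvs(r3, two_sample_sheet).set_index("sample_id")
        assert out.loc["A", "count"] == 1 and out.loc["B", "count"] == 1

    def test_recovers_planted_counts_exactly_in_strict_mode(self):
        recs, sheet, truth = sd.gen_variants(seed=3)
        strict = vp.filter_variants(recs, vp.FilterConfig(mode="strict"), sheet)
        counts = vp.count_novel_snvs(strict, sheet).set_index("sample_id")
        for sid, k in truth["true_counts"].items():
            assert counts.loc[sid, "count"] == k


class TestAnova:
    def test_identical_cells_give_zero_f(self):
        df = sd.gen_count_table(
            {("1%", "w3"): 5.0, ("5%", "w3"): 5.0, ("1%", "w6"): 5.0, ("5%", "w6"): 5.0},
            {k: 0.0 for k in [("1%", "w3"), ("5%", "w3"), ("1%", "w6"), ("5%", "w6")]},
            n_reps=3, seed=0,
        )
        res = vp.group_anova(df)
        assert res.f_group == pytest.approx(0.0, abs=1e-10)
        assert res.p_group == pytest.approx(1.0)

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            df = sd.gen_count_table(
                {("1%", "w3"): rng.uniform(2, 10), ("5%", "w3"): rng.uniform(2, 10),
                 ("1%", "w6"): rng.uniform(2, 30), ("5%", "w6"): rng.uniform(2, 30)},
                {("1%", "w3"): 1.0, ("5%", "w3"): 1.0, ("1%", "w6"): 2.0, ("5%", "w6"): 2.0},
                n_reps=4, seed=int(rng.integers(1e6)),
            )
            res = vp.group_anova(df)
            sst = float(((df["count"] - df["count"].mean()) ** 2).sum())
            assert res.ss_total == pytest.approx(sst, abs=1e-9)

    def test_constructed_group_effect_significant(self):
        df = sd.gen_count_table(
            {("1%", "w3"): 6.0, ("5%", "w3"): 6.0, ("1%", "w6"): 7.0, ("5%", "w6"): 20.0},
            {("1%", "w3"): 0.19, ("5%", "w3"): 0.19, ("1%", "w6"): 0.19, ("5%", "w6"): 3.61},
            n_reps=3, seed=42,
        )
        res = vp.group_anova(df)
        assert res.p_group < 0.05

    def test_empty_cell_raises_named(self):
        df = pd.DataFrame(
            {
                "fbs_group": ["1%", "1%", "5%", "5%"],
                "timepoint": ["w3", "w3", "w3", "w3"],
                "count": [1.0, 2.0, 3.0, 4.0],
            }
        )
        df2 = pd.concat(
            [df, pd.DataFrame({"fbs_group": ["1%"], "timepoint": ["w6"], "count": [5.0]})]
        )
        with pytest.raises(ValueError, match="empty cell"):
            vp.group_anova(df2)

    def test_permutation_oracle_agrees(self):
        # parametric p for the group factor vs a label-permutation null
        rng = np.random.default_rng(5)
        df = sd.gen_count_table(
            {("1%", "w3"): 5.0, ("5%", "w3"): 7.0, ("1%", "w6"): 5.0, ("5%", "w6"): 7.0},
            {k: 2.0 for k in [("1%", "w3"), ("5%", "w3"), ("1%", "w6"), ("5%", "w6")]},
            n_reps=4, seed=17,
        )
        observed = vp.group_anova(df).f_group
        n_perm, hits = 400, 0
        values = df["count"].to_numpy().copy()
        for _ in range(n_perm):
            shuffled = df.copy()
            shuffled["count"] = rng.permutation(values)
            if vp.group_anova(shuffled).f_group >= observed:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        p_param = vp.group_anova(df).p_group
        assert abs(p_perm - p_param) <= 0.12


class TestChromosomewise:
    def _sheet_and_records(self, n_on_chr1, n_on_chr2):
        recs, sheet, _ = sd.gen_variants(seed=1)
        return recs, sheet

    def test_min_variant_rule_boundary(self, two_sample_sheet):
        def rec(chrom, pos):
            return vp.VariantRecord(
                chrom=chrom, pos=pos, ref="A", alt="T",
                depth={"A": 50, "B": 50, "S": 50},
                vaf={"A": 0.3, "B": 0.2, "S": 0.0},
                seed_vaf=0.0,
            )
        records = [rec("chr1", i * 10 + 1) for i in range(3)]  # 3 variants: excluded
        records += [rec("chr2", i * 10 + 1) for i in range(4)]  # 4 variants: included
        out = vp.chromosomewise_analysis(records, two_sample_sheet, min_variants=4)
        assert "chr1" not in set(out.chrom)
        # chr2 qualifies on variant count even though the tiny design may not
        # support a full ANOVA
        assert set(out.chrom) <= {"chr2"}

    def test_generated_design_produces_table(self):
        recs, sheet, _ = sd.gen_variants(seed=2)
        out = vp.chromosomewise_analysis(
            recs, sheet, vp.FilterConfig(mode="relaxed"), min_variants=4
        )
        assert (out.n_variants >= 4).all()
        assert {"ss_group", "ss_within", "p_group"} <= set(out.columns)

    def test_no_chromosome_passes_gives_empty_table(self, two_sample_sheet):
        out = vp.chromosomewise_analysis([], two_sample_sheet)
        assert out.empty


class TestVafDistribution:
    def test_degenerate_all_quarter(self, two_sample_sheet):
        recs = [
            vp.VariantRecord(
                chrom="chr1", pos=i * 7 + 1, ref="A", alt="T",
                depth={"A": 40, "B": 40, "S": 40},
                vaf={"A": 0.25, "B": 0.25, "S": 0.0},
                seed_vaf=0.0,
            )
            for i in range(6)
        ]
        summary, p = vp.vaf_distribution_summary(recs, two_sample_sheet)
        assert np.allclose(summary.mean_vaf, 0.25)
        assert np.allclose(summary.sd_vaf, 0.0)
        assert p == pytest.approx(1.0)  # identical group distributions

    def test_generated_vafs_cluster_near_quarter(self):
        recs, sheet, _ = sd.gen_variants(seed=6)
        kept = vp.filter_variants(recs, vp.FilterConfig(mode="relaxed"), sheet)
        summary, p = vp.vaf_distribution_summary(kept, sheet)
        # truncated Beta(2.5, 7.5) at 0.1 has mean ~0.27
        assert summary.mean_vaf.between(0.15, 0.4).all()
        assert 0.0 <= p <= 1.0
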