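"""I/O round-trips, record validation and allele harmonization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.summary_data import (FormatError, LdMatrix, harmonize,
                                   read_association_table,
                                   write_association_table)

from .conftest import assoc


class TestTableIO:
    def test_round_trip_identity(self, tmp_path):
        records = [
            assoc("rs1", 0.1, 0.02, eaf=0.25),
            assoc("rs2", -0.3, 0.05, eaf=None),  # missing eaf -> "NA"
            assoc("rs3", 0.0001, 0.01, n=None, n_cases=100.0, n_controls=200.0,
                  trait_type="binary"),
        ]
        path = tmp_path / "t.tsv"
        write_association_table(records, path)
        text = path.read_text()
        assert len(text.splitlines()) == 4  # header + 3 rows
        assert "NA" in text.splitlines()[2]
        report = read_association_table(path)
        assert report.rejections == []
        assert list(report) == records

    def test_invalid_rows_rejected_with_report(self, tmp_path):
        good = "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.04\t500\tNA\tNA\tG1\tquantitative"
        bad_se = "rs2\t1\t200\tA\tG\t0.2\t0.1\t0\t0.04\t500\tNA\tNA\tG1\tquantitative"
        bad_num = "rs3\t1\t300\tA\tG\t0.2\txx\t0.05\t0.04\t500\tNA\tNA\tG1\tquantitative"
        multi = "rs4\t1\t400\tAT\tG\t0.2\t0.1\t0.05\t0.04\t500\tNA\tNA\tG1\tquantitative"
        header = ("variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\t"
                  "beta\tse\tpvalue\tn\tn_cases\tn_controls\ttrait_id\ttrait_type")
        path = tmp_path / "t.tsv"
        path.write_text("\n".join([header, good, bad_se, bad_num, multi]) + "\n")
        report = read_association_table(path)
        assert [r.variant_id for r in report] == ["rs1"]
        lines = [line for line, _ in report.rejections]
        assert lines == [3, 4, 5]  # 1-based line numbers, header = line 1

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("variant_id\tchrom\n" "rs1\t1\n")
        with pytest.raises(FormatError, match="pos"):
            read_association_table(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\tGENE\n"
            "rs1\t2\t500\tC\tT\t0.1\t0.2\t0.04\t1e-6\t800\tG2\n")
        report = read_association_table(path, dialect={
            "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2", "eaf": "FREQ",
            "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
            "trait_id": "GENE"})
        (rec,) = report.records
        assert (rec.variant_id, rec.chrom, rec.pos) == ("rs1", "2", 500)


class TestRecordInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(se=0.0), dict(se=-1.0), dict(pvalue=0.0), dict(pvalue=1.5),
        dict(eaf=1.2), dict(ea="A", oa="A"), dict(ea="N", oa="G"),
    ])
    def test_rejected(self, kwargs):
        with pytest.raises(ValueError):
            assoc("rs1", 0.1, kwargs.pop("se", 0.05),
                  pvalue=kwargs.pop("pvalue", 0.5), **kwargs)


class TestLdMatrix:
    def test_invariants_checked_on_construction(self):
        with pytest.raises(ValueError, match="symmetric"):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            LdMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))
        with pytest.raises(ValueError, match="PSD"):
            LdMatrix(["a", "b", "c"],
                     np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]]))

    def test_submatrix_preserves_order(self):
        rho = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        ld = LdMatrix(["a", "b", "c"], rho)
        sub = ld.submatrix(["c", "a"])
        assert sub.variant_ids == ["c", "a"]
        assert sub.correlation("c", "a") == 0.25


class TestHarmonize:
    def test_aligned_pair_kept_unchanged(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="G")
        o = assoc("rs1", -0.2, 0.03, "OUT", ea="A", oa="G")
        res = harmonize([e], [o])
        assert res.excluded == []
        assert res.outcome[0].beta == -0.2

    def test_swapped_alleles_flip_beta_and_eaf(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="G", eaf=0.3)
        o = assoc("rs1", -0.2, 0.03, "OUT", ea="G", oa="A", eaf=0.7)
        res = harmonize([e], [o])
        out = res.outcome[0]
        assert (out.effect_allele, out.other_allele) == ("A", "G")
        assert out.beta == pytest.approx(0.2)
        assert out.eaf == pytest.approx(0.3)

    def test_strand_flip_relabelled(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="G")
        o = assoc("rs1", 0.15, 0.03, "OUT", ea="T", oa="C")
        res = harmonize([e], [o])
        assert res.outcome[0].effect_allele == "A"
        assert res.outcome[0].beta == 0.15

    def test_palindromic_midfrequency_excluded(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="T", eaf=0.50)
        o = assoc("rs1", 0.1, 0.02, "OUT", ea="A", oa="T", eaf=0.50)
        res = harmonize([e], [o])
        assert res.excluded == [("rs1", "palindromic_ambiguous")]

    def test_palindromic_missing_eaf_excluded(self):
        e = assoc("rs1", 0.1, 0.02, ea="G", oa="C", eaf=None)
        o = assoc("rs1", 0.1, 0.02, "OUT", ea="G", oa="C", eaf=0.2)
        res = harmonize([e], [o])
        assert res.excluded == [("rs1", "palindromic_ambiguous")]

    def test_palindromic_oriented_by_frequency(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="T", eaf=0.2)
        o = assoc("rs1", 0.3, 0.02, "OUT", ea="A", oa="T", eaf=0.8)
        res = harmonize([e], [o])  # opposite frequency side: other strand order
        assert res.outcome[0].beta == pytest.approx(-0.3)
        assert res.outcome[0].eaf == pytest.approx(0.2)

    def test_irreconcilable_alleles_excluded_never_kept(self):
        e = assoc("rs1", 0.1, 0.02, ea="A", oa="G")
        o = assoc("rs1", 0.1, 0.02, "OUT", ea="A", oa="C")
        res = harmonize([e], [o])
        assert res.exposure == [] and res.excluded == [("rs1", "allele_mismatch")]

    def test_missing_counterpart_reported(self):
        res = harmonize([assoc("rs1"), assoc("rs2", pos=2)], [assoc("rs1", trait="OUT")])
        assert ("rs2", "missing_counterpart") in res.excluded

    def test_idempotent(self):
        exp = [assoc("rs1", 0.1, 0.02, ea="A", oa="G", eaf=0.3),
               assoc("rs2", -0.2, 0.05, ea="C", oa="G", eaf=0.2, pos=2)]
        out = [assoc("rs1", 0.2, 0.03, "OUT", ea="G", oa="A", eaf=0.7),
               assoc("rs2", 0.4, 0.05, "OUT", ea="C", oa="G", eaf=0.25, pos=2)]
        once = harmonize(exp, out)
        twice = harmonize(once.exposure, once.outcome)
        assert twice.exposure == once.exposure
        assert twice.outcome == once.outcome
        assert twice.excluded == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_double_flip_invariance(self, seed):
        """Swapping every outcome record's alleles (negating beta, reflecting
        eaf) must harmonize to the same aligned pairs as the original."""
        rng = np.random.default_rng(seed)
        pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("G", "C")]
        exp, out = [], []
        for j in range(6):
            ea, oa = pairs[rng.integers(len(pairs))]
            eaf = float(rng.uniform(0.05, 0.95))
            exp.append(assoc(f"rs{j}", float(rng.normal()), 0.05, ea=ea, oa=oa,
                             eaf=eaf, pos=j + 1))
            out.append(assoc(f"rs{j}", float(rng.normal()), 0.05, "OUT", ea=ea,
                             oa=oa, eaf=eaf, pos=j + 1))
        flipped = [dataclasses.replace(o, effect_allele=o.other_allele,
                                       other_allele=o.effect_allele,
                                       beta=-o.beta, eaf=1.0 - o.eaf)
                   for o in out]
        res_a = harmonize(exp, out)
        res_b = harmonize(exp, flipped)
        assert [o.variant_id for o in res_a.outcome] == [o.variant_id for o in res_b.outcome]
        for a, b in zip(res_a.outcome, res_b.outcome):
            assert a.beta == pytest.approx(b.beta)
            assert a.effect_allele == b.effect_allele
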