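"""Parsing and allele-harmonization behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrpath.summary_data import (AnalysisError, FormatError, harmonize,
                                 read_summary_stats)

from conftest import make_stats

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, rows, header=HEADER):
    p = tmp_path / "stats.tsv"
    p.write_text(header + "".join(rows))
    return p


def _row(snp, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, p=1e-8, n=1000,
         chrom=1, pos=1000):
    return f"{snp}\t{chrom}\t{pos}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t{n}\n"


class TestRead:
    def test_well_formed_file_parses_identically(self, tmp_path):
        p = _write(tmp_path, [_row("rs1"), _row("rs2", beta=-0.2), _row("rs3")])
        s = read_summary_stats(p, "continuous")
        assert len(s) == 3 and s.n_dropped == 0
        assert s.table.loc[1, "beta"] == -0.2
        rec = s.records[0]
        assert (rec.variant_id, rec.effect_allele, rec.n) == ("rs1", "A", 1000)

    def test_nonpositive_se_row_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, [_row("rs1"), _row("rs2", se=0.0), _row("rs3")])
        s = read_summary_stats(p, "continuous")
        assert len(s) == 2 and s.n_dropped == 1
        assert "rs2" not in set(s.table["variant_id"])

    def test_lowercase_alleles_uppercased(self, tmp_path):
        # hand-parsed expectation: same three rows, alleles A/G upper-case
        p = _write(tmp_path, [_row("rs1", ea="a", oa="g"),
                              _row("rs2", ea="t", oa="c"),
                              _row("rs3")])
        s = read_summary_stats(p, "continuous")
        assert len(s) == 3
        assert list(s.table["effect_allele"]) == ["A", "T", "A"]
        assert list(s.table["other_allele"]) == ["G", "C", "G"]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(FormatError, match="missing mandatory"):
            read_summary_stats(p, "continuous")

    def test_empty_file_is_input_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_summary_stats(p, "continuous")

    def test_comma_delimited_sniffed(self, tmp_path):
        p = tmp_path / "stats.csv"
        p.write_text(HEADER.replace("\t", ",") + _row("rs1").replace("\t", ","))
        assert len(read_summary_stats(p, "binary")) == 1


def _pair(exp_rows, out_rows):
    return (make_stats(exp_rows, "X"), make_stats(out_rows, "Y"))


class TestHarmonize:
    def test_matching_alleles_keep_beta(self):
        e, o = _pair([{"beta": 0.1}], [{"beta": 0.2}])
        h = harmonize(e, o)
        assert h.by[0] == 0.2 and h.n_snps == 1

    def test_swapped_alleles_flip_sign(self):
        e, o = _pair([{"effect_allele": "A", "other_allele": "G"}],
                     [{"effect_allele": "G", "other_allele": "A", "beta": 0.2}])
        h = harmonize(e, o)
        assert h.by[0] == -0.2

    def test_strand_complement_resolved(self):
        e, o = _pair([{"effect_allele": "A", "other_allele": "G"}],
                     [{"effect_allele": "T", "other_allele": "C", "beta": 0.2}])
        assert harmonize(e, o).by[0] == 0.2
        e, o = _pair([{"effect_allele": "A", "other_allele": "G"}],
                     [{"effect_allele": "C", "other_allele": "T", "beta": 0.2}])
        assert harmonize(e, o).by[0] == -0.2

    def test_palindromic_midfrequency_dropped(self):
        e, o = _pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}],
                     [{"effect_allele": "A", "other_allele": "T", "eaf": 0.3}])
        h = harmonize(e, o)
        assert h.n_snps == 0
        assert h.dropped == [("rs000", "palindromic_ambiguous")]

    def test_palindromic_missing_eaf_dropped(self):
        e, o = _pair([{"effect_allele": "C", "other_allele": "G", "eaf": np.nan}],
                     [{"effect_allele": "C", "other_allele": "G", "eaf": 0.2}])
        assert harmonize(e, o).dropped == [("rs000", "palindromic_ambiguous")]

    def test_palindromic_frequency_orientation(self):
        # clear frequencies on the same side: keep; on opposite sides: flip
        e, o = _pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.2}],
                     [{"effect_allele": "A", "other_allele": "T", "eaf": 0.25,
                       "beta": 0.3}])
        assert harmonize(e, o).by[0] == 0.3
        e, o = _pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.2}],
                     [{"effect_allele": "A", "other_allele": "T", "eaf": 0.75,
                       "beta": 0.3}])
        assert harmonize(e, o).by[0] == -0.3

    def test_unresolvable_alleles_dropped_with_reason(self):
        e, o = _pair([{"effect_allele": "A", "other_allele": "G"}],
                     [{"effect_allele": "A", "other_allele": "C"}])
        assert harmonize(e, o).dropped == [("rs000", "allele_mismatch")]

    def test_empty_intersection_names_both_traits(self):
        e = make_stats([{}], "dietX")
        o = make_stats([{}], "migraine")
        o.table["variant_id"] = ["zzz"]
        with pytest.raises(AnalysisError, match="dietX.*migraine"):
            harmonize(e, o)

    def test_idempotent_on_aligned_pair(self, rng):
        n = 8
        rows_e = [{"beta": float(b)} for b in rng.normal(size=n)]
        rows_o = [{"beta": float(b)} for b in rng.normal(size=n)]
        e, o = _pair(rows_e, rows_o)
        h1 = harmonize(e, o)
        # feed the harmonized outcome back in: nothing may change
        o2 = make_stats([{"beta": float(b)} for b in h1.by], "Y")
        h2 = harmonize(e, o2)
        np.testing.assert_array_equal(h1.by, h2.by)
        np.testing.assert_array_equal(h1.bx, h2.bx)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["AG", "CT", "AT", "CG"]),
                              st.floats(0.05, 0.95),
                              st.floats(-0.5, 0.5)),
                    min_size=1, max_size=6))
    def test_sign_symmetry_under_label_flip(self, spec):
        """Relabelling outcome alleles (and negating beta, reflecting eaf)
        yields an identical harmonized set."""
        rows_e, rows_o, rows_flip = [], [], []
        for alleles, eaf, beta in spec:
            ea, oa = alleles[0], alleles[1]
            rows_e.append({"effect_allele": ea, "other_allele": oa, "eaf": eaf})
            rows_o.append({"effect_allele": ea, "other_allele": oa,
                           "eaf": eaf, "beta": beta})
            rows_flip.append({"effect_allele": oa, "other_allele": ea,
                              "eaf": 1 - eaf, "beta": -beta})
        e, o = _pair(rows_e, rows_o)
        flipped = make_stats(rows_flip, "Y")
        h1, h2 = harmonize(e, o), harmonize(e, flipped)
        assert h1.variants == h2.variants
        np.testing.assert_allclose(h1.by, h2.by, atol=1e-12)
        assert sorted(h1.dropped) == sorted(h2.dropped)

    def test_retained_plus_dropped_covers_intersection(self, rng):
        alleles = [("A", "G"), ("A", "T"), ("C", "G"), ("T", "C")] * 3
        rows_e = [{"effect_allele": a, "other_allele": b,
                   "eaf": float(rng.uniform(0.05, 0.95))} for a, b in alleles]
        rows_o = [{"effect_allele": a, "other_allele": b,
                   "eaf": float(rng.uniform(0.05, 0.95))} for a, b in alleles]
        e, o = _pair(rows_e, rows_o)
        h = harmonize(e, o)
        assert h.n_snps + len(h.dropped) == len(alleles)


class TestPvalueConsistency:
    def test_exact_wald_pvalues_pass(self):
        from mrpath.summary_data import pvalue_consistency
        from mrpath.synthetic import SimConfig, simulate_two_sample
        exp, _, _ = simulate_two_sample(SimConfig(J=100, theta=0.2, seed=0))
        assert pvalue_consistency(exp).all()

    def test_corrupted_pvalue_flagged(self):
        from mrpath.summary_data import pvalue_consistency
        from mrpath.synthetic import SimConfig, simulate_two_sample
        exp, _, _ = simulate_two_sample(SimConfig(J=20, seed=1))
        exp.table.loc[3, "pval"] = 0.5
        exp.table.loc[3, "beta"] = 10 * exp.table.loc[3, "se"]
        mask = pvalue_consistency(exp)
        assert not mask[3] and mask.sum() == 19


def test_harmonized_set_tsv_roundtrip(tmp_path, rng):
    h = harmonize(make_stats([{"beta": 0.1}, {"beta": 0.2}], "X"),
                  make_stats([{"beta": 0.3}, {"beta": -0.1}], "Y"))
    p = tmp_path / "h.tsv"
    h.to_tsv(p)
    back = pd.read_csv(p, sep="\t")
    np.testing.assert_allclose(back["by"], h.by)
    assert list(back["variant_id"]) == h.variants
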