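import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from omicsmr import (
    DuplicateSnpError,
    SumstatsError,
    SumstatsTable,
    harmonize_pair,
    read_sumstats,
    write_sumstats,
)

from conftest import make_table

VALID_3 = """SNP A1 A2 freq b se p N
rs1 A G 0.30 0.10 0.02 1e-9 50000
rs2 T C 0.45 -0.05 0.01 2e-5 50000
rs3 AT A 0.10 0.02 0.03 0.5 50000
"""


class TestReadSumstats:
    def test_valid_fixture_parses_in_order(self, ma_file):
        t = read_sumstats(ma_file(VALID_3), "lipid", "risk_factor")
        assert len(t) == 3
        assert t.snp_ids == ["rs1", "rs2", "rs3"]
        r = t.lookup("rs2")
        assert r.effect_allele == "T" and r.beta == -0.05 and r.n == 50000
        # indel alleles are legal and preserved verbatim
        assert t.lookup("rs3").effect_allele == "AT"

    def test_zero_valid_rows_is_an_error(self, ma_file):
        path = ma_file("SNP A1 A2 freq b se p N\nrs1 A G 0.3 0.1 0 1e-9 50000\n")
        with pytest.raises(SumstatsError, match="zero valid rows"):
            read_sumstats(path, "t", "risk_factor")

    def test_duplicate_snp_is_a_hard_error_naming_it(self, ma_file):
        path = ma_file(
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.02 1e-9 50000\n"
            "rs1 A G 0.3 0.1 0.02 1e-9 50000\n"
        )
        with pytest.raises(DuplicateSnpError, match="rs1"):
            read_sumstats(path, "t", "risk_factor")

    def test_malformed_header(self, ma_file):
        path = ma_file("SNP EA OA freq b se p N\nrs1 A G 0.3 0.1 0.02 1e-9 50000\n")
        with pytest.raises(SumstatsError, match="header"):
            read_sumstats(path, "t", "risk_factor")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "nope.ma", "t", "risk_factor")

    def test_extra_columns_ignored(self, ma_file, caplog):
        path = ma_file(
            "SNP A1 A2 freq b se p N chr\nrs1 A G 0.3 0.1 0.02 1e-9 50000 7\n"
        )
        with caplog.at_level("WARNING"):
            t = read_sumstats(path, "t", "risk_factor")
        assert len(t) == 1
        assert "extra column" in caplog.text

    @pytest.mark.parametrize(
        "bad_row",
        [
            "rs9 A A 0.3 0.1 0.02 1e-9 50000",  # identical alleles
            "rs9 A G 1.3 0.1 0.02 1e-9 50000",  # eaf out of range
            "rs9 A G 0.3 0.1 0.02 0 50000",  # p = 0
            "rs9 A G 0.3 0.1 0.02 1e-9 0",  # n = 0
            "rs9 N G 0.3 0.1 0.02 1e-9 50000",  # non-ACGT allele
            "rs9 A G NA 0.1 0.02 1e-9 50000",  # missing frequency
        ],
    )
    def test_invalid_rows_dropped_with_count(self, ma_file, bad_row):
        path = ma_file(
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.02 1e-9 50000\n" + bad_row + "\n"
        )
        t = read_sumstats(path, "t", "risk_factor")
        assert t.snp_ids == ["rs1"]


class TestWriteSumstats:
    def test_roundtrip_identical(self, tmp_path, ma_file):
        t = read_sumstats(ma_file(VALID_3), "lipid", "risk_factor")
        out = tmp_path / "out.ma"
        write_sumstats(t, out)
        t2 = read_sumstats(out, "lipid", "risk_factor")
        pd.testing.assert_frame_equal(t.df, t2.df, check_dtype=False)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 0.99),
                st.floats(-2, 2),
                st.floats(1e-4, 1.0),
                st.floats(1e-30, 1.0, exclude_min=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_roundtrip_property(self, rows):
        import tempfile

        t = make_table(
            snp=[f"rs{i}" for i in range(len(rows))],
            freq=[r[0] for r in rows],
            b=[r[1] for r in rows],
            se=[r[2] for r in rows],
            p=[r[3] for r in rows],
        )
        with tempfile.NamedTemporaryFile("w", suffix=".ma") as fh:
            write_sumstats(t, fh.name)
            t2 = read_sumstats(fh.name, "trait", "risk_factor")
        assert t2.snp_ids == t.snp_ids
        np.testing.assert_allclose(t2.df["b"], t.df["b"], rtol=1e-9)
        np.testing.assert_allclose(t2.df["p"], t.df["p"], rtol=1e-9)


class TestHarmonizePair:
    def test_identical_alleles_unchanged(self):
        ex = make_table(snp=["rs1", "rs2"], b=[0.1, 0.2])
        out = make_table(snp=["rs1", "rs2"], b=[0.3, -0.4])
        _, out_h, rep = harmonize_pair(ex, out)
        assert list(out_h.df["b"]) == [0.3, -0.4]
        assert rep.n_flipped == 0 and rep.n_kept == 2

    def test_swapped_alleles_flip_beta_and_eaf(self):
        ex = make_table(snp=["rs1"], a1=["A"], a2=["G"])
        out = make_table(snp=["rs1"], a1=["G"], a2=["A"], b=[0.3], freq=[0.2])
        _, out_h, rep = harmonize_pair(ex, out)
        assert out_h.lookup("rs1").beta == pytest.approx(-0.3)
        assert out_h.lookup("rs1").eaf == pytest.approx(0.8)
        assert rep.n_flipped == 1

    def test_strand_complement_resolved(self):
        ex = make_table(snp=["rs1"], a1=["A"], a2=["G"], b=[0.1])
        out = make_table(snp=["rs1"], a1=["T"], a2=["C"], b=[0.3])
        _, out_h, rep = harmonize_pair(ex, out)
        assert out_h.lookup("rs1").beta == pytest.approx(0.3)
        assert rep.n_flipped == 0 and rep.n_kept == 1

    def test_complement_swap_flips(self):
        ex = make_table(snp=["rs1"], a1=["A"], a2=["G"], b=[0.1])
        out = make_table(snp=["rs1"], a1=["C"], a2=["T"], b=[0.3], freq=[0.2])
        _, out_h, _ = harmonize_pair(ex, out)
        assert out_h.lookup("rs1").beta == pytest.approx(-0.3)

    def test_ambiguous_palindromic_dropped(self):
        ex = make_table(snp=["rs1", "rs2"], a1=["A", "A"], a2=["T", "G"],
                        freq=[0.49, 0.3])
        out = make_table(snp=["rs1", "rs2"], a1=["A", "A"], a2=["T", "G"],
                         freq=[0.49, 0.3])
        ex_h, _, rep = harmonize_pair(ex, out, drop_palindromic_maf_window=0.08)
        assert ex_h.snp_ids == ["rs2"]
        assert rep.n_dropped_palindromic == 1

    def test_clear_palindromic_kept(self):
        ex = make_table(snp=["rs1"], a1=["C"], a2=["G"], freq=[0.1])
        out = make_table(snp=["rs1"], a1=["C"], a2=["G"], freq=[0.12])
        ex_h, _, _ = harmonize_pair(ex, out, drop_palindromic_maf_window=0.08)
        assert ex_h.snp_ids == ["rs1"]

    def test_irreconcilable_alleles_dropped(self):
        ex = make_table(snp=["rs1", "rs2"], a1=["A", "A"], a2=["G", "G"])
        out = make_table(snp=["rs1", "rs2"], a1=["A", "A"], a2=["C", "G"])
        ex_h, _, rep = harmonize_pair(ex, out)
        assert ex_h.snp_ids == ["rs2"] and rep.n_dropped_mismatch == 1

    def test_empty_intersection_is_hard_error(self):
        from omicsmr import HarmonizationError

        ex = make_table(snp=["rs1"])
        out = make_table(snp=["rs2"])
        with pytest.raises(HarmonizationError):
            harmonize_pair(ex, out)

    def test_idempotent(self):
        ex = make_table(snp=["rs1", "rs2"], a1=["A", "T"], a2=["G", "C"])
        out = make_table(snp=["rs1", "rs2"], a1=["G", "T"], a2=["A", "C"],
                         b=[0.3, 0.1], freq=[0.2, 0.4])
        ex1, out1, _ = harmonize_pair(ex, out)
        ex2, out2, rep2 = harmonize_pair(ex1, out1)
        pd.testing.assert_frame_equal(out1.df, out2.df)
        pd.testing.assert_frame_equal(ex1.df, ex2.df)
        assert rep2.n_flipped == 0

    def test_allele_flip_involution(self):
        """Swapping every outcome record's allele labels (with beta/eaf
        relabeling) must yield numerically identical harmonized output."""
        ex = make_table(snp=["rs1", "rs2"], a1=["A", "T"], a2=["G", "C"],
                        b=[0.1, -0.2])
        out = make_table(snp=["rs1", "rs2"], a1=["A", "T"], a2=["G", "C"],
                         b=[0.3, 0.5], freq=[0.2, 0.7])
        flipped = out.df.copy()
        flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
        flipped["b"] = -flipped["b"]
        flipped["freq"] = 1 - flipped["freq"]
        out_flipped = SumstatsTable(out.trait_id, out.trait_kind, flipped)
        _, h1, _ = harmonize_pair(ex, out)
        _, h2, _ = harmonize_pair(ex, out_flipped)
        pd.testing.assert_frame_equal(h1.df, h2.df)

    def test_exposure_betas_never_altered(self):
        ex = make_table(snp=["rs1", "rs2"], a1=["A", "T"], a2=["G", "C"],
                        b=[0.11, -0.22])
        out = make_table(snp=["rs1", "rs2"], a1=["G", "C"], a2=["A", "T"],
                         b=[0.3, 0.5])
        ex_h, _, _ = harmonize_pair(ex, out)
        assert list(ex_h.df["b"]) == [0.11, -0.22]
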