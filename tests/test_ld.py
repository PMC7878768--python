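import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from omicsmr import (
    GenotypePanel,
    LdError,
    PanelFormatError,
    compute_ld,
    ld_clump,
    read_panel,
    write_dosage_text,
)

from conftest import ld_from_r, make_table

DOSAGE_4x3 = """s1 s2 s3
0 1 2
1 1 0
2 0 1
1 2 NA
"""


def _write_plink(tmp_path, dosages, snp_ids):
    """Encode a dosage matrix (rows=samples) as a bed/bim/fam triplet."""
    n, m = dosages.shape
    prefix = tmp_path / "panel"
    with open(str(prefix) + ".bim", "w") as fh:
        for j, s in enumerate(snp_ids):
            fh.write(f"1\t{s}\t0\t{(j + 1) * 1000}\tA\tG\n")
    with open(str(prefix) + ".fam", "w") as fh:
        for i in range(n):
            fh.write(f"F{i} I{i} 0 0 0 -9\n")
    code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    blob = bytearray([0x6C, 0x1B, 0x01])
    for j in range(m):
        for byte_start in range(0, n, 4):
            byte = 0
            for k, i in enumerate(range(byte_start, min(byte_start + 4, n))):
                v = dosages[i, j]
                c = 0b01 if np.isnan(v) else code[v]
                byte |= c << (2 * k)
            blob.append(byte)
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(bytes(blob))
    return prefix


class TestReadPanel:
    def test_dosage_text_shape(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text(DOSAGE_4x3)
        panel = read_panel(path, "dosage_text")
        assert panel.dosages.shape == (4, 3)
        assert panel.snp_ids == ["s1", "s2", "s3"]
        assert np.isnan(panel.dosages[3, 2])

    def test_dosage_text_rejects_out_of_domain(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("s1 s2\n0 1\n3 2\n")
        with pytest.raises(PanelFormatError, match=r"row 2.*s1"):
            read_panel(path, "dosage_text")

    def test_dosage_text_roundtrip(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text(DOSAGE_4x3)
        panel = read_panel(path, "dosage_text")
        out = tmp_path / "copy.txt"
        write_dosage_text(panel, out)
        panel2 = read_panel(out, "dosage_text")
        np.testing.assert_array_equal(panel.dosages, panel2.dosages)

    def test_plink_bed_matches_source_dosages(self, tmp_path):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(7, 5)).astype(float)
        dos[2, 3] = np.nan
        prefix = _write_plink(tmp_path, dos, [f"s{j}" for j in range(5)])
        panel = read_panel(prefix, "plink_bed")
        np.testing.assert_array_equal(panel.dosages, dos)

    def test_plink_fam_length_mismatch(self, tmp_path):
        dos = np.ones((6, 4))
        prefix = _write_plink(tmp_path, dos, [f"s{j}" for j in range(4)])
        with open(str(prefix) + ".fam", "a") as fh:
            for i in range(3):  # 6 -> 9 samples changes the bytes-per-SNP count
                fh.write(f"F9{i} I9{i} 0 0 0 -9\n")
        with pytest.raises(PanelFormatError, match="inconsistent"):
            read_panel(prefix, "plink_bed")

    def test_plink_bad_magic(self, tmp_path):
        dos = np.ones((4, 2)) * 2
        prefix = _write_plink(tmp_path, dos, ["s0", "s1"])
        raw = open(str(prefix) + ".bed", "rb").read()
        with open(str(prefix) + ".bed", "wb") as fh:
            fh.write(b"\x00\x00\x00" + raw[3:])
        with pytest.raises(PanelFormatError, match="bed"):
            read_panel(prefix, "plink_bed")


class TestComputeLd:
    def test_self_correlation_is_one(self):
        panel = GenotypePanel(["a", "b"], np.array([[0, 2], [1, 1], [2, 0], [1, 2]]))
        ld = compute_ld(panel, ["a"])
        assert ld.r[0, 0] == 1.0

    def test_exact_anticorrelation(self):
        panel = GenotypePanel(
            ["x", "y"], np.array([[0, 2], [1, 1], [2, 0], [1, 1]], dtype=float)
        )
        ld = compute_ld(panel, ["x", "y"])
        assert ld.r_between("x", "y") == pytest.approx(-1.0)

    def test_matches_bruteforce_pairwise_complete_oracle(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(40, 3)).astype(float)
        dos[rng.random((40, 3)) < 0.1] = np.nan
        panel = GenotypePanel(["a", "b", "c"], dos)
        ld = compute_ld(panel, ["a", "b", "c"])

        def pearson(u, v):  # hand-rolled oracle
            keep = ~(np.isnan(u) | np.isnan(v))
            u, v = u[keep] - u[keep].mean(), v[keep] - v[keep].mean()
            return float(u @ v / np.sqrt((u @ u) * (v @ v)))

        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                if i < j:
                    assert ld.r_between(a, b) == pytest.approx(
                        pearson(dos[:, i], dos[:, j]), abs=1e-12
                    )

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        panel = GenotypePanel(
            [f"s{j}" for j in range(6)], rng.integers(0, 3, (30, 6)).astype(float)
        )
        ld = compute_ld(panel, panel.snp_ids)
        np.testing.assert_array_equal(ld.r, ld.r.T)
        np.testing.assert_array_equal(np.diag(ld.r), np.ones(6))

    def test_monomorphic_snp_named_in_error(self):
        panel = GenotypePanel(["ok", "flat"], np.array([[0, 1], [1, 1], [2, 1]]))
        with pytest.raises(LdError, match="flat"):
            compute_ld(panel, ["ok", "flat"])

    def test_insufficient_pairwise_overlap(self):
        dos = np.array([[0.0, np.nan], [1, np.nan], [2, np.nan], [np.nan, 1],
                        [np.nan, 0]])
        panel = GenotypePanel(["a", "b"], dos)
        with pytest.raises(LdError, match="non-missing"):
            compute_ld(panel, ["a", "b"])


class TestLdClump:
    def _ld(self, r2_s3_s1=0.8):
        r = np.eye(3)
        ids = ["s1", "s2", "s3"]
        r[0, 2] = r[2, 0] = np.sqrt(r2_s3_s1)
        r[0, 1] = r[1, 0] = r[1, 2] = r[2, 1] = 0.1  # r2 = 0.01
        return ld_from_r(ids, r)

    def test_greedy_hand_trace(self):
        stats = make_table(snp=["s1", "s2", "s3"], p=[1e-10, 1e-9, 1e-12])
        got = ld_clump(stats, self._ld(), r2_max=0.05, p_max=5e-8)
        assert got == ["s3", "s2"]

    def test_no_ld_keeps_all_in_p_order(self):
        stats = make_table(snp=["s1", "s2", "s3"], p=[1e-10, 1e-9, 1e-12])
        got = ld_clump(stats, ld_from_r(["s1", "s2", "s3"], np.eye(3)),
                       r2_max=0.05, p_max=5e-8)
        assert got == ["s3", "s1", "s2"]

    def test_nothing_significant_returns_empty(self):
        stats = make_table(snp=["s1", "s2"], p=[0.5, 0.5])
        assert ld_clump(stats, ld_from_r(["s1", "s2"], np.eye(2)),
                        r2_max=0.05, p_max=5e-8) == []

    def test_tie_broken_by_position_then_id(self):
        stats = make_table(snp=["b", "a"], p=[1e-9, 1e-9])
        ld = ld_from_r(["b", "a"], np.eye(2))
        assert ld_clump(stats, ld, 0.05, 5e-8, positions={"b": 100, "a": 200})[0] == "b"
        assert ld_clump(stats, ld, 0.05, 5e-8)[0] == "a"  # lexicographic fallback

    def test_missing_snp_in_ld_is_error(self):
        stats = make_table(snp=["s1", "s9"])
        with pytest.raises(LdError, match="s9"):
            ld_clump(stats, ld_from_r(["s1"], np.eye(1)), 0.05, 5e-8)

    @given(st.integers(0, 2**31 - 1))
    def test_accepted_pairs_below_r2_max_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        ids = [f"s{j}" for j in range(k)]
        A = rng.normal(size=(k, k))
        cov = A @ A.T
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        ld = ld_from_r(ids, r)
        p = rng.uniform(1e-12, 1e-4, size=k)
        stats = make_table(snp=ids, p=list(p))
        got = ld_clump(stats, ld, r2_max=0.3, p_max=1e-3)
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                assert ld.r_between(a, b) ** 2 < 0.3
        perm = rng.permutation(k)
        shuffled = make_table(snp=[ids[j] for j in perm], p=[p[j] for j in perm])
        assert ld_clump(shuffled, ld, r2_max=0.3, p_max=1e-3) == got
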