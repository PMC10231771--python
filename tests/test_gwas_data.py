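import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphmr import (
    LDStructure,
    SnpRecord,
    TraitCorrelation,
    estimate_rho_null_z,
    harmonize_pair,
    read_summary_stats,
    repair_psd,
    shrink_small_rho,
    write_summary_stats,
)
from graphmr.exceptions import (
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)


def rec(snp, ea="A", oa="G", beta=0.1, se=0.01, n=10000):
    return SnpRecord(snp, "1", 123, ea, oa, beta, se, 0.5, n)


class TestReadWrite:
    def test_parses_rows_with_custom_column_map(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(
            "SNP\tEA\tOA\tBETA\tSE\tP\tN\n"
            "rs1\tA\tG\t0.10\t0.01\t1e-10\t50000\n"
            "rs2\tC\tT\t-0.05\t0.02\t0.3\t50000\n"
            "rs3\tG\tA\t0.02\t0.015\t0.5\t50000\n"
        )
        cmap = {"effect_allele": "EA", "other_allele": "OA", "beta": "BETA",
                "se": "SE", "pval": "P", "n": "N"}
        records = read_summary_stats(path, cmap)
        assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]
        assert records[1].beta == -0.05
        assert records[0].n == 50000

    def test_zero_se_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "ss.csv"
        path.write_text(
            "SNP,effect_allele,other_allele,beta,se,pval,samplesize\n"
            "rs1,A,G,0.1,0.0,0.5,1000\n"
            "rs2,A,G,0.1,0.01,0.5,1000\n"
        )
        records = read_summary_stats(path)
        assert len(records) == 1
        assert read_summary_stats.last_dropped == 1

    def test_roundtrip_preserves_numeric_fields_exactly(self, tmp_path, rng):
        records = [
            SnpRecord(
                f"rs{i}", "2", i + 1, "A", "G",
                float(rng.standard_normal() * 0.1),
                float(0.01 + rng.random() * 0.01),
                float(rng.random()),
                25000,
            )
            for i in range(20)
        ]
        path = tmp_path / "out.tsv"
        write_summary_stats(records, path)
        back = read_summary_stats(path)
        assert [r.beta for r in back] == [r.beta for r in records]
        assert [r.se for r in back] == [r.se for r in records]
        assert [r.pval for r in back] == [r.pval for r in records]

    def test_missing_column_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tbeta\nrs1\t0.1\n")
        with pytest.raises(FormatError):
            read_summary_stats(path)

    def test_empty_file_raises_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_summary_stats(path)


class TestHarmonize:
    def test_matching_alleles_kept_unchanged(self):
        pair = harmonize_pair([rec("rs1", beta=0.1)], [rec("rs1", beta=0.2)])
        assert pair.beta_x[0] == 0.1 and pair.beta_y[0] == 0.2

    def test_swapped_alleles_flip_outcome_beta(self):
        pair = harmonize_pair(
            [rec("rs1", "A", "G", beta=0.1)], [rec("rs1", "G", "A", beta=0.2)]
        )
        assert pair.beta_y[0] == -0.2

    def test_palindromic_snp_dropped(self):
        xs = [rec(f"rs{i}") for i in range(4)] + [rec("rs9", "A", "T")]
        ys = [rec(f"rs{i}") for i in range(4)] + [rec("rs9", "A", "T")]
        assert harmonize_pair(xs, ys).m == 4

    def test_empty_intersection_raises(self):
        with pytest.raises(DataError):
            harmonize_pair([rec("rs1")], [rec("rs2")])

    def test_idempotent(self):
        xs = [rec("rs1", "A", "G", 0.1), rec("rs2", "C", "T", -0.2), rec("rs3", "G", "C", 0.3)]
        ys = [rec("rs1", "G", "A", 0.4), rec("rs2", "C", "T", 0.1), rec("rs3", "G", "C", 0.2)]
        once = harmonize_pair(xs, ys)
        back_x = [rec(s, beta=b, se=e) for s, b, e in zip(once.snp_ids, once.beta_x, once.se_x)]
        back_y = [rec(s, beta=b, se=e) for s, b, e in zip(once.snp_ids, once.beta_y, once.se_y)]
        twice = harmonize_pair(back_x, back_y)
        np.testing.assert_array_equal(once.beta_y, twice.beta_y)
        assert once.snp_ids == twice.snp_ids


class TestRhoFromNullZ:
    def test_identical_vectors_give_one(self, rng):
        z = rng.uniform(-1.5, 1.5, size=200)
        assert estimate_rho_null_z(z, z) == pytest.approx(1.0)

    def test_independent_draws_near_zero(self, rng):
        n = 100_000
        zx, zy = rng.standard_normal((2, n))
        rho = estimate_rho_null_z(zx, zy, null_threshold=None)
        assert abs(rho) < 3.0 / np.sqrt(n)

    def test_too_few_survivors_raises(self, rng):
        z = rng.uniform(-1, 1, size=30)
        with pytest.raises(InsufficientDataError):
            estimate_rho_null_z(z, z)

    def test_symmetric_and_joint_sign_flip_invariant(self, rng):
        zx = rng.standard_normal(500)
        zy = 0.5 * zx + rng.standard_normal(500)
        a = estimate_rho_null_z(zx, zy)
        assert estimate_rho_null_z(zy, zx) == pytest.approx(a, abs=1e-12)
        assert estimate_rho_null_z(-zx, -zy) == pytest.approx(a, abs=1e-12)


class TestShrinkSmallRho:
    def test_small_entries_zeroed_large_kept(self):
        P = TraitCorrelation(np.array([[1.0, 0.05, -0.3], [0.05, 1.0, 0.0], [-0.3, 0.0, 1.0]]))
        out = shrink_small_rho(P)
        assert out.P[0, 1] == 0.0
        assert out.P[0, 2] == -0.3
        np.testing.assert_array_equal(np.diag(out.P), 1.0)

    def test_identity_fixed_point(self):
        P = TraitCorrelation(np.eye(4))
        out = shrink_small_rho(P)
        np.testing.assert_array_equal(out.P, np.eye(4))

    def test_idempotent_and_symmetric(self, rng):
        M = rng.uniform(-0.4, 0.4, (5, 5))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 1.0)
        once = shrink_small_rho(TraitCorrelation(M))
        twice = shrink_small_rho(once)
        np.testing.assert_array_equal(once.P, twice.P)
        np.testing.assert_array_equal(once.P, once.P.T)

    def test_cutoff_ge_one_raises(self):
        with pytest.raises(ParameterError):
            shrink_small_rho(TraitCorrelation(np.eye(2)), cutoff=1.0)


class TestRepairPsd:
    def test_identity_unchanged(self):
        np.testing.assert_array_equal(repair_psd(np.eye(3)), np.eye(3))

    def test_negative_eigenvalue_clipped(self):
        out = repair_psd(np.diag([1.0, -0.01]))
        np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-12)

    def test_asymmetric_raises(self):
        with pytest.raises(ParameterError):
            repair_psd(np.array([[1.0, 0.5], [0.2, 1.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_output_psd_and_projection(self, seed):
        gen = np.random.default_rng(seed)
        M = gen.standard_normal((6, 6))
        M = 0.5 * (M + M.T)
        out = repair_psd(M)
        assert np.linalg.eigvalsh(out).min() >= -1e-12
        np.testing.assert_allclose(repair_psd(out), out, atol=1e-10)


class TestLDStructure:
    def test_from_blocks_zero_cross_block(self):
        blocks = {
            "b1": (["rs1", "rs2"], np.array([[1.0, 0.4], [0.4, 1.0]])),
            "b2": (["rs3"], np.array([[1.0]])),
        }
        ld = LDStructure.from_blocks(blocks)
        assert ld.R[0, 2] == 0.0 and ld.R[2, 1] == 0.0
        assert ld.R[0, 1] == 0.4
        assert ld.block_assignment["rs3"] == "b2"


class TestLDBlockIO:
    def test_block_directory_roundtrip(self, tmp_path):
        from graphmr.gwas_data import read_ld_blocks, write_matrix_tsv
        import pandas as pd

        write_matrix_tsv(np.array([[1.0, 0.3], [0.3, 1.0]]), ["rs1", "rs2"], tmp_path / "blk1.tsv")
        write_matrix_tsv(np.array([[1.0]]), ["rs3"], tmp_path / "blk2.tsv")
        pd.DataFrame(
            {"snp_id": ["rs1", "rs2", "rs3"], "block": ["blk1", "blk1", "blk2"]}
        ).to_csv(tmp_path / "assign.tsv", sep="\t", index=False)
        ld = read_ld_blocks(tmp_path, tmp_path / "assign.tsv")
        assert ld.R[0, 1] == 0.3
        assert ld.R[0, 2] == 0.0
        assert ld.block_assignment["rs3"] == "blk2"
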