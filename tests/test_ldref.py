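"""Reference-panel LD: scores, band matrices, blocks, working correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polygee import ldref


def brute_force_ld_scores(haps, cm, window):
    """O(n^2) double loop over all pairs within the window."""
    H = haps.astype(float)
    n_hap, n_var = H.shape
    out = np.zeros(n_var)
    for l in range(n_var):
        for v in range(n_var):
            if abs(cm[l] - cm[v]) <= window:
                r = np.corrcoef(H[:, l], H[:, v])[0, 1]
                out[l] += r * r
    return out


def random_panel(rng, n_hap=60, n_var=25, span_cm=3.0):
    while True:
        haps = (rng.random((n_hap, n_var)) < rng.uniform(0.1, 0.9, n_var)).astype(np.int8)
        if ldref.polymorphic_mask(haps).all():
            return haps, np.sort(rng.uniform(0, span_cm, n_var))


class TestLDScores:
    def test_matches_brute_force_oracle(self, rng):
        haps, cm = random_panel(rng)
        got = ldref.ld_scores(haps, cm, window_cm=1.0)
        np.testing.assert_allclose(got, brute_force_ld_scores(haps, cm, 1.0), rtol=1e-10)

    def test_isolated_variant_scores_one(self, rng):
        haps = (rng.random((40, 3)) < 0.5).astype(np.int8)
        cm = np.array([0.0, 5.0, 10.0])  # all > 1 cM apart
        np.testing.assert_allclose(ldref.ld_scores(haps, cm), 1.0)

    def test_perfect_pair_scores_two(self, rng):
        col = (rng.random(40) < 0.5).astype(np.int8)
        col[0] = 1 - col[0]  # guard against monomorphism
        haps = np.column_stack([col, col])
        np.testing.assert_allclose(ldref.ld_scores(haps, np.array([0.0, 0.1])), 2.0)

    def test_monomorphic_variant_rejected(self):
        haps = np.array([[1, 0], [1, 1], [1, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            ldref.ld_scores(haps, np.array([0.0, 0.1]))


class TestBandLDMatrix:
    def test_identical_columns_have_unit_r2(self, rng):
        haps, cm = random_panel(rng, n_var=4)
        haps[:, 1] = haps[:, 0]
        cm[1] = cm[0] + 1e-4
        band = ldref.band_ld_matrix(haps, np.sort(cm))
        assert band.r2[0, 1] == pytest.approx(1.0)

    def test_entries_beyond_cutoff_exactly_zero(self, rng):
        haps, cm = random_panel(rng, n_var=30, span_cm=5.0)
        band = ldref.band_ld_matrix(haps, cm, cutoff_cm=1.0)
        dense = band.r2.toarray()
        far = np.abs(cm[:, None] - cm[None, :]) > 1.0
        assert np.all(dense[far] == 0.0)
        np.testing.assert_allclose(dense, dense.T)

    def test_independent_columns_have_small_r2(self, rng):
        haps = (rng.random((10_000, 2)) < 0.5).astype(np.int8)
        band = ldref.band_ld_matrix(haps, np.array([0.0, 0.5]))
        assert band.r2[0, 1] < 0.01

    def test_scores_equal_row_sums(self, rng):
        haps, cm = random_panel(rng)
        band = ldref.band_ld_matrix(haps, cm)
        np.testing.assert_allclose(band.scores(), ldref.ld_scores(haps, cm), rtol=1e-10)

    def test_save_load_roundtrip(self, rng, tmp_path):
        haps, cm = random_panel(rng)
        band = ldref.band_ld_matrix(haps, cm, bp=np.arange(1, len(cm) + 1) * 100)
        band.save(tmp_path / "panel")
        back = ldref.BandLDMatrix.load(tmp_path / "panel")
        np.testing.assert_allclose(back.r2.toarray(), band.r2.toarray(), rtol=1e-9)
        np.testing.assert_array_equal(back.bp, band.bp)
        assert back.cutoff_cm == band.cutoff_cm


class TestPartitionBlocks:
    def test_boundaries_are_half_open_cm_intervals(self):
        blocks = ldref.partition_blocks(np.array([0.2, 0.8, 1.3]))
        assert [(b.start, b.stop) for b in blocks] == [(0, 2), (2, 3)]
        assert blocks[0].cm_start == 0.0 and blocks[0].cm_end == 1.0

    def test_single_block_when_all_within_one_cm(self):
        blocks = ldref.partition_blocks(np.array([1.1, 1.5, 1.9]))
        assert len(blocks) == 1 and blocks[0].size == 3

    def test_uniform_25_cm_region_gives_about_25_blocks(self):
        cm = np.linspace(0.01, 24.99, 1000)
        assert len(ldref.partition_blocks(cm)) == 25

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            ldref.partition_blocks(np.array([0.5, 0.2, 1.0]))

    def test_chromosomes_partition_independently(self):
        cm = np.array([0.1, 0.2, 0.1, 1.5])
        chrom = np.array(["1", "1", "2", "2"], dtype=object)
        blocks = ldref.partition_blocks(cm, chrom)
        assert [(b.chrom, b.start, b.stop) for b in blocks] == [
            ("1", 0, 2),
            ("2", 2, 3),
            ("2", 3, 4),
        ]


class TestWorkingCorrelations:
    def test_single_variant_block_is_scalar_one(self, rng):
        haps, cm = random_panel(rng, n_var=1)
        band = ldref.band_ld_matrix(haps, cm)
        Rs = ldref.working_correlations(band, ldref.partition_blocks(cm))
        np.testing.assert_allclose(Rs[0], [[1.0]])

    def test_uncorrelated_block_is_identity(self, rng):
        haps = (rng.random((20_000, 3)) < 0.5).astype(np.int8)
        cm = np.array([0.0, 0.3, 0.6])
        band = ldref.band_ld_matrix(haps, cm)
        band.r2.data[np.abs(band.r2.data) < 0.5] = 0.0  # drop sampling noise
        R = ldref.working_correlations(band, ldref.partition_blocks(cm))[0]
        np.testing.assert_allclose(R, np.eye(3))

    def test_psd_repair_fixes_indefinite_matrix(self):
        R = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        assert np.linalg.eigvalsh(R)[0] < 0
        fixed = ldref.psd_repair(R)
        assert np.linalg.eigvalsh(fixed)[0] >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        # repair stays close to the input
        assert np.linalg.norm(fixed - R) < np.linalg.norm(R)

    def test_psd_matrix_untouched(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(ldref.psd_repair(R), R)

    def test_block_diagonal_r2_reproduced_exactly(self, rng):
        # blocks aligned to cM boundaries: extraction is the inverse of
        # assembling a block-diagonal matrix
        haps, _ = random_panel(rng, n_var=6)
        cm = np.array([0.1, 0.5, 0.9, 1.2, 1.5, 1.8])
        band = ldref.band_ld_matrix(haps, cm, cutoff_cm=0.75)
        blocks = ldref.partition_blocks(cm)
        dense = band.r2.toarray()
        dense[:3, 3:] = dense[3:, :3] = 0.0  # align to boundaries
        band.r2 = type(band.r2)(dense)
        Rs = ldref.working_correlations(band, blocks)
        for b, R in zip(blocks, Rs):
            sub = ldref.psd_repair(dense[b.start : b.stop, b.start : b.stop])
            np.testing.assert_allclose(R, sub)


class TestShrinkCorrelation:
    def test_endpoints(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_array_equal(ldref.shrink_correlation(R, 1.0), R)
        np.testing.assert_array_equal(ldref.shrink_correlation(R, 0.0), np.eye(2))

    def test_64_percent_convention(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        shrunk = ldref.shrink_correlation(R, 0.64)
        assert shrunk[0, 1] == pytest.approx(0.32)
        np.testing.assert_allclose(np.diag(shrunk), 1.0)

    @given(s=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_preserves_positive_semidefiniteness(self, s, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 4))
        C = A @ A.T + 1e-9 * np.eye(4)
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        assert np.linalg.eigvalsh(ldref.shrink_correlation(R, s))[0] >= -1e-10


class TestAdjacency:
    def test_consecutive_blocks_on_same_chromosome(self):
        cm = np.array([0.1, 1.1, 2.1])
        blocks = ldref.partition_blocks(cm)
        assert ldref.adjacency(blocks) == {(0, 1), (1, 2)}

    def test_chromosome_boundary_breaks_adjacency(self):
        cm = np.array([0.1, 0.2])
        chrom = np.array(["1", "2"], dtype=object)
        assert ldref.adjacency(ldref.partition_blocks(cm, chrom)) == frozenset()

    def test_single_block_has_no_pairs(self):
        assert ldref.adjacency(ldref.partition_blocks(np.array([0.5]))) == frozenset()


class TestGeneticMap:
    def test_interpolation_is_linear_between_points(self):
        track = ldref.GeneticMapTrack(
            chrom=np.array(["1", "1"], dtype=object),
            bp=np.array([100, 300]),
            cm=np.array([0.0, 2.0]),
        )
        got = track.interpolate(["1", "1", "1"], [100, 200, 300])
        np.testing.assert_allclose(got, [0.0, 1.0, 2.0])

    def test_outside_span_is_nan(self):
        track = ldref.GeneticMapTrack(
            chrom=np.array(["1", "1"], dtype=object),
            bp=np.array([100, 300]),
            cm=np.array([0.0, 2.0]),
        )
        got = track.interpolate(["1", "2"], [50, 200])
        assert np.isnan(got).all()

    def test_decreasing_cm_rejected(self):
        with pytest.raises(ValueError, match="decrease"):
            ldref.GeneticMapTrack(
                chrom=np.array(["1", "1"], dtype=object),
                bp=np.array([100, 200]),
                cm=np.array([1.0, 0.5]),
            )

    def test_reads_three_column_and_plink_dialects(self, tmp_path):
        f3 = tmp_path / "map.txt"
        f3.write_text("chr bp cM\n1 100 0.0\n1 300 2.0\n")
        fp = tmp_path / "plink.map"
        fp.write_text("1 rs1 0.0 100\n1 rs2 2.0 300\n")
        for f in (f3, fp):
            track = ldref.read_genetic_map(f)
            np.testing.assert_array_equal(track.bp, [100, 300])
            np.testing.assert_allclose(track.cm, [0.0, 2.0])


def test_ldscore_file_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {"CHR": ["1", "1"], "SNP": ["rs1", "rs2"], "BP": [100, 200], "L2": [1.5, 3.25]}
    )
    ldref.write_ldscores(df, tmp_path / "scores.l2.ldscore")
    back = ldref.read_ldscores(tmp_path / "scores.l2.ldscore")
    pd.testing.assert_frame_equal(back, df)


def test_haplotype_text_matrix_reader(tmp_path):
    f = tmp_path / "haps.txt"
    f.write_text("# rows = haplotypes\n0 1 0\n1 1 0\n0 0 1\n1 0 1\n")
    H = ldref.read_haplotypes_txt(f)
    assert H.shape == (4, 3) and H.dtype == np.int8
    f.write_text("0 2 0\n1 1 0\n")
    with pytest.raises(ValueError, match="0/1"):
        ldref.read_haplotypes_txt(f)


def test_vcf_haplotypes_reader(tmp_path):
    vcf = tmp_path / "panel.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|0\t0|1\n"
        "1\t300\trs3\tA\tC\t.\t.\t.\tGT\t0/1\t0|1\n"  # unphased: skipped
    )
    haps, chrom, bp, ref, alt = ldref.read_vcf_haplotypes(vcf)
    assert haps.shape == (4, 2)
    np.testing.assert_array_equal(haps[:, 0], [0, 1, 1, 1])
    np.testing.assert_array_equal(bp, [100, 200])
    assert list(ref) == ["A", "C"] and list(alt) == ["G", "T"]
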