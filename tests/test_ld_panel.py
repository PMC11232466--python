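"""LD matrix construction, shrinkage, partitioning, eigen systems, serialization."""

import numpy as np
import pytest

from lderge.gwis import standardize
from lderge.ld_panel import (
    EigenSystem,
    VariantInfo,
    compute_ld_matrix,
    eigendecompose_block,
    ledoit_wolf_intensity,
    load_panel,
    partition_blocks,
    save_panel,
    shrink_ld,
)


def _variants(positions, chrom="1"):
    return [
        VariantInfo(id=f"v{i}", chrom=chrom, pos=int(p), a1="A", a2="G", maf=0.3)
        for i, p in enumerate(positions)
    ]


class TestComputeLD:
    def test_orthogonal_columns_give_identity(self):
        g1 = standardize(np.array([1.0, -1.0, 1.0, -1.0]))
        g2 = standardize(np.array([1.0, 1.0, -1.0, -1.0]))
        block = compute_ld_matrix(np.column_stack([g1, g2]))
        assert block.R[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(block.ld_scores, [1.0, 1.0], atol=1e-12)

    def test_duplicated_column_is_perfect_ld(self):
        g = standardize(np.array([0.0, 1.0, 2.0, 1.0, 0.0]))
        block = compute_ld_matrix(np.column_stack([g, g]))
        assert block.R[0, 1] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(block.ld_scores, [2.0, 2.0], atol=1e-12)

    def test_sign_flip_gives_r_minus_one(self):
        g1 = standardize(np.array([-1.0, 0.0, 1.0]))
        g2 = standardize(np.array([1.0, 0.0, -1.0]))
        block = compute_ld_matrix(np.column_stack([g1, g2]))
        assert block.R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_column_names_index(self):
        g = standardize(np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_ld_matrix(np.column_stack([g, np.zeros(4)]))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_ld_matrix(np.empty((5, 0)))

    def test_ld_scores_are_rowsums_of_squared_r(self, rng):
        X = standardize(rng.standard_normal((60, 8)))
        block = compute_ld_matrix(X)
        np.testing.assert_allclose(block.ld_scores, (block.R**2).sum(axis=1), atol=1e-10)
        assert np.all(block.ld_scores >= 1 - 1e-8)


class TestShrinkage:
    def test_zero_intensity_is_identity_operation(self, rng):
        X = standardize(rng.standard_normal((50, 5)))
        block = compute_ld_matrix(X)
        np.testing.assert_allclose(shrink_ld(block, 0.0).R, block.R, atol=1e-14)

    def test_full_intensity_gives_identity_matrix(self, rng):
        X = standardize(rng.standard_normal((50, 5)))
        block = compute_ld_matrix(X)
        np.testing.assert_allclose(shrink_ld(block, 1.0).R, np.eye(5), atol=1e-14)

    def test_intensity_out_of_range_rejected(self, rng):
        X = standardize(rng.standard_normal((50, 3)))
        block = compute_ld_matrix(X)
        with pytest.raises(ValueError):
            shrink_ld(block, 1.5)

    def test_auto_matches_ledoit_wolf_oracle(self, rng):
        """Shrinkage intensity agrees with an independently coded oracle of the
        Ledoit-Wolf formula (explicit per-sample loop, no shared code path)."""
        X = standardize(rng.standard_normal((50, 5)))
        n, m = X.shape
        S = X.T @ X / n
        d2 = np.sum((S - np.eye(m)) ** 2)
        b2_terms = [np.sum((np.outer(X[i], X[i]) - S) ** 2) for i in range(n)]
        b2 = min(d2, sum(b2_terms) / n**2)
        oracle = min(1.0, b2 / d2)
        assert ledoit_wolf_intensity(X) == pytest.approx(oracle, abs=1e-10)

        block = compute_ld_matrix(X)
        shrunk = shrink_ld(block, "auto", standardized_genotypes=X)
        off = ~np.eye(m, dtype=bool)
        assert np.all(np.abs(shrunk.R[off]) <= np.abs(block.R[off]) + 1e-15)
        assert oracle > 0  # sample noise guarantees a strict contraction here
        assert np.all(np.abs(shrunk.R[off]) < np.abs(block.R[off]) + 1e-15)

    def test_shrinkage_monotone_in_intensity(self, rng):
        X = standardize(rng.standard_normal((40, 6)))
        block = compute_ld_matrix(X)
        off = ~np.eye(6, dtype=bool)
        prev = np.abs(block.R[off])
        for alpha in (0.2, 0.5, 0.9):
            cur = np.abs(shrink_ld(block, alpha).R[off])
            assert np.all(cur <= prev + 1e-15)
            prev = cur


class TestPartition:
    def test_uncorrelated_variants_become_singletons(self):
        variants = _variants(np.arange(10) * 1000 + 1)
        blocks = partition_blocks(variants, {}, r_threshold=0.00373, window_bp=100_000)
        assert blocks == [(i, i + 1) for i in range(10)]

    def test_two_separated_clusters_give_two_blocks(self):
        pos = list(range(1, 6)) + [200_001 + k for k in range(5)]
        variants = _variants(pos)
        rband = {}
        for a in range(5):
            for b in range(a + 1, 5):
                rband[(a, b)] = 0.9
                rband[(a + 5, b + 5)] = 0.9
        blocks = partition_blocks(variants, rband, r_threshold=0.00373, window_bp=100_000)
        assert blocks == [(0, 5), (5, 10)]

    def test_chain_of_linked_neighbors_merges_to_one_block(self):
        variants = _variants([1 + 10_000 * k for k in range(6)])
        rband = {(k, k + 1): 0.5 for k in range(5)}
        blocks = partition_blocks(variants, rband, r_threshold=0.00373, window_bp=100_000)
        assert blocks == [(0, 6)]

    def test_window_limits_linkage(self):
        variants = _variants([1, 300_000])
        rband = {(0, 1): 0.9}  # linked but 300 kb apart
        blocks = partition_blocks(variants, rband, r_threshold=0.00373, window_bp=100_000)
        assert blocks == [(0, 1), (1, 2)]

    def test_chromosome_change_breaks_blocks(self):
        variants = _variants([1, 1001], chrom="1") + _variants([1, 1001], chrom="2")
        # cross-chromosome "correlation" must be ignored
        rband = {(1, 2): 0.9}
        blocks = partition_blocks(variants, rband, r_threshold=0.00373, window_bp=100_000)
        assert (1, 3) not in blocks
        assert len(blocks) == 4

    def test_unsorted_positions_rejected(self):
        variants = _variants([100, 50])
        with pytest.raises(ValueError, match="sorted"):
            partition_blocks(variants, {}, r_threshold=0.1, window_bp=1000)

    def test_no_linked_pair_crosses_boundary_bruteforce(self, rng):
        """Property: brute-force scan confirms the partition constraint."""
        m = 40
        pos = np.sort(rng.integers(1, 500_000, size=m))
        variants = _variants(pos)
        R = np.zeros((m, m))
        for _ in range(60):
            i, j = sorted(rng.integers(0, m, size=2))
            if i != j:
                R[i, j] = rng.uniform(-1, 1)
        thr, window = 0.3, 100_000
        blocks = partition_blocks(variants, R, r_threshold=thr, window_bp=window)
        boundary = np.zeros(m, dtype=int)
        for b, (a, c) in enumerate(blocks):
            boundary[a:c] = b
        for i in range(m):
            for j in range(i + 1, m):
                linked = abs(R[i, j]) > thr and abs(pos[j] - pos[i]) <= window
                if linked:
                    assert boundary[i] == boundary[j]


class TestEigen:
    def test_identity_matrix_keeps_all_unit_eigenvalues(self):
        block = compute_ld_matrix(standardize(np.random.default_rng(0).standard_normal((100, 3))))
        block.R = np.eye(3)
        es = eigendecompose_block(block)
        np.testing.assert_allclose(es.D, [1.0, 1.0, 1.0], atol=1e-12)
        assert es.n_retained == 3

    def test_perfect_ld_drops_null_component(self):
        g = standardize(np.array([0.0, 1.0, 2.0, 1.0, 0.0]))
        block = compute_ld_matrix(np.column_stack([g, g]))
        es = eigendecompose_block(block)
        np.testing.assert_allclose(es.D, [2.0], atol=1e-10)
        assert es.n_retained == 1

    def test_two_by_two_eigenvalues_are_one_plus_minus_r(self, rng):
        X = standardize(rng.standard_normal((200, 2)))
        block = compute_ld_matrix(X)
        block.R = np.array([[1.0, 0.5], [0.5, 1.0]])
        es = eigendecompose_block(block)
        np.testing.assert_allclose(es.D, [1.5, 0.5], atol=1e-12)

    def test_eigenpairs_satisfy_rv_equals_dv(self, rng):
        X = standardize(rng.standard_normal((120, 6)))
        block = compute_ld_matrix(X)
        es = eigendecompose_block(block)
        for k in range(es.n_retained):
            np.testing.assert_allclose(
                block.R @ es.U[:, k], es.D[k] * es.U[:, k], atol=1e-8
            )
        np.testing.assert_allclose(es.U.T @ es.U, np.eye(es.n_retained), atol=1e-8)

    def test_trace_and_frobenius_conservation(self, rng):
        """Pre-filter eigenvalues sum to the block dimension; for full-rank
        blocks sum d_k^2 equals sum r_jk^2 (Frobenius identity)."""
        X = standardize(rng.standard_normal((150, 8)))
        block = compute_ld_matrix(X)
        es = eigendecompose_block(block)
        assert es.n_retained == 8
        assert es.D.sum() == pytest.approx(8.0, abs=1e-6)
        assert np.sum(es.D**2) == pytest.approx(np.sum(block.R**2), abs=1e-6)
        assert np.sum(es.D**2) == pytest.approx(block.ld_scores.sum(), abs=1e-6)

    def test_nonfinite_entries_rejected(self, rng):
        X = standardize(rng.standard_normal((50, 3)))
        block = compute_ld_matrix(X)
        block.R[0, 1] = np.nan
        with pytest.raises(ValueError):
            eigendecompose_block(block)


class TestPanelSerialization:
    def test_round_trip_is_exact(self, small_panel, tmp_path):
        panel, _ = small_panel
        path = str(tmp_path / "panel.npz")
        save_panel(panel, path, n_ref=800, provenance="unit test")
        loaded = load_panel(path)
        assert len(loaded) == len(panel)
        for a, b in zip(panel, loaded):
            np.testing.assert_array_equal(a.U, b.U)
            np.testing.assert_array_equal(a.D, b.D)
            np.testing.assert_array_equal(a.ld_scores, b.ld_scores)
            assert [v.id for v in a.variants] == [v.id for v in b.variants]
            assert [v.pos for v in a.variants] == [v.pos for v in b.variants]

    def test_corrupted_block_count_rejected(self, small_panel, tmp_path):
        import json

        panel, _ = small_panel
        path = str(tmp_path / "panel.npz")
        save_panel(panel, path)
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(bytes(arrays["__meta__"].tobytes()).decode())
        meta["n_blocks"] += 3
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        bad = str(tmp_path / "bad.npz")
        np.savez(bad, **arrays)
        with pytest.raises(ValueError, match="truncated"):
            load_panel(bad)

    def test_not_a_panel_rejected(self, tmp_path):
        path = str(tmp_path / "junk.npz")
        np.savez(path, a=np.arange(3))
        with pytest.raises(ValueError, match="metadata"):
            load_panel(path)

    def test_variant_count_conserved_across_many_blocks(self, tmp_path):
        panel = []
        for b in range(100):
            variants = [
                VariantInfo(id=f"b{b}v{k}", chrom="1", pos=b * 1000 + k + 1, a1="A", a2="C", maf=0.2)
                for k in range(50)
            ]
            panel.append(
                EigenSystem(
                    U=np.eye(50),
                    D=np.ones(50),
                    n_retained=50,
                    block_id=b,
                    variants=variants,
                    ld_scores=np.ones(50),
                )
            )
        path = str(tmp_path / "big.npz")
        save_panel(panel, path)
        loaded = load_panel(path)
        assert sum(len(es.variants) for es in loaded) == 5000


class TestVariantInfo:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pos=0),
            dict(a1="A", a2="A"),
            dict(maf=0.6),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(id="v", chrom="1", pos=10, a1="A", a2="G", maf=0.1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VariantInfo(**base)
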