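import math
import sys

import numpy as np
import pytest

from heclip.data_prep import (
    apply_batch_correction_hook,
    build_cohort,
    extract_patch,
    normalize_expression,
    select_genes,
    split_by_slice,
)
from heclip.types import HEG, HVG, ExpressionMatrix, GeneSelection, SpotRecord

from .oracles import loop_extract_patch


def _ramp_image(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


class TestExtractPatch:
    def test_window_exactly_covers_image(self):
        img = _ramp_image(256, 256)
        out = extract_patch(img, SpotRecord("s", 128, 128, "a"), 256)
        np.testing.assert_array_equal(out, img)

    def test_interior_window_coordinates(self):
        # a 256-patch at (x=200, y=300) spans columns [72, 328) and rows [172, 428)
        img = _ramp_image(500, 400)
        out = extract_patch(img, SpotRecord("s", 200, 300, "a"), 256)
        np.testing.assert_array_equal(out, img[172:428, 72:328])

    def test_zero_padding_matches_per_pixel_oracle(self):
        img = _ramp_image(100, 100, seed=3)
        out = extract_patch(img, SpotRecord("s", 10, 10, "a"), 256)
        expected = np.array(loop_extract_patch(img.tolist(), 10, 10, 256), dtype=np.uint8)
        np.testing.assert_array_equal(out, expected)
        # in-bounds region equals the source crop
        np.testing.assert_array_equal(out[118:218, 118:218], img[0:100, 0:100])

    @pytest.mark.parametrize("shift", [1, 7, 13])
    def test_translation_consistency(self, shift):
        rng = np.random.default_rng(shift)
        img = rng.integers(0, 256, size=(60, 80, 3), dtype=np.uint8)
        shifted = np.roll(img, -shift, axis=1)
        a = extract_patch(img, SpotRecord("s", 40 + shift, 30, "a"), 16)
        b = extract_patch(shifted, SpotRecord("s", 40, 30, "a"), 16)
        np.testing.assert_array_equal(a, b)

    def test_errors(self):
        img = _ramp_image(32, 32)
        with pytest.raises(ValueError):
            extract_patch(img[:, :, :2], SpotRecord("s", 5, 5, "a"), 16)
        with pytest.raises(ValueError):
            extract_patch(img, SpotRecord("s", 5, 5, "a"), -4)


class TestNormalizeExpression:
    def test_two_gene_row(self):
        out = normalize_expression(np.array([[1.0, 1.0]]), ["s1"], ["g1", "g2"])
        np.testing.assert_allclose(out.values[0], [math.log(1 + 5000)] * 2, rtol=1e-12)
        assert out.values[0, 0] == pytest.approx(8.5174, abs=1e-4)

    def test_zero_row_left_zero(self, caplog):
        out = normalize_expression(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]]), ["a", "b"], list("xyz"))
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_row_at_target_sum_is_log1p_only(self):
        row = np.array([[4000.0, 6000.0]])
        out = normalize_expression(row, ["s"], ["g1", "g2"])
        np.testing.assert_allclose(out.values, np.log1p(row), rtol=1e-12)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e4])
    def test_row_scale_invariance(self, scale):
        counts = np.array([[2.0, 5.0, 1.0], [10.0, 0.0, 4.0]])
        a = normalize_expression(counts, ["a", "b"], list("xyz"))
        b = normalize_expression(counts * scale, ["a", "b"], list("xyz"))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(6, 9)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        out = normalize_expression(counts, [f"s{i}" for i in range(6)], [f"g{j}" for j in range(9)])
        expected = np.log1p(counts / counts.sum(axis=1, keepdims=True) * 1e4)
        np.testing.assert_allclose(out.values, expected, rtol=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression(np.array([[-1.0, 2.0]]), ["s"], ["g1", "g2"])


def _matrix(values, spots, genes):
    return ExpressionMatrix(np.asarray(values, dtype=float), spots, genes)


class TestSelectGenes:
    @pytest.fixture
    def three_gene_matrix(self):
        # g1 constant 10 (mean 10, var 0); g2 {0,0,10,10} (mean 5, var 25); g3 constant 1
        values = np.array([[10, 0, 1], [10, 0, 1], [10, 10, 1], [10, 10, 1]], dtype=float)
        return _matrix(values, ["s1", "s2", "s3", "s4"], ["g1", "g2", "g3"])

    def test_heg_picks_highest_mean(self, three_gene_matrix):
        sel = select_genes([three_gene_matrix], HEG, n=1)
        assert sel.gene_names == ["g1"]

    def test_hvg_picks_highest_variance(self, three_gene_matrix):
        sel = select_genes([three_gene_matrix], HVG, n=1)
        assert sel.gene_names == ["g2"]

    def test_full_selection_is_rank_reorder(self, three_gene_matrix):
        sel = select_genes([three_gene_matrix], HEG, n=3)
        assert sorted(sel.gene_names) == ["g1", "g2", "g3"]
        assert sel.gene_names == ["g1", "g2", "g3"]  # means 10, 5, 1

    def test_permutation_invariance(self, rng):
        values = rng.gamma(2.0, 2.0, size=(12, 8))
        genes = [f"g{j}" for j in range(8)]
        spots = [f"s{i}" for i in range(12)]
        base = _matrix(values, spots, genes)
        spot_perm = rng.permutation(12)
        gene_perm = rng.permutation(8)
        shuffled = _matrix(
            values[np.ix_(spot_perm, gene_perm)],
            [spots[i] for i in spot_perm],
            [genes[j] for j in gene_perm],
        )
        for mode in (HEG, HVG):
            assert select_genes([base], mode, 4).gene_names == select_genes([shuffled], mode, 4).gene_names

    def test_n_exceeding_available_returns_all(self, three_gene_matrix):
        sel = select_genes([three_gene_matrix], HEG, n=99)
        assert len(sel.gene_names) == 3

    def test_hvg_pools_across_slices(self, rng):
        genes = [f"g{j}" for j in range(6)]
        a = _matrix(rng.gamma(2, 1, size=(10, 6)), [f"a{i}" for i in range(10)], genes)
        b = _matrix(rng.gamma(2, 1, size=(10, 6)), [f"b{i}" for i in range(10)], genes)
        sel = select_genes([a, b], HVG, n=3)
        pooled = np.vstack([a.values, b.values])
        pooled_var = pooled.var(axis=0)
        top3 = sorted(range(6), key=lambda j: (-pooled_var[j], genes[j]))[:3]
        assert sel.gene_names == [genes[j] for j in top3]

    def test_mismatched_namespace_rejected(self, three_gene_matrix):
        other = _matrix(np.ones((2, 2)), ["x", "y"], ["h1", "h2"])
        with pytest.raises(ValueError):
            select_genes([three_gene_matrix, other], HEG, 1)


class TestBuildCohortAndSplit:
    @pytest.fixture
    def inputs(self, rng):
        genes = [f"g{j}" for j in range(10)]
        spots = [SpotRecord(f"s{i}", 16, 16, f"slice{i % 3}") for i in range(15)]
        # shuffled expression row order relative to the spot list
        order = rng.permutation(15)
        expr = _matrix(rng.gamma(2, 1, size=(15, 10)), [f"s{i}" for i in order], genes)
        selection = GeneSelection(HEG, 4, genes[:4])
        images = {f"slice{k}": np.full((32, 32, 3), 50 * (k + 1), dtype=np.uint8) for k in range(3)}
        return images, spots, expr, selection

    def test_shapes_and_spot_id_join(self, inputs):
        images, spots, expr, selection = inputs
        cohort = build_cohort(images, spots, expr, selection, patch_size=16)
        assert len(cohort) == 15
        lookup = dict(zip(expr.spot_ids, expr.values))
        for pair in cohort:
            np.testing.assert_array_equal(pair.expression, lookup[pair.spot.spot_id][:4])
            assert pair.patch.shape == (16, 16, 3)

    def test_empty_spot_list(self, inputs):
        images, _, expr, selection = inputs
        cohort = build_cohort(images, [], expr, selection, patch_size=16)
        assert len(cohort) == 0

    def test_missing_expression_row_is_hard_error(self, inputs):
        images, spots, expr, selection = inputs
        bad = spots + [SpotRecord("ghost", 5, 5, "slice0")]
        with pytest.raises(KeyError, match="ghost"):
            build_cohort(images, bad, expr, selection, patch_size=16)

    def test_split_partition(self, inputs):
        images, spots, expr, selection = inputs
        cohort = build_cohort(images, spots, expr, selection, patch_size=16)
        ref, qry = split_by_slice(cohort, "slice2")
        assert len(ref) + len(qry) == len(cohort)
        ref_ids = set(ref.spot_ids())
        qry_ids = set(qry.spot_ids())
        assert ref_ids.isdisjoint(qry_ids)
        assert ref_ids | qry_ids == set(cohort.spot_ids())
        assert qry.slice_ids() == ["slice2"]
        assert ref.role == "reference" and qry.role == "query"

    def test_split_sizes(self, inputs):
        images, _, expr, selection = inputs
        spots = (
            [SpotRecord(f"a{i}", 16, 16, "s1") for i in range(4)]
            + [SpotRecord(f"b{i}", 16, 16, "s2") for i in range(5)]
            + [SpotRecord(f"c{i}", 16, 16, "s3") for i in range(6)]
        )
        genes = selection.gene_names
        expr15 = _matrix(np.ones((15, 4)), [s.spot_id for s in spots], genes)
        images = {"s1": images["slice0"], "s2": images["slice1"], "s3": images["slice2"]}
        cohort = build_cohort(images, spots, expr15, GeneSelection(HEG, 4, genes), patch_size=16)
        ref, qry = split_by_slice(cohort, "s3")
        assert (len(ref), len(qry)) == (9, 6)

    def test_single_slice_split_is_error(self, inputs):
        images, spots, expr, selection = inputs
        one_slice = [s for s in spots if s.slice_id == "slice0"]
        cohort = build_cohort(images, one_slice, expr, selection, patch_size=16)
        with pytest.raises(ValueError):
            split_by_slice(cohort, "slice0")

    def test_unknown_slice_lists_available(self, inputs):
        images, spots, expr, selection = inputs
        cohort = build_cohort(images, spots, expr, selection, patch_size=16)
        with pytest.raises(ValueError, match="slice0"):
            split_by_slice(cohort, "nope")


CENTERING_HOOK = (
    f"{sys.executable} -c "
    '"'
    "import sys, pandas as pd; "
    "expr = pd.read_csv('{input}', index_col=0); "
    "labels = pd.read_csv('{labels}', sep='\\t').set_index('spot_id')['slice_id']; "
    "out = expr - expr.groupby(labels).transform('mean') + expr.mean(); "
    "out.to_csv('{output}')"
    '"'
)


class TestBatchCorrectionHook:
    def test_disabled_hook_is_identity(self):
        m = _matrix(np.arange(12.0).reshape(3, 4), ["a", "b", "c"], list("wxyz"))
        out = apply_batch_correction_hook(m, ["s1", "s1", "s2"], command=None)
        assert out is m

    def test_external_centering_hook_shrinks_slice_gap(self, rng):
        # two-slice synthetic input with a known mean shift between slices
        base = rng.gamma(2.0, 1.0, size=(20, 5))
        values = base.copy()
        values[10:] += 2.0
        labels = ["s1"] * 10 + ["s2"] * 10
        m = _matrix(values, [f"p{i}" for i in range(20)], list("abcde"))
        gap_before = np.abs(values[:10].mean(axis=0) - values[10:].mean(axis=0)).mean()
        out = apply_batch_correction_hook(m, labels, command=CENTERING_HOOK)
        gap_after = np.abs(out.values[:10].mean(axis=0) - out.values[10:].mean(axis=0)).mean()
        assert out.values.shape == values.shape
        assert gap_after <= gap_before
        assert gap_after < 1e-8

    def test_failing_tool_propagates_with_log(self):
        m = _matrix(np.ones((2, 2)), ["a", "b"], ["g1", "g2"])
        cmd = f"{sys.executable} -c \"import sys; sys.stderr.write('boom'); sys.exit(3)\""
        with pytest.raises(RuntimeError, match="boom"):
            apply_batch_correction_hook(m, ["s1", "s2"], command=cmd)
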