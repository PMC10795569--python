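"""Kernel-level checks: hand-computed probabilities, structural mappings,
threshold conversions and the invariance properties that distinguish the
MNRM and tree conceptions of extreme responding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ersirt import (
    MISSING,
    MnrmItem,
    ModelStructureError,
    PersonTraits,
    ScoringMatrix,
    TreeItem,
    agreement_prob,
    conditional_extreme_agreement,
    expand_pseudo_items,
    gpcm_category_probs,
    intercepts_from_thresholds,
    irtree_category_probs,
    irtree_node_probs,
    mnrm_category_probs,
    pseudo_items,
    thresholds_from_intercepts,
)

finite = dict(allow_nan=False, allow_infinity=False)


class TestScoringMatrix:
    def test_ers_pattern(self):
        s = ScoringMatrix.ers(4)
        assert np.array_equal(s.scores[:, 0], [0, 1, 2, 3])
        assert np.array_equal(s.scores[:, 1], [1, 0, 0, 1])

    def test_gpcm_pattern(self):
        s = ScoringMatrix.gpcm(5)
        assert s.n_dims == 1 and np.array_equal(s.scores[:, 0], np.arange(5))

    @pytest.mark.parametrize(
        "bad",
        [
            [[1, 0], [0, 1]],  # substantive column not 0..K-1
            [[0, 2], [1, 0], [2, 0], [3, 1]],  # style entry outside {0, 1}
            [[0], ],  # K < 2
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ModelStructureError):
            ScoringMatrix(np.array(bad))


class TestMnrmKernel:
    def test_hand_computed_symmetric_item(self, symmetric_item, ers_scoring):
        # softmax of the intercepts (0, 1.5, 1.5, 0) at theta = 0
        p = mnrm_category_probs(PersonTraits(np.zeros(2)), symmetric_item, ers_scoring)
        expect = np.exp([0, 1.5, 1.5, 0])
        np.testing.assert_allclose(p, expect / expect.sum(), atol=1e-12)
        np.testing.assert_allclose(p, [0.0912, 0.4088, 0.4088, 0.0912], atol=5e-5)

    def test_unit_ers_makes_symmetric_item_uniform(self, symmetric_item, ers_scoring):
        # all four linear predictors equal 1.5 at theta = (0, 1)
        p = mnrm_category_probs([0.0, 1.0], symmetric_item, ers_scoring)
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_zero_slopes_give_uniform(self, ers_scoring):
        item = MnrmItem([0.0, 0.0], np.zeros(4))
        p = mnrm_category_probs([1.3, -2.1], item, ers_scoring)
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_location_invariance(self, symmetric_item, ers_scoring):
        shifted = MnrmItem(symmetric_item.slopes, symmetric_item.intercepts + 7.3)
        theta = np.array([[0.4, -1.2], [2.0, 0.3]])
        np.testing.assert_allclose(
            mnrm_category_probs(theta, symmetric_item, ers_scoring),
            mnrm_category_probs(theta, shifted, ers_scoring),
            atol=1e-12,
        )

    def test_dimension_mismatch_is_structural(self, symmetric_item, ers_scoring):
        with pytest.raises(ModelStructureError):
            mnrm_category_probs([0.0, 0.0, 0.0], symmetric_item, ers_scoring)
        uni = MnrmItem([1.0], np.zeros(4))
        with pytest.raises(ModelStructureError):
            mnrm_category_probs([0.0, 0.0], uni, ers_scoring)

    def test_nonfinite_theta_rejected(self, symmetric_item, ers_scoring):
        with pytest.raises(ValueError):
            mnrm_category_probs([np.nan, 0.0], symmetric_item, ers_scoring)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        t1=st.floats(-4, 4, **finite),
        t2=st.floats(-4, 4, **finite),
        a1=st.floats(0.1, 3, **finite),
        a2=st.floats(0.1, 3, **finite),
        c=st.lists(st.floats(-4, 4, **finite), min_size=3, max_size=3),
    )
    def test_simplex_normalization(self, t1, t2, a1, a2, c):
        item = MnrmItem([a1, a2], np.concatenate([[0.0], c]))
        p = mnrm_category_probs([t1, t2], item, ScoringMatrix.ers(4))
        assert np.all(p > 0) and np.all(p < 1)
        assert abs(p.sum() - 1.0) < 1e-12


class TestGpcm:
    def test_equals_mnrm_with_zero_ers_slope(self, symmetric_item, ers_scoring):
        zero_ers = MnrmItem([1.5, 0.0], symmetric_item.intercepts)
        theta1 = np.linspace(-3, 3, 11)
        theta = np.column_stack([theta1, np.full(11, 2.0)])
        np.testing.assert_array_equal(
            gpcm_category_probs(theta1, symmetric_item),
            mnrm_category_probs(theta, zero_ers, ers_scoring),
        )

    def test_hand_value_at_zero(self, symmetric_item):
        p = gpcm_category_probs(0.0, symmetric_item)
        np.testing.assert_allclose(p, [0.0912, 0.4088, 0.4088, 0.0912], atol=5e-5)

    def test_mass_moves_to_top_category_for_large_theta(self, symmetric_item):
        p = gpcm_category_probs(25.0, symmetric_item)
        assert p[3] > 1 - 1e-6


class TestThresholdConversion:
    def test_hand_algebra(self):
        c = intercepts_from_thresholds([-1.0, 0.0, 1.0], 1.5)
        np.testing.assert_allclose(c, [0.0, 1.5, 1.5, 0.0], atol=1e-14)

    def test_zero_thresholds(self):
        np.testing.assert_allclose(
            intercepts_from_thresholds([0.0, 0.0, 0.0], 2.7), np.zeros(4), atol=0
        )

    def test_inverse_round_trip(self):
        tau = np.array([-0.8, 0.15, 1.9])
        item = MnrmItem.from_thresholds(tau, (1.3, 0.9))
        np.testing.assert_allclose(thresholds_from_intercepts(item), tau, atol=1e-14)

    def test_equal_intercepts_give_zero_thresholds(self):
        item = MnrmItem([2.0], np.zeros(4))
        np.testing.assert_allclose(thresholds_from_intercepts(item), 0.0, atol=0)

    def test_scale_cancellation(self):
        tau = np.array([-1.0, 0.2, 0.9])
        a = MnrmItem.from_thresholds(tau, (1.1, 1.1))
        b = MnrmItem([2.2, 2.2], 2.0 * a.intercepts)
        np.testing.assert_allclose(thresholds_from_intercepts(b), tau, atol=1e-14)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            intercepts_from_thresholds([0.0, 1.0], 0.0)


class TestTreeKernel:
    def test_all_halves_at_origin(self):
        item = TreeItem(1.5, 0.0, 0.7, 1.0, 0.0, 0.0)
        np.testing.assert_allclose(irtree_node_probs([0.0, 0.0], item), 0.5, atol=1e-14)
        np.testing.assert_allclose(
            irtree_category_probs([0.0, 0.0], item), 0.25, atol=1e-14
        )

    def test_node1_hand_value(self):
        item = TreeItem(1.5, 0.0, 0.7, 1.0, 0.0, 0.0)
        p = irtree_node_probs([1.0, 0.0], item)
        np.testing.assert_allclose(p[0], 1.0 / (1.0 + np.exp(-1.5)), atol=1e-12)

    def test_ers_monotonicity_on_extremity_nodes(self, tree_item):
        grid = np.column_stack([np.full(9, 0.3), np.linspace(-2, 2, 9)])
        p = irtree_node_probs(grid, tree_item)
        assert np.all(np.diff(p[:, 1]) < 0)  # node 2: extreme disagreement down
        assert np.all(np.diff(p[:, 2]) > 0)  # node 3: extreme agreement up
        assert np.allclose(p[:, 0], p[0, 0])  # node 1 blind to ERS

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        t1=st.floats(-4, 4, **finite),
        t2=st.floats(-4, 4, **finite),
        params=st.lists(st.floats(-2.5, 2.5, **finite), min_size=6, max_size=6),
    )
    def test_category_probs_sum_to_one(self, t1, t2, params):
        item = TreeItem(*params)
        p = irtree_category_probs([t1, t2], item)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_marginalization_identity(self, tree_item, theta2_grid):
        # P(3) + P(4) equals the node-1 probability for every ERS value
        grid = np.column_stack([np.full_like(theta2_grid, 0.8), theta2_grid])
        cats = irtree_category_probs(grid, tree_item)
        nodes = irtree_node_probs(grid, tree_item)
        np.testing.assert_allclose(cats[:, 2] + cats[:, 3], nodes[:, 0], atol=1e-12)


class TestPseudoItems:
    @pytest.mark.parametrize(
        "resp,expected",
        [
            (1, (0, 0, MISSING)),
            (2, (0, 1, MISSING)),
            (3, (1, MISSING, 0)),
            (4, (1, MISSING, 1)),
        ],
    )
    def test_exact_mapping(self, resp, expected):
        assert pseudo_items(resp).node_values == expected

    @pytest.mark.parametrize("bad", [0, 5, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            pseudo_items(bad)

    def test_vectorized_expansion_matches_scalar(self):
        resp = np.array([[1, 2], [3, 4]])
        codes = expand_pseudo_items(resp)
        for i in range(2):
            for j in range(2):
                assert tuple(codes[i, j]) == pseudo_items(resp[i, j]).node_values

    def test_structural_missingness_invariants(self):
        for r in (1, 2, 3, 4):
            v = pseudo_items(r).node_values
            assert v[0] in (0, 1)
            assert (v[0] == 0) == (v[2] == MISSING)
            assert (v[0] == 1) == (v[1] == MISSING)


class TestErsInvariances:
    """The two signature properties that separate the model families."""

    def test_mnrm_conditional_extreme_constant_in_ers(
        self, asymmetric_item, ers_scoring, theta2_grid
    ):
        for t1 in (-1.0, 0.0, 1.5):
            grid = np.column_stack([np.full_like(theta2_grid, t1), theta2_grid])
            c = conditional_extreme_agreement("mnrm", grid, asymmetric_item, ers_scoring)
            assert np.ptp(c) < 1e-10

    def test_mnrm_conditional_moderate_constant_in_ers(
        self, asymmetric_item, ers_scoring, theta2_grid
    ):
        # P(3 | {2, 3}) is likewise free of the ERS trait
        grid = np.column_stack([np.full_like(theta2_grid, 0.7), theta2_grid])
        p = mnrm_category_probs(grid, asymmetric_item, ers_scoring)
        cond = p[:, 2] / (p[:, 1] + p[:, 2])
        assert np.ptp(cond) < 1e-10

    def test_irtree_agreement_constant_in_ers(self, tree_item, theta2_grid):
        for t1 in (-2.0, 0.0, 2.0):
            grid = np.column_stack([np.full_like(theta2_grid, t1), theta2_grid])
            a = agreement_prob("irtree", grid, tree_item)
            assert np.ptp(a) < 1e-10

    def test_mnrm_agreement_at_symmetric_point_is_half(
        self, symmetric_item, ers_scoring, theta2_grid
    ):
        grid = np.column_stack([np.zeros_like(theta2_grid), theta2_grid])
        a = agreement_prob("mnrm", grid, symmetric_item, ers_scoring)
        np.testing.assert_allclose(a, 0.5, atol=1e-12)

    def test_mnrm_agreement_varies_with_ers_off_center(
        self, symmetric_item, ers_scoring, theta2_grid
    ):
        grid = np.column_stack([np.ones_like(theta2_grid), theta2_grid])
        a = agreement_prob("mnrm", grid, symmetric_item, ers_scoring)
        assert np.ptp(a) > 0.05

    def test_irtree_conditional_extreme_varies_with_ers(self, tree_item, theta2_grid):
        grid = np.column_stack([np.zeros_like(theta2_grid), theta2_grid])
        c = conditional_extreme_agreement("irtree", grid, tree_item)
        assert np.ptp(c) > 0.02

    def test_symmetric_midpoint_is_half_under_both_families(self, symmetric_item, ers_scoring):
        c = conditional_extreme_agreement("mnrm", [0.0, 0.0], symmetric_item, ers_scoring)
        assert abs(c - 0.5) < 1e-12
        sym_tree = TreeItem(1.4, 0.0, 0.5, 1.1, 0.3, -0.3)
        c2 = conditional_extreme_agreement("irtree", [0.0, 0.0], sym_tree)
        assert abs(c2 - 0.5) < 1e-12
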