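"""Loss family: closed forms, continuity, invariances, anchor matching."""

import math

import numpy as np
import pytest

from pbbline.errors import ParameterError
from pbbline.pbb_losses import (
    AutoBalance,
    DflTarget,
    LossConfig,
    MaskPair,
    ObjectnessGrid,
    box_loss,
    ciou_loss,
    dfl_loss,
    match_anchors,
    objectness_loss,
    order_loss,
    seg_loss,
    total_loss_v5,
    total_loss_v8,
    vertex_loss,
)
from pbbline.polygon_core import QuadPBB, SimplePolygon, canonicalize_vertices, min_bounding_rect

from conftest import random_canonical_quad, random_convex_quad

SQ = QuadPBB(((0, 0), (1, 0), (1, 1), (0, 1)))


def _shift(q: QuadPBB, dx: float, dy: float) -> QuadPBB:
    return QuadPBB(tuple((x + dx, y + dy) for x, y in q.vertices))


class TestCiouLoss:
    def test_identical_quads(self):
        assert ciou_loss(SQ, SQ) == 0.0

    def test_disjoint_quads(self):
        far = _shift(SQ, 100, 100)
        assert ciou_loss(SQ, far) == 1.0

    def test_half_overlap_closed_form(self):
        half = QuadPBB(((0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)))
        assert ciou_loss(SQ, half) == pytest.approx(2 / 3)

    def test_translation_invariance(self, rng):
        for _ in range(10):
            a = canonicalize_vertices(random_canonical_quad(rng))
            b = canonicalize_vertices(random_canonical_quad(rng))
            dx, dy = rng.uniform(-50, 50, size=2)
            assert ciou_loss(a, b) == pytest.approx(
                ciou_loss(_shift(a, dx, dy), _shift(b, dx, dy))
            )


class TestOrderLoss:
    def test_zero_on_canonical_quads(self, rng):
        for _ in range(100):
            q = canonicalize_vertices(random_convex_quad(rng))
            assert order_loss(q) == 0.0

    def test_single_x_violation_equals_one_sixth(self):
        # canonical unit square with x1 pushed to x2 + 1 only
        q = QuadPBB(((2, 0), (1, 0), (1, 1), (0, 1)))
        assert order_loss(q) == pytest.approx(1 / 6)

    def test_all_vertices_identical_is_zero(self):
        q = QuadPBB(((3, 3), (3, 3), (3, 3), (3, 3)))
        assert order_loss(q) == 0.0

    def test_translation_invariance(self, rng):
        q = QuadPBB(((2, 0), (1, 0), (1, 1), (0, 1)))
        for _ in range(10):
            dx, dy = rng.uniform(-100, 100, size=2)
            assert order_loss(_shift(q, dx, dy)) == pytest.approx(order_loss(q))

    def test_quadratic_hinge_growth(self):
        def violated(delta):
            return QuadPBB(((1 + delta, 0), (1, 0), (1, 1), (0, 1)))

        assert order_loss(violated(2.0)) == pytest.approx(4 * order_loss(violated(1.0)))


class TestVertexLoss:
    def test_zero_on_identical(self):
        assert vertex_loss(SQ, SQ) == 0.0

    def test_offset_at_beta_closed_form(self):
        pred = _shift(SQ, 0.11, 0.0)
        # only the 4 x-coordinates are off, each by exactly beta
        expected = 4 * (0.11 - 0.5 * 0.11) / 8
        assert vertex_loss(pred, SQ, beta=0.11) == pytest.approx(expected)

    def test_unit_offset_closed_form(self):
        pred = QuadPBB(tuple((x + 1, y + 1) for x, y in SQ.vertices))
        assert vertex_loss(pred, SQ, beta=0.11) == pytest.approx(1 - 0.5 * 0.11)

    def test_continuity_at_beta(self):
        beta = 0.11
        eps = 1e-12
        below = 0.5 * (beta - eps) ** 2 / beta
        above = (beta + eps) - 0.5 * beta
        assert below == pytest.approx(0.5 * beta, abs=1e-9)
        assert above == pytest.approx(0.5 * beta, abs=1e-9)
        pred_below = _shift(SQ, beta - eps, 0)
        pred_above = _shift(SQ, beta + eps, 0)
        assert vertex_loss(pred_below, SQ, beta) == pytest.approx(
            vertex_loss(pred_above, SQ, beta), abs=1e-9
        )

    def test_invalid_beta_rejected(self):
        with pytest.raises(ParameterError):
            vertex_loss(SQ, SQ, beta=0.0)


class TestBoxLoss:
    def test_zero_on_identical_canonical(self, rng):
        for _ in range(50):
            q = canonicalize_vertices(random_canonical_quad(rng))
            assert box_loss(q, q) == 0.0

    def test_disjoint_unit_offset_sum(self):
        target = SQ
        pred = _shift(SQ, 100, 100)  # disjoint, canonical
        expected = 1.0 + 0.0 + vertex_loss(pred, target)
        assert box_loss(pred, target) == pytest.approx(expected)

    def test_dominates_ciou_term(self, rng):
        for _ in range(10):
            a = canonicalize_vertices(random_canonical_quad(rng))
            b = canonicalize_vertices(random_canonical_quad(rng))
            assert box_loss(a, b) >= ciou_loss(a, b)


class TestObjectnessLoss:
    def test_perfect_prediction_near_zero(self):
        grid = ObjectnessGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert objectness_loss(grid) == pytest.approx(0.0, abs=1e-5)

    def test_single_cell_half_confidence(self):
        grid = ObjectnessGrid(np.array([0.5]), np.array([1.0]))
        assert objectness_loss(grid) == pytest.approx(math.log(2))

    def test_sum_reduction_additivity(self):
        one = ObjectnessGrid(np.array([0.3]), np.array([1.0]))
        many = ObjectnessGrid(np.full(7, 0.3), np.ones(7))
        assert objectness_loss(many) == pytest.approx(7 * objectness_loss(one))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ObjectnessGrid(np.zeros(3), np.zeros(4))


class TestDflLoss:
    def test_integer_target_one_hot_is_zero(self):
        p = np.zeros(8)
        p[3] = 1.0
        assert dfl_loss([DflTarget(t=3.0, p=p)]) == pytest.approx(0.0, abs=1e-5)

    def test_half_way_target_split_mass(self):
        p = np.zeros(8)
        p[3] = p[4] = 0.5
        assert dfl_loss([DflTarget(t=3.5, p=p)]) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("k", range(2, 17))
    def test_uniform_distribution_gives_log_k(self, k):
        p = np.full(k, 1.0 / k)
        t = (k - 1) * 0.37
        assert dfl_loss([DflTarget(t=t, p=p)]) == pytest.approx(math.log(k))

    def test_integer_target_reduces_to_cross_entropy(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 10))
            p = rng.dirichlet(np.ones(k))
            t = int(rng.integers(0, k))
            expected = -math.log(max(p[t], 1e-7))
            assert dfl_loss([DflTarget(t=float(t), p=p)]) == pytest.approx(expected)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ParameterError):
            DflTarget(t=9.0, p=np.full(8, 1 / 8))

    def test_mean_over_targets(self):
        p = np.zeros(4)
        p[1] = p[2] = 0.5
        single = dfl_loss([DflTarget(t=1.5, p=p)])
        assert dfl_loss([DflTarget(t=1.5, p=p)] * 5) == pytest.approx(single)


class TestSegLoss:
    def test_perfect_mask(self):
        gt = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert seg_loss(MaskPair(gt, gt, box_area=4)) == pytest.approx(0.0, abs=1e-5)

    def test_all_half_predictions(self):
        gt = (np.arange(16).reshape(4, 4) % 2).astype(float)
        pair = MaskPair(np.full((4, 4), 0.5), gt, box_area=16)
        assert seg_loss(pair) == pytest.approx(math.log(2))

    def test_halving_area_doubles_loss(self):
        gt = np.ones((4, 4))
        pred = np.full((4, 4), 0.7)
        full = seg_loss(MaskPair(pred, gt, box_area=16))
        half = seg_loss(MaskPair(pred, gt, box_area=8))
        assert half == pytest.approx(2 * full)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ParameterError):
            MaskPair(np.ones((2, 2)), np.ones((2, 2)), box_area=0)


class TestTotalLosses:
    def test_v5_unit_weights(self):
        cfg = LossConfig(lambda_box=1.0, lambda_obj=1.0)
        assert total_loss_v5(0.5, 0.5, cfg) == pytest.approx(1.0)

    def test_v5_zero_box_weight(self):
        cfg = LossConfig(lambda_box=0.0, lambda_obj=2.0)
        assert total_loss_v5(123.0, 0.25, cfg) == pytest.approx(0.5)

    def test_v5_pure_without_autobalance(self):
        cfg = LossConfig(lambda_box=0.05, lambda_obj=1.0, autobalance=False)
        vals = [total_loss_v5(1.0, 1.0, cfg) for _ in range(5)]
        assert len(set(vals)) == 1

    def test_v8_dot_product(self):
        cfg = LossConfig(lambda_1=1, lambda_2=2, lambda_3=3, lambda_4=4)
        assert total_loss_v8(1, 1, 1, 1, cfg) == pytest.approx(10.0)
        assert total_loss_v8(4, 3, 2, 1, cfg) == pytest.approx(4 + 6 + 6 + 4)

    def test_v8_zero_terms(self):
        assert total_loss_v8(0, 0, 0, 0, LossConfig()) == 0.0

    def test_linearity_in_weights(self, rng):
        terms = rng.uniform(0.1, 2.0, size=4)
        c1 = LossConfig(lambda_1=1, lambda_2=1, lambda_3=1, lambda_4=1)
        c2 = LossConfig(lambda_1=2, lambda_2=2, lambda_3=2, lambda_4=2)
        assert total_loss_v8(*terms, c2) == pytest.approx(2 * total_loss_v8(*terms, c1))

    def test_autobalance_factors_positive_and_slow(self):
        bal = AutoBalance(n_scales=3)
        assert bal.factors == [1.0, 1.0, 1.0]
        for _ in range(100):
            factors = bal.update([0.5, 1.0, 2.0])
            assert all(f > 0 for f in factors)
        # slowly varying: 100 updates move factors by a small amount
        assert all(abs(f - 1.0) < 0.1 for f in bal.factors)

    def test_autobalance_scales_objectness_weight(self):
        cfg = LossConfig(lambda_box=0.0, lambda_obj=1.0, autobalance=True)
        assert total_loss_v5(0.0, 1.0, cfg, balance_factor=2.0) == pytest.approx(2.0)


class TestLossConfig:
    def test_yaml_round_trip(self):
        cfg = LossConfig.from_yaml(
            "box: 0.1\nobj: 2.0\nbeta: 0.2\nautobalance: true\nanchor_t: 3.0\nlambda3: 0.5\n"
        )
        assert cfg.lambda_box == 0.1
        assert cfg.lambda_obj == 2.0
        assert cfg.beta == 0.2
        assert cfg.autobalance is True
        assert cfg.anchor_ratio_threshold == 3.0
        assert cfg.lambda_3 == 0.5

    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            LossConfig(beta=-1)
        with pytest.raises(ParameterError):
            LossConfig(anchor_ratio_threshold=0.5)


class TestMatchAnchors:
    def test_exact_anchor_matches(self):
        poly = SimplePolygon(((0, 0), (10, 0), (10, 20), (0, 20)))
        assert match_anchors([poly], [(10, 20)], 4.0) == [(0, 0)]

    def test_wildly_wrong_anchor_unmatched(self):
        poly = SimplePolygon(((0, 0), (10, 0), (10, 20), (0, 20)))
        assert match_anchors([poly], [(100, 20)], 4.0) == []

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ParameterError):
            match_anchors([], [], 4.0)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        polys = [
            SimplePolygon(tuple(map(tuple, random_convex_quad(rng, 0, 500))))
            for _ in range(15)
        ]
        anchors = [tuple(rng.uniform(5, 200, size=2)) for _ in range(6)]
        got = set(match_anchors(polys, anchors, 4.0))
        expected = set()
        for i, poly in enumerate(polys):
            r = min_bounding_rect(poly)
            for j, (pw, ph) in enumerate(anchors):
                ratios = [r.w / pw, pw / r.w, r.h / ph, ph / r.h]
                if max(ratios) < 4.0:
                    expected.add((i, j))
        assert got == expected
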