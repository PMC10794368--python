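"""Distance functions against independent loop-coded oracles, plus the
alignment and composite losses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalign import tensor as T
from vitalign.errors import (ConfigurationError, DimensionError,
                             InvalidLabelError)
from vitalign.losses import (AlignmentLossConfig, HELLINGER_NORMALIZATION,
                             attention_alignment_loss, bhattacharyya_distance,
                             composite_loss, hellinger_distance,
                             js_divergence, normalize_rows, tv_distance)
from vitalign.tensor import Tensor

EPS = 1e-8


# -- independent oracles (elementwise loops, no vectorization) ---------------

def tv_oracle(p, q):
    s = 0.0
    for a, b in zip(p, q):
        s += abs(a - b)
    return 0.5 * s


def js_oracle(p, q, eps=EPS):
    s = 0.0
    for a, b in zip(p, q):
        m = 0.5 * (a + b)
        s += 0.5 * a * math.log((a + eps) / (m + eps))
        s += 0.5 * b * math.log((b + eps) / (m + eps))
    return s


def hellinger_oracle(p, q):
    s = 0.0
    for a, b in zip(p, q):
        s += (math.sqrt(a) - math.sqrt(b)) ** 2
    return math.sqrt(s) / math.sqrt(2.0)


def bhattacharyya_oracle(p, q, eps=EPS):
    s = 0.0
    for a, b in zip(p, q):
        s += math.sqrt(a * b)
    return -math.log(max(s, eps))


def random_prob_pairs(n_pairs, max_len=32, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_pairs):
        n = int(rng.integers(2, max_len + 1))
        p = rng.random(n)
        q = rng.random(n)
        yield p / p.sum(), q / q.sum()


class TestNormalizeRows:
    def test_symmetric_row(self):
        np.testing.assert_allclose(normalize_rows(np.array([2.0, 2.0])),
                                   [0.5, 0.5], atol=1e-9)

    def test_negative_entries_use_absolute_value(self):
        np.testing.assert_allclose(normalize_rows(np.array([-1.0, 3.0])),
                                   [0.25, 0.75], atol=1e-9)

    def test_idempotent_on_stochastic_rows(self):
        rng = np.random.default_rng(0)
        rows = rng.random((5, 8))
        rows /= rows.sum(-1, keepdims=True)
        np.testing.assert_allclose(normalize_rows(rows), rows, atol=1e-6)

    def test_zero_row_becomes_uniform(self):
        out = normalize_rows(np.zeros((1, 4)))
        np.testing.assert_allclose(out, 0.25, atol=1e-6)

    def test_tensor_path_differentiable(self):
        x = Tensor(np.array([[1.0, 3.0]]), requires_grad=True)
        y = normalize_rows(x)
        (y * np.array([1.0, 0.0])).sum().backward()
        assert x.grad is not None
        np.testing.assert_allclose(y.data, [[0.25, 0.75]], atol=1e-6)


class TestDistanceExamples:
    def test_tv_hand_example(self):
        assert tv_distance([0.7, 0.3], [0.4, 0.6]) == pytest.approx(0.3)

    def test_tv_disjoint_supports(self):
        assert tv_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_tv_identity(self):
        p = np.array([0.2, 0.5, 0.3])
        assert tv_distance(p, p) == 0.0

    def test_js_identity_and_bound(self):
        p = np.array([0.3, 0.7])
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-7)
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(
            math.log(2), abs=1e-6)

    def test_hellinger_examples(self):
        p = np.array([0.1, 0.9])
        assert hellinger_distance(p, p) == 0.0
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        expected = HELLINGER_NORMALIZATION * np.linalg.norm(
            np.sqrt([0.5, 0.5]) - np.sqrt([0.9, 0.1]))
        assert hellinger_distance([0.5, 0.5], [0.9, 0.1]) == pytest.approx(
            expected, abs=1e-10)

    def test_bhattacharyya_examples(self):
        p = np.array([0.4, 0.6])
        assert bhattacharyya_distance(p, p) == pytest.approx(0.0, abs=1e-7)
        assert bhattacharyya_distance([1, 0], [0, 1]) == pytest.approx(
            -math.log(EPS))
        assert bhattacharyya_distance([0.5, 0.5], [0.9, 0.1]) == pytest.approx(
            -math.log(math.sqrt(0.45) + math.sqrt(0.05)), abs=1e-10)

    def test_length_mismatch_raises(self):
        for fn in (tv_distance, js_divergence, hellinger_distance,
                   bhattacharyya_distance):
            with pytest.raises(DimensionError):
                fn([0.5, 0.5], [1.0, 0.0, 0.0])


class TestOracleEquivalence:
    @pytest.mark.parametrize("fn,oracle", [
        (tv_distance, tv_oracle),
        (js_divergence, js_oracle),
        (hellinger_distance, hellinger_oracle),
        (bhattacharyya_distance, bhattacharyya_oracle),
    ])
    def test_matches_loop_oracle(self, fn, oracle):
        for p, q in random_prob_pairs(500, seed=11):
            assert fn(p, q) == pytest.approx(oracle(p, q), abs=1e-8)


class TestMetricAxioms:
    def test_axioms_on_random_pairs(self):
        rng = np.random.default_rng(123)
        n = 2000
        for p, q in random_prob_pairs(n, seed=123):
            r = rng.random(len(p))
            r /= r.sum()
            tv_pq = tv_distance(p, q)
            assert tv_pq == pytest.approx(tv_distance(q, p))
            assert 0.0 <= tv_pq <= 1.0
            assert tv_pq <= tv_distance(p, r) + tv_distance(r, q) + 1e-12
            h_pq = hellinger_distance(p, q)
            assert h_pq == pytest.approx(hellinger_distance(q, p))
            assert 0.0 <= h_pq <= 1.0 + 1e-12
            assert h_pq <= (hellinger_distance(p, r)
                            + hellinger_distance(r, q) + 1e-12)
            js_pq = js_divergence(p, q)
            assert js_pq == pytest.approx(js_divergence(q, p), abs=1e-12)
            assert -1e-9 <= js_pq <= math.log(2) + 1e-9
            b_pq = bhattacharyya_distance(p, q)
            assert b_pq == pytest.approx(bhattacharyya_distance(q, p))
            assert b_pq >= -1e-9

    def test_tv_order_consistency_along_a_ray(self):
        rng = np.random.default_rng(5)
        p = rng.random(6)
        p /= p.sum()
        d = rng.random(6)
        d /= d.sum()
        prev = -1.0
        for t in np.linspace(0, 1, 21):
            q = (1 - t) * p + t * d
            cur = tv_distance(p, q)
            assert cur >= prev - 1e-12
            prev = cur

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=16),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=16))
    @settings(max_examples=50, deadline=None)
    def test_tv_symmetric_bounded_hypothesis(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / sum(a[:n])
        q = np.array(b[:n]) / sum(b[:n])
        d = tv_distance(p, q)
        assert d == pytest.approx(tv_distance(q, p))
        assert 0.0 <= d <= 1.0 + 1e-12


def _stacks(rng, shape=(2, 2, 4, 4), depth=2, grad=False):
    cur, ref = [], []
    for _ in range(depth):
        a = rng.random(shape) + 0.05
        a /= a.sum(-1, keepdims=True)
        b = rng.random(shape) + 0.05
        b /= b.sum(-1, keepdims=True)
        cur.append(Tensor(a, requires_grad=grad))
        ref.append(Tensor(b))
    return cur, ref


class TestAttentionAlignmentLoss:
    def test_identity_is_zero_for_all_distances(self):
        rng = np.random.default_rng(0)
        cur, _ = _stacks(rng)
        for dist in ("tv", "js", "hellinger", "bhattacharyya"):
            cfg = AlignmentLossConfig(distance=dist)
            assert attention_alignment_loss(cur, cur, cfg).item() == \
                pytest.approx(0.0, abs=1e-6)

    def test_single_differing_row_sum_reduction(self):
        base = np.zeros((1, 1, 2, 2))
        base[..., 0, 0] = 1.0
        base[..., 1, 1] = 1.0
        other = base.copy()
        other[0, 0, 0] = [0.0, 1.0]  # one row flipped to disjoint support
        cfg = AlignmentLossConfig(distance="tv", reduction="sum")
        val = attention_alignment_loss([Tensor(other)], [Tensor(base)], cfg)
        assert val.item() == pytest.approx(1.0, abs=1e-6)

    def test_mean_equals_sum_over_row_count(self):
        rng = np.random.default_rng(3)
        cur, ref = _stacks(rng, shape=(2, 3, 5, 5), depth=3)
        rows_per_block = 2 * 3 * 5
        s = attention_alignment_loss(
            cur, ref, AlignmentLossConfig(distance="tv", reduction="sum"))
        m = attention_alignment_loss(
            cur, ref, AlignmentLossConfig(distance="tv", reduction="mean"))
        assert m.item() == pytest.approx(s.item() / rows_per_block, rel=1e-9)

    def test_matches_rowwise_vector_oracle(self):
        rng = np.random.default_rng(9)
        cur, ref = _stacks(rng, shape=(1, 2, 3, 3), depth=2)
        for dist, fn in [("tv", tv_oracle), ("js", js_oracle),
                         ("hellinger", hellinger_oracle),
                         ("bhattacharyya", bhattacharyya_oracle)]:
            cfg = AlignmentLossConfig(distance=dist, reduction="sum")
            got = attention_alignment_loss(cur, ref, cfg).item()
            want = 0.0
            for c, r in zip(cur, ref):
                for q_row, p_row in zip(c.data.reshape(-1, 3),
                                        r.data.reshape(-1, 3)):
                    qn = np.abs(q_row) / (np.abs(q_row).sum() + EPS)
                    pn = np.abs(p_row) / (np.abs(p_row).sum() + EPS)
                    want += fn(qn, pn)
            assert got == pytest.approx(want, abs=1e-7)

    def test_depth_mismatch_raises(self):
        rng = np.random.default_rng(0)
        cur, ref = _stacks(rng)
        with pytest.raises(DimensionError):
            attention_alignment_loss(cur[:1], ref, AlignmentLossConfig())

    def test_block_shape_mismatch_names_block(self):
        rng = np.random.default_rng(0)
        cur, ref = _stacks(rng)
        ref[1] = Tensor(rng.random((2, 2, 5, 5)))
        with pytest.raises(DimensionError, match="block 1"):
            attention_alignment_loss(cur, ref, AlignmentLossConfig())

    def test_block_subset_selector(self):
        rng = np.random.default_rng(4)
        cur, ref = _stacks(rng, depth=3)
        full = attention_alignment_loss(
            cur, ref, AlignmentLossConfig(distance="tv", reduction="sum"))
        only0 = attention_alignment_loss(
            cur, ref, AlignmentLossConfig(distance="tv", reduction="sum",
                                          blocks=(0,)))
        both = attention_alignment_loss(
            cur, ref, AlignmentLossConfig(distance="tv", reduction="sum",
                                          blocks=(1, 2)))
        assert full.item() == pytest.approx(only0.item() + both.item(),
                                            rel=1e-9)


class TestCompositeLoss:
    def test_lambda_zero_total_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        cur, ref = _stacks(rng)
        cfg = AlignmentLossConfig(distance="tv", lam=0.0)
        bd = composite_loss(logits, np.array([0, 1, 2, 0]), cur, ref, cfg)
        assert bd.total.item() == bd.cross_entropy.item()

    def test_absent_reference_means_zero_attention_term(self):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((2, 3)), requires_grad=True)
        bd = composite_loss(logits, np.array([0, 1]), None, None,
                            AlignmentLossConfig(lam=2.0))
        assert bd.attention.item() == 0.0
        assert bd.total.item() == bd.cross_entropy.item()

    def test_total_decomposition(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        cur, ref = _stacks(rng)
        cfg = AlignmentLossConfig(distance="js", lam=0.7)
        bd = composite_loss(logits, np.array([0, 1, 2, 0]), cur, ref, cfg)
        assert bd.total.item() == pytest.approx(
            bd.cross_entropy.item() + 0.7 * bd.attention.item(), abs=1e-6)

    def test_one_hot_perfect_logits_drive_ce_to_zero(self):
        labels = np.array([0, 1])
        logits = Tensor(np.array([[30.0, 0, 0], [0, 30.0, 0]]))
        bd = composite_loss(logits, labels, None, None, AlignmentLossConfig())
        assert bd.cross_entropy.item() == pytest.approx(0.0, abs=1e-10)

    def test_out_of_range_label_raises(self):
        logits = Tensor(np.zeros((2, 3)))
        with pytest.raises(InvalidLabelError):
            composite_loss(logits, np.array([0, 5]), None, None,
                           AlignmentLossConfig())

    def test_gradients_flow_through_both_terms(self):
        rng = np.random.default_rng(2)
        logits = Tensor(rng.standard_normal((2, 3)), requires_grad=True)
        cur, ref = _stacks(rng, grad=True)
        cfg = AlignmentLossConfig(distance="tv", lam=1.5)
        bd = composite_loss(logits, np.array([0, 1]), cur, ref, cfg)
        bd.total.backward()
        assert logits.grad is not None and np.abs(logits.grad).sum() > 0
        assert cur[0].grad is not None and np.abs(cur[0].grad).sum() > 0


class TestFiniteDifferenceGradients:
    def test_grad_wrt_logits_and_attention_logits(self):
        """Composite-loss gradient check on a tiny instance at 1e-4 rel tol.

        The attention operand is produced through a softmax so the check
        exercises the same path training uses.
        """
        rng = np.random.default_rng(7)
        labels = np.array([0, 1])
        raw_logits = rng.standard_normal((2, 3))
        raw_attn = rng.standard_normal((1, 1, 3, 3))
        ref = rng.random((1, 1, 3, 3)) + 0.1
        ref /= ref.sum(-1, keepdims=True)
        cfg = AlignmentLossConfig(distance="tv", lam=0.8)

        def value(rl, ra):
            logits = Tensor(rl, requires_grad=True)
            attn = T.softmax(Tensor(ra, requires_grad=True), axis=-1)
            bd = composite_loss(logits, labels, [attn], [Tensor(ref)], cfg)
            return bd, logits, attn

        bd, logits_t, _ = value(raw_logits, raw_attn)
        attn_parent = None
        bd.total.backward()
        analytic_logits = logits_t.grad.copy()

        # numeric wrt logits
        for idx in [(0, 0), (1, 2)]:
            eps = 1e-6
            up = raw_logits.copy(); up[idx] += eps
            dn = raw_logits.copy(); dn[idx] -= eps
            num = (value(up, raw_attn)[0].total.item()
                   - value(dn, raw_attn)[0].total.item()) / (2 * eps)
            assert analytic_logits[idx] == pytest.approx(num, rel=1e-4,
                                                         abs=1e-8)

        # numeric wrt pre-softmax attention logits
        base = Tensor(raw_attn, requires_grad=True)
        attn = T.softmax(base, axis=-1)
        bd2 = composite_loss(Tensor(raw_logits), labels, [attn],
                             [Tensor(ref)], cfg)
        bd2.total.backward()
        for idx in [(0, 0, 0, 1), (0, 0, 2, 2)]:
            eps = 1e-6
            up = raw_attn.copy(); up[idx] += eps
            dn = raw_attn.copy(); dn[idx] -= eps
            num = (value(raw_logits, up)[0].total.item()
                   - value(raw_logits, dn)[0].total.item()) / (2 * eps)
            assert base.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestConfigValidation:
    def test_unknown_distance_rejected(self):
        with pytest.raises(ConfigurationError):
            AlignmentLossConfig(distance="wasserstein")

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            AlignmentLossConfig(lam=-0.1)

    def test_epsilon_range_enforced(self):
        with pytest.raises(ConfigurationError):
            AlignmentLossConfig(epsilon=0.1)
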