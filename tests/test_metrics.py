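"""Evaluation statistics."""

import math

import numpy as np
import pytest

from duplexscan import (
    BasePairSet,
    confusion,
    correlation_report,
    intervals_overlap,
    rank_product,
    relative_hit_score,
)


def test_basepairset_enforces_monogamy():
    BasePairSet([(1, 10), (2, 9)])
    with pytest.raises(ValueError, match="query"):
        BasePairSet([(1, 10), (1, 9)])
    with pytest.raises(ValueError, match="target"):
        BasePairSet([(1, 10), (2, 10)])


def test_confusion_perfect_prediction():
    truth = BasePairSet((i, 20 - i) for i in range(1, 11))
    rep = confusion(truth, truth)
    assert (rep.sen, rep.ppv, rep.f, rep.mcc) == (1.0, 1.0, 1.0, 1.0)


def test_confusion_arithmetic():
    truth = BasePairSet((i, 30 - i) for i in range(1, 11))
    pred = BasePairSet([(i, 30 - i) for i in range(1, 10)] + [(15, 2)])
    rep = confusion(pred, truth)
    assert (rep.tp, rep.fp, rep.fn) == (9, 1, 1)
    assert rep.sen == pytest.approx(0.9)
    assert rep.ppv == pytest.approx(0.9)
    assert rep.mcc == pytest.approx(0.9)
    assert rep.f == pytest.approx(0.9)


def test_confusion_degenerate_flagged():
    truth = BasePairSet([(1, 5)])
    rep = confusion(BasePairSet([]), truth)
    assert rep.sen == 0.0 and rep.ppv == 0.0 and rep.degenerate


def test_confusion_swap_exchanges_sen_and_ppv():
    a = BasePairSet([(1, 9), (2, 8), (3, 7)])
    b = BasePairSet([(1, 9), (2, 8), (4, 6)])
    r1, r2 = confusion(a, b), confusion(b, a)
    assert r1.sen == r2.ppv and r1.ppv == r2.sen and r1.mcc == r2.mcc


def test_rank_product_examples():
    # best everywhere -> RP 1
    rp = rank_product({"a": [1, 2, 3], "b": [5, 6, 7], "c": [9, 9, 9]})
    assert rp["a"] == pytest.approx(1.0)
    # tie -> both rank 1.5
    rp = rank_product({"a": [4], "b": [4]})
    assert rp["a"] == rp["b"] == pytest.approx(1.5)
    # ranks (1, 4) over two interactions -> geometric mean 2
    counts = {"a": [1, 40], "b": [2, 10], "c": [3, 20], "d": [4, 30]}
    assert rank_product(counts)["a"] == pytest.approx(2.0)


def test_rank_product_invariant_under_monotone_transform():
    counts = {"a": [3, 7, 1], "b": [10, 2, 5], "c": [6, 6, 9]}
    transformed = {g: [c**2 + 1 for c in v] for g, v in counts.items()}
    assert rank_product(counts) == rank_product(transformed)


def test_relative_hit_score_examples():
    rhs = relative_hit_score({"a": [1], "b": [10]})
    assert rhs["a"] == pytest.approx(0.9)
    assert rhs["b"] == pytest.approx(0.0)
    # scale invariance per interaction
    rhs2 = relative_hit_score({"a": [7], "b": [70]})
    assert rhs2 == pytest.approx(rhs)
    # method holding the max count everywhere scores 0
    rhs3 = relative_hit_score({"a": [5, 8], "b": [9, 20], "c": [2, 3]})
    assert rhs3["b"] == pytest.approx(0.0)


def test_relative_hit_score_skips_all_zero_interactions():
    rhs = relative_hit_score({"a": [0, 1], "b": [0, 4]})
    assert rhs["a"] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        relative_hit_score({"a": [0], "b": [0]})


def test_correlation_linear_and_monotone():
    x = np.linspace(-30, -5, 40)
    rep = correlation_report(x, 2 * x + 1)
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.spearman_rho == pytest.approx(1.0)
    assert rep.top_overlap_pct == pytest.approx(100.0)
    rep2 = correlation_report(x, np.exp(x / 10.0))
    assert rep2.spearman_rho == pytest.approx(1.0)


def test_correlation_constant_vector_flagged():
    rep = correlation_report([1, 1, 1, 1], [1, 2, 3, 4])
    assert rep.flagged and math.isnan(rep.pearson_r)


def test_top_k_overlap_counts_shared_candidates():
    x = [-10, -9, -8, -7] + [0.0] * 36   # top 2 of 40 at 5%
    y = [-10, -1, -8, -7] + [0.0] * 36
    rep = correlation_report(x, y)
    assert rep.top_overlap_pct == pytest.approx(50.0)


def test_intervals_overlap_rule():
    assert intervals_overlap((5, 10), (10, 20))
    assert not intervals_overlap((5, 9), (10, 20))
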