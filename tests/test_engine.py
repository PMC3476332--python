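"""Scanner correctness: closed forms, oracle chain, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duplexscan import (
    NucSeq,
    best_hit,
    brute_force_enumerate,
    collect_candidates,
    extend_and_traceback,
    full_dp_reference,
    make_matrix,
    scan,
    search,
)
from duplexscan.engine import STRUCT_GAP_Q, STRUCT_GAP_T, STRUCT_PAIR
from duplexscan.matrix import PAIR_TYPE, encode

from conftest import random_nucseq


def test_perfect_gc_helix_closed_form(m04, t04):
    q = NucSeq("q", "G" * 10)
    t = NucSeq("t", "C" * 10)
    expected = -100 * 9 * t04.stack_energy("GG", "CC")
    assert scan(q, t, m04).best_score.max() == expected
    score, hit = full_dp_reference(q, t, m04)
    assert score == expected
    assert hit.structure == STRUCT_PAIR * 10
    # energy: stacks + duplex initiation, no end penalties for G-C termini
    assert hit.energy == pytest.approx(-expected / 100.0 + t04.duplex_init / 100.0)


def test_no_canonical_pair_scores_zero(m04):
    q, t = NucSeq("q", "AAAA"), NucSeq("t", "CCCC")
    res = scan(q, t, m04)
    assert (res.best_score == 0).all()
    assert collect_candidates(res) == []
    assert full_dp_reference(q, t, m04) == (0, None)
    assert brute_force_enumerate(q, t, m04) == 0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        NucSeq("q", "")


@pytest.mark.parametrize("penalized", [False, True])
def test_oracle_chain_on_random_tiny_instances(m04, m04_pen, rng, penalized):
    """scan == full-matrix DP == exhaustive enumeration."""
    mat = m04_pen if penalized else m04
    for _ in range(150):
        q = random_nucseq(rng, 1, 6, seq_id="q")
        t = random_nucseq(rng, 1, 6, seq_id="t")
        bf = brute_force_enumerate(q, t, mat)
        fd, _ = full_dp_reference(q, t, mat)
        sc = int(scan(q, t, mat).best_score.max())
        assert bf == fd == sc, (q.residues, t.residues)


def test_scan_equals_full_dp_on_larger_instances(m04, rng):
    for _ in range(25):
        q = random_nucseq(rng, 10, 60, seq_id="q")
        t = random_nucseq(rng, 20, 160, seq_id="t")
        fd, _ = full_dp_reference(q, t, m04)
        assert int(scan(q, t, m04).best_score.max()) == fd


def test_scan_memory_is_linear_in_query(m04):
    q = NucSeq("q", "GCAU" * 25)   # m = 100
    t = NucSeq("t", "AUGC" * 100)  # n = 400
    res = scan(q, t, m04)
    assert res.aux_cells == 6 * (len(q) + 1)
    assert res.aux_cells < len(q) * len(t) / 10


def _check_structure(hit, query, target):
    assert hit.structure[0] == STRUCT_PAIR and hit.structure[-1] == STRUCT_PAIR
    q_cols = [c for c in hit.structure if c != STRUCT_GAP_Q]
    t_cols = [c for c in hit.structure if c != STRUCT_GAP_T]
    assert len(q_cols) == hit.q_end - hit.q_start + 1
    assert len(t_cols) == hit.t_end - hit.t_start + 1
    # walk the alignment: pair columns must be canonical, antiparallel
    qi, tj = hit.q_start, hit.t_end
    qcodes, tcodes = encode(query.residues), encode(target.residues)
    for col in hit.structure:
        if col == STRUCT_PAIR:
            assert PAIR_TYPE[qcodes[qi - 1], tcodes[tj - 1]] >= 0
        if col != STRUCT_GAP_Q:
            qi += 1
        if col != STRUCT_GAP_T:
            tj -= 1
    assert qi == hit.q_end + 1 and tj == hit.t_start - 1


def test_hit_structures_are_valid(m04, rng):
    found = 0
    for _ in range(30):
        q = random_nucseq(rng, 8, 30, with_n=False, seq_id="q")
        t = random_nucseq(rng, 15, 60, with_n=False, seq_id="t")
        for hit in search(q, t, m04, threshold=0.0):
            _check_structure(hit, q, t)
            found += 1
    assert found > 50


def test_swap_symmetry_exact_on_perfect_complements(m04, rng):
    from duplexscan import perfect_complement

    for _ in range(15):
        q = random_nucseq(rng, 10, 35, with_n=False, seq_id="q")
        t = perfect_complement(q)
        fwd, rev = scan(q, t, m04), scan(t, q, m04)
        assert fwd.best_score.max() == rev.best_score.max()
        big = len(q) + len(t)
        h1 = extend_and_traceback(q, t, m04, collect_candidates(fwd)[0], window=big)
        h2 = extend_and_traceback(t, q, m04, collect_candidates(rev)[0], window=big)
        assert h1.score == h2.score
        assert h1.energy == pytest.approx(h2.energy)
        assert (h1.q_start, h1.q_end, h1.t_start, h1.t_end) == (
            h2.t_start, h2.t_end, h2.q_start, h2.q_end)


def test_swap_symmetry_bounded_on_random_pairs(m04, rng):
    # loops mixing gaps and mismatches have order-dependent entry/exit
    # costs, so swapped optima may differ by up to about one bulge-opening
    # per mixed loop; pure helices/bulges/symmetric loops are exact
    for _ in range(25):
        q = random_nucseq(rng, 8, 40, with_n=False, seq_id="q")
        t = random_nucseq(rng, 15, 70, with_n=False, seq_id="t")
        fwd = int(scan(q, t, m04).best_score.max())
        rev = int(scan(t, q, m04).best_score.max())
        assert abs(fwd - rev) <= 300


def test_unpairable_flanks_do_not_change_optimum(m04, rng):
    for _ in range(10):
        q = random_nucseq(rng, 6, 20, with_n=False, seq_id="q")
        t = random_nucseq(rng, 10, 30, with_n=False, seq_id="t")
        base = scan(q, t, m04).best_score.max()
        qf = NucSeq("q", "NNN" + q.residues + "NN")
        tf = NucSeq("t", "NN" + t.residues + "NNN")
        assert scan(qf, tf, m04).best_score.max() == base


def test_penalty_never_improves_energies(m04, m04_pen, rng):
    for _ in range(10):
        q = random_nucseq(rng, 10, 25, with_n=False, seq_id="q")
        t = random_nucseq(rng, 15, 40, with_n=False, seq_id="t")
        h0 = best_hit(q, t, m04, window=80)
        h3 = best_hit(q, t, m04_pen, window=80)
        e0 = h0.energy if h0 else 0.0
        e3 = h3.energy if h3 else 0.0
        assert e3 >= e0 - 1e-9


def test_collect_candidates_ordering_and_threshold(m04):
    q = NucSeq("q", "GGGGGG")
    t = NucSeq("t", "CCCCCCAAACCCCCC")
    res = scan(q, t, m04)
    cands = collect_candidates(res, 0.0)
    assert cands, "complementary site must be found"
    scores = [c.score for c in cands]
    assert scores == sorted(scores, reverse=True)
    strong = collect_candidates(res, -10.0)
    assert all(c.score >= 1000 for c in strong)
    with pytest.raises(ValueError):
        collect_candidates(res, +1.0)


def test_two_disjoint_sites_both_reported(m04):
    site = "GGGGGGGG"
    target = "AAAA" + "CCCCCCCC" + "AAAAAAAAAA" + "CCCCCCCC" + "AAAA"
    hits = search(NucSeq("q", site), NucSeq("t", target), m04, threshold=-10.0, merge=True)
    regions = {(h.t_start <= 12, h.t_start >= 23) for h in hits}
    assert (True, False) in regions and (False, True) in regions


def test_repeated_query_site_links_one_query_position(m04):
    # two copies of the complement in the query, one site in the target:
    # each target row keeps only its best query end
    q = NucSeq("q", "GGGGGGGG" + "AAAA" + "GGGGGGGG")
    t = NucSeq("t", "AACCCCCCCCAA")
    res = scan(q, t, m04)
    rows = [j for j in range(1, len(t) + 1) if res.best_score[j] > 0]
    assert rows
    for j in rows:
        assert res.qends[j, 0] > 0  # a single linked query end per row


def test_window_truncation_returns_best_fitting_duplex(m04):
    q = NucSeq("q", "G" * 30)
    t = NucSeq("t", "C" * 30)
    cand = collect_candidates(scan(q, t, m04))[0]
    hit = extend_and_traceback(q, t, m04, cand, window=10)
    assert hit.q_end - hit.q_start + 1 <= 10
    assert hit.t_end - hit.t_start + 1 <= 10
    assert hit.structure == STRUCT_PAIR * 10


def test_suboptimal_layers_track_distinct_query_ends(m04):
    q = NucSeq("q", "GGGGGGGGACGACGAGGGGGGGG")
    t = NucSeq("t", "CCCCCCCC")
    res = scan(q, t, m04, n_subopt=2)
    j = int(np.argmax(res.scores[:, 1]))
    assert res.scores[j, 1] > 0
    assert res.qends[j, 0] != res.qends[j, 1]
    assert res.scores[j, 0] >= res.scores[j, 1]


def test_search_sorted_by_energy(m04):
    q = NucSeq("q", "GGGGGGGGAAAAGGGG")
    t = NucSeq("t", "CCCCAAAACCCCCCCC")
    hits = search(q, t, m04, threshold=0.0)
    energies = [h.energy for h in hits]
    assert energies == sorted(energies)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=1, max_size=5),
       st.text(alphabet="ACGU", min_size=1, max_size=5))
def test_scan_matches_brute_force_property(s, t):
    mat = make_matrix("t04")
    q, r = NucSeq("q", s), NucSeq("t", t)
    assert int(scan(q, r, mat).best_score.max()) == brute_force_enumerate(q, r, mat)
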