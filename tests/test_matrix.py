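"""Composition rules and invariants of the dinucleotide matrix."""

import itertools

import numpy as np
import pytest

from duplexscan import column_score, dump_matrix_tsv, load_matrix_tsv, make_matrix
from duplexscan.matrix import GAP, N, PAIR_TYPE, _NEG
from duplexscan.params import affine_model, load_params


def test_gap_extension_entry(m04):
    # bulge extension 0.4 kcal/mol -> -40 centi-kcal at zero penalty
    assert column_score(m04, "A", "A", "-", "-") == -40


def test_start_entries(m04, m04_pen):
    # non-canonical columns may not start an alignment
    assert m04.start[0, 1] == 0  # (A, C)
    pair_mask = PAIR_TYPE >= 0
    assert (np.asarray(m04.start)[~pair_mask] == 0).all()
    assert (np.asarray(m04.start)[pair_mask] == 0).all()
    # with a per-nucleotide penalty the initiating column is charged too
    assert (np.asarray(m04_pen.start)[pair_mask] == -30).all()


def test_stack_entry_matches_embedded_table(m04, t04):
    # 5'GC/3'CG: score is -100x the embedded stack energy
    assert column_score(m04, "G", "C", "C", "G") == -int(round(100 * t04.stack_energy("GC", "CG")))


def test_loop_entries_follow_affine_components(m04, t04):
    aff = affine_model(t04)
    half = aff.intloop_open / 2.0
    es = aff.intloop_ext_sym
    term = t04.terminal_au_gu
    # pair -> mismatch, GC closing pair (no closure penalty)
    assert column_score(m04, "G", "A", "C", "A") == -int(round(half + es))
    # pair -> mismatch closing on AU: closure charged
    assert column_score(m04, "A", "A", "U", "A") == -int(round(half + es)) - term
    # mismatch -> pair entering a GU pair: closure charged
    assert column_score(m04, "A", "G", "A", "U") == -int(round(half)) - term
    # mismatch -> mismatch
    assert column_score(m04, "A", "A", "A", "A") == -int(round(es))
    # pair -> gap opens a bulge (affine cost of a 1-nt gap run)
    assert column_score(m04, "G", "G", "C", "-") == -int(round(aff.bulge_open + aff.bulge_ext))
    # mismatch -> gap extends an interior loop asymmetrically
    assert column_score(m04, "A", "A", "A", "-") == -int(round(aff.intloop_ext_asym))
    # gap -> pair pays only the closure of the new pair
    assert column_score(m04, "A", "G", "-", "C") == 0
    assert column_score(m04, "A", "A", "-", "U") == -term


def test_entries_with_n_never_positive(m04):
    scores = np.asarray(m04.scores)
    for q1, q2, t1, t2 in itertools.product(range(6), repeat=4):
        if N in (q1, q2, t1, t2):
            val = scores[6 * q1 + q2, 6 * t1 + t2]
            assert val <= 0


def test_unreachable_transitions_are_sentinels(m04):
    # opposite-strand gaps are never adjacent in the three-state model
    assert m04.scores[6 * GAP + 0, 6 * 0 + GAP] == _NEG
    # a column cannot have gaps on both strands
    assert m04.scores[6 * 0 + GAP, 6 * 0 + GAP] == _NEG


def test_monotone_in_penalty(m04, m04_pen):
    s0, s3 = np.asarray(m04.scores), np.asarray(m04_pen.scores)
    valid = s0 > _NEG
    assert (s3[valid] <= s0[valid]).all()
    assert (s3[valid] == s0[valid] - 30).all()


def test_penalty_must_be_nonnegative():
    with pytest.raises(ValueError):
        make_matrix("t04", per_nt_penalty=-0.1)


def test_tsv_round_trip(m04_pen):
    text = dump_matrix_tsv(m04_pen)
    back = load_matrix_tsv(text)
    assert back.vintage == m04_pen.vintage
    assert back.per_nt_penalty == m04_pen.per_nt_penalty
    assert np.array_equal(back.scores, m04_pen.scores)
    assert np.array_equal(back.start, m04_pen.start)


def test_rebuild_is_bit_exact(m04):
    again = make_matrix("t04")
    assert np.array_equal(np.asarray(m04.scores), np.asarray(again.scores))


def test_column_score_rejects_foreign_symbols(m04):
    with pytest.raises(ValueError, match="alphabet"):
        column_score(m04, "A", "B", "U", "U")
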