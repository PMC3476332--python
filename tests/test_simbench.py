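"""Simulated mutated-complement benchmark."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duplexscan import (
    NucSeq,
    SimConfig,
    generate_benchmark,
    levenshtein,
    mutate,
    perfect_complement,
    random_seq,
)
from duplexscan.simbench import benchmark_fasta


def test_random_seq_gc_extremes(rng):
    assert set(random_seq(200, 100, rng).residues) <= set("GC")
    assert set(random_seq(200, 0, rng).residues) <= set("AU")


def test_random_seq_gc_fraction_binomial(rng):
    n = 10_000
    s = random_seq(n, 50, rng).residues
    gc = (s.count("G") + s.count("C")) / n
    assert abs(gc - 0.5) < 3 * 0.5 / np.sqrt(n)


def test_random_seq_validation(rng):
    with pytest.raises(ValueError):
        random_seq(0, 50, rng)
    with pytest.raises(ValueError):
        random_seq(10, 120, rng)


def test_perfect_complement_examples():
    assert perfect_complement(NucSeq("a", "GGGG")).residues == "CCCC"
    assert perfect_complement(NucSeq("a", "AUGC")).residues == "GCAU"
    with pytest.raises(ValueError, match="N"):
        perfect_complement(NucSeq("a", "ACGN"))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=1, max_size=40))
def test_complement_is_an_involution(s):
    seq = NucSeq("s", s)
    assert perfect_complement(perfect_complement(seq)).residues == s


def test_mutate_zero_rounds_is_identity(rng):
    s = NucSeq("s", "ACGUACGUACGU")
    assert mutate(s, 0, rng=rng).residues == s.residues


def test_single_round_mutants_have_ld_one(rng):
    s = NucSeq("s", "ACGUGGCCAAUUACGUGGCC")
    for _ in range(200):
        m = mutate(s, 1, rng=rng)
        assert levenshtein(s.residues, m.residues) == 1


def test_mutation_operation_frequencies(rng):
    """Substitution/deletion/insertion drawn with 0.75/0.17/0.08."""
    s = NucSeq("s", "ACGU" * 13)  # 52-mer, length tracks indels
    counts = {"sub": 0, "del": 0, "ins": 0}
    n = 4000
    for _ in range(n):
        m = mutate(s, 1, rng=rng)
        if len(m) < len(s):
            counts["del"] += 1
        elif len(m) > len(s):
            counts["ins"] += 1
        else:
            counts["sub"] += 1
    for key, p in (("sub", 0.75), ("del", 0.17), ("ins", 0.08)):
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[key] - n * p) < 3 * sigma, counts


@lru_cache(maxsize=None)
def _lev_recursive(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return min(
        _lev_recursive(a[1:], b) + 1,
        _lev_recursive(a, b[1:]) + 1,
        _lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


def test_levenshtein_against_recursive_definition(rng):
    assert levenshtein("ACGU", "ACGU") == 0
    assert levenshtein("ACGU", "") == 4
    for _ in range(50):
        a = "".join(rng.choice(list("ACGU"), size=int(rng.integers(0, 7))))
        b = "".join(rng.choice(list("ACGU"), size=int(rng.integers(0, 7))))
        assert levenshtein(a, b) == _lev_recursive(a, b)


def test_probabilities_must_sum_to_one():
    with pytest.raises(ValueError):
        SimConfig(sub_p=0.5, del_p=0.5, ins_p=0.5)


def _small_config(seed=11):
    return SimConfig(lengths=(50,), gc_contents=(50,), n_seqs_per_class=5, seed=seed)


def test_benchmark_reproducible_and_annotated():
    d1 = generate_benchmark(_small_config())
    d2 = generate_benchmark(_small_config())
    assert benchmark_fasta(d1) == benchmark_fasta(d2)
    assert any(d.ld == 0 for d in d1)
    for d in d1:
        assert d.ld <= d.n_mutation_rounds
        assert d.ld == levenshtein(
            perfect_complement(d.original).residues, d.mutant_target.residues
        )
    # rounds 0..floor(50/3) for each of the 5 sequences
    assert len(d1) == 5 * 17
    assert len({d.ld for d in d1}) >= 10


def test_benchmark_differs_across_seeds():
    assert generate_benchmark(_small_config(1))[0].original.residues != \
        generate_benchmark(_small_config(2))[0].original.residues
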