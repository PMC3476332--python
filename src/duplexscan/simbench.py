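"""Simulated duplex benchmark: mutated perfect complements.

Random RNA sequences are drawn over a grid of lengths and GC contents; for
each sequence the perfect (reverse Watson-Crick) complement — its optimal
binding partner — is derived and then degraded by stepwise point mutation:
at every round a random position is substituted (probability 0.75),
deleted (0.17) or a random nucleotide is inserted (0.08).  Keeping the
mutant after every cumulative round yields duplexes spanning a wide range
of Levenshtein distances (LD) from the optimal partner, which is what the
scanner-vs-full-model comparisons are stratified by.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import edlib
import numpy as np

from .engine import NucSeq

__all__ = [
    "SimConfig",
    "SimDuplex",
    "random_seq",
    "perfect_complement",
    "mutate",
    "levenshtein",
    "generate_benchmark",
    "benchmark_fasta",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class SimConfig:
    """Benchmark layout and mutation process.

    Defaults follow the study conditions: lengths 20..50 nt in steps of 5,
    GC contents 10/30/50/70/90%, substitution/deletion/insertion with
    probabilities 0.75/0.17/0.08, and a length-dependent mutation depth of
    ``floor(length / 3)`` rounds so LDs span up to about a third of the
    sequence length.
    """

    lengths: Tuple[int, ...] = (20, 25, 30, 35, 40, 45, 50)
    gc_contents: Tuple[int, ...] = (10, 30, 50, 70, 90)
    n_seqs_per_class: int = 1000
    sub_p: float = 0.75
    del_p: float = 0.17
    ins_p: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(self.sub_p + self.del_p + self.ins_p, 1.0):
            raise ValueError("mutation probabilities must sum to 1")
        if min(self.sub_p, self.del_p, self.ins_p) < 0:
            raise ValueError("mutation probabilities must be >= 0")

    def max_rounds(self, length: int) -> int:
        return length // 3


@dataclass(frozen=True)
class SimDuplex:
    """One benchmark instance: a sequence and its mutated complement."""

    original: NucSeq
    mutant_target: NucSeq
    n_mutation_rounds: int
    ld: int  # Levenshtein distance from the perfect complement


def random_seq(length: int, gc_percent: float, rng: np.random.Generator, seq_id: str = "rand") -> NucSeq:
    """I.i.d. sequence with P(G) = P(C) = gc/200 and P(A) = P(U) = (100-gc)/200."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_percent <= 100:
        raise ValueError("GC content must be within 0..100%")
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    res = rng.choice(np.array(list("ACGU")), size=length, p=[a, g, g, a])
    return NucSeq(seq_id, "".join(res))


def perfect_complement(seq: NucSeq) -> NucSeq:
    """Reverse Watson-Crick complement — the perfectly pairing antiparallel
    partner.  Rejects sequences containing N."""
    if "N" in seq.residues:
        raise ValueError(f"sequence {seq.id!r} contains N; complement undefined")
    return NucSeq(seq.id + "|rc", seq.residues.translate(_COMPLEMENT)[::-1])


def mutate(
    seq: NucSeq,
    n_rounds: int,
    probs: Tuple[float, float, float] = (0.75, 0.17, 0.08),
    rng: np.random.Generator | None = None,
) -> NucSeq:
    """Apply ``n_rounds`` sequential point edits (substitution, deletion,
    insertion with the given probabilities).  Substitutions always change
    the base; insertions draw a uniform base at a uniform position
    (including both ends).  Stops early if the sequence would vanish."""
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    bases = "ACGU"
    res = list(seq.residues)
    applied = 0
    for _ in range(n_rounds):
        if not res:
            break
        op = rng.choice(3, p=probs)
        if op == 0:  # substitution with a different base
            pos = int(rng.integers(len(res)))
            choices = [b for b in bases if b != res[pos]]
            res[pos] = choices[int(rng.integers(len(choices)))]
        elif op == 1:  # deletion; never shrink to the empty sequence
            if len(res) == 1:
                break
            pos = int(rng.integers(len(res)))
            del res[pos]
        else:  # insertion, ends included
            pos = int(rng.integers(len(res) + 1))
            res.insert(pos, bases[int(rng.integers(4))])
        applied += 1
    return NucSeq(f"{seq.id}|mut{applied}", "".join(res))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def generate_benchmark(config: SimConfig) -> List[SimDuplex]:
    """Materialize the benchmark: for every (length, GC) class and
    sequence, the mutant after each cumulative round 0..max_rounds,
    annotated with its LD from the perfect complement.  Byte-reproducible
    from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    probs = (config.sub_p, config.del_p, config.ins_p)
    out: List[SimDuplex] = []
    for length in config.lengths:
        for gc in config.gc_contents:
            for s in range(config.n_seqs_per_class):
                sid = f"L{length}_GC{gc}_{s:04d}"
                orig = random_seq(length, gc, rng, seq_id=sid)
                comp = perfect_complement(orig)
                cur = comp
                for rounds in range(config.max_rounds(length) + 1):
                    if rounds > 0:
                        cur = NucSeq(
                            f"{comp.id}|r{rounds}",
                            mutate(cur, 1, probs, rng).residues,
                        )
                    out.append(
                        SimDuplex(
                            original=orig,
                            mutant_target=cur,
                            n_mutation_rounds=rounds,
                            ld=levenshtein(comp.residues, cur.residues),
                        )
                    )
    return out


def benchmark_fasta(duplexes: Sequence[SimDuplex]) -> Tuple[str, str]:
    """Render the benchmark as (multi-FASTA, TSV manifest); mutant IDs
    encode class, cumulative round and LD."""
    fa, tsv = [], ["query_id\ttarget_id\trounds\tld"]
    seen = set()
    for d in duplexes:
        if d.original.id not in seen:
            seen.add(d.original.id)
            fa.append(f">{d.original.id}\n{d.original.residues}")
        tid = f"{d.original.id}|r{d.n_mutation_rounds}|ld{d.ld}"
        fa.append(f">{tid}\n{d.mutant_target.residues}")
        tsv.append(f"{d.original.id}\t{tid}\t{d.n_mutation_rounds}\t{d.ld}")
    return "\n".join(fa) + "\n", "\n".join(tsv) + "\n"
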