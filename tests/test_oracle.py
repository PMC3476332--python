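"""Full-model duplex oracle: closed forms, exhaustive enumeration, and an
external cross-check against RNAduplex."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest

from duplexscan import (
    NucSeq,
    OracleConfig,
    duplex_mfe,
    full_dp_reference,
    load_params,
    perfect_complement,
)
from duplexscan.matrix import PAIR_TYPE, encode
from duplexscan.oracle import loop_energy
from duplexscan.params import PAIR_INDEX

from conftest import random_nucseq


def test_perfect_helix_agrees_with_scanner(m04, t04):
    # on an ungapped helix both models reduce to stacks + initiation
    q, t = NucSeq("q", "G" * 10), NucSeq("t", "C" * 10)
    e_full, hit = duplex_mfe(q, t)
    _, scan_hit = full_dp_reference(q, t, m04)
    assert hit.structure == "|" * 10
    assert e_full == pytest.approx(scan_hit.energy)
    assert e_full == pytest.approx(9 * t04.stack_energy("GG", "CC") + t04.duplex_init / 100.0)


def test_one_by_one_loop_uses_tabulated_value(t04):
    # GGGG A GGGG / (3'->5') CCCC A CCCC: central A.A 1x1 loop closed by
    # two G-C pairs
    q = NucSeq("q", "GGGGAGGGG")
    t = NucSeq("t", "CCCCACCCC")
    e, hit = duplex_mfe(q, t)
    gc, cg = PAIR_INDEX["GC"], PAIR_INDEX["CG"]
    a = 1  # table code for A
    # far closing pair is read from the opposite strand: G-C becomes CG
    int11 = int(t04.intloop_11[gc, cg, a, a])
    # 3 stacks in each closing helix arm + the tabulated 1x1 loop
    expected = (6 * int(t04.stack[gc, cg]) + int11 + t04.duplex_init) / 100.0
    assert e == pytest.approx(expected)
    assert "x" in hit.structure


def test_no_interaction_sentinel():
    assert duplex_mfe(NucSeq("q", "AAAA"), NucSeq("t", "CCCC")) == (0.0, None)


def test_swap_invariance(rng):
    for _ in range(10):
        q = random_nucseq(rng, 8, 25, with_n=False, seq_id="q")
        t = random_nucseq(rng, 8, 25, with_n=False, seq_id="t")
        e1, _ = duplex_mfe(q, t)
        e2, _ = duplex_mfe(t, q)
        assert e1 == pytest.approx(e2)


def _enumerate_duplex_structures(q: NucSeq, t: NucSeq, params) -> float:
    """Independent oracle: enumerate every chain of canonical pairs and
    score it with the nearest-neighbor loop rules."""
    tab = [1, 2, 3, 4, 0, 0]
    qc = encode(q.residues)
    rc = encode(t.residues)[::-1]
    m, n = len(qc), len(rc)
    pairs = [
        (i, k) for i, k in itertools.product(range(m), range(n))
        if PAIR_TYPE[qc[i], rc[k]] >= 0
    ]
    term = params.terminal_au_gu
    best = 0

    def closure(i, k):
        return term if PAIR_TYPE[qc[i], rc[k]] >= 2 else 0

    def extend(chain, energy):
        nonlocal best
        i1, k1 = chain[-1]
        best = min(best, energy + closure(i1, k1))
        for i2, k2 in pairs:
            if i2 <= i1 or k2 <= k1:
                continue
            n1, n2 = i2 - i1 - 1, k2 - k1 - 1
            if n1 + n2 > 30:
                continue
            t1 = PAIR_TYPE[qc[i1], rc[k1]]
            t2 = PAIR_TYPE[rc[k2], qc[i2]]
            e = loop_energy(
                params, n1, n2, t1, t2,
                tab[qc[i1 + 1]] if n1 + n2 else 0,
                tab[rc[k1 + 1]] if n1 + n2 else 0,
                tab[qc[i2 - 1]] if n1 + n2 else 0,
                tab[rc[k2 - 1]] if n1 + n2 else 0,
            )
            extend(chain + [(i2, k2)], energy + e)

    for i, k in pairs:
        extend([(i, k)], params.duplex_init + closure(i, k))
    return best / 100.0


@pytest.mark.parametrize("vintage", ["t04", "t99"])
def test_oracle_matches_exhaustive_enumeration(vintage, rng):
    params = load_params(vintage)
    config = OracleConfig(vintage=vintage)
    for _ in range(25):
        q = random_nucseq(rng, 4, 7, with_n=False, seq_id="q")
        t = random_nucseq(rng, 4, 7, with_n=False, seq_id="t")
        e_dp, _ = duplex_mfe(q, t, config)
        e_enum = _enumerate_duplex_structures(q, t, params)
        assert e_dp == pytest.approx(e_enum), (q.residues, t.residues)


def test_oracle_matches_rnaduplex_on_full_span_duplexes(rng):
    """RNAduplex (Turner 2004) is an independent implementation of the same
    duplex model; it always adds exterior dangling ends, so agreement is
    checked on duplexes whose MFE structure spans both sequences entirely
    (no flanking nucleotides, hence no dangle terms)."""
    if shutil.which("RNAduplex") is None:  # pragma: no cover
        pytest.fail("RNAduplex binary not available for the cross-check")
    checked = 0
    for _ in range(40):
        core = random_nucseq(rng, 14, 20, with_n=False, seq_id="q")
        q = NucSeq("q", "GC" + core.residues + "GC")
        res = list(perfect_complement(q).residues)
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(3, len(res) - 3))
            res[pos] = rng.choice([b for b in "ACGU" if b != res[pos]])
        t = NucSeq("t", "".join(res))
        e_my, hit = duplex_mfe(q, t)
        if hit is None or (hit.q_start, hit.q_end, hit.t_start, hit.t_end) != (
            1, len(q), 1, len(t)
        ):
            continue
        out = subprocess.run(
            ["RNAduplex"], input=f"{q.residues}\n{t.residues}\n",
            capture_output=True, text=True, check=True,
        )
        line = out.stdout.strip().splitlines()[-1]
        parts = line.split()
        if parts[1] != f"1,{len(q)}" or parts[3] != f"1,{len(t)}":
            continue
        e_ref = float(line.split("(")[-1].rstrip(")").strip())
        assert e_my == pytest.approx(e_ref, abs=0.011), (q.residues, t.residues)
        checked += 1
    assert checked >= 10


def test_compare_models_perfect_complements_agree(m04, rng):
    from duplexscan import SimConfig, generate_benchmark
    from duplexscan.oracle import compare_models

    ds = [d for d in generate_benchmark(
        SimConfig(lengths=(30,), gc_contents=(50,), n_seqs_per_class=4, seed=9)
    ) if d.ld == 0]
    df = compare_models(ds, m04)
    # unmutated complements are ungapped helices: the models coincide
    assert np.allclose(df.energy_scan, df.energy_full)


def test_config_validation():
    with pytest.raises(ValueError):
        OracleConfig(max_loop=2)
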