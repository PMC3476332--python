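"""Full nearest-neighbor intermolecular duplex MFE (the "full model").

This is the reference the scanner's simplified dinucleotide scheme is
measured against: a DuplexFold-style dynamic program over base pairs with
exact loop tables — stacking energies, tabulated bulge and interior-loop
initiations, the 1x1 / 1x2 / 2x2 small-loop lookups, the Ninio asymmetry
penalty, interior-loop terminal mismatches and helix-end A-U/G-U
penalties, plus duplex initiation.  Intramolecular pairs and multiloops
are outside the model.  Loop transitions are bounded by ``max_loop``
unpaired nucleotides; initiation tables are extrapolated logarithmically
(Jacobson-Stockmayer) beyond size 30.

Energies are evaluated in integer centi-kcal/mol; the inner DP is
numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .engine import (
    STRUCT_GAP_Q,
    STRUCT_GAP_T,
    STRUCT_MISMATCH,
    STRUCT_PAIR,
    DuplexHit,
    NucSeq,
    best_hit,
)
from .matrix import PAIR_TYPE, DinucMatrix
from .params import TurnerParamSet, Vintage, load_params

__all__ = ["OracleConfig", "duplex_mfe", "compare_models", "loop_energy"]

BIG = 10**7

# nucleotide code (A C G U - N) -> small-loop/mismatch table index (E A C G U)
_TAB_CODE = np.array([1, 2, 3, 4, 0, 0], dtype=np.int32)


@dataclass(frozen=True)
class OracleConfig:
    """Oracle settings: parameter vintage, loop-size bound, and whether
    interior-loop terminal-mismatch terms are applied (NNDB default)."""

    vintage: Vintage = Vintage.T04
    max_loop: int = 30
    include_loop_terminal_mismatches: bool = True

    def __post_init__(self):
        if self.max_loop < 4:
            raise ValueError("max_loop must be >= 4")


@njit(cache=False)
def _loop_energy(
    n1, n2, t1, t2, si1, sj1, sp1, sq1,
    stack, bulge, internal, int11, int21, int22, mmi, mm1n, mm23,
    ninio_m, ninio_max, term_au, lxc, use_mm,
):
    """Energy (centi-kcal) of the loop between two consecutive pairs.

    ``t1`` closes the loop on the duplex 5'-query side, ``t2`` is the far
    pair read from the opposite strand; ``si1/sj1`` and ``sp1/sq1`` are the
    loop-adjacent nucleotides (table codes) next to each pair.
    """
    if n1 > n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:  # stacked pair
        return stack[t1, t2]
    if ns == 0:  # bulge
        if nl <= 30:
            e = bulge[nl]
        else:
            e = bulge[30] + int(lxc * math.log(nl / 30.0))
        if nl == 1:
            e += stack[t1, t2]  # stacking persists through a 1-nt bulge
        else:
            if t1 >= 2:
                e += term_au
            if t2 >= 2:
                e += term_au
        return e
    # interior loops
    if ns == 1:
        if nl == 1:
            return int11[t1, t2, si1, sj1]
        if nl == 2:
            if n1 == 1:
                return int21[t1, t2, si1, sq1, sj1]
            return int21[t2, t1, sq1, si1, sp1]
        if nl + 1 <= 30:
            e = internal[nl + 1]
        else:
            e = internal[30] + int(lxc * math.log((nl + 1) / 30.0))
        e += min(ninio_max, (nl - 1) * ninio_m)
        if use_mm:
            e += mm1n[t1, si1, sj1] + mm1n[t2, sq1, sp1]
        return e
    if ns == 2 and nl == 2:
        return int22[t1, t2, si1, sp1, sq1, sj1]
    if ns == 2 and nl == 3:
        e = internal[5] + ninio_m
        if use_mm:
            e += mm23[t1, si1, sj1] + mm23[t2, sq1, sp1]
        return e
    u = nl + ns
    if u <= 30:
        e = internal[u]
    else:
        e = internal[30] + int(lxc * math.log(u / 30.0))
    e += min(ninio_max, (nl - ns) * ninio_m)
    if use_mm:
        e += mmi[t1, si1, sj1] + mmi[t2, sq1, sp1]
    return e


@njit(cache=False)
def _duplex_dp(
    q, r, tab, pair_type,
    stack, bulge, internal, int11, int21, int22, mmi, mm1n, mm23,
    ninio_m, ninio_max, term_au, duplex_init, lxc, max_loop, use_mm,
):
    """Pair-based DP; D[i, k] = best duplex ending in pair (i, k), with
    initiation and the 5'-end penalty included."""
    m, n = len(q), len(r)
    D = np.full((m, n), BIG, dtype=np.int64)
    bpi = np.full((m, n), -1, dtype=np.int32)
    bpk = np.full((m, n), -1, dtype=np.int32)
    for i in range(m):
        for k in range(n):
            t2 = pair_type[r[k], q[i]]  # (i, k) read from the far strand
            if pair_type[q[i], r[k]] < 0:
                continue
            best = duplex_init
            if pair_type[q[i], r[k]] >= 2:
                best += term_au
            pi, pk = -1, -1
            sp1 = tab[q[i - 1]] if i >= 1 else 0
            sq1 = tab[r[k - 1]] if k >= 1 else 0
            for p in range(max(0, i - max_loop - 1), i):
                n1 = i - p - 1
                if q[p] > 3:
                    continue
                for l in range(max(0, k - max_loop - 1 + n1), k):
                    n2 = k - l - 1
                    if n1 + n2 > max_loop:
                        continue
                    t1 = pair_type[q[p], r[l]]
                    if t1 < 0 or D[p, l] >= BIG:
                        continue
                    e = _loop_energy(
                        n1, n2, t1, t2,
                        tab[q[p + 1]], tab[r[l + 1]], sp1, sq1,
                        stack, bulge, internal, int11, int21, int22,
                        mmi, mm1n, mm23,
                        ninio_m, ninio_max, term_au, lxc, use_mm,
                    )
                    cand = D[p, l] + e
                    if cand < best:
                        best = cand
                        pi, pk = p, l
            D[i, k] = best
            bpi[i, k] = pi
            bpk[i, k] = pk
    # close the duplex: 3'-end penalty
    emin = BIG
    bi, bk = -1, -1
    for i in range(m):
        for k in range(n):
            if D[i, k] >= BIG:
                continue
            e = D[i, k]
            if pair_type[q[i], r[k]] >= 2:
                e += term_au
            if e < emin:
                emin = e
                bi, bk = i, k
    return emin, bi, bk, bpi, bpk


@lru_cache(maxsize=4)
def _tables(vintage: Vintage):
    p = load_params(vintage)
    return (
        p.stack.astype(np.int64),
        p.bulge_init.astype(np.int64),
        p.intloop_init.astype(np.int64),
        p.intloop_11.astype(np.int64),
        p.intloop_12.astype(np.int64),
        p.intloop_22.astype(np.int64),
        p.mismatch_interior.astype(np.int64),
        p.mismatch_interior_1n.astype(np.int64),
        p.mismatch_interior_23.astype(np.int64),
    )


def loop_energy(
    params: TurnerParamSet,
    n1: int,
    n2: int,
    t1: int,
    t2: int,
    si1: int = 0,
    sj1: int = 0,
    sp1: int = 0,
    sq1: int = 0,
    include_mismatches: bool = True,
) -> int:
    """Loop energy between consecutive pairs, in centi-kcal (pure-Python
    path of the compiled kernel; nucleotide arguments are table codes)."""
    tabs = _tables(params.vintage)
    return int(
        _loop_energy.py_func(
            n1, n2, t1, t2, si1, sj1, sp1, sq1, *tabs,
            params.asym_penalty, params.max_asym_total,
            params.terminal_au_gu, params.lxc, include_mismatches,
        )
    )


def duplex_mfe(
    query: NucSeq, target: NucSeq, config: OracleConfig = OracleConfig()
) -> Tuple[float, Optional[DuplexHit]]:
    """Minimum free energy duplex under the full nearest-neighbor model.

    Returns ``(energy_kcal, hit)``; when no duplex is more stable than the
    open state (energy >= 0), the no-interaction sentinel ``(0.0, None)``
    is returned.
    """
    params = load_params(config.vintage)
    q = query.codes().astype(np.int64)
    r = target.codes()[::-1].astype(np.int64)  # target read 3'->5'
    emin, bi, bk, bpi, bpk = _duplex_dp(
        q, r, _TAB_CODE.astype(np.int64), PAIR_TYPE.astype(np.int64),
        *_tables(config.vintage),
        params.asym_penalty, params.max_asym_total, params.terminal_au_gu,
        params.duplex_init, params.lxc, config.max_loop,
        config.include_loop_terminal_mismatches,
    )
    if emin >= 0 or bi < 0:
        return 0.0, None
    # chain of pairs, 3' -> 5' in the query
    pairs = []
    i, k = bi, bk
    while i >= 0:
        pairs.append((i, k))
        i, k = int(bpi[pairs[-1][0], pairs[-1][1]]), int(bpk[pairs[-1][0], pairs[-1][1]])
    pairs.reverse()
    struct = []
    for (i1, k1), (i2, k2) in zip(pairs, pairs[1:]):
        struct.append(STRUCT_PAIR)
        n1, n2 = i2 - i1 - 1, k2 - k1 - 1
        sym = min(n1, n2)
        struct.extend([STRUCT_MISMATCH] * sym)
        struct.extend([STRUCT_GAP_T if n1 > n2 else STRUCT_GAP_Q] * abs(n1 - n2))
    struct.append(STRUCT_PAIR)
    n = len(target)
    first, last = pairs[0], pairs[-1]
    hit = DuplexHit(
        query_id=query.id,
        target_id=target.id,
        q_start=first[0] + 1,
        q_end=last[0] + 1,
        t_start=n - last[1],
        t_end=n - first[1],
        energy=round(emin / 100.0, 2),
        score=-int(emin),
        structure="".join(struct),
    )
    return hit.energy, hit


def compare_models(duplex_set, matrix: DinucMatrix, config: OracleConfig = OracleConfig()):
    """Score every simulated duplex with the scanner and with the full
    model; returns a DataFrame of paired energies and relative deviations
    |(full - scan) / full|.

    The traceback window is widened to cover the whole duplex: the
    benchmark measures the energy model, not the windowing heuristic.
    """
    import pandas as pd

    rows = []
    for d in duplex_set:
        window = len(d.original) + len(d.mutant_target)
        hit = best_hit(d.original, d.mutant_target, matrix, window=window)
        e_scan = hit.energy if hit is not None else 0.0
        e_full, _ = duplex_mfe(d.original, d.mutant_target, config)
        rows.append(
            {
                "pair_id": d.original.id,
                "rounds": d.n_mutation_rounds,
                "ld": d.ld,
                "energy_scan": e_scan,
                "energy_full": e_full,
                "rel_diff": abs((e_full - e_scan) / e_full) if e_full != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
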