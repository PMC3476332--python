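"""Three-state local duplex scanner.

The scanner finds near-complementary antiparallel duplexes between a query
and a target by a Smith-Waterman-Gotoh-like local alignment in which
"match" means "canonical base pair" and the score of a column depends on
the previous column through the dinucleotide matrix
(:class:`~duplexscan.matrix.DinucMatrix`).

States: ``M`` holds interactions ending in a consumed column on both
strands (stacked pair or interior-loop position), ``Bq`` ends in a bulged
query nucleotide (gap in the target strand) and ``Bt`` in a bulged target
nucleotide.  ``Bq``/``Bt`` are entered from ``M`` (loop opening) or extend
themselves; direct ``Bq``/``Bt`` adjacency is not part of the model.
Alignments start at canonical-pair columns only and are evaluated at
canonical-pair columns (a duplex begins and ends with a base pair).

Phase 1 (:func:`scan`) sweeps the full query x target rectangle keeping
only two rows per state table, recording for every target position the
best interaction score ending there and its query end (optionally the 2nd
and 3rd best, at distinct query ends).  Phase 2
(:func:`extend_and_traceback`) re-runs the DP with full matrices on a
small window around each candidate and reconstructs the duplex structure
and free energy.  :func:`full_dp_reference` (quadratic-memory DP) and
:func:`brute_force_enumerate` (exhaustive alignment enumeration) are
slower oracles used to validate the scan.

Reported free energies are assembled as
``-score/100 + duplex initiation + terminal A-U/G-U penalties`` at both
duplex ends, in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .matrix import GAP, PAIR_TYPE, DinucMatrix, encode
from .params import load_params

__all__ = [
    "NucSeq",
    "ScanResult",
    "DuplexHit",
    "Candidate",
    "scan",
    "collect_candidates",
    "extend_and_traceback",
    "search",
    "best_hit",
    "full_dp_reference",
    "brute_force_enumerate",
]

NEGINF = -(2**40)

#: structure annotation characters, per alignment column
STRUCT_PAIR, STRUCT_MISMATCH, STRUCT_GAP_Q, STRUCT_GAP_T = "|", "x", "q", "t"


@dataclass(frozen=True)
class NucSeq:
    """A 5'->3' nucleotide sequence over ``A C G U N``."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set("ACGUN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside ACGUN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        return encode(self.residues)


@dataclass
class ScanResult:
    """Per-target-position row maxima from the linear-space scan.

    ``scores[j, l]`` (centi-kcal, clamped at 0) and ``qends[j, l]`` give the
    l-th best interaction whose final alignment column sits at target
    position ``j`` (1-based; the query 3' end pairs this position).
    """

    m: int
    n: int
    n_subopt: int
    scores: np.ndarray  # (n+1, n_subopt) int64
    qends: np.ndarray   # (n+1, n_subopt) int32
    aux_cells: int      # DP cells allocated by the scan (linear in m)

    @property
    def best_score(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def best_qend(self) -> np.ndarray:
        return self.qends[:, 0]


@dataclass(frozen=True, order=True)
class Candidate:
    """A qualifying phase-1 row: target position, query end, raw score."""

    t_pos: int
    q_end: int
    score: int


@dataclass
class DuplexHit:
    """One predicted duplex.

    Coordinates are 1-based inclusive, both sequences 5'->3'; the strands
    run antiparallel, so ``q_start`` pairs ``t_end`` and ``q_end`` pairs
    ``t_start``.  ``structure`` annotates alignment columns 5'->3' in the
    query: ``|`` pair, ``x`` mismatch, ``q``/``t`` gap in query/target.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    energy: float      # kcal/mol, with initiation and end penalties
    score: int         # raw centi-kcal alignment score
    structure: str


def _prepare(query: NucSeq, target: NucSeq) -> Tuple[np.ndarray, np.ndarray]:
    q = query.codes().astype(np.int64)
    r = target.codes()[::-1].astype(np.int64)  # target read 3'->5'
    return q, r


def scan(query: NucSeq, target: NucSeq, matrix: DinucMatrix, n_subopt: int = 1) -> ScanResult:
    """Phase-1 linear-space scan; O(m*n) time, O(m + n) extra space."""
    if n_subopt not in (1, 2, 3):
        raise ValueError("n_subopt must be 1, 2 or 3")
    q, r = _prepare(query, target)
    m, n = len(q), len(r)
    S = matrix.scores
    start_tab = matrix.start

    # per-query-position dinucleotide row indices (valid for i >= 2)
    qd_mm = np.zeros(m + 1, dtype=np.int64)
    qd_mm[2:] = 6 * q[:-1] + q[1:]
    qd_from_bt = 6 * GAP + np.concatenate(([0], q))   # query dinuc ('-', q_i)
    qd_to_gap = np.concatenate(([0], 6 * q + GAP))    # query dinuc (q_i, '-')
    idx = np.arange(m + 1, dtype=np.int64)

    M_prev = np.full(m + 1, NEGINF, dtype=np.int64)
    Bq_prev = np.full(m + 1, NEGINF, dtype=np.int64)
    Bt_prev = np.full(m + 1, NEGINF, dtype=np.int64)

    out_scores = np.zeros((n + 1, n_subopt), dtype=np.int64)
    out_qends = np.zeros((n + 1, n_subopt), dtype=np.int32)
    aux = 6 * (m + 1)

    gg = 6 * GAP + GAP
    # the gap-extension entry is class-constant; read it from one cell
    ext_entry = int(S[0 * 6 + 0, gg])  # query dinuc (A,A), target ('-','-')

    prev_t = 0
    for k in range(1, n + 1):
        t_cur = int(r[k - 1])
        td_mm = 6 * prev_t + t_cur
        td_from_bq = 6 * GAP + t_cur       # prev col (q_{i-1}, '-')
        td_to_gap = 6 * t_cur + GAP        # cur col (q_i, '-') after (.., r_k)

        pair_t = PAIR_TYPE[q, t_cur]       # (m,) pair-type per query nt
        start_col = np.where(pair_t >= 0, start_tab[q, t_cur], NEGINF)

        M_cur = np.full(m + 1, NEGINF, dtype=np.int64)
        if k >= 2:
            M_cur[1:] = np.maximum.reduce([
                M_prev[:-1] + S[qd_mm[1:], td_mm],
                Bq_prev[:-1] + S[qd_mm[1:], td_from_bq],
                Bt_prev[:-1] + S[qd_from_bt[1:], td_mm],
            ])
            M_cur[1] = NEGINF  # no i-1 predecessor for the first query nt
        np.maximum(M_cur[1:], start_col, out=M_cur[1:])

        # Bq (bulged query nt, gap in target strand): in-row affine recursion
        Bq_cur = np.full(m + 1, NEGINF, dtype=np.int64)
        if m > 1:
            open_arr = np.full(m + 1, NEGINF, dtype=np.int64)
            open_arr[2:] = M_cur[1:-1] + S[qd_mm[2:], td_to_gap]
            shifted = open_arr - idx * ext_entry
            np.maximum.accumulate(shifted, out=shifted)
            Bq_cur = shifted + idx * ext_entry
            Bq_cur[:2] = NEGINF

        # Bt (bulged target nt): element-wise from the previous row
        Bt_cur = np.full(m + 1, NEGINF, dtype=np.int64)
        if k >= 2:
            Bt_cur[1:] = np.maximum(
                M_prev[1:] + S[qd_to_gap[1:], td_mm],
                Bt_prev[1:] + S[gg, td_mm],
            )

        # row maxima over canonical-pair columns
        j = n + 1 - k  # original target coordinate of this row
        vals = np.where(pair_t >= 0, M_cur[1:], NEGINF)
        if n_subopt == 1:
            i_best = int(np.argmax(vals)) + 1
            sc = int(vals[i_best - 1])
            if sc > 0:
                out_scores[j, 0] = sc
                out_qends[j, 0] = i_best
        else:
            order = np.argsort(vals, kind="stable")[::-1][:n_subopt]
            for l, ii in enumerate(order):
                sc = int(vals[ii])
                if sc > 0:
                    out_scores[j, l] = sc
                    out_qends[j, l] = int(ii) + 1

        M_prev, Bq_prev, Bt_prev = M_cur, Bq_cur, Bt_cur
        prev_t = t_cur

    return ScanResult(
        m=m, n=n, n_subopt=n_subopt, scores=out_scores, qends=out_qends,
        aux_cells=aux,
    )


def collect_candidates(result: ScanResult, threshold_energy: float = 0.0) -> List[Candidate]:
    """Rows whose best score reaches ``-100 * threshold_energy`` (kcal/mol,
    <= 0), best first; ties broken by (target position, query end)."""
    if threshold_energy > 0:
        raise ValueError("energy threshold must be <= 0 kcal/mol")
    bar = max(1, int(round(-100 * threshold_energy)))
    out = []
    for j in range(1, result.n + 1):
        for l in range(result.n_subopt):
            sc = int(result.scores[j, l])
            if sc >= bar:
                out.append(Candidate(t_pos=j, q_end=int(result.qends[j, l]), score=sc))
    out.sort(key=lambda c: (-c.score, c.t_pos, c.q_end))
    return out


# ---------------------------------------------------------------------------
# phase 2: full-matrix DP on a window, with traceback


def _full_dp(q: np.ndarray, r: np.ndarray, matrix: DinucMatrix):
    """Full three-state DP over encoded query x reversed target."""
    m, n = len(q), len(r)
    S = matrix.scores
    start_tab = matrix.start
    M = np.full((m + 1, n + 1), NEGINF, dtype=np.int64)
    Bq = np.full((m + 1, n + 1), NEGINF, dtype=np.int64)
    Bt = np.full((m + 1, n + 1), NEGINF, dtype=np.int64)
    gg = 6 * GAP + GAP
    for i in range(1, m + 1):
        qi = int(q[i - 1])
        qm1 = int(q[i - 2]) if i >= 2 else -1
        for k in range(1, n + 1):
            tk = int(r[k - 1])
            tm1 = int(r[k - 2]) if k >= 2 else -1
            best = NEGINF
            if PAIR_TYPE[qi, tk] >= 0:
                best = int(start_tab[qi, tk])
            if i >= 2 and k >= 2:
                qd = 6 * qm1 + qi
                td = 6 * tm1 + tk
                best = max(
                    best,
                    M[i - 1, k - 1] + S[qd, td],
                    Bq[i - 1, k - 1] + S[qd, 6 * GAP + tk],
                    Bt[i - 1, k - 1] + S[6 * GAP + qi, td],
                )
            M[i, k] = best
            if i >= 2:
                qd = 6 * qm1 + qi
                Bq[i, k] = max(
                    M[i - 1, k] + S[qd, 6 * tk + GAP],
                    Bq[i - 1, k] + S[qd, gg],
                )
            if k >= 2:
                td = 6 * tm1 + tk
                Bt[i, k] = max(
                    M[i, k - 1] + S[6 * qi + GAP, td],
                    Bt[i, k - 1] + S[gg, td],
                )
    return M, Bq, Bt


def _traceback(q, r, matrix: DinucMatrix, M, Bq, Bt, i, k):
    """Walk back from M[i, k]; returns columns [(q_sym, t_sym)], 5'->3'."""
    S = matrix.scores
    start_tab = matrix.start
    gg = 6 * GAP + GAP
    cols: List[Tuple[int, int]] = []
    state = "M"
    while True:
        qi = int(q[i - 1]) if i >= 1 else -1
        tk = int(r[k - 1]) if k >= 1 else -1
        qm1 = int(q[i - 2]) if i >= 2 else -1
        tm1 = int(r[k - 2]) if k >= 2 else -1
        if state == "M":
            cols.append((qi, tk))
            val = M[i, k]
            if PAIR_TYPE[qi, tk] >= 0 and val == start_tab[qi, tk]:
                break  # shortest duplex wins at equal score
            qd, td = 6 * qm1 + qi, 6 * tm1 + tk
            if i >= 2 and k >= 2 and val == M[i - 1, k - 1] + S[qd, td]:
                i, k = i - 1, k - 1
            elif i >= 2 and k >= 2 and val == Bq[i - 1, k - 1] + S[qd, 6 * GAP + tk]:
                state, i, k = "Bq", i - 1, k - 1
            elif i >= 2 and k >= 2 and val == Bt[i - 1, k - 1] + S[6 * GAP + qi, td]:
                state, i, k = "Bt", i - 1, k - 1
            else:  # pragma: no cover - would indicate a DP inconsistency
                raise AssertionError("traceback failed in M state")
        elif state == "Bq":
            cols.append((qi, GAP))
            val = Bq[i, k]
            qd = 6 * qm1 + qi
            if val == M[i - 1, k] + S[qd, 6 * tk + GAP]:
                state, i = "M", i - 1
            elif val == Bq[i - 1, k] + S[qd, gg]:
                i -= 1
            else:  # pragma: no cover
                raise AssertionError("traceback failed in Bq state")
        else:
            cols.append((GAP, tk))
            val = Bt[i, k]
            if val == M[i, k - 1] + S[6 * qi + GAP, 6 * tm1 + tk]:
                state, k = "M", k - 1
            elif val == Bt[i, k - 1] + S[gg, 6 * tm1 + tk]:
                k -= 1
            else:  # pragma: no cover
                raise AssertionError("traceback failed in Bt state")
    cols.reverse()
    return cols, i, k  # i, k = first consumed positions (1-based, local)


def _assemble_hit(
    query: NucSeq,
    target: NucSeq,
    matrix: DinucMatrix,
    cols: Sequence[Tuple[int, int]],
    q_first: int,
    q_last: int,
    t_hi: int,
    k_first: int,
    k_last: int,
    score: int,
) -> DuplexHit:
    """Build a hit from traceback columns; ``t_hi`` is the original target
    coordinate of local reversed index 1."""
    params = load_params(matrix.vintage)
    struct = []
    for a, b in cols:
        if a == GAP:
            struct.append(STRUCT_GAP_Q)
        elif b == GAP:
            struct.append(STRUCT_GAP_T)
        elif PAIR_TYPE[a, b] >= 0:
            struct.append(STRUCT_PAIR)
        else:
            struct.append(STRUCT_MISMATCH)
    first_pt = PAIR_TYPE[cols[0][0], cols[0][1]]
    last_pt = PAIR_TYPE[cols[-1][0], cols[-1][1]]
    term = params.terminal_au_gu
    e_centi = -score + params.duplex_init
    for pt in (first_pt, last_pt):
        if pt >= 2:  # GU, UG, AU, UA
            e_centi += term
    return DuplexHit(
        query_id=query.id,
        target_id=target.id,
        q_start=q_first,
        q_end=q_last,
        t_start=t_hi - (k_last - 1),
        t_end=t_hi - (k_first - 1),
        energy=round(e_centi / 100.0, 2),
        score=score,
        structure="".join(struct),
    )


def extend_and_traceback(
    query: NucSeq,
    target: NucSeq,
    matrix: DinucMatrix,
    candidate: Candidate,
    window: int = 40,
) -> DuplexHit:
    """Recompute structure and energy around a phase-1 candidate.

    The window spans ``window`` target positions whose 5' edge is the
    candidate's target position (the duplex extends toward the target 3'
    end as the query is walked 3'->5'), and caps the query extent at
    ``window`` nucleotides ending at the candidate's query end.  If the
    true duplex exceeds the window, the best duplex fitting inside it is
    returned.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(target)
    j0 = candidate.t_pos
    j1 = min(n, j0 + window - 1)
    i1 = candidate.q_end
    i0 = max(1, i1 - window + 1)
    q = encode(query.residues[i0 - 1:i1]).astype(np.int64)
    r = encode(target.residues[j0 - 1:j1])[::-1].astype(np.int64)
    M, Bq, Bt = _full_dp(q, r, matrix)
    pair_ok = PAIR_TYPE[q[:, None], r[None, :]] >= 0
    masked = np.where(pair_ok, M[1:, 1:], NEGINF)
    # re-evaluate the identified interaction: its final column sits at the
    # candidate's target position, i.e. the last local row
    bk = len(r)
    bi = int(np.argmax(masked[:, bk - 1])) + 1
    score = int(masked[bi - 1, bk - 1])
    if score <= 0:  # windowing cut the anchored duplex; report the best fit
        flat = int(np.argmax(masked))
        bi, bk = flat // len(r) + 1, flat % len(r) + 1
        score = int(masked[bi - 1, bk - 1])
    cols, fi, fk = _traceback(q, r, matrix, M, Bq, Bt, bi, bk)
    return _assemble_hit(
        query, target, matrix, cols,
        q_first=i0 + fi - 1, q_last=i0 + bi - 1,
        t_hi=j1, k_first=fk, k_last=bk, score=score,
    )


def full_dp_reference(
    query: NucSeq, target: NucSeq, matrix: DinucMatrix
) -> Tuple[int, Optional[DuplexHit]]:
    """Quadratic-memory oracle: optimal score and hit over the full
    rectangle; ``(0, None)`` when no interaction scores positively."""
    q, r = _prepare(query, target)
    M, Bq, Bt = _full_dp(q, r, matrix)
    pair_ok = PAIR_TYPE[q[:, None], r[None, :]] >= 0
    masked = np.where(pair_ok, M[1:, 1:], NEGINF)
    flat = int(np.argmax(masked))
    bi, bk = flat // len(r) + 1, flat % len(r) + 1
    score = int(masked[bi - 1, bk - 1])
    if score <= 0:
        return 0, None
    cols, fi, fk = _traceback(q, r, matrix, M, Bq, Bt, bi, bk)
    hit = _assemble_hit(
        query, target, matrix, cols,
        q_first=fi, q_last=bi, t_hi=len(target), k_first=fk, k_last=bk,
        score=score,
    )
    return score, hit


def _target_overlap(a: DuplexHit, b: DuplexHit) -> float:
    lo = max(a.t_start, b.t_start)
    hi = min(a.t_end, b.t_end)
    if hi < lo:
        return 0.0
    shorter = min(a.t_end - a.t_start, b.t_end - b.t_start) + 1
    return (hi - lo + 1) / shorter


def search(
    query: NucSeq,
    target: NucSeq,
    matrix: DinucMatrix,
    threshold: float = 0.0,
    window: int = 40,
    n_subopt: int = 1,
    merge: bool = False,
) -> List[DuplexHit]:
    """End-to-end pipeline: scan, collect, extend; hits sorted by energy
    (most stable first).  With ``merge``, hits whose target intervals
    overlap by >= 50% are collapsed, keeping the best energy."""
    result = scan(query, target, matrix, n_subopt=n_subopt)
    hits: List[DuplexHit] = []
    seen = set()
    for cand in collect_candidates(result, threshold):
        hit = extend_and_traceback(query, target, matrix, cand, window=window)
        key = (hit.q_start, hit.q_end, hit.t_start, hit.t_end)
        if key not in seen:
            seen.add(key)
            hits.append(hit)
    hits.sort(key=lambda h: (h.energy, h.t_start, h.q_start))
    if merge:
        kept: List[DuplexHit] = []
        for hit in hits:
            if all(_target_overlap(hit, other) < 0.5 for other in kept):
                kept.append(hit)
        hits = kept
    return hits


def best_hit(
    query: NucSeq, target: NucSeq, matrix: DinucMatrix, window: int = 40
) -> Optional[DuplexHit]:
    """Best single duplex: extend only the near-optimal phase-1 rows.

    Rows within initiation-plus-two-end-penalties of the top raw score are
    re-evaluated, since final energies reorder raw scores by at most that
    amount; the minimum-energy hit is returned (``None`` if nothing scores
    positively).
    """
    result = scan(query, target, matrix)
    cands = collect_candidates(result, 0.0)
    if not cands:
        return None
    params = load_params(matrix.vintage)
    slack = 2 * params.terminal_au_gu
    top = cands[0].score
    best: Optional[DuplexHit] = None
    for cand in cands:
        if cand.score < top - slack:
            break
        hit = extend_and_traceback(query, target, matrix, cand, window=window)
        if best is None or hit.energy < best.energy:
            best = hit
    return best


def brute_force_enumerate(
    query: NucSeq, target: NucSeq, matrix: DinucMatrix, max_len: int = 9
) -> int:
    """Exhaustively score every co-linear interaction alignment.

    Enumerates all alignments whose first and last columns are canonical
    pairs, with mismatch and single-strand gap columns in between (gap
    columns on opposite strands never adjacent), scoring columns with the
    same dinucleotide matrix.  Returns the maximum score (0 if nothing
    positive).  Exponential; intended as an oracle for tiny sequences.
    """
    if len(query) > max_len or len(target) > max_len:
        raise ValueError(f"brute force limited to sequences of <= {max_len} nt")
    q, r = _prepare(query, target)
    m, n = len(q), len(r)
    S = matrix.scores
    start_tab = matrix.start
    best = 0

    def rec(i: int, k: int, a: int, b: int, score: int):
        # (i, k): 1-based positions consumed so far; (a, b) last column
        nonlocal best
        # extend with a consumed column on both strands
        if i < m and k < n:
            a2, b2 = int(q[i]), int(r[k])
            rec(i + 1, k + 1, a2, b2, score + int(S[6 * a + a2, 6 * b + b2]))
        # bulged query nucleotide (gap in target strand)
        if i < m and a != GAP:  # no Bt->Bq adjacency
            a2 = int(q[i])
            rec(i + 1, k, a2, GAP, score + int(S[6 * a + a2, 6 * b + GAP]))
        if k < n and b != GAP:
            b2 = int(r[k])
            rec(i, k + 1, GAP, b2, score + int(S[6 * a + GAP, 6 * b + b2]))
        if a != GAP and b != GAP and PAIR_TYPE[a, b] >= 0:
            best = max(best, score)

    for i in range(1, m + 1):
        for k in range(1, n + 1):
            a, b = int(q[i - 1]), int(r[k - 1])
            if PAIR_TYPE[a, b] >= 0:
                rec(i, k, a, b, int(start_tab[a, b]))
    return best
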