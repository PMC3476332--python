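"""The 36x36 dinucleotide scoring matrix.

The scanner works on alignment *columns*: each column pairs one query
symbol with one target symbol (either may be the gap symbol ``-``), the
target being read 3'->5' relative to the query (antiparallel duplex).
Scoring a column requires the previous column as context, so the matrix is
indexed by (query dinucleotide, target dinucleotide) over the 6-letter
alphabet ``A C G U - N`` — 36 x 36 integer entries in centi-kcal/mol,
maximization convention (positive = stabilizing).

Entry composition by column classes (pair / mismatch / gap):

========== ========== =====================================================
previous    current    score
========== ========== =====================================================
pair        pair       -stack(quartet)
pair        mismatch   -(intloop_open/2 + ext_sym) - closure(previous pair)
mismatch    pair       -(intloop_open/2) - closure(new pair)
mismatch    mismatch   -ext_sym
pair        gap        -(bulge_open + bulge_ext) - closure(previous pair)
gap         gap        -bulge_ext   (also asymmetric interior extension)
mismatch    gap        -ext_asym
gap         mismatch   -ext_sym
gap         pair       -closure(new pair)
========== ========== =====================================================

A gap column cannot tell a bulge from the asymmetric part of an interior
loop.  When the previous column is itself a gap the case is genuinely
ambiguous and the (cheaper) bulge extension is assigned; when the previous
column is a mismatch the surrounding loop is necessarily an interior loop,
so the asymmetry slope (ext_asym) applies.

closure() is the terminal A-U/G-U penalty, charged where a loop or bulge
interrupts a helix; the same penalty is applied to the two duplex termini
when the engine assembles a reported free energy.  A user-chosen
per-nucleotide penalty is subtracted once from every entry (each entry
consumes exactly one alignment column).  Interaction-initiating columns are
scored by a separate 6x6 start table: canonical (Watson-Crick or wobble)
pairs may start an alignment, all other start entries are zero and may not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    PAIR_INDEX,
    TurnerParamSet,
    AffineLoopModel,
    Vintage,
    affine_model,
    load_params,
)

__all__ = [
    "ALPHABET",
    "GAP",
    "N",
    "encode",
    "pair_type",
    "DinucMatrix",
    "build_matrix",
    "make_matrix",
    "column_score",
    "dump_matrix_tsv",
    "load_matrix_tsv",
]

#: symbol order defining all matrix indices
ALPHABET = "ACGU-N"
A, C, G, U, GAP, N = range(6)
_SYM_INDEX = {s: i for i, s in enumerate(ALPHABET)}

#: pair-type code for (query symbol, target symbol), -1 if non-canonical
PAIR_TYPE = -np.ones((6, 6), dtype=np.int32)
for _name, _code in PAIR_INDEX.items():
    PAIR_TYPE[_SYM_INDEX[_name[0]], _SYM_INDEX[_name[1]]] = _code

#: pair types whose closure carries the terminal A-U/G-U penalty (GU UG AU UA)
_PENALIZED = np.array([0, 0, 1, 1, 1, 1], dtype=np.int32)

_NEG = -(10**6)  # sentinel: transition not representable in the state model


def encode(residues: str) -> np.ndarray:
    """Encode a residue string over ``ACGU-N`` as symbol codes."""
    try:
        return np.array([_SYM_INDEX[s] for s in residues], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside alphabet {ALPHABET!r}") from None


def pair_type(q_sym: int, t_sym: int) -> int:
    """Canonical pair-type code of a column, or -1."""
    return int(PAIR_TYPE[q_sym, t_sym])


def _col_kind(a: int, b: int) -> str:
    """Column class: P(air), X (mismatch), Q (gap in query), T (gap in target)."""
    if a == GAP and b == GAP:
        return "!"
    if a == GAP:
        return "Q"
    if b == GAP:
        return "T"
    return "P" if PAIR_TYPE[a, b] >= 0 else "X"


@dataclass(frozen=True)
class DinucMatrix:
    """Scoring matrix plus the alignment-start table.

    ``scores[6*q1+q2, 6*t1+t2]`` scores a transition into the column
    ``(q2, t2)`` given previous column ``(q1, t1)``; ``start[q, t]`` scores
    an alignment-initiating column.  Integer centi-kcal/mol throughout.
    """

    vintage: Vintage
    per_nt_penalty: int  # centi-kcal per column
    scores: np.ndarray   # (36, 36) int32
    start: np.ndarray    # (6, 6) int32

    def __post_init__(self):
        self.scores.setflags(write=False)
        self.start.setflags(write=False)


def build_matrix(
    params: TurnerParamSet,
    affine: AffineLoopModel,
    per_nt_penalty: float = 0.0,
) -> DinucMatrix:
    """Compose the 36x36 matrix from a parameter set and its affine loop
    model.  ``per_nt_penalty`` is in kcal/mol per alignment column, >= 0."""
    if per_nt_penalty < 0:
        raise ValueError("per-nucleotide penalty must be >= 0")
    pen = int(round(per_nt_penalty * 100))
    half_open = affine.intloop_open / 2.0
    ext_sym = affine.intloop_ext_sym
    bulge_open = affine.bulge_open + affine.bulge_ext
    bulge_ext = affine.bulge_ext
    term = params.terminal_au_gu

    scores = np.full((36, 36), _NEG, dtype=np.int32)
    for q1 in range(6):
        for q2 in range(6):
            for t1 in range(6):
                for t2 in range(6):
                    prev, cur = _col_kind(q1, t1), _col_kind(q2, t2)
                    if "!" in (prev, cur):
                        continue
                    if {prev, cur} == {"Q", "T"}:
                        continue  # opposite-strand gaps never adjacent
                    prev_pt = PAIR_TYPE[q1, t1]
                    cur_pt = PAIR_TYPE[q2, t2]
                    if cur == "P":
                        if prev == "P":
                            # stack of (q2,t2) on (q1,t1); second pair read
                            # from the opposite strand
                            val = -float(params.stack[prev_pt, PAIR_TYPE[t2, q2]])
                        elif prev == "X":
                            val = -half_open - term * _PENALIZED[cur_pt]
                        else:
                            val = -float(term * _PENALIZED[cur_pt])
                    elif cur == "X":
                        if prev == "P":
                            val = -(half_open + ext_sym) - term * _PENALIZED[prev_pt]
                        else:
                            val = -ext_sym
                    else:  # gap column
                        if prev == "P":
                            val = -bulge_open - term * _PENALIZED[prev_pt]
                        elif prev == "X":
                            val = -affine.intloop_ext_asym
                        else:
                            val = -bulge_ext
                    scores[6 * q1 + q2, 6 * t1 + t2] = int(round(val)) - pen

    start = np.zeros((6, 6), dtype=np.int32)
    start[PAIR_TYPE >= 0] = -pen
    return DinucMatrix(
        vintage=params.vintage, per_nt_penalty=pen, scores=scores, start=start
    )


def make_matrix(vintage: Vintage | str = Vintage.T04, per_nt_penalty: float = 0.0) -> DinucMatrix:
    """Build the matrix for a vintage in one call."""
    params = load_params(vintage)
    return build_matrix(params, affine_model(params), per_nt_penalty)


def column_score(matrix: DinucMatrix, prev_q: str, cur_q: str, prev_t: str, cur_t: str) -> int:
    """Score (centi-kcal) of the transition into column ``(cur_q, cur_t)``
    given previous column ``(prev_q, prev_t)``; target symbols are read
    3'->5' relative to the query."""
    syms = [prev_q, cur_q, prev_t, cur_t]
    codes = []
    for s in syms:
        if s not in _SYM_INDEX:
            raise ValueError(f"symbol {s!r} outside alphabet {ALPHABET!r}")
        codes.append(_SYM_INDEX[s])
    return int(matrix.scores[6 * codes[0] + codes[1], 6 * codes[2] + codes[3]])


def dump_matrix_tsv(matrix: DinucMatrix) -> str:
    """Symbol-labeled TSV rendering of the matrix (round-trips exactly)."""
    dinucs = [a + b for a in ALPHABET for b in ALPHABET]
    lines = [
        f"# vintage\t{matrix.vintage.value}",
        f"# per_nt_penalty\t{matrix.per_nt_penalty}",
        "\t".join(["q\\t"] + dinucs),
    ]
    for i, qd in enumerate(dinucs):
        lines.append("\t".join([qd] + [str(int(v)) for v in matrix.scores[i]]))
    lines.append("\t".join(["start"] + list(ALPHABET)))
    for i, s in enumerate(ALPHABET):
        lines.append("\t".join([s] + [str(int(v)) for v in matrix.start[i]]))
    return "\n".join(lines) + "\n"


def load_matrix_tsv(text: str) -> DinucMatrix:
    """Parse the TSV produced by :func:`dump_matrix_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    vintage = Vintage(lines[0].split("\t")[1])
    pen = int(lines[1].split("\t")[1])
    scores = np.array(
        [[int(v) for v in ln.split("\t")[1:]] for ln in lines[3:39]], dtype=np.int32
    )
    start = np.array(
        [[int(v) for v in ln.split("\t")[1:]] for ln in lines[40:46]], dtype=np.int32
    )
    return DinucMatrix(vintage=vintage, per_nt_penalty=pen, scores=scores, start=start)
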