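"""Turner nearest-neighbor parameter sets and their affine loop approximations.

The scanner's dinucleotide scoring matrix cannot represent length-dependent
loop initiation tables, so bulge and interior-loop energies are approximated
by affine (opening + per-nucleotide extension) models fitted here against the
embedded tables.  The full tables themselves (including the 1x1 / 1x2 / 2x2
small-loop lookups) are retained for the full-model duplex oracle.

All energies are handled internally as integers in centi-kcal/mol
(0.01 kcal/mol) so dynamic-programming arithmetic is exact; public helpers
report plain kcal/mol.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Tuple

import numpy as np

from . import _nndb_t04, _nndb_t99

__all__ = [
    "Vintage",
    "TurnerParamSet",
    "AffineLoopModel",
    "load_params",
    "fit_affine_bulge",
    "fit_affine_interior",
    "PAIRS",
    "PAIR_INDEX",
    "NT_ORDER",
    "INF",
]

INF = _nndb_t04.INF

#: canonical pair types, in table order; index is the "pair type" code
PAIRS: Tuple[str, ...] = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_INDEX: Dict[str, int] = {p: i for i, p in enumerate(PAIRS)}

#: nucleotide order used by the small-loop / mismatch tables (0 = no base)
NT_ORDER = "EACGU"

#: pair types closed by an A-U or G-U pair (helix-end penalty applies)
WOBBLE_OR_AU = frozenset({"GU", "UG", "AU", "UA"})


class Vintage(str, enum.Enum):
    """Parameter vintage: the 1999 or the 2004 nearest-neighbor rule set."""

    T99 = "t99"
    T04 = "t04"


def _decode(text: str, shape: Tuple[int, ...]) -> np.ndarray:
    return np.array(text.split(), dtype=np.int32).reshape(shape)


@dataclass(frozen=True)
class TurnerParamSet:
    """One vintage of embedded nearest-neighbor constants.

    Energies are integer centi-kcal/mol.  ``stack[p1, p2]`` is the free
    energy of stacking pair ``p2`` onto pair ``p1``, with ``p2`` read from
    the opposite strand (the usual quartet convention); ``bulge_init[k]`` /
    ``intloop_init[k]`` are loop initiation energies for total unpaired
    length ``k`` (index 0 unused, :data:`INF` where undefined).
    """

    vintage: Vintage
    stack: np.ndarray          # (6, 6)
    bulge_init: np.ndarray     # (31,)
    intloop_init: np.ndarray   # (31,)
    intloop_11: np.ndarray     # (6, 6, 5, 5)
    intloop_12: np.ndarray     # (6, 6, 5, 5, 5)
    intloop_22: np.ndarray     # (6, 6, 5, 5, 5, 5), padded from ACGU axes
    mismatch_interior: np.ndarray      # (6, 5, 5)
    mismatch_interior_1n: np.ndarray   # (6, 5, 5)
    mismatch_interior_23: np.ndarray   # (6, 5, 5)
    asym_penalty: int          # per-nucleotide asymmetry slope (Ninio)
    max_asym_total: int        # cap on the total asymmetry penalty
    terminal_au_gu: int        # helix-end penalty per A-U / G-U pair
    duplex_init: int           # intermolecular initiation
    lxc: float                 # log-extrapolation coefficient beyond size 30

    def stack_energy(self, quartet_top: str, quartet_bottom: str) -> float:
        """Stack energy in kcal/mol for 5'-``quartet_top``-3' over
        3'-``quartet_bottom``-5' (e.g. ``("GC", "CG")``)."""
        p1 = PAIR_INDEX[quartet_top[0] + quartet_bottom[0]]
        p2 = PAIR_INDEX[quartet_bottom[1] + quartet_top[1]]
        return self.stack[p1, p2] / 100.0

    def is_closure_penalized(self, pair: str) -> bool:
        return pair in WOBBLE_OR_AU


@dataclass(frozen=True)
class AffineLoopModel:
    """Affine approximation of the loop tables, in centi-kcal/mol.

    ``bulge_open + k * bulge_ext`` reproduces the tabulated bulge initiation
    exactly for k = 2..6.  The interior-loop curve
    ``intloop_open + (s / 2) * intloop_ext_sym`` is a least-squares fit to
    the tabulated symmetric interior-loop initiations over total sizes
    s = 4..14 (the well-approximated region); larger loops are deliberately
    over-penalized.  ``intloop_ext_asym`` is the per-nucleotide asymmetry
    slope of the parameter set.
    """

    bulge_open: float
    bulge_ext: float
    intloop_open: float
    intloop_ext_sym: float
    intloop_ext_asym: float

    def bulge_cost(self, k: int) -> float:
        """Affine bulge cost (centi-kcal) for a k-nt bulge, k >= 1."""
        return self.bulge_open + k * self.bulge_ext

    def interior_cost(self, size: int) -> float:
        """Affine symmetric interior-loop cost (centi-kcal) for total
        unpaired length ``size``."""
        return self.intloop_open + (size / 2.0) * self.intloop_ext_sym


_MODULES = {Vintage.T99: _nndb_t99, Vintage.T04: _nndb_t04}


def load_params(vintage: Vintage | str = Vintage.T04) -> TurnerParamSet:
    """Return the embedded constant set for one vintage.

    The tables ship with the package; no files are read at runtime.
    Raises :class:`ValueError` for an unknown vintage.
    """
    try:
        vintage = Vintage(vintage)
    except ValueError as exc:
        raise ValueError(
            f"unknown parameter vintage {vintage!r}; expected 't99' or 't04'"
        ) from exc
    return _load_params(vintage)


@lru_cache(maxsize=None)
def _load_params(vintage: Vintage) -> TurnerParamSet:
    mod = _MODULES[vintage]
    int22 = np.full((6, 6, 5, 5, 5, 5), INF, dtype=np.int32)
    int22[:, :, 1:, 1:, 1:, 1:] = _decode(mod.INT22, (6, 6, 4, 4, 4, 4))
    return TurnerParamSet(
        vintage=vintage,
        stack=_decode(mod.STACK, (6, 6)),
        bulge_init=_decode(mod.BULGE, (31,)),
        intloop_init=_decode(mod.INTERNAL, (31,)),
        intloop_11=_decode(mod.INT11, (6, 6, 5, 5)),
        intloop_12=_decode(mod.INT21, (6, 6, 5, 5, 5)),
        intloop_22=int22,
        mismatch_interior=_decode(mod.MISMATCH_I, (6, 5, 5)),
        mismatch_interior_1n=_decode(mod.MISMATCH_1N, (6, 5, 5)),
        mismatch_interior_23=_decode(mod.MISMATCH_23, (6, 5, 5)),
        asym_penalty=mod.NINIO_M,
        max_asym_total=mod.NINIO_MAX,
        terminal_au_gu=mod.TERM_AU,
        duplex_init=mod.DUPLEX_INIT,
        lxc=mod.LXC,
    )


def fit_affine_bulge(params: TurnerParamSet) -> Tuple[float, float]:
    """Fit the affine bulge model; returns ``(open, ext)`` in kcal/mol.

    ``ext`` is the common difference of the bulge initiation table over
    sizes 2..6 and ``open = bulge_init(2) - 2 * ext``, so that
    ``open + k * ext`` reproduces the table exactly for k = 2..6.  A
    non-constant difference indicates a corrupted table and raises
    :class:`ValueError`.
    """
    tab = params.bulge_init
    diffs = np.diff(tab[2:7])
    if not np.all(diffs == diffs[0]):
        raise ValueError(
            f"bulge initiation table of {params.vintage.value} is not affine "
            f"over sizes 2..6 (differences {diffs.tolist()})"
        )
    ext = float(diffs[0])
    opening = float(tab[2]) - 2.0 * ext
    return opening / 100.0, ext / 100.0


def fit_affine_interior(params: TurnerParamSet) -> Tuple[float, float, float]:
    """Fit the affine interior-loop model.

    Returns ``(open, ext_sym, ext_asym)`` in kcal/mol.  ``ext_asym`` is the
    parameter set's per-nucleotide asymmetry slope; ``open`` and ``ext_sym``
    are least-squares fitted so that ``open + (s/2) * ext_sym`` tracks the
    tabulated symmetric interior-loop initiations over total sizes
    s = 4, 6, ..., 14.
    """
    sizes = np.arange(4, 15, 2)
    steps = sizes / 2.0
    y = params.intloop_init[sizes].astype(float)
    ext_sym, opening = np.polyfit(steps, y, 1)
    return opening / 100.0, float(ext_sym) / 100.0, params.asym_penalty / 100.0


def affine_model(params: TurnerParamSet) -> AffineLoopModel:
    """Convenience: both affine fits bundled, in centi-kcal/mol."""
    b_open, b_ext = fit_affine_bulge(params)
    i_open, i_sym, i_asym = fit_affine_interior(params)
    return AffineLoopModel(
        bulge_open=b_open * 100.0,
        bulge_ext=b_ext * 100.0,
        intloop_open=i_open * 100.0,
        intloop_ext_sym=i_sym * 100.0,
        intloop_ext_asym=i_asym * 100.0,
    )


def dump_params_tsv(params: TurnerParamSet) -> str:
    """Render the scalar constants and 1-D loop tables as TSV for
    inspection (stack quartets are part of the matrix dump instead)."""
    lines = [f"# vintage\t{params.vintage.value}"]
    lines.append(f"asym_penalty\t{params.asym_penalty}")
    lines.append(f"max_asym_total\t{params.max_asym_total}")
    lines.append(f"terminal_au_gu\t{params.terminal_au_gu}")
    lines.append(f"duplex_init\t{params.duplex_init}")
    lines.append(f"lxc\t{params.lxc}")
    for name, tab in (("bulge", params.bulge_init), ("interior", params.intloop_init)):
        for k in range(1, 31):
            v = int(tab[k])
            lines.append(f"{name}_init\t{k}\t{'INF' if v >= INF else v}")
    return "\n".join(lines) + "\n"
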