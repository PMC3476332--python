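"""FASTA input, hit tables, and run configuration."""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Union

from Bio import SeqIO

from .engine import DuplexHit, NucSeq
from .params import Vintage

__all__ = ["RunConfig", "read_fasta", "write_hits", "read_hits", "HIT_COLUMNS"]

HIT_COLUMNS = (
    "query_id", "q_start", "q_end",
    "target_id", "t_start", "t_end",
    "energy_kcal", "structure",
)

_ALLOWED = set("ACGUN")


@dataclass(frozen=True)
class RunConfig:
    """Everything a search run depends on; serialized into output headers."""

    vintage: Vintage = Vintage.T04
    threshold: float = -5.0       # kcal/mol
    per_nt_penalty: float = 0.0   # kcal/mol per alignment column
    window: int = 40              # nt
    n_subopt: int = 1
    merge: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.threshold > 0:
            raise ValueError("energy threshold must be <= 0")
        if self.per_nt_penalty < 0:
            raise ValueError("per-nucleotide penalty must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_subopt not in (1, 2, 3):
            raise ValueError("n_subopt must be 1, 2 or 3")

    def header(self) -> str:
        fields = asdict(self)
        fields["vintage"] = self.vintage.value
        pairs = " ".join(f"{k}={v}" for k, v in fields.items())
        return f"# duplexscan {pairs}"


def read_fasta(source: Union[str, Path, TextIO]) -> List[NucSeq]:
    """Read a (multi-)FASTA file of RNA or DNA sequences.

    T/t is mapped to U; lowercase is accepted; IUPAC ambiguity codes other
    than N are rejected with a position-specific message.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no FASTA records found")
    out = []
    for rec in records:
        res = str(rec.seq).upper().replace("T", "U")
        for pos, sym in enumerate(res, start=1):
            if sym not in _ALLOWED:
                raise ValueError(
                    f"record {rec.id!r}: illegal symbol {sym!r} at position {pos}"
                )
        out.append(NucSeq(rec.id, res))
    return out


def write_hits(
    hits: Sequence[DuplexHit],
    path: Union[str, Path, TextIO],
    config: Optional[RunConfig] = None,
) -> None:
    """Write hits as TSV with a ``#``-prefixed provenance header."""
    buf = _io.StringIO()
    if config is not None:
        buf.write(config.header() + "\n")
    buf.write("# " + "\t".join(HIT_COLUMNS) + "\n")
    for h in hits:
        buf.write(
            f"{h.query_id}\t{h.q_start}\t{h.q_end}\t"
            f"{h.target_id}\t{h.t_start}\t{h.t_end}\t"
            f"{h.energy:.2f}\t{h.structure}\n"
        )
    text = buf.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def read_hits(source: Union[str, Path, TextIO]) -> List[DuplexHit]:
    """Parse a hit table written by :func:`write_hits` (round-trips)."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = source.read().splitlines()
    out = []
    for line in lines:
        if not line or line.startswith("#"):
            continue
        qid, qs, qe, tid, ts, te, energy, structure = line.split("\t")
        out.append(
            DuplexHit(
                query_id=qid, target_id=tid,
                q_start=int(qs), q_end=int(qe),
                t_start=int(ts), t_end=int(te),
                energy=float(energy), score=0, structure=structure,
            )
        )
    return out
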