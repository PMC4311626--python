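"""Lipobox scanning.

Bacterial lipoproteins carry an N-terminal lipobox, here the (V/L)XXC
class: a valine or leucine, two arbitrary residues, and the invariant
cysteine that is lipidated and becomes the mature N-terminus after signal
peptidase II cleavage.  The scanner reports every match whose cysteine
falls inside an N-terminal window, flagging the exact sequence LGCC — the
lipidation site found in TadD-like pilotin/docking proteins — as canonical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InputError
from .seqio import ProteinFamily

#: default N-terminal window (residues) within which the lipobox cysteine
#: must fall; typical of lipoprotein signal peptide lengths.
DEFAULT_WINDOW = 40

CANONICAL = "LGCC"
_LIPOBOX = re.compile(r"(?=([VL]..C))")


@dataclass(frozen=True)
class LipoboxHit:
    """One (V/L)XXC match; positions are 1-based."""

    start: int
    motif: str
    cys_position: int
    canonical: bool

    def __post_init__(self) -> None:
        if len(self.motif) != 4 or self.motif[3] != "C":
            raise InputError(f"invalid lipobox motif {self.motif!r}")
        if self.cys_position != self.start + 3:
            raise InputError("cys_position must be start + 3")


def scan_lipobox(sequence: str, window: int = DEFAULT_WINDOW) -> list[LipoboxHit]:
    """All (V/L)XXC matches whose cysteine lies within the first *window* residues.

    Matches may overlap; they are returned in order of start position.
    The sequence must be ungapped.
    """
    if window < 4:
        raise InputError("window must be at least 4 residues")
    seq = sequence.upper()
    if "-" in seq:
        raise InputError("scan_lipobox expects an ungapped sequence")
    hits = []
    for m in _LIPOBOX.finditer(seq):
        start = m.start() + 1  # 1-based
        cys = start + 3
        if cys > window:
            break
        motif = m.group(1)
        hits.append(
            LipoboxHit(start=start, motif=motif, cys_position=cys,
                       canonical=motif == CANONICAL)
        )
    return hits


def scan_family(family: ProteinFamily, window: int = DEFAULT_WINDOW):
    """Scan every record of a family; yields (record id, hit) pairs.

    Gap characters are stripped first, so aligned families can be scanned.
    """
    for rec in family.records:
        for hit in scan_lipobox(rec.sequence.replace("-", ""), window=window):
            yield rec.id, hit
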