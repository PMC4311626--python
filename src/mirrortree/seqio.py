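"""Family I/O and homolog-set construction.

A *protein family* here is an organism-labeled set of sequences for one
reference protein, at most one sequence per organism, the unit on which the
mirrortree analysis operates.  Families are read from FASTA or Clustal
alignments; the organism tag is either parsed from the sequence header
(token after the last ``|``) or supplied through a two-column TSV mapping.

Homolog-hit tables (e.g. exported from a BLAST search) can be filtered by
query coverage and reduced to one representative sequence per organism.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

from .errors import InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed in a ProteinRecord: the 20 standard amino acids, the
#: alignment gap '-' and the unknown residue 'X'.
ALLOWED_CHARS = frozenset(AMINO_ACIDS + "-X")


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence with its identifier and organism tag."""

    id: str
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("record id must be non-empty")
        if not self.organism:
            raise InputError(f"record {self.id!r}: organism must be non-empty")
        if not self.sequence:
            raise InputError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - ALLOWED_CHARS
        if bad:
            raise InputError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected 20-letter amino-acid alphabet, '-' or 'X')"
            )


@dataclass
class ProteinFamily:
    """Ordered collection of :class:`ProteinRecord` for one reference protein.

    ``aligned`` is True iff all sequences have equal length.  Uniqueness of
    record ids is enforced; uniqueness of organisms is the caller's
    responsibility (use :func:`select_one_per_organism` upstream) and is
    checked where it matters, at the distance stage.
    """

    name: str
    records: list[ProteinRecord] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"family {self.name!r}: duplicate record ids {dup}")
        lengths = {len(r.sequence) for r in self.records}
        self.aligned = len(lengths) == 1 and bool(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def organisms(self) -> list[str]:
        return [r.organism for r in self.records]

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise InputError(f"family {self.name!r} is not aligned")
        return len(self.records[0].sequence)


@dataclass(frozen=True)
class HomologHit:
    """One homology-search hit: subject sequence, organism, score, coverage."""

    subject_id: str
    organism: str
    bitscore: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise InputError(
                f"hit {self.subject_id!r}: coverage {self.coverage} not in [0, 1]"
            )
        if self.bitscore < 0:
            raise InputError(f"hit {self.subject_id!r}: negative bitscore")


def _organism_from_header(header: str) -> str:
    """Default organism rule: token after the last '|'; the whole id if none."""
    if "|" in header:
        tag = header.rsplit("|", 1)[1]
        if tag:
            return tag
    return header


def _read_mapping(mapping_file: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(mapping_file).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise InputError(
                f"{mapping_file}: line {lineno}: expected two tab-separated columns"
            )
        mapping[parts[0]] = parts[1]
    return mapping


def read_family(
    path: str | Path,
    format: str = "fasta",
    organism_rule: str = "header_field",
    mapping_file: str | Path | None = None,
    name: str | None = None,
) -> ProteinFamily:
    """Read a family from a FASTA or Clustal file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"fasta"`` or ``"clustal"``.
    organism_rule
        ``"header_field"`` (token after the last ``|`` in the id) or
        ``"mapping_file"`` (two-column TSV id→organism, via *mapping_file*).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format not in ("fasta", "clustal"):
        raise InputError(f"unsupported format {format!r}")
    if organism_rule == "mapping_file":
        if mapping_file is None:
            raise InputError("organism_rule='mapping_file' requires mapping_file")
        mapping = _read_mapping(mapping_file)
    elif organism_rule == "header_field":
        mapping = None
    else:
        raise InputError(f"unknown organism_rule {organism_rule!r}")

    try:
        if format == "clustal":
            seqs = list(AlignIO.read(str(path), "clustal"))
        else:
            seqs = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise InputError(f"{path}: parse error: {exc}") from exc

    if not seqs:
        raise InputError(f"{path}: no records")

    records = []
    for rec in seqs:
        if mapping is not None:
            try:
                organism = mapping[rec.id]
            except KeyError:
                raise InputError(
                    f"{path}: record {rec.id!r} missing from mapping file"
                ) from None
        else:
            organism = _organism_from_header(rec.id)
        records.append(
            ProteinRecord(id=rec.id, organism=organism, sequence=str(rec.seq).upper())
        )
    return ProteinFamily(name=name or path.stem, records=records)


def write_family(family: ProteinFamily, path: str | Path) -> None:
    """Write a family as FASTA, one record per line pair.

    Headers carry the record id verbatim, so a read→write→read round trip
    with the same organism rule reproduces ids, organisms and sequences.
    """
    buf = io.StringIO()
    for rec in family.records:
        buf.write(f">{rec.id}\n{rec.sequence}\n")
    Path(path).write_text(buf.getvalue())


def read_hits(path: str | Path) -> list[HomologHit]:
    """Read a TSV hit table with columns subject_id, organism, bitscore, coverage."""
    try:
        df = pd.read_csv(path, sep="\t")
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise InputError(f"{path}: {exc}") from exc
    required = {"subject_id", "organism", "bitscore", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        HomologHit(
            subject_id=str(row.subject_id),
            organism=str(row.organism),
            bitscore=float(row.bitscore),
            coverage=float(row.coverage),
        )
        for row in df.itertuples()
    ]


def filter_hits(hits: Iterable[HomologHit], min_coverage: float) -> list[HomologHit]:
    """Keep hits whose query coverage is *strictly* greater than ``min_coverage``.

    The strict inequality matters at the boundary: with the conventional
    0.60 threshold, a hit covering exactly 60% of the query is dropped.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise InputError(f"min_coverage {min_coverage} not in [0, 1]")
    return [h for h in hits if h.coverage > min_coverage]


def select_one_per_organism(hits: Sequence[HomologHit]) -> list[HomologHit]:
    """Reduce a hit list to one representative per organism.

    The representative is the hit with the highest bitscore; ties broken by
    higher coverage, then lexicographically smallest subject_id.  Organisms
    keep their order of first appearance.  Idempotent.
    """
    best: dict[str, HomologHit] = {}
    for hit in hits:
        cur = best.get(hit.organism)
        if cur is None:
            best[hit.organism] = hit
            continue
        if (-hit.bitscore, -hit.coverage, hit.subject_id) < (
            -cur.bitscore,
            -cur.coverage,
            cur.subject_id,
        ):
            best[hit.organism] = hit
    return list(best.values())
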