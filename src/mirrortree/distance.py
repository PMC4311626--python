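"""Pairwise evolutionary distances from protein alignments.

The pipeline works with two distance estimates:

* the observed proportion of differing sites (p-distance), with an explicit
  gap policy — ``pairwise_deletion`` drops gap/'X' columns per sequence
  pair, ``complete_deletion`` drops any column containing a gap or 'X'
  in any sequence before comparing;
* its Poisson correction for a 20-state equal-rates substitution process,
  d = -(19/20) ln(1 - 20 p / 19), which converts the observed fraction back
  to an expected number of substitutions per site and is additive on trees.

'X' residues are treated as missing data, like gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateStatisticError, InputError
from .seqio import AMINO_ACIDS, ProteinFamily

#: p-distances at or above this value saturate the Poisson correction:
#: 19/20 is the asymptotic difference fraction between unrelated sequences.
SATURATION = 19.0 / 20.0

GAP_POLICIES = ("pairwise_deletion", "complete_deletion")
CORRECTIONS = ("poisson", "none")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with organism labels and zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InputError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise InputError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InputError("distance matrix contains negative entries")
        if np.any(np.abs(np.diagonal(self.values)) > 1e-12):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise InputError("distance matrix must be symmetric")
        # exact symmetry/zero diagonal below the validation tolerance
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        """Restrict to the given labels, in the given order."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [index[lab] for lab in labels]
        except KeyError as exc:
            raise InputError(f"label {exc.args[0]!r} not in matrix") from None
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV with a header row and a leading label column."""
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{v:.10g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise InputError(f"{path}: empty distance matrix")
        labels = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([float(x) for x in parts[1:]])
        if len(rows) != len(labels):
            raise InputError(f"{path}: row count does not match header")
        return cls(labels, np.array(rows))

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square (lower+upper) distance format."""
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(f"{lab:<10s}" + "  ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _encode(family: ProteinFamily) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences as a (records, columns) byte matrix plus a validity mask."""
    arr = np.frombuffer(
        "".join(r.sequence for r in family.records).encode("ascii"), dtype=np.uint8
    ).reshape(len(family.records), family.alignment_length)
    valid = np.isin(arr, np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8))
    return arr, valid


def p_distance_matrix(
    family: ProteinFamily, gap_policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Observed-difference (p) distance matrix between the family's organisms.

    Entry (i, j) is the number of differing comparable columns over the
    number of comparable columns, where a column is comparable when both
    residues are standard amino acids (no gap, no 'X').  A pair with no
    comparable column at all is an error, not a silent zero.
    """
    if gap_policy not in GAP_POLICIES:
        raise InputError(f"unknown gap_policy {gap_policy!r}")
    if not family.aligned:
        raise InputError(f"family {family.name!r} is not aligned")
    if len(family) < 2:
        raise InputError(f"family {family.name!r}: need at least 2 records")
    organisms = family.organisms
    if len(set(organisms)) != len(organisms):
        dup = sorted({o for o in organisms if organisms.count(o) > 1})
        raise InputError(
            f"family {family.name!r}: multiple records for organisms {dup}; "
            "select one sequence per organism first"
        )

    arr, valid = _encode(family)
    if gap_policy == "complete_deletion":
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]

    n = len(family)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            total = int(comparable.sum())
            if total == 0:
                raise DegenerateStatisticError(
                    f"family {family.name!r}: no comparable columns between "
                    f"{organisms[i]!r} and {organisms[j]!r}"
                )
            diffs = int((arr[i, comparable] != arr[j, comparable]).sum())
            mat[i, j] = mat[j, i] = diffs / total
    return DistanceMatrix(list(organisms), mat)


def poisson_correct(D: DistanceMatrix) -> DistanceMatrix:
    """Poisson (20-state equal-rates) correction of a p-distance matrix.

    Maps p to -(19/20) ln(1 - 20 p / 19); zero maps to zero.  Saturated
    entries (p >= 19/20) have no finite corrected distance and raise.
    """
    p = D.values
    if np.any(p >= SATURATION):
        i, j = np.argwhere(p >= SATURATION)[0]
        raise DegenerateStatisticError(
            f"saturated p-distance {p[i, j]:.4f} >= {SATURATION} between "
            f"{D.labels[i]!r} and {D.labels[j]!r}; Poisson correction undefined"
        )
    with np.errstate(divide="ignore"):
        d = -SATURATION * np.log1p(-p / SATURATION)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(D.labels), d)


def distance_matrix(
    family: ProteinFamily,
    gap_policy: str = "pairwise_deletion",
    correction: str = "poisson",
) -> DistanceMatrix:
    """p-distance with the chosen gap policy, optionally Poisson-corrected."""
    if correction not in CORRECTIONS:
        raise InputError(f"unknown correction {correction!r}")
    D = p_distance_matrix(family, gap_policy=gap_policy)
    return poisson_correct(D) if correction == "poisson" else D
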