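"""The mirrortree statistic: correlation between two families' distance matrices.

Two protein families that coevolve (e.g. an interacting secretin/pilotin
pair) accumulate substitutions along the same species history, so their
phylogenetic distance matrices are similar.  The mirrortree score is the
Pearson correlation r between the upper triangles of the two matrices,
restricted to the N organisms the families share:

    r = sum_i (R_i - Rbar)(S_i - Sbar)
        / sqrt( sum_i (R_i - Rbar)^2 * sum_i (S_i - Sbar)^2 )

with n = (N^2 - N)/2 entries per matrix, R_i the distances of the first
family, S_i the corresponding distances of the second, and Rbar, Sbar their
means.

Significance is assessed by a Mantel-style permutation test: the organism
labels of the second matrix are permuted jointly (rows and columns), which
preserves the within-matrix distance structure and is the exchangeable null
for "the two trees agree beyond chance".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix
from .errors import DegenerateStatisticError, InputError

#: below this many shared organisms n = (N^2 - N)/2 <= 3 and the
#: correlation is close to degenerate.
DEFAULT_MIN_ORGANISMS = 4


@dataclass
class MatchedPair:
    """The two families' distances restricted to their common organisms.

    ``R`` and ``S`` hold the flattened upper triangles (i < j over the
    lexicographically sorted common organisms) of the first and second
    family's matrix; position k of R and of S refers to the same organism
    pair.
    """

    common_organisms: list[str]
    R: np.ndarray
    S: np.ndarray
    matrix1: DistanceMatrix = field(repr=False)
    matrix2: DistanceMatrix = field(repr=False)

    @property
    def N(self) -> int:
        return len(self.common_organisms)

    @property
    def n(self) -> int:
        return (self.N * self.N - self.N) // 2


@dataclass(frozen=True)
class MirrortreeResult:
    """Correlation r, its permutation p-value, and the sizes behind them."""

    r: float
    N: int
    n: int
    p_value: float
    B_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "N": self.N,
            "n": self.n,
            "p_value": self.p_value,
            "B_permutations": self.B_permutations,
            "seed": self.seed,
        }


def match_organisms(
    M1: DistanceMatrix,
    M2: DistanceMatrix,
    min_organisms: int = DEFAULT_MIN_ORGANISMS,
) -> MatchedPair:
    """Intersect the organism sets and align both matrices on them.

    Common organisms are sorted lexicographically and both matrices are
    subset in that order, so position k of the two flattened triangles
    always refers to the same organism pair.
    """
    common = sorted(set(M1.labels) & set(M2.labels))
    if len(common) < min_organisms:
        raise InputError(
            f"insufficient common organisms: {len(common)} < {min_organisms}"
        )
    sub1 = M1.submatrix(common)
    sub2 = M2.submatrix(common)
    iu = np.triu_indices(len(common), k=1)
    return MatchedPair(
        common_organisms=common,
        R=sub1.values[iu],
        S=sub2.values[iu],
        matrix1=sub1,
        matrix2=sub2,
    )


def tree_correlation(pair: MatchedPair) -> float:
    """Pearson correlation between the paired distance vectors R and S."""
    return _pearson(pair.R, pair.S)


def _pearson(R: np.ndarray, S: np.ndarray) -> float:
    if R.size < 3:
        raise InputError(f"need at least 3 distance pairs, got {R.size}")
    dR = R - R.mean()
    dS = S - S.mean()
    # constant vectors have zero variance only up to rounding in the mean
    tolR = 1e-12 * max(1.0, abs(float(R.mean())))
    tolS = 1e-12 * max(1.0, abs(float(S.mean())))
    if (dR @ dR) <= R.size * tolR**2 or (dS @ dS) <= S.size * tolS**2:
        raise DegenerateStatisticError(
            "degenerate distance matrix: zero variance in distances"
        )
    denom = np.sqrt((dR @ dR) * (dS @ dS))
    return float((dR @ dS) / denom)


def permutation_pvalue(
    pair: MatchedPair,
    B: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MirrortreeResult:
    """Mantel-style permutation test of the mirrortree correlation.

    The null is built by permuting the organism assignment of the second
    family's matrix — rows and columns jointly, so every permuted matrix
    has exactly the same multiset of distances — and recomputing r against
    the fixed first matrix.  The p-value uses the add-one correction

        p = (1 + #{r_perm at least as extreme as r_obs}) / (1 + B)

    so it is never zero; its floor is 1/(B+1).  ``alternative`` is
    ``"two-sided"`` (extremeness of \\|r\\|) or ``"greater"``.
    """
    if B < 19:
        raise InputError("B must be >= 19 for a meaningful permutation test")
    if alternative not in ("two-sided", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    r_obs = tree_correlation(pair)
    S_full = squareform(pair.S)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(pair.N, k=1)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(pair.N)
        s_perm = S_full[np.ix_(perm, perm)][iu]
        r_perm = _pearson(pair.R, s_perm)
        if alternative == "two-sided":
            if abs(r_perm) >= abs(r_obs):
                exceed += 1
        elif r_perm >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + B)
    return MirrortreeResult(
        r=r_obs, N=pair.N, n=pair.n, p_value=p, B_permutations=B, seed=seed
    )
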