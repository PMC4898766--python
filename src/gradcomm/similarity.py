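"""Pairwise compositional similarity (Sørensen, Jaccard).

Includes the identity J = S/(2-S) linking the two indices and the
inference of integer shared-species counts from printed richness and
similarity values — the reconstruction surface for published similarity
tables that omit the underlying counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import IncidenceMatrix
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class PairCounts:
    """a = shared species, b = exclusive to first, c = exclusive to second."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ParameterError("pair counts must be non-negative")

    @property
    def richness_first(self) -> int:
        return self.a + self.b

    @property
    def richness_second(self) -> int:
        return self.a + self.c


def pair_counts(x, y) -> PairCounts:
    """Exact set arithmetic on two species sets."""
    x, y = set(x), set(y)
    return PairCounts(a=len(x & y), b=len(x - y), c=len(y - x))


def sorensen_similarity(pc: PairCounts) -> float:
    """Sørensen-Dice index 2a/(2a+b+c)."""
    denom = 2 * pc.a + pc.b + pc.c
    if denom == 0:
        raise InputError("Sørensen undefined for two empty communities")
    return 2.0 * pc.a / denom


def jaccard_similarity(pc: PairCounts) -> float:
    """Jaccard index a/(a+b+c)."""
    denom = pc.a + pc.b + pc.c
    if denom == 0:
        raise InputError("Jaccard undefined for two empty communities")
    return pc.a / denom


def jaccard_from_sorensen(s: float) -> float:
    """Convert a Sørensen similarity to Jaccard via J = S/(2-S)."""
    if not 0.0 <= s <= 1.0:
        raise ParameterError(f"Sørensen similarity {s} outside [0, 1]")
    return s / (2.0 - s)


def sorensen_from_jaccard(j: float) -> float:
    """Inverse identity S = 2J/(1+J)."""
    if not 0.0 <= j <= 1.0:
        raise ParameterError(f"Jaccard similarity {j} outside [0, 1]")
    return 2.0 * j / (1.0 + j)


def infer_shared_count(s1: int, s2: int, sorensen: float) -> int:
    """Nearest-integer shared-species count behind a printed Sørensen value.

    Solves 2a/(s1+s2) = sorensen for a, rounding half-up and clamping to
    the feasible range [0, min(s1, s2)].
    """
    if s1 < 1 or s2 < 1:
        raise ParameterError("community richness must be >= 1")
    if not 0.0 <= sorensen <= 1.0:
        raise ParameterError(f"Sørensen similarity {sorensen} outside [0, 1]")
    a = math.floor(sorensen * (s1 + s2) / 2.0 + 0.5)  # half-up
    return max(0, min(a, s1, s2))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    index: str  # "sorensen" | "jaccard"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ParameterError("similarity matrix shape mismatch")
        self.values = v

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


def similarity_matrix(X: IncidenceMatrix, index: str = "sorensen") -> SimilarityMatrix:
    """All pairwise similarities between the units of an incidence matrix."""
    if X.n_units < 2:
        raise InputError("similarity matrix needs at least 2 units")
    if index not in ("sorensen", "jaccard"):
        raise ParameterError(f"index must be sorensen|jaccard, got {index!r}")
    fn = sorensen_similarity if index == "sorensen" else jaccard_similarity
    sets = [X.species_set(u) for u in X.units]
    n = len(sets)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = fn(pair_counts(sets[i], sets[j]))
    return SimilarityMatrix(list(X.units), vals, index)


def combined_table(X: IncidenceMatrix) -> np.ndarray:
    """Sørensen below / Jaccard above the diagonal, publication layout."""
    s = similarity_matrix(X, "sorensen").values
    j = similarity_matrix(X, "jaccard").values
    out = np.eye(X.n_units)
    iu = np.triu_indices(X.n_units, 1)
    il = np.tril_indices(X.n_units, -1)
    out[iu] = j[iu]
    out[il] = s[il]
    return out
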