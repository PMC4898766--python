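"""Beta-diversity partitioning, community clustering, and distance decay.

Two decomposition families are supported: turnover + nestedness on the
Sørensen dissimilarity (beta_sor = beta_sim + beta_sne), and
replacement + richness-difference on the Jaccard (or Sørensen)
dissimilarity (beta_cc = beta_repl + beta_rich).  Both are exact
additive partitions, pairwise and multi-site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import IncidenceMatrix, SpecimenTable, build_incidence, great_circle_km
from .errors import InputError, ParameterError
from .similarity import PairCounts, pair_counts, sorensen_similarity, jaccard_similarity


@dataclass(frozen=True)
class BetaDecomposition:
    family: str  # baselga_sorensen | carvalho_jaccard | carvalho_sorensen
    total: float
    turnover: float
    nestedness_or_richness: float
    scope: str = "pairwise"

    def __post_init__(self) -> None:
        for v in (self.total, self.turnover, self.nestedness_or_richness):
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ParameterError(f"beta component {v} outside [0, 1]")


def baselga_pair(pc: PairCounts) -> BetaDecomposition:
    """Pairwise Sørensen dissimilarity split into turnover and nestedness."""
    a, b, c = pc.a, pc.b, pc.c
    if a + b + c == 0:
        raise InputError("beta undefined for two empty communities")
    total = (b + c) / (2 * a + b + c)
    bmin = min(b, c)
    turnover = bmin / (a + bmin) if (a + bmin) > 0 else 0.0
    return BetaDecomposition("baselga_sorensen", total, turnover, total - turnover)


def baselga_multisite(X: IncidenceMatrix) -> BetaDecomposition:
    """Multi-site Sørensen dissimilarity partition over all units."""
    if X.n_units < 2:
        raise InputError("multi-site beta needs at least 2 units")
    cells = X.cells.astype(bool)
    S_i = cells.sum(axis=0)          # per-site richness
    S_T = X.n_species                # pooled richness (no all-zero rows)
    sum_min = sum_max = 0
    for i, j in combinations(range(X.n_units), 2):
        b_ij = int((cells[:, i] & ~cells[:, j]).sum())
        b_ji = int((cells[:, j] & ~cells[:, i]).sum())
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    core = int(S_i.sum()) - S_T
    denom_sim = core + sum_min
    turnover = sum_min / denom_sim if denom_sim > 0 else 0.0
    denom_sor = 2 * core + sum_min + sum_max
    total = (sum_min + sum_max) / denom_sor if denom_sor > 0 else 0.0
    return BetaDecomposition(
        "baselga_sorensen", total, turnover, total - turnover,
        scope=f"multisite({X.n_units})",
    )


def carvalho_pair(pc: PairCounts, family: str = "jaccard") -> BetaDecomposition:
    """Pairwise replacement + richness-difference partition."""
    a, b, c = pc.a, pc.b, pc.c
    if a + b + c == 0:
        raise InputError("beta undefined for two empty communities")
    denom = (a + b + c) if family == "jaccard" else (2 * a + b + c)
    if family not in ("jaccard", "sorensen"):
        raise ParameterError(f"family must be jaccard|sorensen, got {family!r}")
    total = (b + c) / denom
    repl = 2 * min(b, c) / denom
    rich = abs(b - c) / denom
    return BetaDecomposition(f"carvalho_{family}", total, repl, rich)


def carvalho_multisite(X: IncidenceMatrix, family: str = "jaccard") -> BetaDecomposition:
    """Mean of pairwise replacement/richness components over all unit pairs.

    The multi-site value is defined here as the unweighted mean of the
    pairwise decompositions (additivity is preserved by linearity).
    """
    if X.n_units < 2:
        raise InputError("multi-site beta needs at least 2 units")
    sets = [X.species_set(u) for u in X.units]
    parts = [carvalho_pair(pair_counts(x, y), family) for x, y in combinations(sets, 2)]
    return BetaDecomposition(
        f"carvalho_{family}",
        float(np.mean([p.total for p in parts])),
        float(np.mean([p.turnover for p in parts])),
        float(np.mean([p.nestedness_or_richness for p in parts])),
        scope=f"multisite({X.n_units}, mean-pairwise)",
    )


def turnover_fraction(d: BetaDecomposition) -> float:
    """Share of total dissimilarity attributable to turnover/replacement."""
    if d.total <= 0:
        raise ParameterError("turnover fraction undefined when total beta is 0")
    return d.turnover / d.total


# ---------------------------------------------------------------------------
# UPGMA clustering


@dataclass
class Dendrogram:
    """Agglomeration history: leaves and (left, right, height) merges.

    ``merges`` entries reference previously produced nodes by index:
    0..n-1 are leaves, n+k is the node created by merge k.  Heights are
    non-decreasing (ultrametric).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def n_leaves(self) -> int:
        return len(self.leaves)

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distance matrix in leaf order."""
        n = len(self.leaves)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        D = np.zeros((n, n))
        for k, (l, r, h) in enumerate(self.merges):
            for i in members[l]:
                for j in members[r]:
                    D[i, j] = D[j, i] = h
            members[n + k] = members[l] + members[r]
        return D

    def to_newick(self) -> str:
        """Newick string; branch lengths are half merge heights."""
        n = len(self.leaves)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for k, (l, r, h) in enumerate(self.merges):
            bl_l = h / 2.0 - height[l] / 2.0
            bl_r = h / 2.0 - height[r] / 2.0
            text[n + k] = f"({text[l]}:{bl_l:.6g},{text[r]}:{bl_r:.6g})"
            height[n + k] = h
        return text[n + len(self.merges) - 1] + ";"

    def first_merge_leaves(self) -> tuple[str, str]:
        l, r, _ = self.merges[0]
        return self.leaves[l], self.leaves[r]


def upgma(D: np.ndarray, labels: list[str] | None = None, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    Average linkage (UPGMA) by default; ``single`` and ``complete``
    provided as alternates.  Ties are broken deterministically by the
    lexicographically smallest pair of current cluster labels (the label
    of a cluster is its smallest leaf label).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ParameterError("upgma needs a symmetric matrix with zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ParameterError("label count does not match matrix size")
    if linkage not in ("average", "single", "complete"):
        raise ParameterError(f"unknown linkage {linkage!r}")

    # active clusters: node_id -> (leaf indices, representative label)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_key = min(
            dist,
            key=lambda k: (dist[k], tuple(sorted((rep[k[0]], rep[k[1]])))),
        )
        i, j = best_key
        h = dist[best_key]
        l, r = (i, j) if rep[i] <= rep[j] else (j, i)
        merges.append((l, r, h))
        members = active[i] + active[j]
        ni, nj = len(active[i]), len(active[j])
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if linkage == "average":
                dnew = (ni * dik + nj * djk) / (ni + nj)
            elif linkage == "single":
                dnew = min(dik, djk)
            else:
                dnew = max(dik, djk)
            dist[(k, next_id)] = dnew
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del active[i], active[j]
        active[next_id] = members
        rep[next_id] = min(rep[l], rep[r])
        next_id += 1
    return Dendrogram(list(labels), merges)


# ---------------------------------------------------------------------------
# Distance decay


@dataclass
class DistanceDecay:
    pairs: list[tuple[str, str, float, float]]  # (unit_a, unit_b, km, similarity)
    intercept: float
    slope: float
    smooth: list[tuple[float, float]]  # (km, locally smoothed similarity)


def distance_decay(
    table: SpecimenTable,
    hypothesis: str,
    unit_definition="locality",
    index: str = "sorensen",
    window_fraction: float = 0.25,
) -> DistanceDecay:
    """Compositional similarity against geographic distance for all unit pairs.

    Fits an ordinary least-squares line and a moving-window
    least-squares smooth (window = *window_fraction* of pairs).
    """
    X = build_incidence(table, hypothesis, unit_definition)
    if X.n_units < 3:
        raise InputError("distance decay needs at least 3 units")
    coords = table.locality_coords()
    if X.unit_definition == "path":
        # centroid of a path's localities
        by_path: dict[str, list[tuple[float, float]]] = {}
        for r in table.records:
            by_path.setdefault(r.path, []).append((r.latitude, r.longitude))
        unit_xy = {p: tuple(np.mean(v, axis=0)) for p, v in by_path.items()}
    else:
        unit_xy = {u: (coords[u][0], coords[u][1]) for u in X.units if u in coords}
    fn = sorensen_similarity if index == "sorensen" else jaccard_similarity
    sets = {u: X.species_set(u) for u in X.units}

    pairs = []
    for a, b in combinations(sorted(unit_xy), 2):
        km = great_circle_km(*unit_xy[a], *unit_xy[b])
        sim = fn(pair_counts(sets[a], sets[b]))
        pairs.append((a, b, km, sim))
    d = np.array([p[2] for p in pairs])
    s = np.array([p[3] for p in pairs])
    if np.allclose(d, d[0]):
        raise InputError("all pairwise distances identical; fit undefined")
    slope, intercept = np.polyfit(d, s, 1)

    order = np.argsort(d)
    w = max(3, int(round(window_fraction * len(pairs))))
    smooth = []
    for rank, idx in enumerate(order):
        lo = max(0, rank - w // 2)
        hi = min(len(pairs), lo + w)
        lo = max(0, hi - w)
        dd, ss = d[order[lo:hi]], s[order[lo:hi]]
        if np.allclose(dd, dd[0]):
            yhat = float(ss.mean())
        else:
            b1, b0 = np.polyfit(dd, ss, 1)
            yhat = float(b1 * d[idx] + b0)
        smooth.append((float(d[idx]), yhat))
    return DistanceDecay(pairs, float(intercept), float(slope), smooth)
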