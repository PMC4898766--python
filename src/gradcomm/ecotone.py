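"""Sliding-window ecotone detection along an elevation gradient.

The sample is sliced into fixed-width elevation bins; adjacent bins are
compared by their shared-species (Sørensen-Dice) index and by counts of
species exclusive to either side.  A transition interval is called where
the shared index drops low, and a boundary where the exclusivity trends
cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import SpecimenTable
from .errors import InputError, ParameterError
from .similarity import pair_counts, sorensen_similarity


@dataclass
class ElevationBins:
    """Equal-width, half-open [low, high) bins anchored at 0 m."""

    width: float
    edges: list[float]                    # bin k covers [edges[k], edges[k+1])
    species_sets: list[set[str]]          # per bin, for the chosen hypothesis
    individual_counts: list[dict[str, int]]  # per bin: species -> n individuals

    @property
    def n_bins(self) -> int:
        return len(self.species_sets)


def slice_elevation(
    table: SpecimenTable, hypothesis: str, width: float = 40.0
) -> ElevationBins:
    """Assign every record to its elevation bin [k*w, (k+1)*w).

    Bins are contiguous from 0 m to the top of the data's elevation
    span; intermediate empty bins are retained.
    """
    if width <= 0:
        raise ParameterError(f"bin width must be positive, got {width}")
    if hypothesis not in table.hypotheses:
        raise ParameterError(f"unknown hypothesis {hypothesis!r}")
    max_elev = max(r.elevation for r in table.records)
    n_bins = int(math.floor(max_elev / width)) + 1
    edges = [k * width for k in range(n_bins + 1)]
    species_sets: list[set[str]] = [set() for _ in range(n_bins)]
    counts: list[dict[str, int]] = [dict() for _ in range(n_bins)]
    for r in table.records:
        sp = r.label(hypothesis)
        if sp is None:
            continue
        k = int(math.floor(r.elevation / width))
        species_sets[k].add(sp)
        counts[k][sp] = counts[k].get(sp, 0) + 1
    return ElevationBins(float(width), edges, species_sets, counts)


@dataclass(frozen=True)
class WindowComparison:
    boundary: float        # shared edge between the two adjacent bins
    shared_index: float    # Sørensen-Dice similarity of the two bins
    below_exclusive: int
    above_exclusive: int
    bin_sizes: tuple[int, int] = (0, 0)  # species counts of the two bins


@dataclass
class SlidingWindowProfile:
    comparisons: list[WindowComparison]
    singleton_policy: str      # "included" | "excluded"
    exclusivity_mode: str      # "pairwise" | "global"
    width: float


def sliding_profile(
    bins: ElevationBins,
    exclude_singletons: bool = False,
    exclusivity_mode: str = "global",
    table: SpecimenTable | None = None,
    hypothesis: str | None = None,
) -> SlidingWindowProfile:
    """Profile adjacent-bin shared-species index and species exclusivity.

    ``global`` exclusivity at a shared edge t counts species whose every
    individual lies strictly below t (below-exclusive) or at/above t
    (above-exclusive) over the whole dataset; ``pairwise`` counts
    species found only in the lower or only in the upper bin of the
    comparison.  Singleton exclusion removes species with exactly one
    individual in the whole table before all computations.
    """
    if exclusivity_mode not in ("pairwise", "global"):
        raise ParameterError(f"exclusivity_mode must be pairwise|global, got {exclusivity_mode!r}")
    total_counts: dict[str, int] = {}
    for c in bins.individual_counts:
        for sp, n in c.items():
            total_counts[sp] = total_counts.get(sp, 0) + n
    drop: set[str] = (
        {sp for sp, n in total_counts.items() if n == 1} if exclude_singletons else set()
    )
    sets = [s - drop for s in bins.species_sets]
    nonempty = [i for i, s in enumerate(sets) if s]
    if len(nonempty) < 2:
        raise InputError("need at least 2 non-empty elevation bins")

    # Highest bin index in which each species occurs / lowest, for global mode
    lo_bin: dict[str, int] = {}
    hi_bin: dict[str, int] = {}
    for i, s in enumerate(sets):
        for sp in s:
            lo_bin.setdefault(sp, i)
            hi_bin[sp] = i

    comparisons: list[WindowComparison] = []
    pairs_idx = [
        (nonempty[k], nonempty[k + 1]) for k in range(len(nonempty) - 1)
    ]
    for lo, hi in pairs_idx:
        edge = bins.edges[hi]  # shared (or intervening) edge elevation
        pc = pair_counts(sets[lo], sets[hi])
        shared = sorensen_similarity(pc) if (pc.a + pc.b + pc.c) else 0.0
        if exclusivity_mode == "pairwise":
            below, above = pc.b, pc.c
        else:
            edge_bin = hi  # species at/above edge start in bin index >= hi
            below = sum(1 for sp in lo_bin if hi_bin[sp] < edge_bin)
            above = sum(1 for sp in lo_bin if lo_bin[sp] >= edge_bin)
        comparisons.append(
            WindowComparison(edge, shared, below, above, (len(sets[lo]), len(sets[hi])))
        )
    return SlidingWindowProfile(
        comparisons,
        "excluded" if exclude_singletons else "included",
        exclusivity_mode,
        bins.width,
    )


@dataclass
class EcotoneCall:
    detected: bool
    transition_interval: tuple[float, float] | None
    boundary: float | None
    diagnostics: dict
    confidence_note: str = ""


def detect_ecotone(
    profile: SlidingWindowProfile,
    low_quantile: float = 0.25,
    absolute_threshold: float | None = None,
    min_bin_species: int = 5,
) -> EcotoneCall:
    """Call the ecotone transition interval and boundary from a profile.

    The transition interval is the maximal contiguous run of adjacent-bin
    comparisons whose shared index falls below a profile-relative
    threshold (the *low_quantile* quantile of the shared-index
    distribution, or *absolute_threshold* when given).  Comparisons in
    which either bin holds fewer than *min_bin_species* species are
    ineligible: sparsely populated terminal bins yield spuriously low
    similarity.  The boundary is the bin edge where the below/above
    exclusivity difference changes sign, searched within (then nearest
    to) the transition interval; with no sign change the
    minimum-shared-index segment is returned with a low-confidence note.
    """
    comps = profile.comparisons
    if len(comps) < 3:
        raise InputError("profile needs at least 3 comparisons")
    shared = np.array([c.shared_index for c in comps])
    eligible = np.array([min(c.bin_sizes) >= min_bin_species for c in comps])
    if not eligible.any():
        eligible = np.ones(len(comps), dtype=bool)
    pool = shared[eligible]
    thr = (
        float(absolute_threshold)
        if absolute_threshold is not None
        else float(np.quantile(pool, low_quantile))
    )
    if absolute_threshold is not None:
        low = (shared < thr) & eligible
    else:
        # quantile threshold: prefer strictly-below so the run stays
        # non-trivial when many values tie at the quantile
        low = (shared < thr) & eligible
        if not low.any():
            low = (shared <= thr) & eligible
    if not low.any():
        return EcotoneCall(False, None, None, {"threshold": thr}, "no ecotone detected")

    # maximal contiguous low run (longest; leftmost on ties)
    best_run: tuple[int, int] | None = None
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            if best_run is None or (j - i) > (best_run[1] - best_run[0]):
                best_run = (i, j)
            i = j + 1
        else:
            i += 1
    assert best_run is not None
    lo_i, hi_i = best_run
    interval = (comps[lo_i].boundary - profile.width, comps[hi_i].boundary + profile.width)

    diff = np.array([c.below_exclusive - c.above_exclusive for c in comps])
    edges = np.array([c.boundary for c in comps])
    crossings = [
        k for k in range(len(diff) - 1)
        if (diff[k] == 0) or (diff[k] < 0 <= diff[k + 1]) or (diff[k] > 0 >= diff[k + 1])
    ]
    diagnostics = {
        "threshold": thr,
        "min_shared_index": float(shared.min()),
        "exclusivity_crossings": [float(edges[k]) for k in in_order(crossings)],
    }
    if crossings:
        centre = 0.5 * (interval[0] + interval[1])
        inside = [k for k in crossings if interval[0] <= edges[k] <= interval[1]]
        pool = inside if inside else crossings
        k = min(pool, key=lambda k: (abs(edges[k] - centre), edges[k]))
        # snap to the edge (of the crossing pair) closest to the zero of diff
        if k + 1 < len(diff) and abs(diff[k + 1]) < abs(diff[k]):
            boundary = float(edges[k + 1])
        else:
            boundary = float(edges[k])
        note = "" if inside else "exclusivity crossing outside transition interval"
        return EcotoneCall(True, interval, boundary, diagnostics, note)
    k_min = int(shared.argmin())
    return EcotoneCall(
        True,
        interval,
        float(edges[k_min]),
        diagnostics,
        "low confidence: no exclusivity sign change; minimum-shared-index segment used",
    )


def in_order(xs):
    return sorted(xs)


def width_sensitivity(
    table: SpecimenTable,
    hypothesis: str,
    widths=(20.0, 40.0, 60.0, 80.0),
    **kwargs,
) -> dict[float, EcotoneCall]:
    """Re-run detection across bin widths; a calibration aid, not a chooser."""
    out = {}
    for w in widths:
        bins = slice_elevation(table, hypothesis, w)
        profile = sliding_profile(bins, **kwargs)
        try:
            out[float(w)] = detect_ecotone(profile)
        except InputError:
            continue
    return out
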