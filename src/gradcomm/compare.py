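"""Agreement scoring between two species partitions of the same specimens.

Each reference species is classified by the relation of its specimen set
to the test partition: recovered exactly (agree), partitioned into
several pure test species (split), wholly combined with other reference
species into one test species (merge), or entangled in a many-to-many
overlap (complex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .data_model import SpecimenTable
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PartitionComparison:
    reference: str
    test: str
    n_reference_species: int
    agree: int
    split: int
    merge: int
    complex: int
    detail: dict[str, str] = field(default_factory=dict)  # ref species -> class

    def __post_init__(self) -> None:
        if self.agree + self.split + self.merge + self.complex != self.n_reference_species:
            raise ParameterError("agreement classes must sum to the reference species count")


def compare_partitions(
    table: SpecimenTable,
    reference: str,
    test: str,
    collapse_haplotypes: bool = False,
) -> PartitionComparison:
    """Classify every reference species as agree/split/merge/complex.

    Rows missing either label are dropped with a logged count.  With
    ``collapse_haplotypes`` the comparison is made on haplotypes (each
    distinct haplotype counted once) instead of individuals; class
    definitions are unchanged because set relations are.
    """
    for h in (reference, test):
        if h not in table.hypotheses:
            raise ParameterError(f"unknown hypothesis {h!r}")
    ref_sets: dict[str, set[str]] = {}
    test_sets: dict[str, set[str]] = {}
    dropped = 0
    for r in table.records:
        ra, te = r.label(reference), r.label(test)
        if ra is None or te is None:
            dropped += 1
            continue
        item = r.haplotype if collapse_haplotypes else r.specimen_id
        if item is None:
            raise InputError("collapse_haplotypes requires a haplotype for every record")
        ref_sets.setdefault(ra, set()).add(item)
        test_sets.setdefault(te, set()).add(item)
    if dropped:
        logger.info("compare_partitions: dropped %d records missing a label", dropped)
    if not ref_sets:
        raise InputError("no specimens carry both hypothesis labels")

    counts = {"agree": 0, "split": 0, "merge": 0, "complex": 0}
    detail: dict[str, str] = {}
    for rsp, rset in ref_sets.items():
        overlapping = [t for t, tset in test_sets.items() if rset & tset]
        if len(overlapping) == 1:
            tset = test_sets[overlapping[0]]
            cls = "agree" if tset == rset else ("merge" if rset < tset else "complex")
        else:
            pure = all(test_sets[t] <= rset for t in overlapping)
            cls = "split" if pure else "complex"
        counts[cls] += 1
        detail[rsp] = cls
    return PartitionComparison(
        reference, test, len(ref_sets),
        counts["agree"], counts["split"], counts["merge"], counts["complex"],
        detail,
    )


def match_percentage(cmp: PartitionComparison) -> float:
    """Percent of reference species exactly recovered by the test partition."""
    if cmp.n_reference_species <= 0:
        raise ParameterError("reference species count must be positive")
    return 100.0 * cmp.agree / cmp.n_reference_species
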