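"""Specimen tables, incidence matrices, biome assignment and geography.

The substrate of every downstream statistic is the species x sample-unit
incidence matrix built from a table of georeferenced specimen records,
each carrying one or more species-hypothesis labels.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: Sentinel accepted as an explicit missing species label.
MISSING_LABEL = ""

_REQUIRED = ("specimen_id", "path", "locality", "latitude", "longitude", "elevation")

DEFAULT_SCHEMA = {
    "specimen_id": "specimen_id",
    "path": "path",
    "locality": "locality",
    "latitude": "latitude",
    "longitude": "longitude",
    "elevation": "elevation_m",
    "haplotype": "haplotype",
    "visit": "visit_date",
}


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected individual with its place and species labels."""

    specimen_id: str
    path: str
    locality: str
    latitude: float
    longitude: float
    elevation: float
    species_labels: Mapping[str, str]
    haplotype: str | None = None
    visit: date | str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"latitude {self.latitude} out of [-90, 90] for {self.specimen_id}"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"longitude {self.longitude} out of [-180, 180] for {self.specimen_id}"
            )
        if self.elevation < 0:
            raise ValidationError(
                f"elevation {self.elevation} < 0 for {self.specimen_id}"
            )
        if not any(v not in (None, MISSING_LABEL) for v in self.species_labels.values()):
            raise ValidationError(
                f"record {self.specimen_id} carries no species label"
            )

    def label(self, hypothesis: str) -> str | None:
        """Species label under *hypothesis*, or None if missing."""
        v = self.species_labels.get(hypothesis)
        return None if v in (None, MISSING_LABEL) else v


@dataclass
class SpecimenTable:
    """Ordered collection of specimen records plus declared hypotheses."""

    records: list[SpecimenRecord]
    hypotheses: list[str]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("specimen table is empty")
        seen: set[str] = set()
        for r in self.records:
            if r.specimen_id in seen:
                raise ValidationError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def paths(self) -> list[str]:
        return sorted({r.path for r in self.records})

    @property
    def localities(self) -> list[str]:
        return sorted({r.locality for r in self.records})

    def locality_coords(self) -> dict[str, tuple[float, float, float]]:
        """locality -> (lat, lon, elevation); mean over records per locality."""
        acc: dict[str, list[tuple[float, float, float]]] = {}
        for r in self.records:
            acc.setdefault(r.locality, []).append(
                (r.latitude, r.longitude, r.elevation)
            )
        return {
            loc: tuple(float(np.mean(col)) for col in zip(*vals))  # type: ignore[misc]
            for loc, vals in acc.items()
        }

    def subset(self, keep) -> "SpecimenTable":
        """New table keeping records where ``keep(record)`` is true."""
        kept = [r for r in self.records if keep(r)]
        if not kept:
            raise InputError("subset removed every record")
        return SpecimenTable(kept, list(self.hypotheses))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "specimen_id": r.specimen_id,
                "path": r.path,
                "locality": r.locality,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "elevation_m": r.elevation,
            }
            for h in self.hypotheses:
                row[f"species_{h}"] = r.species_labels.get(h, MISSING_LABEL) or ""
            row["haplotype"] = r.haplotype or ""
            row["visit_date"] = str(r.visit) if r.visit is not None else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)


def read_specimen_table(
    source,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> SpecimenTable:
    """Read and validate a delimited specimen table.

    Parameters
    ----------
    source
        Path or text stream of a CSV/TSV file with a header row.
    schema
        Map from canonical field names (``specimen_id``, ``path``,
        ``locality``, ``latitude``, ``longitude``, ``elevation``,
        ``haplotype``, ``visit``) to the column names present in the
        file.  Species hypotheses are auto-detected from columns named
        ``species_<hypothesis>`` unless the schema maps hypothesis names
        explicitly via keys of the form ``species:<hypothesis>``.
    delimiter
        Force a delimiter; auto-detected (csv sniffing) when None.

    Raises
    ------
    SchemaError
        If a required column cannot be resolved.
    ValidationError
        If a row fails validation (reported with its row number).
    InputError
        If the file is empty.
    """
    resolved = dict(DEFAULT_SCHEMA)
    hyp_cols: dict[str, str] = {}
    if schema:
        for k, v in schema.items():
            if k.startswith("species:"):
                hyp_cols[k.split(":", 1)[1]] = v
            else:
                resolved[k] = v

    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    if not text.strip():
        raise InputError("empty specimen table input")

    if delimiter is None:
        header = text.splitlines()[0]
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False)
    if df.empty:
        raise InputError("specimen table has a header but no rows")

    for key in _REQUIRED:
        if resolved[key] not in df.columns:
            raise SchemaError(
                f"required column {key!r} (expected as {resolved[key]!r}) not found"
            )
    if not hyp_cols:
        for col in df.columns:
            if col.startswith("species_"):
                hyp_cols[col[len("species_"):]] = col
    if not hyp_cols:
        raise SchemaError("no species hypothesis column (species_<name>) found")

    records: list[SpecimenRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rowd = dict(zip(df.columns, row))
        try:
            labels = {h: rowd.get(c, "").strip() for h, c in hyp_cols.items()}
            records.append(
                SpecimenRecord(
                    specimen_id=rowd[resolved["specimen_id"]].strip(),
                    path=rowd[resolved["path"]].strip(),
                    locality=rowd[resolved["locality"]].strip(),
                    latitude=_parse_float(rowd[resolved["latitude"]], "latitude"),
                    longitude=_parse_float(rowd[resolved["longitude"]], "longitude"),
                    elevation=_parse_float(rowd[resolved["elevation"]], "elevation"),
                    species_labels=labels,
                    haplotype=rowd.get(resolved["haplotype"], "").strip() or None,
                    visit=rowd.get(resolved["visit"], "").strip() or None,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return SpecimenTable(records, sorted(hyp_cols))


def _parse_float(value: str, what: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"unparseable {what}: {value!r}") from None


# ---------------------------------------------------------------------------
# Incidence matrices


@dataclass
class IncidenceMatrix:
    """Binary species x sample-unit matrix."""

    species: list[str]
    units: list[str]
    cells: np.ndarray  # shape (S_obs, n_units), dtype int8, strictly 0/1
    unit_definition: str = "custom"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.species), len(self.units)):
            raise ValidationError("cells shape does not match species/units")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValidationError("incidence cells must be 0/1")
        if (self.cells.sum(axis=1) == 0).any():
            raise ValidationError("all-zero species row in incidence matrix")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def species_set(self, unit: str) -> frozenset[str]:
        j = self.units.index(unit)
        return frozenset(s for s, v in zip(self.species, self.cells[:, j]) if v)

    def species_sets(self) -> dict[str, frozenset[str]]:
        return {u: self.species_set(u) for u in self.units}

    def merge_units(self, mapping: Mapping[str, str], unit_definition: str = "custom") -> "IncidenceMatrix":
        """Collapse units into groups via ``mapping[unit] -> group``."""
        groups = sorted({mapping[u] for u in self.units if u in mapping})
        cols = []
        for g in groups:
            idx = [j for j, u in enumerate(self.units) if mapping.get(u) == g]
            cols.append(self.cells[:, idx].max(axis=1))
        cells = np.stack(cols, axis=1)
        keep = cells.sum(axis=1) > 0
        return IncidenceMatrix(
            [s for s, k in zip(self.species, keep) if k],
            groups,
            cells[keep],
            unit_definition,
        )

    def to_tsv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(self.cells, index=self.species, columns=self.units)
        df.index.name = "species"
        df.to_csv(path, sep="\t")
        if sidecar and isinstance(path, (str, Path)):
            meta = {
                "unit_definition": self.unit_definition,
                "n_species": self.n_species,
                "n_units": self.n_units,
            }
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path, unit_definition: str = "custom") -> "IncidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(s) for s in df.index],
            [str(u) for u in df.columns],
            df.to_numpy(dtype=np.int8),
            unit_definition,
        )


def build_incidence(
    table: SpecimenTable,
    hypothesis: str,
    unit_definition="locality",
) -> IncidenceMatrix:
    """Build a presence/absence matrix over configurable sample-units.

    ``unit_definition`` may be ``"locality"`` (default), ``"path"``,
    ``("elevation_bin", width)``, ``("biome", threshold)`` or a mapping
    ``locality -> unit``.  Records lacking a species label under
    *hypothesis*, or whose unit is unresolvable, are dropped with a
    logged count.
    """
    if hypothesis not in table.hypotheses:
        raise ParameterError(
            f"unknown hypothesis {hypothesis!r}; available: {table.hypotheses}"
        )
    unit_of, definition = _unit_resolver(unit_definition)

    pairs: set[tuple[str, str]] = set()
    dropped_label = dropped_unit = 0
    for r in table.records:
        sp = r.label(hypothesis)
        if sp is None:
            dropped_label += 1
            continue
        u = unit_of(r)
        if u is None:
            dropped_unit += 1
            continue
        pairs.add((sp, u))
    if dropped_label:
        logger.info("build_incidence: %d records lacked a %r label", dropped_label, hypothesis)
    if dropped_unit:
        logger.info("build_incidence: %d records had unresolvable units", dropped_unit)
    if not pairs:
        raise InputError("no records resolvable into incidence cells")

    species = sorted({p[0] for p in pairs})
    units = _sorted_units([p[1] for p in pairs], definition)
    cells = np.zeros((len(species), len(units)), dtype=np.int8)
    srow = {s: i for i, s in enumerate(species)}
    ucol = {u: j for j, u in enumerate(units)}
    for s, u in pairs:
        cells[srow[s], ucol[u]] = 1
    return IncidenceMatrix(species, units, cells, definition)


def _unit_resolver(unit_definition):
    if unit_definition == "locality":
        return (lambda r: r.locality), "locality"
    if unit_definition == "path":
        return (lambda r: r.path), "path"
    if isinstance(unit_definition, Mapping):
        mapping = unit_definition
        return (lambda r: mapping.get(r.locality)), "custom"
    if isinstance(unit_definition, tuple) and len(unit_definition) == 2:
        kind, param = unit_definition
        if kind == "elevation_bin":
            if param <= 0:
                raise ParameterError("elevation_bin width must be > 0")
            w = float(param)
            return (
                lambda r: f"{int(math.floor(r.elevation / w) * w):05d}",
                f"elevation_bin({param})",
            )
        if kind == "biome":
            if param <= 0:
                raise ParameterError("biome threshold must be > 0")
            t = float(param)
            return (
                lambda r: "dry" if r.elevation < t else "moist",
                f"biome({param})",
            )
    raise ParameterError(f"unrecognised unit definition {unit_definition!r}")


def _sorted_units(units: Iterable[str], definition: str) -> list[str]:
    uniq = sorted(set(units))
    if definition == "biome" or definition.startswith("biome("):
        # dry (low elevation) before moist
        order = {"dry": 0, "moist": 1}
        uniq.sort(key=lambda u: order.get(u, 2))
    return uniq


# ---------------------------------------------------------------------------
# Biomes


@dataclass(frozen=True)
class BiomeAssignment:
    """Half-open elevation split: [0, t) dry, [t, inf) moist."""

    threshold: float
    labels: Mapping[str, str]  # specimen_id -> {"dry", "moist"}


def assign_biome(table: SpecimenTable, threshold_m: float) -> BiomeAssignment:
    """Label every record dry (< threshold) or moist (>= threshold)."""
    if threshold_m <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold_m}")
    labels = {
        r.specimen_id: ("dry" if r.elevation < threshold_m else "moist")
        for r in table.records
    }
    return BiomeAssignment(float(threshold_m), labels)


# ---------------------------------------------------------------------------
# Geography


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ParameterError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ParameterError(f"longitude {lon} out of range")
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (
        math.sin((p2 - p1) / 2.0) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def max_pairwise_distance(
    table: SpecimenTable, exclude_paths: set[str] | frozenset[str] = frozenset()
) -> tuple[str, str, float]:
    """Maximum great-circle distance over all locality pairs.

    Returns ``(locality_a, locality_b, km)`` with the pair in
    lexicographic order; ties broken lexicographically.
    """
    coords = {
        loc: (lat, lon)
        for loc, (lat, lon, _elev) in table.subset(
            lambda r: r.path not in exclude_paths
        ).locality_coords().items()
    }
    locs = sorted(coords)
    if len(locs) < 2:
        raise InputError("need at least two distinct localities")
    best: tuple[str, str, float] | None = None
    for i, a in enumerate(locs):
        for b in locs[i + 1:]:
            d = great_circle_km(*coords[a], *coords[b])
            if best is None or d > best[2] or (d == best[2] and (a, b) < best[:2]):
                best = (a, b, d)
    assert best is not None
    return best


def summarize_singletons(
    table: SpecimenTable, hypothesis: str, basis: str = "individuals"
) -> tuple[int, float]:
    """Count species represented by exactly one individual (or haplotype).

    Returns ``(count, fraction_of_observed_species)``.
    """
    if hypothesis not in table.hypotheses:
        raise ParameterError(f"unknown hypothesis {hypothesis!r}")
    if basis not in ("individuals", "haplotypes"):
        raise ParameterError(f"basis must be individuals|haplotypes, got {basis!r}")
    per_species: dict[str, list[SpecimenRecord]] = {}
    for r in table.records:
        sp = r.label(hypothesis)
        if sp is not None:
            per_species.setdefault(sp, []).append(r)
    if not per_species:
        raise InputError(f"no records labelled under {hypothesis!r}")
    if basis == "haplotypes":
        if any(r.haplotype is None for rs in per_species.values() for r in rs):
            raise InputError("haplotype basis requires a haplotype for every record")
        sizes = {sp: len({r.haplotype for r in rs}) for sp, rs in per_species.items()}
    else:
        sizes = {sp: len(rs) for sp, rs in per_species.items()}
    count = sum(1 for n in sizes.values() if n == 1)
    return count, count / len(sizes)
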