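"""Domain types and file I/O for capture records, genotypes, habitat maps and pedigrees.

The spatial universe is a fenced park whose perimeter is fringed by numbered
bushes; every capture is coarsened to the bush where it happened.  Individuals
are marked lizards observed across seasonal cohorts (spring/fall); genotypes
are codominant microsatellite calls (two integer allele sizes per locus).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from shapely.geometry import LineString, Polygon, mapping, shape

__all__ = [
    "ValidationError",
    "CohortKey",
    "HabitatMap",
    "CaptureRecord",
    "Individual",
    "GenotypeTable",
    "PedigreeLink",
    "HEAVYWEIGHT_SVL_MM",
    "classify_morph",
    "read_capture_table",
    "write_capture_table",
    "read_genotypes",
    "write_genotypes",
    "read_habitat",
    "write_habitat",
    "read_pedigree",
    "write_pedigree",
    "build_individuals",
    "cohort_members",
]

#: SVL threshold (mm) separating lightweight from heavyweight male morphs.
HEAVYWEIGHT_SVL_MM = 64.0

SEASONS = ("spring", "fall")


class ValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class CohortKey:
    """A seasonal sampling cohort.  Orders spring before fall within a year."""

    year: int
    season_index: int  # 0 = spring, 1 = fall

    @classmethod
    def of(cls, year: int, season: str) -> "CohortKey":
        season = season.strip().lower()
        if season not in SEASONS:
            raise ValidationError(f"unparseable season {season!r} (expected spring|fall)")
        return cls(int(year), SEASONS.index(season))

    @property
    def season(self) -> str:
        return SEASONS[self.season_index]

    @property
    def label(self) -> str:
        return ("S" if self.season_index == 0 else "F") + str(self.year)

    def next(self) -> "CohortKey":
        if self.season_index == 0:
            return CohortKey(self.year, 1)
        return CohortKey(self.year + 1, 0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortKey({self.label})"


@dataclass
class HabitatMap:
    """Numbered bush polygons plus the park perimeter fence.

    Coordinates are planar metres in a local park frame (origin at the
    southwest fence corner).
    """

    bushes: dict[int, Polygon]
    fence: LineString
    crs_note: str = "local planar metres, origin SW fence corner"

    def __post_init__(self) -> None:
        if len(self.bushes) == 0:
            raise ValidationError("habitat map has no bushes")
        for bid, poly in self.bushes.items():
            if not isinstance(bid, int) or bid < 1:
                raise ValidationError(f"bush_id {bid!r} must be a positive integer")
            if (not poly.is_valid) or poly.area <= 0:
                raise ValidationError(f"bush {bid} polygon is degenerate or self-intersecting")
        if not self.fence.is_closed:
            raise ValidationError("fence polyline must be closed")

    @property
    def bush_ids(self) -> list[int]:
        return sorted(self.bushes)

    def centroid(self, bush_id: int) -> tuple[float, float]:
        c = self.bushes[bush_id].centroid
        return (c.x, c.y)

    def validate_near_fence(self, buffer_m: float = 10.0) -> None:
        """Check every bush centroid lies within ``buffer_m`` of the fence."""
        for bid, poly in self.bushes.items():
            if self.fence.distance(poly.centroid) > buffer_m:
                raise ValidationError(
                    f"bush {bid} centroid is farther than {buffer_m} m from the fence"
                )


@dataclass(frozen=True)
class CaptureRecord:
    """One observation of a marked lizard in one seasonal cohort."""

    individual_id: str
    cohort: CohortKey
    sex: str  # "M" | "F"
    svl: float  # snout-vent length, mm
    bush_id: int
    mass: float | None = None  # g
    x: float | None = None  # raw capture coordinates, retained but unused
    y: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if not self.svl > 0:
            raise ValidationError(f"svl must be positive, got {self.svl}")
        if self.mass is not None and not self.mass > 0:
            raise ValidationError(f"mass must be positive, got {self.mass}")

    @property
    def morph(self) -> str:
        return classify_morph(self.svl)


@dataclass
class Individual:
    """A marked lizard aggregated across its capture records."""

    individual_id: str
    sex: str
    records: list[CaptureRecord] = field(default_factory=list)

    @property
    def first_cohort(self) -> CohortKey:
        return min(r.cohort for r in self.records)

    @property
    def max_svl(self) -> float:
        return max(r.svl for r in self.records)

    @property
    def capture_bushes(self) -> list[int]:
        return sorted({r.bush_id for r in self.records})

    def record_at(self, cohort: CohortKey) -> CaptureRecord | None:
        for r in self.records:
            if r.cohort == cohort:
                return r
        return None

    def morph_at(self, cohort: CohortKey) -> str | None:
        """Size morph in a given cohort (None if not captured then)."""
        r = self.record_at(cohort)
        return None if r is None else classify_morph(r.svl)


def classify_morph(svl: float) -> str:
    """Classify a male size morph from snout-vent length.

    Heavyweight iff svl >= 64.0 mm; the threshold at which New Orleans male
    green anoles show the large-head/high-bite-force morphology.
    """
    if not svl > 0:
        raise ValidationError(f"svl must be positive, got {svl}")
    return "heavyweight" if svl >= HEAVYWEIGHT_SVL_MM else "lightweight"


def build_individuals(records: Iterable[CaptureRecord]) -> dict[str, Individual]:
    """Aggregate capture records into individuals; sex must be consistent."""
    out: dict[str, Individual] = {}
    for rec in records:
        ind = out.get(rec.individual_id)
        if ind is None:
            out[rec.individual_id] = Individual(rec.individual_id, rec.sex, [rec])
        else:
            if ind.sex != rec.sex:
                raise ValidationError(
                    f"individual {rec.individual_id} recorded as both sexes"
                )
            ind.records.append(rec)
    for ind in out.values():
        ind.records.sort(key=lambda r: r.cohort)
    return out


def cohort_members(records: Iterable[CaptureRecord]) -> dict[CohortKey, list[str]]:
    """Map each cohort to the sorted ids with a record in it."""
    out: dict[CohortKey, list[str]] = {}
    for rec in records:
        out.setdefault(rec.cohort, []).append(rec.individual_id)
    return {k: sorted(set(v)) for k, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# Capture table CSV
# ---------------------------------------------------------------------------

CAPTURE_HEADER = ["id", "year", "season", "sex", "svl_mm", "mass_g", "bush_id"]

# plausibility window for SVL (mm); records outside are rejected
SVL_WINDOW = (20.0, 80.0)


def read_capture_table(
    path: str | Path,
    habitat: HabitatMap,
    svl_window: tuple[float, float] = SVL_WINDOW,
) -> list[CaptureRecord]:
    """Read a capture CSV, validating bush ids, seasons and duplicates."""
    records: list[CaptureRecord] = []
    seen: set[tuple[str, CohortKey]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header mandatory")
        missing = set(CAPTURE_HEADER[:5] + ["bush_id"]) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            cohort = CohortKey.of(int(row["year"]), row["season"])
            bush_id = int(row["bush_id"])
            if bush_id not in habitat.bushes:
                raise ValidationError(
                    f"{path} row {i}: unknown bush_id {bush_id} "
                    f"(habitat has {len(habitat.bushes)} bushes)"
                )
            svl = float(row["svl_mm"])
            if not (svl_window[0] <= svl <= svl_window[1]):
                raise ValidationError(
                    f"{path} row {i}: svl {svl} outside plausibility window {svl_window}"
                )
            key = (row["id"], cohort)
            if key in seen:
                raise ValidationError(
                    f"{path} row {i}: duplicate record for {row['id']} in {cohort.label}"
                )
            seen.add(key)
            mass_raw = (row.get("mass_g") or "").strip()
            records.append(
                CaptureRecord(
                    individual_id=row["id"],
                    cohort=cohort,
                    sex=row["sex"].strip().upper()[:1],
                    svl=svl,
                    mass=float(mass_raw) if mass_raw else None,
                    bush_id=bush_id,
                )
            )
    return records


def write_capture_table(records: Sequence[CaptureRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CAPTURE_HEADER)
        for r in records:
            w.writerow(
                [
                    r.individual_id,
                    r.cohort.year,
                    r.cohort.season,
                    r.sex,
                    f"{r.svl:g}",
                    "" if r.mass is None else f"{r.mass:g}",
                    r.bush_id,
                ]
            )


# ---------------------------------------------------------------------------
# Genotypes: GenePop and two-columns-per-locus CSV
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Individual x locus diploid microsatellite calls.

    Allele pairs are unordered; they are normalised to sorted tuples on
    construction.  Missing calls are ``None``.
    """

    loci: list[str]
    calls: dict[str, dict[str, tuple[int, int] | None]]

    def __post_init__(self) -> None:
        for ind, by_locus in self.calls.items():
            for loc, pair in by_locus.items():
                if pair is not None:
                    a, b = pair
                    by_locus[loc] = (min(a, b), max(a, b))

    @property
    def ids(self) -> list[str]:
        return list(self.calls)

    def get(self, individual_id: str, locus: str) -> tuple[int, int] | None:
        return self.calls.get(individual_id, {}).get(locus)

    def missing_fraction(self, individual_id: str) -> float:
        by_locus = self.calls.get(individual_id, {})
        n_missing = sum(1 for loc in self.loci if by_locus.get(loc) is None)
        return n_missing / len(self.loci)

    def complete_ids(self, max_missing: float = 0.25) -> list[str]:
        """Ids with at most ``max_missing`` fraction of loci missing."""
        return [i for i in self.ids if self.missing_fraction(i) <= max_missing]

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        return GenotypeTable(
            list(self.loci), {i: dict(self.calls[i]) for i in ids if i in self.calls}
        )


def _genepop_width(table: GenotypeTable) -> int:
    biggest = 0
    for by_locus in table.calls.values():
        for pair in by_locus.values():
            if pair is not None:
                biggest = max(biggest, *pair)
    return 3 if biggest > 99 else 2


def write_genotypes(
    table: GenotypeTable, path: str | Path, format: str = "genepop", title: str = "genotypes"
) -> None:
    if format == "genepop":
        w = _genepop_width(table)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(title + "\n")
            for loc in table.loci:
                fh.write(loc + "\n")
            fh.write("Pop\n")
            for ind, by_locus in table.calls.items():
                cells = []
                for loc in table.loci:
                    pair = by_locus.get(loc)
                    if pair is None:
                        cells.append("0" * (2 * w))
                    else:
                        cells.append(f"{pair[0]:0{w}d}{pair[1]:0{w}d}")
                fh.write(f"{ind}, " + " ".join(cells) + "\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            wcsv = csv.writer(fh)
            header = ["id"]
            for loc in table.loci:
                header += [f"{loc}_1", f"{loc}_2"]
            wcsv.writerow(header)
            for ind, by_locus in table.calls.items():
                row: list[str] = [ind]
                for loc in table.loci:
                    pair = by_locus.get(loc)
                    row += ["NA", "NA"] if pair is None else [str(pair[0]), str(pair[1])]
                wcsv.writerow(row)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes(
    path: str | Path,
    format: str = "genepop",
    capture_ids: set[str] | None = None,
) -> GenotypeTable:
    """Read a genotype table; individuals absent from ``capture_ids`` are retained
    with a warning (import ``warnings``-free: collected on the table as attribute)."""
    if format == "genepop":
        table = _read_genepop(path)
    elif format == "csv":
        table = _read_genotype_csv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if capture_ids is not None:
        orphans = [i for i in table.ids if i not in capture_ids]
        if orphans:
            import warnings

            warnings.warn(
                f"{len(orphans)} genotyped individuals absent from capture table "
                f"(e.g. {orphans[:3]}); retained",
                stacklevel=2,
            )
    return table


def _read_genepop(path: str | Path) -> GenotypeTable:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise ValidationError(f"{path}: truncated GenePop file")
    # title line, then locus names (one per line or comma-separated) until "Pop"
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend([t.strip() for t in lines[i].split(",") if t.strip()])
        i += 1
    if i == len(lines):
        raise ValidationError(f"{path}: no 'Pop' separator found")
    calls: dict[str, dict[str, tuple[int, int] | None]] = {}
    for ln in lines[i:]:
        if ln.strip().lower() == "pop" or not ln.strip():
            continue
        if "," not in ln:
            raise ValidationError(f"{path}: malformed GenePop line {ln!r}")
        ind, rest = ln.split(",", 1)
        ind = ind.strip()
        cells = rest.split()
        if len(cells) != len(loci):
            raise ValidationError(
                f"{path}: individual {ind} has {len(cells)} genotypes for {len(loci)} loci"
            )
        width = len(cells[0]) // 2
        by_locus: dict[str, tuple[int, int] | None] = {}
        for loc, cell in zip(loci, cells):
            if len(cell) % 2 != 0 or len(cell) // 2 not in (2, 3):
                raise ValidationError(f"{path}: odd allele code {cell!r} at locus {loc}")
            w = len(cell) // 2
            a, b = int(cell[:w]), int(cell[w:])
            by_locus[loc] = None if (a == 0 or b == 0) else (min(a, b), max(a, b))
        calls[ind] = by_locus
    return GenotypeTable(loci, calls)


def _read_genotype_csv(path: str | Path) -> GenotypeTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[0] != "id" or (len(header) - 1) % 2 != 0:
            raise ValidationError(f"{path}: expected 'id' plus two columns per locus")
        loci = []
        for j in range(1, len(header), 2):
            name = header[j]
            if name.endswith("_1"):
                name = name[:-2]
            loci.append(name)
        calls: dict[str, dict[str, tuple[int, int] | None]] = {}
        for row in reader:
            by_locus: dict[str, tuple[int, int] | None] = {}
            for k, loc in enumerate(loci):
                a_raw, b_raw = row[1 + 2 * k], row[2 + 2 * k]
                if a_raw in ("NA", "", "0") or b_raw in ("NA", "", "0"):
                    by_locus[loc] = None
                else:
                    a, b = int(a_raw), int(b_raw)
                    by_locus[loc] = (min(a, b), max(a, b))
            calls[row[0]] = by_locus
    return GenotypeTable(loci, calls)


# ---------------------------------------------------------------------------
# Habitat GeoJSON
# ---------------------------------------------------------------------------


def write_habitat(habitat: HabitatMap, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"bush_id": bid},
            "geometry": mapping(poly),
        }
        for bid, poly in sorted(habitat.bushes.items())
    ]
    features.append(
        {
            "type": "Feature",
            "properties": {"role": "fence", "crs_note": habitat.crs_note},
            "geometry": mapping(habitat.fence),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_habitat(path: str | Path) -> HabitatMap:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    bushes: dict[int, Polygon] = {}
    fence: LineString | None = None
    crs_note = "local planar metres, origin SW fence corner"
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("role") == "fence" or isinstance(geom, LineString):
            fence = LineString(geom)
            crs_note = props.get("crs_note", crs_note)
        else:
            bid = int(props["bush_id"])
            if bid in bushes:
                raise ValidationError(f"{path}: duplicate bush_id {bid}")
            bushes[bid] = Polygon(geom)
    if fence is None:
        raise ValidationError(f"{path}: no fence LineString feature")
    return HabitatMap(bushes, fence, crs_note)


# ---------------------------------------------------------------------------
# Pedigree CSV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeLink:
    """An inferred parent-offspring assignment."""

    offspring_id: str
    parent_id: str
    parent_role: str  # "sire" | "dam"
    support: float
    replicates_supporting: int

    def __post_init__(self) -> None:
        if self.parent_role not in ("sire", "dam"):
            raise ValidationError(f"parent_role must be sire|dam, got {self.parent_role!r}")
        if not (0.0 <= self.support <= 1.0):
            raise ValidationError(f"support must be in [0,1], got {self.support}")


PEDIGREE_HEADER = ["offspring_id", "parent_id", "parent_role", "support", "replicates_supporting"]


def write_pedigree(links: Sequence[PedigreeLink], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PEDIGREE_HEADER)
        for link in links:
            w.writerow(
                [
                    link.offspring_id,
                    link.parent_id,
                    link.parent_role,
                    repr(link.support),
                    link.replicates_supporting,
                ]
            )


def read_pedigree(path: str | Path) -> list[PedigreeLink]:
    links: list[PedigreeLink] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            links.append(
                PedigreeLink(
                    offspring_id=row["offspring_id"],
                    parent_id=row["parent_id"],
                    parent_role=row["parent_role"],
                    support=float(row["support"]),
                    replicates_supporting=int(row["replicates_supporting"]),
                )
            )
    # reject multiple parents of one role and cyclic parentage
    seen_roles: set[tuple[str, str]] = set()
    g = nx.DiGraph()
    for link in links:
        key = (link.offspring_id, link.parent_role)
        if key in seen_roles:
            raise ValidationError(
                f"{path}: offspring {link.offspring_id} has more than one {link.parent_role}"
            )
        seen_roles.add(key)
        g.add_edge(link.parent_id, link.offspring_id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValidationError(f"{path}: cyclic parentage {cycle}")
    return links
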