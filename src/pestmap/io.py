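"""Readers for administrative complaint-data dialects and areal geography.

Municipal 311-style exports vary in column naming and date formatting, so
reading goes through a small dialect map (canonical field -> CSV column,
plus accepted date formats).  Parsing streams row by row and never loads a
file whole; malformed rows are counted and logged, not fatal.  The
keyword filter reproduces a text-search extraction of category-specific
inquiries (substring, case-insensitive, auditable via a per-record match
rationale).  Geography comes in as GeoJSON polygons from which a
queen-contiguity graph (any shared boundary point) is built.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import shape
from shapely.strtree import STRtree

from .lattice import AreaLattice
from .panel import MonthlySeries, PanelCounts

logger = logging.getLogger(__name__)

DEFAULT_KEYWORDS = frozenset({"bed bug", "bedbug", "bed bugs"})

CANONICAL_FIELDS = ("created_date", "agency", "descriptor", "area_id", "complaint_type")


@dataclass
class InquiryRecord:
    """One inquiry/complaint row in canonical form."""

    created_date: date
    agency: str = ""
    descriptor: str = ""
    area_id: str | None = None
    complaint_type: str = ""
    match_rationale: str | None = None


@dataclass
class Dialect:
    """Column map and date formats of one export flavour."""

    columns: dict[str, str] = field(
        default_factory=lambda: {f: f for f in CANONICAL_FIELDS}
    )
    date_formats: tuple[str, ...] = ("%Y-%m-%d", "%m/%d/%Y", "%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "columns" in raw:
            kwargs["columns"] = dict(raw["columns"])
        if "date_formats" in raw:
            kwargs["date_formats"] = tuple(raw["date_formats"])
        return cls(**kwargs)

    def parse_date(self, text: str) -> date:
        for fmt in self.date_formats:
            try:
                return datetime.strptime(text.strip(), fmt).date()
            except ValueError:
                continue
        raise ValueError(f"unparseable date {text!r}")


def read_inquiries(
    path, dialect: Dialect | None = None
) -> Iterator[InquiryRecord]:
    """Stream canonical records from a CSV export.

    Rows whose date cannot be parsed are counted and logged at the end of
    the stream, never raised.  Row order is preserved.  Missing mapped
    columns (other than the optional area_id) raise immediately.
    """
    dialect = dialect or Dialect()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: no CSV header")
        header = set(reader.fieldnames)
        # area_id and agency are optional; the text fields and date are not
        required = {
            col
            for name, col in dialect.columns.items()
            if name in ("created_date", "descriptor", "complaint_type")
        }
        missing = sorted(required - header)
        if missing:
            raise ValueError(f"{path}: missing mapped columns {missing}")
        rejected = 0
        for row in reader:
            get = lambda name: row.get(dialect.columns.get(name, name), "") or ""  # noqa: E731
            try:
                created = dialect.parse_date(get("created_date"))
            except ValueError:
                rejected += 1
                continue
            area = get("area_id").strip() or None
            yield InquiryRecord(
                created_date=created,
                agency=get("agency"),
                descriptor=get("descriptor"),
                area_id=area,
                complaint_type=get("complaint_type"),
            )
        if rejected:
            logger.warning("%s: rejected %d malformed rows", path, rejected)


def filter_bedbug(
    records: Iterable[InquiryRecord],
    keyword_set: Iterable[str] = DEFAULT_KEYWORDS,
) -> Iterator[InquiryRecord]:
    """Keep records whose descriptor or complaint type mentions a keyword.

    Case-insensitive substring match; each retained record carries which
    phrase matched which field, so the extraction is auditable.  The
    default phrase set targets bed-bug inquiries and is configurable.
    """
    keywords = [k.lower() for k in keyword_set]
    if not keywords:
        raise ValueError("keyword set must be non-empty")
    for rec in records:
        rationale = None
        for fieldname in ("descriptor", "complaint_type"):
            text = getattr(rec, fieldname).lower()
            for kw in keywords:
                if kw in text:
                    rationale = f"{kw!r} in {fieldname}"
                    break
            if rationale:
                break
        if rationale:
            rec.match_rationale = rationale
            yield rec


def aggregate_monthly(
    records: Iterable[InquiryRecord],
    denominator: dict[str, float] | None = None,
    label: str = "",
) -> MonthlySeries:
    """Count records per calendar month into a consecutive MonthlySeries.

    Months between the first and last observed record are zero-filled.
    ``denominator`` optionally maps 'YYYY-MM' to a parallel total series.
    """
    counts: dict[str, int] = {}
    for rec in records:
        key = f"{rec.created_date.year:04d}-{rec.created_date.month:02d}"
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("no records to aggregate")
    keys = sorted(counts)
    first = datetime.strptime(keys[0], "%Y-%m")
    last = datetime.strptime(keys[-1], "%Y-%m")
    months = []
    y, m = first.year, first.month
    while (y, m) <= (last.year, last.month):
        months.append(f"{y:04d}-{m:02d}")
        m += 1
        if m > 12:
            y, m = y + 1, 1
    values = np.array([counts.get(k, 0) for k in months], dtype=float)
    denom = None
    if denominator is not None:
        try:
            denom = np.array([float(denominator[k]) for k in months])
        except KeyError as exc:
            raise ValueError(f"denominator missing month {exc.args[0]}") from None
    return MonthlySeries(
        t=np.arange(len(months)), y=values, denominator=denom, label=label
    )


def aggregate_panel(
    records: Iterable[InquiryRecord],
    populations: pd.DataFrame,
) -> PanelCounts:
    """Count records per (area, year) into a PanelCounts.

    ``populations`` is a frame with columns area_id, year, population; its
    (area, year) grid defines the panel, so areas or years without records
    appear with y = 0.  Records in areas absent from the population table
    raise with the orphan ids listed; records without an area id are
    excluded with their count logged.
    """
    for col in ("area_id", "year", "population"):
        if col not in populations.columns:
            raise ValueError(f"population table missing column {col!r}")
    known = set(populations["area_id"])
    counts: dict[tuple[str, int], int] = {}
    orphans: set[str] = set()
    n_missing_area = 0
    for rec in records:
        if rec.area_id is None:
            n_missing_area += 1
            continue
        if rec.area_id not in known:
            orphans.add(rec.area_id)
            continue
        key = (rec.area_id, rec.created_date.year)
        counts[key] = counts.get(key, 0) + 1
    if orphans:
        raise ValueError(
            f"records in areas absent from the population table: {sorted(orphans)}"
        )
    if n_missing_area:
        logger.warning(
            "excluded %d records without an area id from the areal panel",
            n_missing_area,
        )
    areas = list(dict.fromkeys(populations["area_id"]))
    years = sorted(populations["year"].unique().tolist())
    pop = (
        populations.pivot(index="area_id", columns="year", values="population")
        .reindex(index=areas, columns=years)
        .to_numpy(dtype=float)
    )
    if np.isnan(pop).any():
        raise ValueError("population table is not a full area x year grid")
    y = np.zeros((len(areas), len(years)))
    aidx = {a: i for i, a in enumerate(areas)}
    yidx = {yr: j for j, yr in enumerate(years)}
    for (a, yr), c in counts.items():
        if yr in yidx:
            y[aidx[a], yidx[yr]] = c
    return PanelCounts(areas, years, y, pop)


def adjacency_from_polygons(
    geo_path, id_property: str = "area_id", populations: dict[str, float] | None = None
) -> AreaLattice:
    """Queen-contiguity lattice from a GeoJSON FeatureCollection.

    Two areas are neighbors when their polygons share any boundary point
    (a shared corner suffices).  Invalid geometries raise with the feature
    named.  Populations default to 1 per area when not supplied.
    """
    with open(geo_path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        raise ValueError(f"{geo_path}: no features")
    ids, geoms = [], []
    for k, feat in enumerate(features):
        props = feat.get("properties", {})
        if id_property not in props:
            raise ValueError(
                f"{geo_path}: feature {k} lacks property {id_property!r}"
            )
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(
                f"{geo_path}: invalid geometry for feature "
                f"{props[id_property]!r}"
            )
        ids.append(str(props[id_property]))
        geoms.append(geom)
    n = len(ids)
    tree = STRtree(geoms)
    rows, cols = [], []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            if g.intersects(geoms[j]) and not g.equals(geoms[j]):
                rows += [i, j]
                cols += [j, i]
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    if populations is None:
        pop = np.ones(n)
    else:
        try:
            pop = np.array([float(populations[a]) for a in ids])
        except KeyError as exc:
            raise ValueError(f"no population for area {exc.args[0]!r}") from None
    return AreaLattice(ids, adj, pop)


def write_geojson_property(
    geo_path, out_path, values: dict[str, float], name: str,
    id_property: str = "area_id",
) -> None:
    """Join a per-area value (e.g. SIR) onto GeoJSON features as a property."""
    with open(geo_path) as fh:
        gj = json.load(fh)
    for feat in gj.get("features", []):
        aid = str(feat.get("properties", {}).get(id_property))
        if aid in values:
            feat["properties"][name] = values[aid]
    with open(out_path, "w") as fh:
        json.dump(gj, fh)
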