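"""Read, validate, summarize and write six-table phenological databases.

The database layout follows the six-table schema used by large
multi-site phenological monitoring archives: comma-separated tables
linked by study-site names and taxon identifiers.

========================  =======================================================
file                      contents
========================  =======================================================
taxonomy.csv              one row per taxon: identifier, scientific name, ranks,
                          GBIF key/status
phenologicalevents.csv    definitions of phenological event types per kingdom
                          (with BBCH codes for plants)
climaticevents.csv        definitions of climatic event types grouped by driver
                          (temperature / snow / ice)
studysites.csv            site name and decimal-degree coordinates
phenology.csv             the observations: one dated event per taxon (or
                          climate) per site per year
informationsources.csv    provenance of each contributing project
========================  =======================================================

In ``phenology.csv`` the sentinel ``taxonidentifier == "Climate"`` marks
climatic-event records; their ``taxon`` field then holds the climatic
group.  The ``quality`` field is empty for clean records; the screens in
this package write the tokens ``suspicious_outlier`` and
``suspicious_bimodal`` into it.

Tables are held in memory as pandas DataFrames with canonical lower-case
column names (matching is case-insensitive and whitespace-trimmed on
load; extra columns are preserved on round-trip).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLIMATE_SENTINEL",
    "QUALITY_OUTLIER",
    "QUALITY_BIMODAL",
    "SCHEMA",
    "SchemaError",
    "Violation",
    "Database",
    "EventGroupSummary",
    "load_database",
    "write_database",
    "validate_links",
    "summarize_events",
    "taxonomic_group",
]

CLIMATE_SENTINEL = "Climate"
QUALITY_OUTLIER = "suspicious_outlier"
QUALITY_BIMODAL = "suspicious_bimodal"

#: file name -> (attribute on Database, required columns in canonical order)
SCHEMA: dict[str, tuple[str, list[str]]] = {
    "taxonomy.csv": (
        "taxa",
        ["taxonidentifier", "taxon", "taxonomiclevel", "kingdom", "phylum",
         "class", "order", "family", "genus", "species", "gbifkey",
         "gbifstatus"],
    ),
    "phenologicalevents.csv": (
        "phenoevents",
        ["kingdom", "eventtype", "description", "bbch"],
    ),
    "climaticevents.csv": (
        "climevents",
        ["group", "eventtype", "description"],
    ),
    "studysites.csv": (
        "sites",
        ["studysite", "latitude", "longitude"],
    ),
    "phenology.csv": (
        "records",
        ["project", "dataset", "studysite", "taxonidentifier", "taxon",
         "eventtype", "year", "dayofyear", "quality"],
    ),
    "informationsources.csv": (
        "sources",
        ["project", "source", "reference"],
    ),
}


class SchemaError(Exception):
    """A fatal schema problem: missing file or missing mandatory column."""


@dataclass(frozen=True)
class Violation:
    """One non-fatal data problem (bad value or broken link)."""

    table: str
    row: int            # 0-based row index within the table
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.row}].{self.field}: {self.message}"


@dataclass
class Database:
    """An in-memory six-table phenological database."""

    records: pd.DataFrame
    sites: pd.DataFrame
    taxa: pd.DataFrame
    phenoevents: pd.DataFrame
    climevents: pd.DataFrame
    sources: pd.DataFrame
    violations: list[Violation] = field(default_factory=list)

    def copy(self) -> "Database":
        return Database(
            records=self.records.copy(),
            sites=self.sites.copy(),
            taxa=self.taxa.copy(),
            phenoevents=self.phenoevents.copy(),
            climevents=self.climevents.copy(),
            sources=self.sources.copy(),
            violations=list(self.violations),
        )

    def is_climate(self) -> pd.Series:
        return self.records["taxonidentifier"] == CLIMATE_SENTINEL

    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class EventGroupSummary:
    """Coverage of one (group, event type) combination.

    N = record count, L = number of distinct locations, S = number of
    distinct species (taxa), S_per_L = mean over locations of the number
    of distinct species observed for that event at that location.
    """

    group: str
    eventtype: str
    N: int
    L: int
    S: int
    S_per_L: float


def _canon(name: str) -> str:
    return name.strip().lower()


def _read_table(path: Path, required: list[str],
                violations: list[Violation]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    rename = {c: _canon(c) for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    # canonical columns first, extras preserved after
    extras = [c for c in df.columns if c not in required]
    return df[required + extras]


def _coerce_int(df: pd.DataFrame, table: str, column: str,
                violations: list[Violation],
                valid=None) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad_parse = out.isna() | (out != np.floor(out.fillna(0)))
    for i in np.flatnonzero(bad_parse.to_numpy()):
        violations.append(Violation(table, int(i), column,
                                    f"unparseable integer {raw.iloc[i]!r}"))
    out = out.where(~bad_parse)
    if valid is not None:
        lo, hi = valid
        out_of_range = out.notna() & ((out < lo) | (out > hi))
        for i in np.flatnonzero(out_of_range.to_numpy()):
            violations.append(Violation(table, int(i), column,
                                        f"value {out.iloc[i]:g} outside [{lo}, {hi}]"))
    return out.astype("Int64")


def load_database(path, dayofyear_range: tuple[int, int] = (1, 366)) -> Database:
    """Load a six-table database directory.

    Missing files and missing mandatory columns are fatal
    (:class:`SchemaError`).  Rows with unparseable ``year``/``dayofyear``
    or coordinates outside their valid ranges are kept, with one
    :class:`Violation` recorded per problem in ``Database.violations``.
    """
    path = Path(path)
    violations: list[Violation] = []
    tables: dict[str, pd.DataFrame] = {}
    for fname, (attr, required) in SCHEMA.items():
        fpath = path / fname
        if not fpath.is_file():
            raise SchemaError(f"missing required file {fname} in {path}")
        tables[attr] = _read_table(fpath, required, violations)

    rec = tables["records"]
    rec["year"] = _coerce_int(rec, "phenology.csv", "year", violations,
                              valid=(1000, 9999))
    rec["dayofyear"] = _coerce_int(rec, "phenology.csv", "dayofyear",
                                   violations, valid=dayofyear_range)

    sites = tables["sites"]
    for col, (lo, hi) in (("latitude", (-90.0, 90.0)),
                          ("longitude", (-180.0, 180.0))):
        vals = pd.to_numeric(sites[col], errors="coerce")
        for i in np.flatnonzero(vals.isna().to_numpy()):
            violations.append(Violation("studysites.csv", int(i), col,
                                        f"unparseable number {sites[col].iloc[i]!r}"))
        for i in np.flatnonzero(((vals < lo) | (vals > hi)).to_numpy()):
            violations.append(Violation("studysites.csv", int(i), col,
                                        f"value {vals.iloc[i]:g} outside [{lo}, {hi}]"))
        sites[col] = vals

    for attr, fname, key in (("sites", "studysites.csv", "studysite"),
                             ("taxa", "taxonomy.csv", "taxonidentifier")):
        dup = tables[attr][key].duplicated(keep="first")
        for i in np.flatnonzero(dup.to_numpy()):
            violations.append(Violation(fname, int(i), key,
                                        f"duplicate key {tables[attr][key].iloc[i]!r}"))

    return Database(violations=violations, **tables)


def write_database(db: Database, path) -> None:
    """Write the six tables as UTF-8, RFC-4180-quoted CSV files.

    Canonical columns come first under their exact schema names; extra
    columns carried through :func:`load_database` are appended so that a
    load/write cycle is lossless.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for fname, (attr, required) in SCHEMA.items():
        df = getattr(db, attr)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {fname}: missing column(s) {missing}")
        extras = [c for c in df.columns if c not in required]
        df[required + extras].to_csv(path / fname, index=False,
                                     encoding="utf-8",
                                     quoting=csv.QUOTE_MINIMAL,
                                     lineterminator="\n")


def validate_links(db: Database) -> list[Violation]:
    """Check referential integrity between the tables.

    One violation per record whose ``studysite`` is absent from
    ``studysites.csv``, whose ``taxonidentifier`` is absent from
    ``taxonomy.csv`` (non-climate records), or — for climate records —
    whose ``eventtype`` is absent from ``climaticevents.csv``.
    Reports, never throws.
    """
    out: list[Violation] = []
    rec = db.records
    known_sites = set(db.sites["studysite"])
    known_taxa = set(db.taxa["taxonidentifier"])
    known_clim = set(db.climevents["eventtype"])
    is_clim = db.is_climate().to_numpy()

    bad_site = ~rec["studysite"].isin(known_sites).to_numpy()
    for i in np.flatnonzero(bad_site):
        out.append(Violation("phenology.csv", int(i), "studysite",
                             f"unknown study site {rec['studysite'].iloc[i]!r}"))
    bad_taxon = ~is_clim & ~rec["taxonidentifier"].isin(known_taxa).to_numpy()
    for i in np.flatnonzero(bad_taxon):
        out.append(Violation("phenology.csv", int(i), "taxonidentifier",
                             f"unknown taxon {rec['taxonidentifier'].iloc[i]!r}"))
    bad_clim = is_clim & ~rec["eventtype"].isin(known_clim).to_numpy()
    for i in np.flatnonzero(bad_clim):
        out.append(Violation("phenology.csv", int(i), "eventtype",
                             f"unknown climatic event {rec['eventtype'].iloc[i]!r}"))
    return out


def taxonomic_group(db: Database) -> pd.Series:
    """Grouping axis for each record: a taxonomic or climatic group.

    Climate records group by their ``taxon`` field, which carries the
    climatic group (temperature/snow/ice).  Phenological records group by
    the taxonomy table's ``class`` when present (e.g. Aves, Magnoliopsida)
    and fall back to ``kingdom`` otherwise.
    """
    rec = db.records
    taxa = db.taxa.drop_duplicates("taxonidentifier").set_index("taxonidentifier")
    cls = rec["taxonidentifier"].map(taxa["class"]) if "class" in taxa else pd.Series("", index=rec.index)
    kingdom = rec["taxonidentifier"].map(taxa["kingdom"]) if "kingdom" in taxa else pd.Series("", index=rec.index)
    group = cls.fillna("").where(cls.fillna("") != "", kingdom.fillna(""))
    group = group.where(group != "", "unknown")
    return group.where(~db.is_climate(), rec["taxon"]).rename("group")


def summarize_events(db: Database) -> list[EventGroupSummary]:
    """Coverage summary per (group, event type): N, L, S and mean S per L."""
    rec = db.records
    if rec.empty:
        return []
    work = pd.DataFrame({
        "group": taxonomic_group(db),
        "eventtype": rec["eventtype"],
        "studysite": rec["studysite"],
        "species": rec["taxonidentifier"],
    })
    out: list[EventGroupSummary] = []
    for (group, eventtype), sub in work.groupby(["group", "eventtype"], sort=True):
        per_site = sub.groupby("studysite")["species"].nunique()
        out.append(EventGroupSummary(
            group=str(group), eventtype=str(eventtype),
            N=int(len(sub)), L=int(sub["studysite"].nunique()),
            S=int(sub["species"].nunique()),
            S_per_L=float(per_site.mean()),
        ))
    return out
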