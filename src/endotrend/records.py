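"""Individual-record tables and species metadata.

The pipeline's primary input is a table of museum specimen measurements:
one row per individual with species id, body mass (g), year of collection,
latitude/longitude (signed decimal degrees) and sex. Records are held in a
:class:`RecordTable`, a thin provenance-carrying wrapper around a pandas
DataFrame with canonical column names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: canonical column order of a record table
RECORD_COLUMNS = ["species_id", "mass", "year", "latitude", "longitude", "sex"]

#: default mapping from input header names to canonical names
DEFAULT_COLUMN_MAP = {
    "species": "species_id",
    "mass_g": "mass",
    "year": "year",
    "lat": "latitude",
    "lon": "longitude",
    "sex": "sex",
}

_SEX_CODES = {"f": "female", "female": "female", "m": "male", "male": "male"}

YEAR_RANGE = (1800, 2100)


class RecordTableError(ValueError):
    """Fatal problem with a record table or its source file."""


@dataclass
class RecordTable:
    """Ordered collection of individual records plus provenance.

    Parameters
    ----------
    df : pandas.DataFrame
        Canonical columns ``species_id, mass, year, latitude, longitude, sex``.
    source : str
        Where the rows came from (path or "synthetic"/"memory").
    filter_log : list of dict
        One entry per cleaning/filtering step already applied, with counts.
    """

    df: pd.DataFrame
    source: str = "memory"
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.df.columns]
        if missing:
            raise RecordTableError(f"record table missing columns: {missing}")
        self.df = self.df[RECORD_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species_id"].unique().tolist())

    def subset(self, mask) -> "RecordTable":
        """New table with the rows where ``mask`` is True; log is inherited."""
        return RecordTable(self.df[mask].copy(), source=self.source,
                           filter_log=list(self.filter_log))

    def log(self, step: str, **counts) -> None:
        self.filter_log.append({"step": step, **counts})

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class SpeciesMeta:
    """Species-level attributes used by the cross-species analyses."""

    species_id: str
    taxo_class: str    # "bird" | "mammal"
    habitat: str       # "aquatic" | "terrestrial"
    n_records: int
    first_year: int
    last_year: int

    @property
    def series_length(self) -> int:
        return self.last_year - self.first_year


def _validate(df: pd.DataFrame, log: list) -> pd.DataFrame:
    """Drop rows with missing/invalid fields, recording counts per reason."""
    n0 = len(df)
    df = df.dropna(subset=RECORD_COLUMNS)
    n_missing = n0 - len(df)

    sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
    n_badsex = int(sex.isna().sum())
    if n_badsex:
        warnings.warn(f"dropping {n_badsex} rows with unknown sex codes",
                      stacklevel=3)
    df = df.assign(sex=sex).dropna(subset=["sex"])

    df = df.assign(
        mass=pd.to_numeric(df["mass"], errors="coerce"),
        year=pd.to_numeric(df["year"], errors="coerce"),
        latitude=pd.to_numeric(df["latitude"], errors="coerce"),
        longitude=pd.to_numeric(df["longitude"], errors="coerce"),
    )
    n1 = len(df)
    df = df.dropna(subset=["mass", "year", "latitude", "longitude"])
    n_nonnum = n1 - len(df)

    ok = (
        df["year"].between(*YEAR_RANGE)
        & df["latitude"].between(-90, 90)
        & df["longitude"].between(-180, 180)
    )
    n_range = int((~ok).sum())
    df = df[ok]
    df = df.assign(year=df["year"].astype(int),
                   species_id=df["species_id"].astype(str))

    log.append({"step": "validate", "n_in": n0, "n_out": len(df),
                "dropped_missing": n_missing, "dropped_bad_sex": n_badsex,
                "dropped_nonnumeric": n_nonnum, "dropped_out_of_range": n_range})
    return df


def read_records(path, dialect: str | None = None,
                 column_map: dict | None = None) -> RecordTable:
    """Read individual records from a delimited file or spreadsheet.

    Parameters
    ----------
    path : path-like
        CSV (UTF-8, header row) or XLSX file. XLSX reads the first worksheet.
    dialect : {"csv", "xlsx"}, optional
        Inferred from the file suffix when omitted.
    column_map : dict, optional
        Maps input header names to the canonical field names; merged over
        :data:`DEFAULT_COLUMN_MAP`. Canonical names are always accepted.

    Returns
    -------
    RecordTable
        All parseable rows; rows with missing or invalid fields are dropped
        and counted in ``filter_log``.
    """
    path = Path(path)
    if not path.exists():
        raise RecordTableError(f"input file not found: {path}")
    dialect = dialect or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    try:
        if dialect == "xlsx":
            raw = pd.read_excel(path, sheet_name=0)
        else:
            raw = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise RecordTableError(f"could not read {path}: {exc}") from exc

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = raw.rename(columns={k: v for k, v in cmap.items() if k in raw.columns})
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise RecordTableError(
            f"{path}: could not locate columns {missing}; "
            f"pass column_map to identify them")

    log: list = []
    df = _validate(raw[RECORD_COLUMNS], log)
    return RecordTable(df, source=str(path), filter_log=log)


def read_species_meta_csv(path) -> dict[str, tuple[str, str]]:
    """Read a ``species_id,class,habitat`` CSV into a classification mapping."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        return {
            str(r[cols["species_id"]]): (str(r[cols["class"]]).lower(),
                                         str(r[cols["habitat"]]).lower())
            for _, r in df.iterrows()
        }
    except KeyError as exc:
        raise RecordTableError(
            f"{path}: species metadata needs columns species_id,class,habitat") from exc


def derive_species_meta(records: RecordTable,
                        class_habitat: dict[str, tuple[str, str]]
                        ) -> dict[str, SpeciesMeta]:
    """Compute per-species record counts and year spans, joined to class/habitat.

    ``class_habitat`` maps every species id in ``records`` to a
    ``(taxo_class, habitat)`` pair; a species missing from the mapping is a
    fatal error naming the offenders.
    """
    absent = [s for s in records.species if s not in class_habitat]
    if absent:
        raise RecordTableError(
            f"species missing from class/habitat mapping: {absent}")
    out: dict[str, SpeciesMeta] = {}
    grp = records.df.groupby("species_id")["year"]
    counts = grp.count()
    first, last = grp.min(), grp.max()
    for sp in records.species:
        cls, hab = class_habitat[sp]
        out[sp] = SpeciesMeta(species_id=sp, taxo_class=cls, habitat=hab,
                              n_records=int(counts[sp]),
                              first_year=int(first[sp]), last_year=int(last[sp]))
    return out


def species_meta_frame(meta: dict[str, SpeciesMeta]) -> pd.DataFrame:
    """Species metadata as a DataFrame indexed by species_id."""
    rows = [
        {"species_id": m.species_id, "taxo_class": m.taxo_class,
         "habitat": m.habitat, "n_records": m.n_records,
         "first_year": m.first_year, "last_year": m.last_year,
         "series_length": m.series_length}
        for m in meta.values()
    ]
    return pd.DataFrame(rows).set_index("species_id")
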