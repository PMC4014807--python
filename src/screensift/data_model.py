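"""Screen tables: CSV ingestion, derived-table provenance, TSV export.

The unit of analysis is a :class:`ScreenTable`: one well-level record per
(plate, well) carrying the well's role (sample or a named control such as
"STX16" or "GFP"), the targeted gene, an optional RNAi reagent identifier,
and 1-100 numeric data columns (raw or normalized readouts). Tables are
either *raw* (loaded from a CSV) or *derived* (produced from a parent table
by a logged operation), so every analysis step leaves an auditable trail.
"""

from __future__ import annotations

import datetime as _dt
import json
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, LimitError, SchemaError
from .geometry import GEOMETRY_384, PlateGeometry

#: Mandatory CSV columns, in schema order, mapped to internal names.
MANDATORY_COLUMNS = {
    "plate number": "plate",
    "well": "well",
    "well type": "well_type",
    "gene symbol": "gene_symbol",
    "entrez gene id": "entrez_id",
}
OPTIONAL_COLUMNS = {"reagent id": "reagent_id"}
#: Internal schema column order; everything else in a table is a data column.
SCHEMA_COLUMNS = ["plate", "well", "well_type", "gene_symbol", "entrez_id", "reagent_id"]
#: Display headers used on export (inverse of the maps above).
DISPLAY_HEADERS = {
    "plate": "Plate number",
    "well": "Well",
    "well_type": "Well type",
    "gene_symbol": "Gene symbol",
    "entrez_id": "Entrez Gene ID",
    "reagent_id": "Reagent ID",
}
#: Role label of non-control wells.
SAMPLE = "sample"
MAX_DATA_COLUMNS = 100


@dataclass
class LoadReport:
    """Bookkeeping from CSV ingestion: what was read and what was suspect."""

    n_records: int = 0
    unknown_well_types: dict[str, int] = field(default_factory=dict)
    non_numeric_cells: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{self.n_records} records"]
        if self.unknown_well_types:
            parts.append(f"undeclared well types: {self.unknown_well_types}")
        if self.non_numeric_cells:
            parts.append(f"non-numeric cells: {self.non_numeric_cells}")
        return "; ".join(parts)


@dataclass
class ProjectMeta:
    name: str
    description: str = ""
    image_path: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("project name must be non-empty")


@dataclass
class ScreenMeta:
    name: str
    description: str = ""
    library: str = ""
    species: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("screen name must be non-empty")


@dataclass
class ScreenTable:
    """Well-level records for one screen plus provenance metadata.

    ``records`` uses the internal schema columns of :data:`SCHEMA_COLUMNS`
    followed by ``data_columns``. ``nature`` is ``"raw"`` for tables loaded
    from file and ``"derived"`` for tables produced by an operation, in
    which case ``parent_table_id`` and ``derivation_log`` record how.
    """

    records: pd.DataFrame
    data_columns: list[str]
    name: str = "table"
    table_id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])
    screen_id: str | None = None
    project_id: str | None = None
    source_filename: str | None = None
    created: str = field(
        default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds")
    )
    nature: str = "raw"
    parent_table_id: str | None = None
    derivation_log: list[str] = field(default_factory=list)
    geometry: PlateGeometry = GEOMETRY_384
    control_types: tuple[str, ...] = ()
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.nature not in ("raw", "derived"):
            raise ValueError(f"nature must be raw or derived, got {self.nature!r}")
        if self.nature == "raw" and (self.parent_table_id or self.derivation_log):
            raise IntegrityError("a raw table cannot have a parent or derivation log")
        if self.nature == "derived" and self.parent_table_id is None:
            raise IntegrityError("a derived table must name its parent")
        if not 1 <= len(self.data_columns) <= MAX_DATA_COLUMNS:
            raise LimitError(
                f"tables carry 1-{MAX_DATA_COLUMNS} data columns, "
                f"got {len(self.data_columns)}"
            )

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def plates(self) -> list[int]:
        return sorted(self.records["plate"].unique().tolist())

    def wells_of_type(self, well_type: str) -> pd.DataFrame:
        return self.records[self.records["well_type"] == well_type]

    def sample_wells(self) -> pd.DataFrame:
        return self.records[self.records["well_type"] == SAMPLE]

    def values_of_type(self, well_type: str, column: str) -> np.ndarray:
        """Non-missing values of one data column restricted to one well role."""
        v = self.wells_of_type(well_type)[column].to_numpy(dtype=float)
        return v[~np.isnan(v)]

    def plate_matrix(self, column: str, plate: int) -> np.ndarray:
        """One plate's data column as a (n_rows, n_cols) array, NaN = missing."""
        if column not in self.data_columns:
            raise KeyError(f"no data column {column!r}")
        mat = np.full((self.geometry.n_rows, self.geometry.n_cols), np.nan)
        sub = self.records[self.records["plate"] == plate]
        for well, value in zip(sub["well"], sub[column]):
            i, j = self.geometry.parse_well(well)
            mat[i, j] = value
        return mat

    # -- derivation ----------------------------------------------------------

    def derive(self, new_records: pd.DataFrame, log_entry: str, name: str | None = None) -> "ScreenTable":
        return derive_table(self, new_records, log_entry, name=name)

    def with_column(self, column: str, values, log_entry: str) -> "ScreenTable":
        """Derive a child table that appends (or replaces) one data column."""
        rec = self.records.copy()
        rec[column] = np.asarray(values, dtype=float)
        child = derive_table(self, rec, log_entry)
        if column not in child.data_columns:
            child.data_columns.append(column)
        return child


def _normalize_header(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def load_screen_csv(
    path: str | Path,
    geometry: PlateGeometry = GEOMETRY_384,
    control_types: tuple[str, ...] | list[str] = (),
    sep: str = ",",
    name: str | None = None,
) -> ScreenTable:
    """Load a raw screen table from a delimited text file.

    The file must carry the mandatory header columns ``Plate number, Well,
    Well type, Gene symbol, Entrez Gene ID`` (case-insensitive); an optional
    ``Reagent ID`` column is kept for multi-reagent analysis, and every other
    column is treated as a numeric data column (at most 100). Well types
    other than ``sample`` or a declared control are kept but flagged in the
    table's :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    header_map: dict[str, str] = {}
    for col in df.columns:
        key = _normalize_header(col)
        if key in MANDATORY_COLUMNS:
            header_map[col] = MANDATORY_COLUMNS[key]
        elif key in OPTIONAL_COLUMNS:
            header_map[col] = OPTIONAL_COLUMNS[key]
    missing = set(MANDATORY_COLUMNS.values()) - set(header_map.values())
    if missing:
        pretty = ", ".join(sorted(DISPLAY_HEADERS[c] for c in missing))
        raise SchemaError(f"missing mandatory column(s): {pretty}")
    df = df.rename(columns=header_map)

    data_cols = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if len(data_cols) > MAX_DATA_COLUMNS:
        raise LimitError(
            f"up to {MAX_DATA_COLUMNS} data columns are supported, "
            f"file has {len(data_cols)}"
        )
    if not data_cols:
        raise SchemaError("file has no data columns")
    if len(set(data_cols)) != len(data_cols):
        raise SchemaError("duplicate data column names")

    report = LoadReport()
    # schema columns
    try:
        df["plate"] = pd.to_numeric(df["plate"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-integer plate number: {exc}") from None
    if (df["plate"] < 1).any():
        raise SchemaError("plate numbers must be >= 1")
    df["well"] = [geometry.normalize_well(w) for w in df["well"]]
    dup = df.duplicated(subset=["plate", "well"])
    if dup.any():
        first = df.loc[dup, ["plate", "well"]].iloc[0]
        raise IntegrityError(
            f"duplicate (plate, well) record: plate {first['plate']} well {first['well']}"
        )
    df["well_type"] = df["well_type"].astype(str).str.strip()
    declared = {SAMPLE, *control_types}
    for wt, n in df["well_type"].value_counts().items():
        if wt not in declared:
            report.unknown_well_types[wt] = int(n)
    df["entrez_id"] = pd.to_numeric(df["entrez_id"], errors="coerce").astype("Int64")
    if "reagent_id" not in df.columns:
        df["reagent_id"] = pd.NA
    df["reagent_id"] = df["reagent_id"].replace("", pd.NA)

    for col in data_cols:
        raw = df[col].replace("", np.nan)
        num = pd.to_numeric(raw, errors="coerce")
        bad = int((num.isna() & raw.notna()).sum())
        if bad:
            report.non_numeric_cells[col] = bad
        df[col] = num.astype(float)

    report.n_records = len(df)
    records = df[SCHEMA_COLUMNS + data_cols].reset_index(drop=True)
    return ScreenTable(
        records=records,
        data_columns=list(data_cols),
        name=name or path.stem,
        source_filename=path.name,
        nature="raw",
        geometry=geometry,
        control_types=tuple(control_types),
        load_report=report,
    )


def derive_table(
    parent: ScreenTable,
    new_records: pd.DataFrame,
    log_entry: str,
    name: str | None = None,
) -> ScreenTable:
    """Create a derived child table with provenance recorded.

    The child's derivation log is the parent's log plus ``log_entry``
    (append-only); an empty entry is refused because every derivation must
    be attributable.
    """
    if not log_entry or not str(log_entry).strip():
        raise ValueError("derivation log entry must be non-empty")
    data_cols = [c for c in new_records.columns if c not in SCHEMA_COLUMNS]
    return ScreenTable(
        records=new_records.reset_index(drop=True),
        data_columns=data_cols,
        name=name or f"{parent.name}+",
        screen_id=parent.screen_id,
        project_id=parent.project_id,
        source_filename=parent.source_filename,
        nature="derived",
        parent_table_id=parent.table_id,
        derivation_log=[*parent.derivation_log, str(log_entry)],
        geometry=parent.geometry,
        control_types=parent.control_types,
    )


def export_table(
    table: ScreenTable, path: str | Path, float_fmt: str = "%.6g", sep: str = "\t"
) -> Path:
    """Write a table as tab-delimited text, schema columns first.

    The output round-trips through :func:`load_screen_csv` with
    ``sep="\\t"`` up to the float formatting precision. Pass ``sep=","``
    for a CSV suitable as a fresh upload.
    """
    path = Path(path)
    df = table.records.copy()
    cols = [c for c in SCHEMA_COLUMNS if c in df.columns] + table.data_columns
    df = df[cols].rename(columns=DISPLAY_HEADERS)
    df.to_csv(path, sep=sep, index=False, float_format=float_fmt)
    return path


def load_table_tsv(path: str | Path, **kwargs) -> ScreenTable:
    """Load a tab-delimited table previously written by :func:`export_table`."""
    return load_screen_csv(path, sep="\t", **kwargs)


class Project:
    """A collection of screens and tables with undo/redo over derivations.

    Persistence is a plain directory: one TSV per table plus a JSON metadata
    file describing the project, its screens, and every table's provenance
    (nature, parent, derivation log). Derivation chains form a forest:
    deleting a table removes exactly that table.
    """

    def __init__(self, meta: ProjectMeta):
        self.meta = meta
        self.screens: dict[str, ScreenMeta] = {}
        self.tables: dict[str, ScreenTable] = {}
        self._undo: list[str] = []  # table ids of derivations, in order
        self._redo: list[ScreenTable] = []

    def add_screen(self, meta: ScreenMeta) -> str:
        screen_id = f"S{len(self.screens) + 1}"
        self.screens[screen_id] = meta
        return screen_id

    def add_table(self, table: ScreenTable, screen_id: str | None = None) -> ScreenTable:
        if table.table_id in self.tables:
            raise IntegrityError(f"table id {table.table_id} already registered")
        if screen_id is not None:
            table.screen_id = screen_id
        table.project_id = self.meta.name
        self.tables[table.table_id] = table
        return table

    def derive(self, parent: ScreenTable, new_records: pd.DataFrame, log_entry: str, name: str | None = None) -> ScreenTable:
        if parent.table_id not in self.tables:
            raise IntegrityError("parent table is not registered in this project")
        child = derive_table(parent, new_records, log_entry, name=name)
        self.add_table(child, screen_id=parent.screen_id)
        self._undo.append(child.table_id)
        self._redo.clear()
        return child

    def register_derived(self, child: ScreenTable) -> ScreenTable:
        """Register an externally derived child of a project table."""
        if child.parent_table_id not in self.tables:
            raise IntegrityError("parent table is not registered in this project")
        self.add_table(child, screen_id=self.tables[child.parent_table_id].screen_id)
        self._undo.append(child.table_id)
        self._redo.clear()
        return child

    def delete_table(self, table_id: str) -> None:
        self.tables.pop(table_id)
        self._undo = [t for t in self._undo if t != table_id]

    def undo(self) -> ScreenTable | None:
        """Drop the most recent derivation; returns the now-visible parent."""
        if not self._undo:
            return None
        child = self.tables.pop(self._undo.pop())
        self._redo.append(child)
        return self.tables.get(child.parent_table_id)

    def redo(self) -> ScreenTable | None:
        if not self._redo:
            return None
        child = self._redo.pop()
        self.add_table(child)
        self._undo.append(child.table_id)
        return child

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "project": vars(self.meta),
            "screens": {sid: vars(m) for sid, m in self.screens.items()},
            "tables": {},
            "undo": self._undo,
        }
        for tid, t in self.tables.items():
            export_table(t, directory / f"{tid}.tsv")
            meta["tables"][tid] = {
                "name": t.name,
                "screen_id": t.screen_id,
                "source_filename": t.source_filename,
                "created": t.created,
                "nature": t.nature,
                "parent_table_id": t.parent_table_id,
                "derivation_log": t.derivation_log,
                "control_types": list(t.control_types),
                "geometry": [t.geometry.n_rows, t.geometry.n_cols],
            }
        (directory / "project.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Project":
        directory = Path(directory)
        meta = json.loads((directory / "project.json").read_text())
        proj = cls(ProjectMeta(**meta["project"]))
        proj.screens = {sid: ScreenMeta(**m) for sid, m in meta["screens"].items()}
        for tid, info in meta["tables"].items():
            geom = PlateGeometry(*info["geometry"])
            t = load_table_tsv(
                directory / f"{tid}.tsv",
                geometry=geom,
                control_types=tuple(info["control_types"]),
                name=info["name"],
            )
            t.table_id = tid
            t.screen_id = info["screen_id"]
            t.source_filename = info["source_filename"]
            t.created = info["created"]
            if info["nature"] == "derived":
                t.nature = "derived"
                t.parent_table_id = info["parent_table_id"]
                t.derivation_log = list(info["derivation_log"])
            proj.tables[tid] = t
            t.project_id = proj.meta.name
        proj._undo = [t for t in meta.get("undo", []) if t in proj.tables]
        return proj
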