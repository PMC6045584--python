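"""Data model and file I/O for chemosensitivity screens.

All tabular formats are plain CSV/TSV (delimiter chosen by file
extension). The long-format read schema is::

    cell_line, replicate, plate_id, well, luminescence

and the plate-layout schema is::

    plate_id, well, role, compound_id, conc_nM

with ``role`` one of ``compound``, ``dmso``, ``positive``, ``empty``.
Wells use 384-well coordinates ``A1``..``P24`` (16 rows x 24 columns)
and are stored internally as 0-based ``(row, column)`` pairs.

Score matrices are written with cell lines as rows (first column header
``cell_line``) and drugs as columns; missing values are empty cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

ROLES = ("compound", "dmso", "positive", "empty")

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


class ScreenIOError(ValueError):
    """Base class for screen file/validation errors."""


class SchemaError(ScreenIOError):
    """A required column is missing or a value violates the schema."""


class GeometryError(ScreenIOError):
    """A well coordinate falls outside the 16x24 plate."""


class DuplicateWellError(ScreenIOError):
    """The same (plate, well) appears more than once in a replicate."""


def parse_well(label: str) -> tuple[int, int]:
    """Parse a well label like ``"B12"`` into 0-based (row, column).

    Raises :class:`GeometryError` for anything outside A1..P24.
    """
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise GeometryError(f"malformed well label {label!r}")
    row = ROW_LETTERS.find(m.group(1).upper())
    col = int(m.group(2)) - 1
    if row < 0 or not (0 <= col < N_COLS):
        raise GeometryError(
            f"well {label!r} outside 384-well geometry (A1..P{N_COLS})"
        )
    return row, col


def format_well(row: int, col: int) -> str:
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise GeometryError(f"(row={row}, col={col}) outside 384-well geometry")
    return f"{ROW_LETTERS[row]}{col + 1}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundEntry:
    compound_id: str
    target_annotation: str
    dose_series: tuple[float, ...]

    def __post_init__(self) -> None:
        doses = tuple(float(c) for c in self.dose_series)
        if any(c <= 0 for c in doses):
            raise SchemaError(
                f"compound {self.compound_id}: concentrations must be > 0"
            )
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise SchemaError(
                f"compound {self.compound_id}: dose series must be strictly increasing"
            )
        object.__setattr__(self, "dose_series", doses)


@dataclass(frozen=True)
class CompoundLibrary:
    """The screened small-molecule library: one dose series per compound."""

    entries: tuple[CompoundEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        ids = [e.compound_id for e in entries]
        if len(set(ids)) != len(ids):
            raise SchemaError("compound_ids must be unique in a library")
        object.__setattr__(self, "entries", entries)

    @property
    def compound_ids(self) -> list[str]:
        return [e.compound_id for e in self.entries]

    def get(self, compound_id: str) -> CompoundEntry:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e
        raise KeyError(compound_id)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.compound_ids

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WellAssignment:
    role: str
    compound_id: str | None = None
    conc_nM: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown well role {self.role!r}; expected one of {ROLES}")
        if self.role == "compound":
            if not self.compound_id or self.conc_nM is None:
                raise SchemaError("compound wells need compound_id and conc_nM")
            if not self.conc_nM > 0:
                raise SchemaError("compound well concentration must be > 0")


@dataclass(frozen=True)
class PlateLayout:
    """Role map for one 384-well plate."""

    plate_id: str
    wells: Mapping[tuple[int, int], WellAssignment]

    def __post_init__(self) -> None:
        wells = dict(self.wells)
        for (r, c) in wells:
            if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
                raise GeometryError(
                    f"plate {self.plate_id}: well (row={r}, col={c}) outside geometry"
                )
        if not any(w.role == "dmso" for w in wells.values()):
            raise SchemaError(
                f"plate {self.plate_id}: at least one DMSO control well required"
            )
        object.__setattr__(self, "wells", wells)

    def wells_with_role(self, role: str) -> list[tuple[int, int]]:
        return [coord for coord, w in self.wells.items() if w.role == role]


@dataclass(frozen=True)
class WellMeasurement:
    plate_id: str
    well: tuple[int, int]
    luminescence: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.luminescence) or self.luminescence < 0:
            raise SchemaError(
                f"plate {self.plate_id} well {format_well(*self.well)}: "
                f"luminescence must be finite and >= 0"
            )


@dataclass(frozen=True)
class Replicate:
    """One replicate screen of a cell line: measurements plus their layouts."""

    index: int
    measurements: tuple[WellMeasurement, ...]
    layouts: Mapping[str, PlateLayout]

    def __post_init__(self) -> None:
        seen: set[tuple[str, tuple[int, int]]] = set()
        for m in self.measurements:
            key = (m.plate_id, m.well)
            if key in seen:
                raise DuplicateWellError(
                    f"replicate {self.index}: duplicate measurement for plate "
                    f"{m.plate_id} well {format_well(*m.well)}"
                )
            seen.add(key)
            if m.plate_id not in self.layouts:
                raise SchemaError(
                    f"replicate {self.index}: no layout for plate {m.plate_id}"
                )
        object.__setattr__(self, "measurements", tuple(self.measurements))
        object.__setattr__(self, "layouts", dict(self.layouts))


@dataclass(frozen=True)
class ScreenDataset:
    """All replicate screens of one cell line against one compound library."""

    cell_line_id: str
    replicates: tuple[Replicate, ...]
    library: CompoundLibrary

    def __post_init__(self) -> None:
        reps = tuple(self.replicates)
        if not reps:
            raise SchemaError(f"{self.cell_line_id}: at least one replicate required")
        for rep in reps:
            for layout in rep.layouts.values():
                for w in layout.wells.values():
                    if w.role == "compound" and w.compound_id not in self.library:
                        raise SchemaError(
                            f"{self.cell_line_id}: compound {w.compound_id!r} in "
                            f"layout {layout.plate_id} missing from library"
                        )
        object.__setattr__(self, "replicates", reps)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class CellLineAnnotation:
    cell_line_id: str
    histotype: str
    genotype_flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype_flags", dict(self.genotype_flags))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=index)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_layouts(path: str | Path) -> dict[str, PlateLayout]:
    """Read plate layouts from a long-format CSV/TSV."""
    df = _read_table(path)
    _require_columns(df, ["plate_id", "well", "role"], "layout file")
    layouts: dict[str, PlateLayout] = {}
    for plate_id, grp in df.groupby("plate_id", sort=True):
        wells: dict[tuple[int, int], WellAssignment] = {}
        for _, row in grp.iterrows():
            coord = parse_well(row["well"])
            if coord in wells:
                raise DuplicateWellError(
                    f"layout for plate {plate_id}: duplicate well {row['well']}"
                )
            role = str(row["role"]).strip()
            compound = str(row.get("compound_id", "")).strip() or None
            conc_raw = str(row.get("conc_nM", "")).strip()
            conc = float(conc_raw) if conc_raw else None
            wells[coord] = WellAssignment(role=role, compound_id=compound, conc_nM=conc)
        layouts[str(plate_id)] = PlateLayout(plate_id=str(plate_id), wells=wells)
    return layouts


def write_layouts(layouts: Mapping[str, PlateLayout], path: str | Path) -> None:
    rows = []
    for layout in layouts.values():
        for coord in sorted(layout.wells):
            w = layout.wells[coord]
            rows.append(
                {
                    "plate_id": layout.plate_id,
                    "well": format_well(*coord),
                    "role": w.role,
                    "compound_id": w.compound_id or "",
                    "conc_nM": "" if w.conc_nM is None else repr(float(w.conc_nM)),
                }
            )
    _write_table(pd.DataFrame(rows), path)


def read_library(path: str | Path) -> CompoundLibrary:
    """Read a compound library from long format (one row per compound x dose)."""
    df = _read_table(path)
    _require_columns(df, ["compound_id", "conc_nM"], "library file")
    entries = []
    for cid, grp in df.groupby("compound_id", sort=True):
        target = ""
        if "target_annotation" in grp.columns:
            target = str(grp["target_annotation"].iloc[0])
        doses = sorted(float(c) for c in grp["conc_nM"])
        entries.append(CompoundEntry(str(cid), target, tuple(doses)))
    return CompoundLibrary(tuple(entries))


def write_library(library: CompoundLibrary, path: str | Path) -> None:
    rows = [
        {
            "compound_id": e.compound_id,
            "target_annotation": e.target_annotation,
            "conc_nM": repr(float(c)),
        }
        for e in library.entries
        for c in e.dose_series
    ]
    _write_table(pd.DataFrame(rows), path)


def library_from_layouts(layouts: Mapping[str, PlateLayout]) -> CompoundLibrary:
    """Infer the compound library from the doses present in the layouts."""
    doses: dict[str, set[float]] = {}
    for layout in layouts.values():
        for w in layout.wells.values():
            if w.role == "compound":
                doses.setdefault(w.compound_id, set()).add(float(w.conc_nM))
    entries = tuple(
        CompoundEntry(cid, "", tuple(sorted(ds))) for cid, ds in sorted(doses.items())
    )
    return CompoundLibrary(entries)


def read_screen_datasets(
    path: str | Path,
    layout_path: str | Path,
    library_path: str | Path | None = None,
) -> dict[str, ScreenDataset]:
    """Read plate measurements for any number of cell lines.

    Parsing is independent of row order; measurements are grouped by
    (cell_line, replicate) and validated against the layouts.
    """
    layouts = read_layouts(layout_path)
    library = (
        read_library(library_path) if library_path else library_from_layouts(layouts)
    )
    df = _read_table(path)
    _require_columns(
        df, ["cell_line", "replicate", "plate_id", "well", "luminescence"],
        "plate-read file",
    )
    datasets: dict[str, ScreenDataset] = {}
    for cell_line, cl_grp in df.groupby("cell_line", sort=True):
        reps = []
        for rep_idx, rep_grp in sorted(
            cl_grp.groupby("replicate"), key=lambda kv: int(kv[0])
        ):
            measurements = []
            plate_ids = set()
            for _, row in rep_grp.iterrows():
                coord = parse_well(row["well"])
                try:
                    lum = float(row["luminescence"])
                except ValueError as exc:
                    raise SchemaError(
                        f"non-numeric luminescence {row['luminescence']!r}"
                    ) from exc
                pid = str(row["plate_id"])
                plate_ids.add(pid)
                measurements.append(WellMeasurement(pid, coord, lum))
            rep_layouts = {}
            for pid in plate_ids:
                if pid not in layouts:
                    raise SchemaError(f"no layout for plate {pid}")
                rep_layouts[pid] = layouts[pid]
            measurements.sort(key=lambda m: (m.plate_id, m.well))
            reps.append(
                Replicate(int(rep_idx), tuple(measurements), rep_layouts)
            )
        datasets[str(cell_line)] = ScreenDataset(
            cell_line_id=str(cell_line), replicates=tuple(reps), library=library
        )
    return datasets


def read_plate_measurements(
    path: str | Path,
    layout_path: str | Path,
    library_path: str | Path | None = None,
) -> ScreenDataset:
    """Read a single cell line's replicate screens from a long-format file.

    The file must contain exactly one cell line; use
    :func:`read_screen_datasets` for multi-line files.
    """
    datasets = read_screen_datasets(path, layout_path, library_path)
    if len(datasets) != 1:
        raise SchemaError(
            f"expected exactly one cell line in {path}, found {sorted(datasets)}"
        )
    return next(iter(datasets.values()))


def write_screen_datasets(
    datasets: Mapping[str, ScreenDataset], path: str | Path
) -> None:
    rows = []
    for ds in datasets.values():
        for rep in ds.replicates:
            for m in rep.measurements:
                rows.append(
                    {
                        "cell_line": ds.cell_line_id,
                        "replicate": rep.index,
                        "plate_id": m.plate_id,
                        "well": format_well(*m.well),
                        "luminescence": repr(float(m.luminescence)),
                    }
                )
    _write_table(pd.DataFrame(rows), path)


def read_annotations(path: str | Path) -> list[CellLineAnnotation]:
    """Read cell-line annotations; every non-id, non-histotype column is a marker."""
    df = _read_table(path)
    _require_columns(df, ["cell_line", "histotype"], "annotation file")
    if df["cell_line"].duplicated().any():
        dupes = df.loc[df["cell_line"].duplicated(), "cell_line"].tolist()
        raise SchemaError(f"duplicate cell_line ids in annotations: {dupes}")
    markers = [c for c in df.columns if c not in ("cell_line", "histotype")]
    return [
        CellLineAnnotation(
            cell_line_id=str(row["cell_line"]),
            histotype=str(row["histotype"]),
            genotype_flags={m: str(row[m]) for m in markers},
        )
        for _, row in df.iterrows()
    ]


def write_annotations(annotations: Sequence[CellLineAnnotation], path: str | Path) -> None:
    markers = sorted({m for a in annotations for m in a.genotype_flags})
    rows = [
        {
            "cell_line": a.cell_line_id,
            "histotype": a.histotype,
            **{m: a.genotype_flags.get(m, "") for m in markers},
        }
        for a in annotations
    ]
    _write_table(pd.DataFrame(rows), path)


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a cell line x drug score matrix (missing values as empty cells).

    Round-trips through :func:`read_score_matrix` to full float precision.
    """
    if scores.index.has_duplicates or scores.columns.has_duplicates:
        raise SchemaError("score matrix index labels must be unique")
    out = scores.copy()
    out.index.name = "cell_line"
    # repr() keeps full double precision through the text round-trip
    out = out.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    _write_table(out, path, index=True)


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    _require_columns(df, ["cell_line"], "score matrix")
    df = df.set_index("cell_line")
    df.index.name = "cell_line"

    def _parse(v: str) -> float:
        v = v.strip()
        if v == "":
            return np.nan
        try:
            return float(v)
        except ValueError as exc:
            raise SchemaError(f"non-numeric score value {v!r}") from exc

    return df.map(_parse).astype(float)
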