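"""Read, validate and write segmented-cell tables.

The pipeline starts downstream of image analysis: a multiplex
immunofluorescence workflow (staining, multispectral imaging, tissue/cell
segmentation, per-marker thresholding) has already produced one row per
segmented cell with its position, tissue compartment (tumor vs stroma) and
a boolean positivity call for each marker in the staining panel.  This
module defines the in-memory data model every other module consumes and the
delimited-text dialect used on disk.

File dialect
------------
A cell table is UTF-8 delimited text (comma or tab, auto-detected), one
header row, preceded by ``#``-prefixed metadata lines declaring the patient,
lesion, marker panel, coordinate units and the imaged regions of interest
(ROIs, one 20x field each)::

    # spatialtme-cell-table: v1
    # patient_id: P01
    # lesion_type: primary
    # lesion_id: P01-PRI
    # panel: CD8,Foxp3,CD68,CD163,PD-L1,Ki67
    # units: um
    # roi: roi_id=R1 x_min=0 y_min=0 x_max=1000 y_max=1000 area_mm2=1.0
    cell_id,roi_id,x_um,y_um,compartment,CD8_pos,Foxp3_pos,...

Coordinates are Cartesian micrometres with a per-ROI origin at the ROI
bounding-box lower-left corner, y increasing upward.  Marker columns are
named ``<marker>_pos`` with values in {0, 1}.  Unrecognized extra columns
are preserved on round trip.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CellTableFormatError, CellTableValidationError, SpatialTMEError

#: The 12-marker panel of the reference immune-profiling study.  Arbitrary
#: extra markers are accepted everywhere; this list is only a convenience.
PANEL_MARKERS = [
    "CD8", "Foxp3", "CD68", "CD163", "CD20", "CD11c",
    "CD66b", "CD56", "PD-L1", "IFN-g", "Ki67", "VEGFR-2",
]

COMPARTMENTS = ("tumor", "stroma")
LESION_TYPES = ("primary", "metastasis")

_MANDATORY_COLUMNS = ["cell_id", "roi_id", "x_um", "y_um", "compartment"]
_UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "mm": 1000.0}


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: position (µm), compartment, marker positivity."""

    cell_id: str
    roi_id: str
    x: float
    y: float
    compartment: str
    markers: Mapping[str, bool]


@dataclass(frozen=True)
class ROI:
    """One imaged 20x field: bounding rectangle (µm) and analyzed tissue area."""

    roi_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    area_mm2: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class SampleMap:
    """All segmented cells and ROI geometry of one lesion of one patient.

    ``cells`` is a DataFrame with columns ``cell_id, roi_id, x, y,
    compartment`` plus one boolean column per panel marker (named exactly as
    in ``panel``) and any extra pass-through columns.
    """

    patient_id: str
    lesion_type: str
    lesion_id: str
    panel: list[str]
    rois: list[ROI]
    cells: pd.DataFrame
    scale_um_per_unit: float = 1.0
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise CellTableValidationError(
                f"lesion_type must be one of {LESION_TYPES}, got {self.lesion_type!r}"
            )
        if len(set(self.panel)) != len(self.panel):
            raise CellTableValidationError("panel contains duplicate marker names")
        if self.scale_um_per_unit != 1.0:
            raise CellTableValidationError(
                "coordinates must be in µm after load (scale_um_per_unit == 1.0)"
            )
        roi_ids = [r.roi_id for r in self.rois]
        if len(set(roi_ids)) != len(roi_ids):
            raise CellTableValidationError("duplicate roi_id in ROI list")
        for r in self.rois:
            if not (r.area_mm2 > 0):
                raise CellTableValidationError(
                    f"ROI {r.roi_id!r} has non-positive area {r.area_mm2}"
                )
            if not (r.x_max > r.x_min and r.y_max > r.y_min):
                raise CellTableValidationError(
                    f"ROI {r.roi_id!r} has an empty bounding rectangle"
                )
        df = self.cells
        needed = ["cell_id", "roi_id", "x", "y", "compartment", *self.panel]
        for col in needed:
            if col not in df.columns:
                raise CellTableFormatError(f"cells frame lacks column {col!r}")
        if len(df) == 0:
            return
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise CellTableValidationError(f"duplicate cell_id {dup!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise CellTableValidationError(
                f"non-finite coordinate in row {bad} (cell_id "
                f"{df['cell_id'].iloc[bad]!r})"
            )
        bad_comp = ~df["compartment"].isin(COMPARTMENTS)
        if bad_comp.any():
            i = int(np.where(bad_comp.to_numpy())[0][0])
            raise CellTableValidationError(
                f"unknown compartment {df['compartment'].iloc[i]!r} in row {i}"
            )
        roi_index = {r.roi_id: r for r in self.rois}
        unknown = ~df["roi_id"].isin(roi_index)
        if unknown.any():
            i = int(np.where(unknown.to_numpy())[0][0])
            raise CellTableValidationError(
                f"cell {df['cell_id'].iloc[i]!r} references undeclared ROI "
                f"{df['roi_id'].iloc[i]!r}"
            )
        for roi_id, grp in df.groupby("roi_id", sort=False):
            r = roi_index[roi_id]
            x = grp["x"].to_numpy(dtype=float)
            y = grp["y"].to_numpy(dtype=float)
            out = (x < r.x_min) | (x > r.x_max) | (y < r.y_min) | (y > r.y_max)
            if out.any():
                cid = grp["cell_id"].to_numpy()[out][0]
                raise CellTableValidationError(
                    f"cell {cid!r} lies outside the bounding rectangle of ROI "
                    f"{roi_id!r}"
                )

    # -- convenience --------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area_mm2(self) -> float:
        return float(sum(r.area_mm2 for r in self.rois))

    def roi(self, roi_id: str) -> ROI:
        for r in self.rois:
            if r.roi_id == roi_id:
                return r
        raise KeyError(roi_id)

    def iter_cells(self) -> Iterator[CellRecord]:
        """Yield cells one at a time as :class:`CellRecord` objects."""
        df = self.cells
        cols = ["cell_id", "roi_id", "x", "y", "compartment", *self.panel]
        for vals in zip(*(df[c] for c in cols)):
            cell_id, roi_id, x, y, comp = vals[:5]
            yield CellRecord(
                cell_id=cell_id,
                roi_id=roi_id,
                x=float(x),
                y=float(y),
                compartment=comp,
                markers=dict(zip(self.panel, map(bool, vals[5:]))),
            )

    def marker_positive_count(self, marker: str) -> int:
        if marker not in self.panel:
            raise KeyError(marker)
        return int(self.cells[marker].sum())


@dataclass
class Cohort:
    """A collection of lesions plus per-patient clinical grouping variables.

    ``clinical`` is a DataFrame indexed by ``patient_id`` with columns
    ``n_liver_metastases`` (integer >= 1) and ``max_metastasis_diameter_cm``
    (positive real); it may be None when no subgroup analysis is wanted.
    """

    samples: list[SampleMap]
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.clinical is not None:
            need = {"n_liver_metastases", "max_metastasis_diameter_cm"}
            missing = need - set(self.clinical.columns)
            if missing:
                raise CellTableFormatError(
                    f"clinical table lacks column(s) {sorted(missing)}"
                )

    def lesions(self, lesion_type: str | None = None) -> list[SampleMap]:
        if lesion_type is None:
            return list(self.samples)
        return [s for s in self.samples if s.lesion_type == lesion_type]

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_ROI_RE = re.compile(
    r"roi_id=(?P<roi_id>\S+)\s+x_min=(?P<x_min>\S+)\s+y_min=(?P<y_min>\S+)\s+"
    r"x_max=(?P<x_max>\S+)\s+y_max=(?P<y_max>\S+)\s+area_mm2=(?P<area_mm2>\S+)"
)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cell_table(path: str | Path, panel_spec: Sequence[str] | None = None) -> SampleMap:
    """Load one lesion's cell table.

    Parameters
    ----------
    path:
        Delimited text file in the dialect described in the module docstring.
    panel_spec:
        Markers that must be present.  When None, the panel declared in the
        file's metadata is used.  A declared-but-absent marker column is a
        format error; positivity is never silently assumed negative.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rois: list[ROI] = []
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                content = line[1:].strip()
                if content.startswith("roi:"):
                    m = _ROI_RE.search(content[4:].strip())
                    if not m:
                        raise CellTableFormatError(
                            f"{path.name}: malformed ROI metadata line: {content!r}"
                        )
                    rois.append(
                        ROI(
                            roi_id=m["roi_id"],
                            x_min=float(m["x_min"]),
                            y_min=float(m["y_min"]),
                            x_max=float(m["x_max"]),
                            y_max=float(m["y_max"]),
                            area_mm2=float(m["area_mm2"]),
                        )
                    )
                elif ":" in content:
                    key, _, value = content.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    for key in ("patient_id", "lesion_type", "lesion_id", "panel"):
        if key not in meta:
            raise CellTableFormatError(f"{path.name}: missing metadata line '# {key}: ...'")
    if not rois:
        raise CellTableFormatError(f"{path.name}: no '# roi:' metadata lines")
    if not body_lines:
        raise CellTableFormatError(f"{path.name}: no header row")

    unit = meta.get("units", "um")
    if unit not in _UNIT_TO_UM:
        raise CellTableFormatError(f"{path.name}: unknown coordinate unit {unit!r}")
    scale = _UNIT_TO_UM[unit]

    declared_panel = [m.strip() for m in meta["panel"].split(",") if m.strip()]
    panel = list(panel_spec) if panel_spec is not None else declared_panel

    delim = _sniff_delimiter(body_lines[0])
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep=delim, dtype=str)

    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CellTableFormatError(f"{path.name}: missing mandatory column {col!r}")
    marker_cols = {m: f"{m}_pos" for m in panel}
    for m, col in marker_cols.items():
        if col not in df.columns:
            raise CellTableFormatError(f"{path.name}: missing marker column {col!r}")

    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].astype(str),
            "roi_id": df["roi_id"].astype(str),
        }
    )
    for axis in ("x", "y"):
        raw = df[f"{axis}_um"]
        vals = np.empty(len(raw), dtype=float)
        # python float() is correctly rounded, so repr-written coordinates
        # round-trip bit-exactly (pd.to_numeric is not guaranteed to)
        for i, v in enumerate(raw):
            try:
                vals[i] = float(v)
            except (TypeError, ValueError):
                vals[i] = np.nan
            if not np.isfinite(vals[i]):
                raise CellTableValidationError(
                    f"{path.name}: non-numeric coordinate {v!r} in data row "
                    f"{i + 1} (column {axis}_um)"
                )
        out[axis] = vals * scale
    out["compartment"] = df["compartment"].astype(str)
    for m, col in marker_cols.items():
        vals = df[col]
        ok = vals.isin(["0", "1"])
        if not ok.all():
            i = int(np.where(~ok.to_numpy())[0][0])
            raise CellTableValidationError(
                f"{path.name}: marker column {col!r} has non-binary value "
                f"{vals.iloc[i]!r} in data row {i + 1}"
            )
        out[m] = vals.astype(int).astype(bool)

    known = set(_MANDATORY_COLUMNS) | set(marker_cols.values())
    extra = [c for c in df.columns if c not in known]
    for c in extra:
        out[c] = df[c]

    return SampleMap(
        patient_id=meta["patient_id"],
        lesion_type=meta["lesion_type"],
        lesion_id=meta["lesion_id"],
        panel=panel,
        rois=rois,
        cells=out,
        extra_columns=extra,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt_float(v: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(v))


def write_cell_table(sample: SampleMap, path: str | Path) -> Path:
    """Write ``sample`` so that :func:`read_cell_table` reproduces it exactly."""
    sample.validate()
    path = Path(path)
    lines: list[str] = []
    lines.append("# spatialtme-cell-table: v1\n")
    lines.append(f"# patient_id: {sample.patient_id}\n")
    lines.append(f"# lesion_type: {sample.lesion_type}\n")
    lines.append(f"# lesion_id: {sample.lesion_id}\n")
    lines.append(f"# panel: {','.join(sample.panel)}\n")
    lines.append("# units: um\n")
    for r in sample.rois:
        lines.append(
            "# roi: "
            f"roi_id={r.roi_id} x_min={_fmt_float(r.x_min)} y_min={_fmt_float(r.y_min)} "
            f"x_max={_fmt_float(r.x_max)} y_max={_fmt_float(r.y_max)} "
            f"area_mm2={_fmt_float(r.area_mm2)}\n"
        )
    header = (
        ["cell_id", "roi_id", "x_um", "y_um", "compartment"]
        + [f"{m}_pos" for m in sample.panel]
        + sample.extra_columns
    )
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    df = sample.cells
    cols = ["cell_id", "roi_id", "x", "y", "compartment", *sample.panel, *sample.extra_columns]
    n_markers = len(sample.panel)
    for vals in zip(*(df[c] for c in cols)):
        cell_id, roi_id, x, y, comp = vals[:5]
        rec = [cell_id, roi_id, _fmt_float(x), _fmt_float(y), comp]
        rec += ["1" if v else "0" for v in vals[5 : 5 + n_markers]]
        rec += list(vals[5 + n_markers :])
        writer.writerow(rec)
    path.write_text("".join(lines) + buf.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# lesion merging
# ---------------------------------------------------------------------------

def merge_lesions(samples: Sequence[SampleMap], lesion_id: str | None = None) -> SampleMap:
    """Concatenate several lesions of the same patient into one sample.

    Supports patients with more than one metastatic lesion when the analysis
    wants a single per-patient metastasis value.  ROI and cell identifiers
    are prefixed with their source lesion_id so they stay unique; total
    analyzed area is the sum over inputs.  A single input is returned
    unchanged.
    """
    if not samples:
        raise SpatialTMEError("merge_lesions needs at least one sample")
    if len(samples) == 1:
        return samples[0]
    first = samples[0]
    for s in samples[1:]:
        if s.patient_id != first.patient_id:
            raise SpatialTMEError("cannot merge lesions from different patients")
        if s.lesion_type != first.lesion_type:
            raise SpatialTMEError(
                "cannot merge lesions of different types "
                f"({first.lesion_type!r} vs {s.lesion_type!r})"
            )
        if s.panel != first.panel:
            raise SpatialTMEError("cannot merge lesions with different panels")
    new_rois: list[ROI] = []
    frames: list[pd.DataFrame] = []
    for s in samples:
        prefix = f"{s.lesion_id}/"
        for r in s.rois:
            new_rois.append(replace(r, roi_id=prefix + r.roi_id))
        df = s.cells.copy()
        df["roi_id"] = prefix + df["roi_id"].astype(str)
        df["cell_id"] = prefix + df["cell_id"].astype(str)
        frames.append(df)
    merged_id = lesion_id or "+".join(s.lesion_id for s in samples)
    extra = first.extra_columns
    cells = pd.concat(frames, ignore_index=True) if frames else first.cells
    return SampleMap(
        patient_id=first.patient_id,
        lesion_type=first.lesion_type,
        lesion_id=merged_id,
        panel=list(first.panel),
        rois=new_rois,
        cells=cells,
        extra_columns=list(extra),
    )


# ---------------------------------------------------------------------------
# cohort-level I/O
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read per-patient clinical grouping variables keyed by patient_id."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim)
    for col in ("patient_id", "n_liver_metastases", "max_metastasis_diameter_cm"):
        if col not in df.columns:
            raise CellTableFormatError(f"{path.name}: missing column {col!r}")
    df = df.set_index(df["patient_id"].astype(str)).drop(columns=["patient_id"])
    if (df["n_liver_metastases"] < 1).any():
        raise CellTableValidationError("n_liver_metastases must be >= 1")
    if (df["max_metastasis_diameter_cm"] <= 0).any():
        raise CellTableValidationError("max_metastasis_diameter_cm must be positive")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = clinical.copy()
    out.insert(0, "patient_id", out.index.astype(str))
    out.to_csv(path, index=False)
    return path


def read_cohort(directory: str | Path, panel_spec: Sequence[str] | None = None) -> Cohort:
    """Load every ``*.cells.csv`` in a directory plus optional clinical.csv."""
    directory = Path(directory)
    files = sorted(directory.glob("*.cells.csv"))
    if not files:
        raise CellTableFormatError(f"no *.cells.csv files in {directory}")
    samples = [read_cell_table(f, panel_spec) for f in files]
    clin_path = directory / "clinical.csv"
    clinical = read_clinical_table(clin_path) if clin_path.exists() else None
    return Cohort(samples=samples, clinical=clinical)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in cohort.samples:
        name = f"{s.patient_id}_{s.lesion_type}_{s.lesion_id}".replace("/", "-")
        write_cell_table(s, directory / f"{name}.cells.csv")
    if cohort.clinical is not None:
        write_clinical_table(cohort.clinical, directory / "clinical.csv")
    return directory
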