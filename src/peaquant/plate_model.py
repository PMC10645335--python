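"""Domain types, plate-table and panel-config I/O, and layout validation.

A multiplex PEA run is organised in plates.  Each well carries one qPCR Ct
value per assay plus the Ct of an internal extension control, and has a role:
patient sample, one of four calibrator levels (High / Middle / Low / Blank)
run in triplicate, one of two QC pools, or a negative control.  Everything
downstream (normalization, standard curves, validation metrics) consumes the
:class:`PlateTable` built here.
"""

from __future__ import annotations

import configparser
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger("peaquant")

# Canonical well-role vocabulary.  Case-insensitive on read, lower-case on write.
ROLE_SAMPLE = "sample"
ROLE_CAL_HIGH = "calibrator_high"
ROLE_CAL_MIDDLE = "calibrator_middle"
ROLE_CAL_LOW = "calibrator_low"
ROLE_CAL_BLANK = "calibrator_blank"
ROLE_QC1 = "qc1"
ROLE_QC2 = "qc2"
ROLE_NEG_CTRL = "negative_control"

ROLES = (
    ROLE_SAMPLE,
    ROLE_CAL_HIGH,
    ROLE_CAL_MIDDLE,
    ROLE_CAL_LOW,
    ROLE_CAL_BLANK,
    ROLE_QC1,
    ROLE_QC2,
    ROLE_NEG_CTRL,
)

CALIBRATOR_ROLES = (ROLE_CAL_HIGH, ROLE_CAL_MIDDLE, ROLE_CAL_LOW, ROLE_CAL_BLANK)

#: Missing-Ct sentinel in plate-table files.
NA_TOKEN = "NA"

#: Significant digits used when writing result tables (round-trip lossless).
_WRITE_SIGFIGS = 12


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """Input violates a structural invariant."""


class ConfigurationError(ValueError):
    """Panel configuration is incomplete or inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayDefinition:
    """One assay of the panel.

    Parameters
    ----------
    assay_id:
        Short unique assay name (e.g. ``"IL6"``).
    unit:
        Reporting unit, typically ``"pg/mL"`` or ``"ng/L"``.
    predilution_factor:
        Sample predilution applied before the assay; reported concentrations
        are multiplied by this factor to return to the neat-sample scale.
        The panel modelled here prediluted all samples ten-fold.
    correction_factor:
        Log2-scale offset applied in NPX normalization (vendor-supplied;
        0 leaves NPX relative with blank background near zero).
    reassigned:
        True for assays whose standard-curve concentrations were rescaled to
        agree with a clinically validated reference method.
    """

    assay_id: str
    unit: str = "pg/mL"
    predilution_factor: float = 10.0
    correction_factor: float = 0.0
    reassigned: bool = False

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ValidationError("assay_id must be non-empty")
        if not (self.predilution_factor > 0):
            raise ValidationError(
                f"predilution_factor must be > 0, got {self.predilution_factor}"
            )


@dataclass(frozen=True)
class PanelConfig:
    """A named panel: an ordered collection of assay definitions."""

    panel_name: str
    assays: tuple[AssayDefinition, ...]
    calibrator_levels: tuple[str, ...] = CALIBRATOR_ROLES

    def __post_init__(self) -> None:
        if len(self.assays) < 1:
            raise ValidationError("panel must define at least one assay")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate assay_id in panel: {ids}")
        if len(self.calibrator_levels) != 4:
            raise ValidationError("exactly four calibrator levels required")

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(a.assay_id for a in self.assays)

    def assay(self, assay_id: str) -> AssayDefinition:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)


@dataclass
class WellRecord:
    """One physical well: role, extension-control Ct, and per-assay Ct.

    Missing Ct values are stored as ``math.nan``.
    """

    plate_id: str
    well_id: str
    role: str
    sample_id: str
    ext_ctrl_ct: float
    ct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for well {self.plate_id}/{self.well_id}"
            )
        if not math.isfinite(self.ext_ctrl_ct):
            raise ValidationError(
                f"ext_ctrl_ct must be finite for well {self.plate_id}/{self.well_id}"
            )


@dataclass
class PlateTable:
    """All wells of one or more plates, plus the panel they were run on."""

    panel: PanelConfig
    wells: list[WellRecord]

    def plates(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.plate_id, None)
        return list(seen)

    def wells_of(self, plate_id: str, role: str | None = None) -> list[WellRecord]:
        out = [w for w in self.wells if w.plate_id == plate_id]
        if role is not None:
            out = [w for w in out if w.role == role]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-per-well / wide-per-assay DataFrame mirroring the CSV dialect."""
        rows = []
        for w in self.wells:
            row = {
                "plate_id": w.plate_id,
                "well_id": w.well_id,
                "role": w.role,
                "sample_id": w.sample_id,
                "ext_ctrl_ct": w.ext_ctrl_ct,
            }
            for aid in self.panel.assay_ids:
                row[f"ct_{aid}"] = w.ct.get(aid, math.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NPXMatrix:
    """Normalized Protein eXpression values, one per (well, assay).

    ``values`` is a long DataFrame with columns
    ``plate_id, well_id, sample_id, role, assay_id, dct, ddct, npx``;
    ``dct`` and ``ddct`` are the normalization intermediates kept for
    provenance.  NPX is on a log2 scale: a larger number means more protein.
    """

    values: pd.DataFrame

    REQUIRED = ("plate_id", "well_id", "sample_id", "role", "assay_id", "dct", "ddct", "npx")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.values.columns]
        if missing:
            raise ValidationError(f"NPXMatrix missing columns: {missing}")

    def wide(self, roles: Sequence[str] = (ROLE_SAMPLE,)) -> pd.DataFrame:
        """Pivot to (plate, well, sample) x assay NPX matrix for given roles."""
        sub = self.values[self.values["role"].isin(roles)]
        return sub.pivot_table(
            index=["plate_id", "well_id", "sample_id"],
            columns="assay_id",
            values="npx",
            aggfunc="first",
        )


# ---------------------------------------------------------------------------
# Panel-config I/O (flat INI, one section per assay)
# ---------------------------------------------------------------------------


def read_panel_config(path: str | Path) -> PanelConfig:
    """Read a panel configuration file.

    Format: INI with a ``[panel]`` section (key ``name``) and one section per
    assay carrying ``unit``, ``predilution_factor``, ``correction_factor`` and
    optional ``reassigned``.  Unknown keys are ignored so the same file can
    carry simulation-truth extensions.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FormatError(f"cannot read panel config {path}")
    if "panel" not in cp:
        raise FormatError(f"panel config {path} lacks a [panel] section")
    name = cp["panel"].get("name", "panel")
    assays = []
    for section in cp.sections():
        if section == "panel":
            continue
        s = cp[section]
        assays.append(
            AssayDefinition(
                assay_id=section,
                unit=s.get("unit", "pg/mL"),
                predilution_factor=s.getfloat("predilution_factor", 10.0),
                correction_factor=s.getfloat("correction_factor", 0.0),
                reassigned=s.getboolean("reassigned", False),
            )
        )
    return PanelConfig(panel_name=name, assays=tuple(assays))


def write_panel_config(panel: PanelConfig, path: str | Path) -> None:
    cp = configparser.ConfigParser()
    cp["panel"] = {"name": panel.panel_name}
    for a in panel.assays:
        cp[a.assay_id] = {
            "unit": a.unit,
            "predilution_factor": repr(a.predilution_factor),
            "correction_factor": repr(a.correction_factor),
            "reassigned": str(a.reassigned).lower(),
        }
    with open(path, "w") as fh:
        cp.write(fh)


# ---------------------------------------------------------------------------
# Plate-table I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ("plate_id", "well_id", "role", "sample_id", "ext_ctrl_ct")


def read_plate_table(path: str | Path, panel: PanelConfig) -> PlateTable:
    """Read a plate-table CSV.

    Dialect: UTF-8 comma-separated, one row per (plate, well); columns
    ``plate_id, well_id, role, sample_id, ext_ctrl_ct`` plus one ``ct_<assay>``
    column per panel assay.  Missing Ct is the literal ``NA``.  Unparseable Ct
    cells are recorded as missing with a logged warning; structural problems
    raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate table {path} lacks required columns: {missing}")
    ct_cols = {aid: f"ct_{aid}" for aid in panel.assay_ids}
    absent = [c for c in ct_cols.values() if c not in df.columns]
    if absent:
        raise FormatError(f"plate table {path} lacks assay columns: {absent}")

    wells: list[WellRecord] = []
    for i, row in df.iterrows():
        role = str(row["role"]).strip().lower()
        if role not in ROLES:
            raise ValidationError(
                f"unknown role label {row['role']!r} in row {i + 2} of {path}"
            )
        try:
            ext = float(row["ext_ctrl_ct"])
        except ValueError as exc:
            raise FormatError(
                f"unparseable ext_ctrl_ct {row['ext_ctrl_ct']!r} in row {i + 2}"
            ) from exc
        ct: dict[str, float] = {}
        for aid, col in ct_cols.items():
            cell = str(row[col]).strip()
            if cell == NA_TOKEN or cell == "":
                ct[aid] = math.nan
                continue
            try:
                ct[aid] = float(cell)
            except ValueError:
                log.warning(
                    "unparseable Ct %r (row %d, assay %s) recorded as missing",
                    cell, i + 2, aid,
                )
                ct[aid] = math.nan
        wells.append(
            WellRecord(
                plate_id=str(row["plate_id"]),
                well_id=str(row["well_id"]),
                role=role,
                sample_id=str(row["sample_id"]),
                ext_ctrl_ct=ext,
                ct=ct,
            )
        )
    return PlateTable(panel=panel, wells=wells)


def _fmt(x: object) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return NA_TOKEN
        return f"{x:.{_WRITE_SIGFIGS}g}"
    return str(x)


def _fmt_exact(x: object) -> str:
    # shortest round-trip representation: read-back is bit-identical
    if isinstance(x, float):
        return NA_TOKEN if math.isnan(x) else repr(x)
    return str(x)


def write_plate_table(table: PlateTable, path: str | Path) -> None:
    """Write a PlateTable in the documented CSV dialect.

    Floats use the shortest round-trip representation, so reading the file
    back reproduces every Ct bit-identically.
    """
    df = table.to_frame()
    df_out = df.copy()
    for c in df_out.columns:
        df_out[c] = df_out[c].map(_fmt_exact)
    df_out.to_csv(path, index=False)


def write_results(obj, path: str | Path) -> None:
    """Write any documented pipeline result to CSV.

    Accepts a DataFrame, an :class:`NPXMatrix`, a :class:`PlateTable`, a list
    of dataclass-like records with a ``to_row`` method, or a list of dicts.
    Column order is deterministic and floats are written with 12 significant
    digits so a read-back reproduces the values.
    """
    if isinstance(obj, PlateTable):
        write_plate_table(obj, path)
        return
    if isinstance(obj, NPXMatrix):
        df = obj.values
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif isinstance(obj, Iterable):
        rows = []
        for item in obj:
            if hasattr(item, "to_row"):
                rows.append(item.to_row())
            elif isinstance(item, Mapping):
                rows.append(dict(item))
            else:
                raise TypeError(f"cannot serialize {type(item).__name__}")
        df = pd.DataFrame(rows)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    out = df.copy()
    for c in out.columns:
        out[c] = out[c].map(_fmt)
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Layout validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayoutFinding:
    """One layout problem: plate, role, expected and observed well counts."""

    plate_id: str
    role: str
    expected: int
    observed: int

    def __str__(self) -> str:
        return (
            f"plate {self.plate_id}: role {self.role} expected "
            f"{self.expected} wells, found {self.observed}"
        )

    def to_row(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "role": self.role,
            "expected": self.expected,
            "observed": self.observed,
        }


def validate_layout(table: PlateTable, strict: bool = False) -> list[LayoutFinding]:
    """Check calibrator / QC layout of every plate.

    Every plate must carry all four calibrator levels; with ``strict=True``
    each level must be present in exact triplicate, and QC pools — when
    present at all — must also be triplicate.  Returns findings rather than
    raising; an empty list means the layout conforms.  Pure function: the
    result does not depend on well order.
    """
    findings: list[LayoutFinding] = []
    for plate in sorted(table.plates()):
        counts = {r: 0 for r in ROLES}
        for w in table.wells_of(plate):
            counts[w.role] += 1
        for role in CALIBRATOR_ROLES:
            n = counts[role]
            if strict:
                if n != 3:
                    findings.append(LayoutFinding(plate, role, 3, n))
            elif n < 1:
                findings.append(LayoutFinding(plate, role, 1, n))
        if strict:
            for role in (ROLE_QC1, ROLE_QC2):
                n = counts[role]
                if n not in (0, 3):
                    findings.append(LayoutFinding(plate, role, 3, n))
    return findings
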