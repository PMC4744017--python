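"""TSV readers/writers for fixation and AOI tables.

Both dialects are plain UTF-8 TSV with a header row and '.' decimal
separators.  Floats are written with Python's shortest-repr formatting so a
write/read round-trip reproduces every field bit-for-bit.

fixations.tsv columns:
    participant_id, phase, trial_index, face_id, race, start_position,
    was_studied, ordinal, x_deg, y_deg, duration_ms, judgment, rt_ms
(judgment/rt_ms are empty on study rows and repeated on every row of a test
trial).  Rows are sorted by participant, phase, trial, ordinal.

aois.tsv columns:
    face_id, race, aoi_name, x0_deg, y0_deg, x1_deg, y1_deg
with the reserved aoi_name "frame" carrying the image frame rectangle.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .model import (
    AOI_NAMES,
    Dataset,
    FaceLayout,
    FixationRecord,
    Rect,
    Response,
    Trial,
    ValidationError,
)

FIXATION_COLUMNS = [
    "participant_id",
    "phase",
    "trial_index",
    "face_id",
    "race",
    "start_position",
    "was_studied",
    "ordinal",
    "x_deg",
    "y_deg",
    "duration_ms",
    "judgment",
    "rt_ms",
]

AOI_COLUMNS = ["face_id", "race", "aoi_name", "x0_deg", "y0_deg", "x1_deg", "y1_deg"]


class SchemaError(ValidationError):
    """A required column is missing from an input table."""


class ParseError(ValidationError):
    """A cell could not be parsed; the message carries the 1-based line number."""


def _require_columns(header: list[str], required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _parse_float(value: str, column: str, line_no: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric {column} value {value!r}"
        ) from None


def _parse_int(value: str, column: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-integer {column} value {value!r}"
        ) from None


def read_fixations(path: str | Path, layouts: list[FaceLayout]) -> Dataset:
    """Read a fixation report and assemble a validated :class:`Dataset`."""
    path = Path(path)
    known_faces = {lay.face_id for lay in layouts}
    rows_by_trial: dict[tuple, list[dict]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no header)")
        _require_columns(list(reader.fieldnames), FIXATION_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            if row["face_id"] not in known_faces:
                raise ValidationError(
                    f"line {line_no}: unknown face_id {row['face_id']!r}"
                )
            row = dict(row)
            row["_line"] = line_no
            key = (row["participant_id"], row["phase"], int(row["trial_index"]))
            rows_by_trial.setdefault(key, []).append(row)

    trials = []
    for (pid, phase, trial_index), rows in sorted(rows_by_trial.items()):
        rows.sort(key=lambda r: int(r["ordinal"]))
        fixations = []
        for r in rows:
            line_no = r["_line"]
            fixations.append(
                FixationRecord(
                    participant_id=pid,
                    phase=phase,
                    trial_index=trial_index,
                    face_id=r["face_id"],
                    race=r["race"],
                    start_position=r["start_position"],
                    ordinal=_parse_int(r["ordinal"], "ordinal", line_no),
                    x=_parse_float(r["x_deg"], "x_deg", line_no),
                    y=_parse_float(r["y_deg"], "y_deg", line_no),
                    duration=_parse_float(r["duration_ms"], "duration_ms", line_no),
                )
            )
        first = rows[0]
        response = None
        if phase == "test":
            response = Response(
                judgment=first["judgment"],
                rt=_parse_float(first["rt_ms"], "rt_ms", first["_line"]),
            )
        trials.append(
            Trial(
                participant_id=pid,
                phase=phase,
                trial_index=trial_index,
                face_id=first["face_id"],
                race=first["race"],
                start_position=first["start_position"],
                was_studied=first["was_studied"] == "true",
                fixations=tuple(fixations),
                response=response,
            )
        )
    return Dataset(layouts=list(layouts), trials=trials)


def write_fixations(ds: Dataset, path: str | Path) -> Path:
    """Write a dataset as fixations.tsv; inverse of :func:`read_fixations`."""
    path = Path(path)
    trials = sorted(
        ds.trials, key=lambda t: (t.participant_id, t.phase, t.trial_index)
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FIXATION_COLUMNS)
        for t in trials:
            judgment = t.response.judgment if t.response else ""
            rt = repr(t.response.rt) if t.response else ""
            for f in t.fixations:
                writer.writerow(
                    [
                        t.participant_id,
                        t.phase,
                        t.trial_index,
                        t.face_id,
                        t.race,
                        t.start_position,
                        "true" if t.was_studied else "false",
                        f.ordinal,
                        repr(f.x),
                        repr(f.y),
                        repr(f.duration),
                        judgment,
                        rt,
                    ]
                )
    return path


def read_aois(path: str | Path) -> list[FaceLayout]:
    """Read an AOI table into validated :class:`FaceLayout` objects."""
    path = Path(path)
    frames: dict[str, Rect] = {}
    races: dict[str, str] = {}
    aois: dict[str, dict[str, Rect]] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no header)")
        _require_columns(list(reader.fieldnames), AOI_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            face_id = row["face_id"]
            if face_id not in aois:
                aois[face_id] = {}
                order.append(face_id)
            races[face_id] = row["race"]
            rect = Rect(
                _parse_float(row["x0_deg"], "x0_deg", line_no),
                _parse_float(row["y0_deg"], "y0_deg", line_no),
                _parse_float(row["x1_deg"], "x1_deg", line_no),
                _parse_float(row["y1_deg"], "y1_deg", line_no),
            )
            name = row["aoi_name"]
            if name == "frame":
                if face_id in frames:
                    raise ValidationError(
                        f"line {line_no}: duplicate frame for face {face_id!r}"
                    )
                frames[face_id] = rect
            else:
                if name in aois[face_id]:
                    raise ValidationError(
                        f"line {line_no}: duplicate AOI ({face_id!r}, {name!r})"
                    )
                aois[face_id][name] = rect
    layouts = []
    for face_id in order:
        if face_id not in frames:
            raise ValidationError(f"face {face_id!r} has no frame row")
        layouts.append(
            FaceLayout(
                face_id=face_id,
                race=races[face_id],
                frame=frames[face_id],
                aois=aois[face_id],
            )
        )
    return layouts


def write_aois(layouts: Iterable[FaceLayout], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(AOI_COLUMNS)
        for lay in layouts:
            rows = [("frame", lay.frame)] + [(n, lay.aois[n]) for n in AOI_NAMES]
            for name, r in rows:
                writer.writerow(
                    [lay.face_id, lay.race, name,
                     repr(r.x0), repr(r.y0), repr(r.x1), repr(r.y1)]
                )
    return path


def convert_eyelink_report(
    path: str | Path,
    out_path: str | Path,
    column_map: dict[str, str] | None = None,
) -> Path:
    """Rename the columns of an EyeLink-style fixation-report TSV.

    Data Viewer exports one row per fixation with columns such as
    ``RECORDING_SESSION_LABEL``, ``CURRENT_FIX_X`` (pixels or degrees) and
    ``CURRENT_FIX_DURATION``.  This stub only renames columns via
    ``column_map`` (export name -> fixations.tsv name); condition labels,
    degree conversion and trial metadata must already be present as columns.
    """
    column_map = column_map or {
        "RECORDING_SESSION_LABEL": "participant_id",
        "TRIAL_INDEX": "trial_index",
        "CURRENT_FIX_INDEX": "ordinal",
        "CURRENT_FIX_X": "x_deg",
        "CURRENT_FIX_Y": "y_deg",
        "CURRENT_FIX_DURATION": "duration_ms",
    }
    path, out_path = Path(path), Path(out_path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise SchemaError(f"{path}: empty file")
    header = [column_map.get(c, c) for c in rows[0]]
    with out_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows[1:])
    return out_path
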