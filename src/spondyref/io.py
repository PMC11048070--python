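"""File formats: landmark/level/subject tables and generic table round-trips.

The wide landmark schema has one row per vertebra:

    subject_id, vertebra, x_as, y_as, x_ps, y_ps, x_ai, y_ai, x_pi, y_pi

Per-level osteophyte/sclerosis flags live in a separate levels table
(subject_id, level_name, osteo_flag) so a flag is unambiguously attached to a
level, and demographics in a subjects table (subject_id, age, sex, bmi,
back_pain, position).  The reader never drops a row silently: every input row
is either accepted or produces a diagnostic naming the violated invariant.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LEVEL_NAMES, LEVEL_PAIRS, Level, Subject, VERTEBRAE, VertebraLandmarks

LANDMARK_COLUMNS = ["subject_id", "vertebra",
                    "x_as", "y_as", "x_ps", "y_ps", "x_ai", "y_ai", "x_pi", "y_pi"]
LEVELS_COLUMNS = ["subject_id", "level_name", "osteo_flag"]
SUBJECTS_COLUMNS = ["subject_id", "age", "sex", "bmi", "back_pain", "position"]


class FormatError(ValueError):
    """Malformed header or unsupported file format."""


@dataclass
class ReadResult:
    """Outcome of a landmark read: accepted subjects plus a full audit."""

    subjects: list[Subject]
    diagnostics: list[dict] = field(default_factory=list)  # rejected rows
    warnings: list[str] = field(default_factory=list)      # e.g. unpaired vertebrae
    n_rows: int = 0
    n_accepted: int = 0


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".csv", ".tsv"):
        return "csv"
    if suffix == ".json":
        return "json"
    raise FormatError(f"cannot infer format from {path!r}; pass format='csv' or 'json'")


def _row_to_vertebra(row: dict, y_down: bool) -> VertebraLandmarks:
    sgn = -1.0 if y_down else 1.0
    return VertebraLandmarks(
        label=str(row["vertebra"]),
        as_pt=(float(row["x_as"]), sgn * float(row["y_as"])),
        ps_pt=(float(row["x_ps"]), sgn * float(row["y_ps"])),
        ai_pt=(float(row["x_ai"]), sgn * float(row["y_ai"])),
        pi_pt=(float(row["x_pi"]), sgn * float(row["y_pi"])),
    )


def read_landmarks(path, format: str | None = None, *, levels_path=None,
                   subjects_path=None, y_down: bool = False) -> ReadResult:
    """Read a landmark file (wide CSV or equivalent JSON) into Subjects.

    Rows violating the corner-order invariants are rejected with a per-row
    diagnostic.  Levels are assembled only when both adjacent vertebrae are
    present; vertebrae left without any level produce a warning.  Optional
    levels/subjects tables attach osteophyte flags and demographics.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"landmark file {path} missing columns: {missing}")
        records = df.to_dict("records")
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["rows"] if isinstance(payload, dict) else payload
        records = []
        for r in rows:
            if not all(c in r for c in LANDMARK_COLUMNS):
                raise FormatError(f"landmark JSON row missing keys: {sorted(r)}")
            records.append(r)
    else:
        raise FormatError(f"unsupported format {fmt!r}")

    flags: dict[tuple[str, str], bool] = {}
    if levels_path is not None:
        lv = pd.read_csv(levels_path, float_precision="round_trip")
        missing = [c for c in LEVELS_COLUMNS if c not in lv.columns]
        if missing:
            raise FormatError(f"levels file {levels_path} missing columns: {missing}")
        for r in lv.itertuples(index=False):
            flags[(str(r.subject_id), str(r.level_name))] = bool(r.osteo_flag)

    demo: dict[str, dict] = {}
    if subjects_path is not None:
        su = pd.read_csv(subjects_path, float_precision="round_trip")
        missing = [c for c in SUBJECTS_COLUMNS if c not in su.columns]
        if missing:
            raise FormatError(f"subjects file {subjects_path} missing columns: {missing}")
        demo = {str(r["subject_id"]): r for r in su.to_dict("records")}

    result = ReadResult(subjects=[], n_rows=len(records))
    by_subject: dict[str, dict[str, VertebraLandmarks]] = {}
    order: list[str] = []
    for i, row in enumerate(records):
        sid = str(row["subject_id"])
        try:
            v = _row_to_vertebra(row, y_down)
        except (KeyError, TypeError, ValueError) as e:
            result.diagnostics.append({"row": i, "subject_id": sid,
                                       "vertebra": row.get("vertebra"),
                                       "message": f"unparseable row: {e}"})
            continue
        if v.label not in VERTEBRAE:
            result.diagnostics.append({"row": i, "subject_id": sid, "vertebra": v.label,
                                       "message": f"unknown vertebra {v.label!r}"})
            continue
        bad = v.violations()
        if bad:
            result.diagnostics.append({"row": i, "subject_id": sid, "vertebra": v.label,
                                       "message": "; ".join(bad)})
            continue
        if sid not in by_subject:
            by_subject[sid] = {}
            order.append(sid)
        if v.label in by_subject[sid]:
            result.diagnostics.append({"row": i, "subject_id": sid, "vertebra": v.label,
                                       "message": f"duplicate vertebra {v.label}"})
            continue
        by_subject[sid][v.label] = v
        result.n_accepted += 1

    for sid in order:
        verts = by_subject[sid]
        levels, used = [], set()
        for name in LEVEL_NAMES:
            sup_lbl, inf_lbl = LEVEL_PAIRS[name]
            if sup_lbl in verts and inf_lbl in verts:
                levels.append(Level(name, verts[sup_lbl], verts[inf_lbl],
                                    osteo_flag=flags.get((sid, name), False)))
                used.update((sup_lbl, inf_lbl))
        for lbl in verts:
            if lbl not in used:
                result.warnings.append(
                    f"subject {sid}: vertebra {lbl} has no adjacent partner; no level formed")
        d = demo.get(sid, {})
        bp = d.get("back_pain")
        result.subjects.append(Subject(
            subject_id=sid,
            age=float(d.get("age", np.nan)),
            sex=str(d.get("sex", "")),
            bmi=float(d.get("bmi", np.nan)),
            back_pain=None if bp is None or (isinstance(bp, float) and np.isnan(bp)) else bool(bp),
            position=str(d.get("position", "side-lying")),
            levels=levels,
        ))
    return result


# ---------------------------------------------------------------------------
# writers

def subjects_to_frames(subjects: list[Subject]) -> dict[str, pd.DataFrame]:
    """Decompose Subjects into the three flat tables of the file schema."""
    lm_rows, lvl_rows, subj_rows = [], [], []
    for s in subjects:
        verts: dict[str, VertebraLandmarks] = {}
        for lv in s.levels:
            verts[lv.sup.label] = lv.sup
            verts[lv.inf.label] = lv.inf
            lvl_rows.append({"subject_id": s.subject_id, "level_name": lv.level_name,
                             "osteo_flag": bool(lv.osteo_flag)})
        for lbl in VERTEBRAE:
            if lbl in verts:
                v = verts[lbl]
                lm_rows.append({
                    "subject_id": s.subject_id, "vertebra": lbl,
                    "x_as": v.as_pt[0], "y_as": v.as_pt[1],
                    "x_ps": v.ps_pt[0], "y_ps": v.ps_pt[1],
                    "x_ai": v.ai_pt[0], "y_ai": v.ai_pt[1],
                    "x_pi": v.pi_pt[0], "y_pi": v.pi_pt[1],
                })
        subj_rows.append({"subject_id": s.subject_id, "age": s.age, "sex": s.sex,
                          "bmi": s.bmi, "back_pain": s.back_pain, "position": s.position})
    return {
        "landmarks": pd.DataFrame(lm_rows, columns=LANDMARK_COLUMNS),
        "levels": pd.DataFrame(lvl_rows, columns=LEVELS_COLUMNS),
        "subjects": pd.DataFrame(subj_rows, columns=SUBJECTS_COLUMNS),
    }


def write_subjects(subjects: list[Subject], out_dir) -> dict[str, Path]:
    """Write landmarks.csv, levels.csv and subjects.csv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = subjects_to_frames(subjects)
    paths = {}
    for name, df in frames.items():
        p = out_dir / f"{name}.csv"
        write_table(df, p)
        paths[name] = p
    return paths


def write_table(records, path, format: str | None = None) -> None:
    """Write a table (DataFrame or list of dicts) with round-trip fidelity.

    Floats are written with repr precision, so read(write(x)) reproduces x
    bit-for-bit for CSV and JSON alike.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"columns": list(df.columns),
                       "rows": df.to_dict("records")}, fh, default=_jsonify)
    else:
        raise FormatError(f"unsupported format {fmt!r}")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_table(path, format: str | None = None) -> pd.DataFrame:
    """Inverse of write_table."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise FormatError(f"unsupported format {fmt!r}")
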