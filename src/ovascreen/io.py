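"""Reading, validating and temporally aligning cohort tables.

Controls have no diagnosis date, so before scoring they are allocated
times-to-diagnosis (tDx) by matching each control's last serum draw to the last
draw of her matched case; earlier draws follow from the control's own inter-draw
spacing.  Throughout the package tDx is in real years with larger = earlier, and
"< k years tDx" is a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import MARKERS, MARKER_COLUMNS, SerumSample, SubjectRecord
from .errors import AlignmentError, ReferentialIntegrityError, SchemaError, ValidationError

_SUBJECT_COLUMNS = ("subject_id", "group", "borderline", "stage", "matched_case_id")
_SAMPLE_COLUMNS = ("subject_id", "tdx_years") + MARKER_COLUMNS


@dataclass
class Cohort:
    """A validated cohort: subject records plus their serial serum samples."""

    subjects: list[SubjectRecord]
    samples: list[SerumSample]
    aligned: bool = False

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def samples_of(self, subject_id: str) -> list[SerumSample]:
        return [s for s in self.samples if s.subject_id == subject_id]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def cases(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group != "control"]


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def read_cohort(subjects_path, samples_path) -> Cohort:
    """Read and validate subjects.csv + samples.csv into a Cohort.

    Raises SchemaError (with row numbers) for malformed tables,
    ReferentialIntegrityError for orphan samples, and ValidationError for
    non-positive concentrations.  ``aligned`` is False if any control sample
    lacks a tdx value.
    """
    try:
        sub = pd.read_csv(subjects_path)
        smp = pd.read_csv(samples_path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise SchemaError(f"cannot read cohort tables: {e}") from e

    missing = set(_SUBJECT_COLUMNS) - set(sub.columns)
    if missing:
        raise SchemaError(f"subjects table missing columns: {sorted(missing)}")
    missing = set(_SAMPLE_COLUMNS) - set(smp.columns) - {"tdx_years"}
    if missing:
        raise SchemaError(f"samples table missing columns: {sorted(missing)}")
    if "tdx_years" not in smp.columns and "draw_time_years" not in smp.columns:
        raise SchemaError("samples table needs a tdx_years or draw_time_years column")

    subjects: list[SubjectRecord] = []
    for i, row in sub.iterrows():
        matched = row["matched_case_id"]
        if pd.isna(matched) or matched == "":
            matched = None
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    borderline=_parse_bool(row["borderline"]),
                    stage=str(row["stage"]) if not pd.isna(row["stage"]) else "none",
                    matched_case_id=matched,
                    excluded_from_training=_parse_bool(row.get("excluded_from_training", False)),
                )
            )
        except ValueError as e:
            raise SchemaError(f"subjects.csv row {i + 2}: {e}") from e

    known_ids = {s.subject_id for s in subjects}
    samples: list[SerumSample] = []
    has_tdx = "tdx_years" in smp.columns
    has_draw = "draw_time_years" in smp.columns
    for i, row in smp.iterrows():
        sid = str(row["subject_id"])
        if sid not in known_ids:
            raise ReferentialIntegrityError(
                f"samples.csv row {i + 2}: subject_id {sid!r} not in subjects table"
            )
        markers = {}
        for col, m in zip(MARKER_COLUMNS, MARKERS):
            v = row[col]
            if pd.isna(v):
                raise SchemaError(f"samples.csv row {i + 2}: missing {col}")
            v = float(v)
            if not v > 0:
                raise ValidationError(
                    f"samples.csv row {i + 2}: {col} must be > 0, got {v}"
                )
            markers[m] = v
        tdx = float(row["tdx_years"]) if has_tdx and not pd.isna(row["tdx_years"]) else None
        draw = (
            float(row["draw_time_years"])
            if has_draw and not pd.isna(row["draw_time_years"])
            else None
        )
        if tdx is None and draw is None:
            raise SchemaError(f"samples.csv row {i + 2}: neither tdx_years nor draw_time_years")
        samples.append(SerumSample(sid, tdx, markers, draw_time=draw))

    control_ids = {s.subject_id for s in subjects if s.group == "control"}
    aligned = all(s.tdx is not None for s in samples if s.subject_id in control_ids)
    if any(s.tdx is None for s in samples if s.subject_id not in control_ids):
        raise SchemaError("case samples must carry tdx_years")
    return Cohort(subjects, samples, aligned=aligned and len(samples) > 0)


def align_controls(cohort: Cohort) -> Cohort:
    """Assign control tDx by matching each control's last draw to its case's.

    An offset is added per control so that its last sample's tdx equals the
    matched case's minimum tdx; all inter-draw intervals are preserved.  Case
    samples are untouched.  Idempotent: aligning an aligned cohort is a no-op.
    """
    case_min_tdx: dict[str, float] = {}
    for s in cohort.samples:
        subj = cohort.subject(s.subject_id)
        if subj.group != "control":
            t = s.tdx
            if t is not None:
                prev = case_min_tdx.get(s.subject_id)
                case_min_tdx[s.subject_id] = t if prev is None else min(prev, t)

    failed = []
    new_samples: list[SerumSample] = []
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(cohort.samples):
        by_subject.setdefault(s.subject_id, []).append(i)

    aligned_samples: dict[int, SerumSample] = {}
    for subj in cohort.controls:
        anchor = case_min_tdx.get(subj.matched_case_id)
        if anchor is None:
            failed.append(subj.subject_id)
            continue
        idxs = by_subject.get(subj.subject_id, [])
        if not idxs:
            continue
        own = [cohort.samples[i] for i in idxs]
        if all(s.tdx is not None for s in own):
            # already on the tdx axis: shift so the latest draw (min tdx) hits anchor
            offset = anchor - min(s.tdx for s in own)
            for i, s in zip(idxs, own):
                aligned_samples[i] = replace(s, tdx=s.tdx + offset)
        elif all(s.draw_time is not None for s in own):
            last = max(s.draw_time for s in own)
            for i, s in zip(idxs, own):
                aligned_samples[i] = replace(s, tdx=anchor + (last - s.draw_time))
        else:
            raise AlignmentError(
                f"control {subj.subject_id}: samples mix tdx and draw_time conventions"
            )

    if failed:
        raise AlignmentError(
            f"controls with no matched case samples: {sorted(failed)}"
        )

    for i, s in enumerate(cohort.samples):
        new_samples.append(aligned_samples.get(i, s))
    return Cohort(cohort.subjects, new_samples, aligned=True)
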