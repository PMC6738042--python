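"""PPV-based risk classification and the simulated annual screening programme.

Every threshold on the risk score has an associated sensitivity-specificity
pair; combined with disease prevalence these give the positive predictive
value ppv = sens*prev / (sens*prev + (1-spec)*(1-prev)) — the probability that
a woman flagged at that threshold actually has cancer, the quantity a clinician
acts on.  Samples are classified severe (S), elevated (E) or intermediate (I)
when their PPV crosses 30%, 5% or 2.5% respectively, otherwise normal (N).

The simulated programme screens each subject annually at years 4, 3, 2, 1
before diagnosis, using the latest sample drawn before each year's cut-off,
and records classification trajectories and year-to-year transition counts
(river-plot data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MARKERS
from .errors import ValidationError
from .io import Cohort
from .model import LogitModel, predict_risk
from .scoring import ScoreVector

CLASSES = ("N", "I", "E", "S")
_SEVERITY = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class RiskThresholds:
    """PPV cut-offs for the severe/elevated/intermediate classes."""

    severe: float = 0.30
    elevated: float = 0.05
    intermediate: float = 0.025

    def __post_init__(self):
        if not self.severe > self.elevated > self.intermediate > 0:
            raise ValidationError(
                "PPV thresholds must satisfy severe > elevated > intermediate > 0"
            )


@dataclass
class PPVTable:
    """(probability threshold, sensitivity, specificity, ppv) rows, ascending
    by threshold, with the prevalence used."""

    frame: pd.DataFrame  # columns: threshold, sensitivity, specificity, ppv
    prevalence: float

    def ppv_at(self, p: float) -> float:
        """PPV of the largest tabulated threshold <= p; 0 below the table."""
        thr = self.frame["threshold"].to_numpy()
        idx = np.searchsorted(thr, p, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.frame["ppv"].iloc[idx])


def build_ppv_table(roc_rows, prevalence: float) -> PPVTable:
    """Convert ROC (threshold, sensitivity, specificity) rows to PPVs under a
    given disease prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValidationError(f"prevalence must be in (0, 1), got {prevalence}")
    rows = sorted(roc_rows, key=lambda r: r[0])
    recs = []
    for thr, sens, spec in rows:
        num = sens * prevalence
        den = num + (1.0 - spec) * (1.0 - prevalence)
        recs.append(
            {
                "threshold": float(thr),
                "sensitivity": float(sens),
                "specificity": float(spec),
                "ppv": float(num / den) if den > 0 else 0.0,
            }
        )
    return PPVTable(pd.DataFrame(recs), prevalence)


def classify_probability(
    p: float, ppv_table: PPVTable, thresholds: RiskThresholds | None = None
) -> str:
    """Risk class N/I/E/S for a probability: look up the PPV of the largest
    tabulated threshold <= p, then take the highest class whose PPV cut-off is
    crossed."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability must be in [0, 1], got {p}")
    if ppv_table.frame.empty:
        raise ValidationError("ppv_table is empty")
    thresholds = thresholds or RiskThresholds()
    ppv = ppv_table.ppv_at(p)
    if ppv >= thresholds.severe:
        return "S"
    if ppv >= thresholds.elevated:
        return "E"
    if ppv >= thresholds.intermediate:
        return "I"
    return "N"


@dataclass
class ScreeningTrajectory:
    subject_id: str
    group: str
    #: per screening year: (sample tdx used, probability, ppv, class) or None
    by_year: dict[int, tuple[float, float, float, str] | None]


@dataclass
class TransitionSummary:
    """Per-group class counts per year and year-to-year transition counts."""

    class_counts: pd.DataFrame  # group, year, class, count
    transitions: pd.DataFrame  # group, year_from, class_from, year_to, class_to, count
    severe_fraction: pd.DataFrame  # group, year, fraction of screened subjects class S


def simulate_screening(
    cohort: Cohort,
    scores: list[ScoreVector],
    model: LogitModel,
    ppv_table: PPVTable,
    years: tuple[int, ...] = (4, 3, 2, 1),
    thresholds: RiskThresholds | None = None,
) -> tuple[list[ScreeningTrajectory], TransitionSummary]:
    """Run the annual screening programme over an aligned, scored cohort.

    The year-y screen sees samples with tdx >= y and uses the latest one
    (smallest such tdx).  Subjects without an eligible scored sample in a year
    get a "no sample" entry.
    """
    thresholds = thresholds or RiskThresholds()
    groups = {s.subject_id: s.group for s in cohort.subjects}
    by_subject: dict[str, list[ScoreVector]] = {}
    for v in scores:
        by_subject.setdefault(v.subject_id, []).append(v)

    trajectories: list[ScreeningTrajectory] = []
    for subj in cohort.subjects:
        own = by_subject.get(subj.subject_id, [])
        by_year: dict[int, tuple[float, float, float, str] | None] = {}
        for y in years:
            eligible = [v for v in own if v.tdx >= y]
            if not eligible:
                by_year[y] = None
                continue
            v = min(eligible, key=lambda s: s.tdx)
            p = predict_risk(v, model)
            ppv = ppv_table.ppv_at(p)
            by_year[y] = (v.tdx, p, ppv, classify_probability(p, ppv_table, thresholds))
        trajectories.append(ScreeningTrajectory(subj.subject_id, subj.group, by_year))

    counts: dict[tuple[str, int, str], int] = {}
    trans: dict[tuple[str, int, str, int, str], int] = {}
    screened: dict[tuple[str, int], int] = {}
    severe: dict[tuple[str, int], int] = {}
    ordered = list(years)
    for tr in trajectories:
        for y in ordered:
            entry = tr.by_year[y]
            cls = entry[3] if entry is not None else "none"
            counts[(tr.group, y, cls)] = counts.get((tr.group, y, cls), 0) + 1
            if entry is not None:
                screened[(tr.group, y)] = screened.get((tr.group, y), 0) + 1
                if cls == "S":
                    severe[(tr.group, y)] = severe.get((tr.group, y), 0) + 1
        for y0, y1 in zip(ordered, ordered[1:]):
            e0, e1 = tr.by_year[y0], tr.by_year[y1]
            c0 = e0[3] if e0 is not None else "none"
            c1 = e1[3] if e1 is not None else "none"
            key = (tr.group, y0, c0, y1, c1)
            trans[key] = trans.get(key, 0) + 1

    class_counts = pd.DataFrame(
        [
            {"group": g, "year": y, "class": c, "count": n}
            for (g, y, c), n in sorted(counts.items())
        ],
        columns=["group", "year", "class", "count"],
    )
    transitions = pd.DataFrame(
        [
            {"group": g, "year_from": y0, "class_from": c0,
             "year_to": y1, "class_to": c1, "count": n}
            for (g, y0, c0, y1, c1), n in sorted(trans.items())
        ],
        columns=["group", "year_from", "class_from", "year_to", "class_to", "count"],
    )
    severe_fraction = pd.DataFrame(
        [
            {
                "group": g,
                "year": y,
                "fraction": severe.get((g, y), 0) / n if n else float("nan"),
                "n_screened": n,
            }
            for (g, y), n in sorted(screened.items())
        ],
        columns=["group", "year", "fraction", "n_screened"],
    )
    return trajectories, TransitionSummary(class_counts, transitions, severe_fraction)


def render_riverplot_data(summary: TransitionSummary) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for any Sankey/river renderer.

    Nodes are (group, year, class) with subject counts; edges are year-to-year
    class transitions with their counts.
    """
    nodes = summary.class_counts.rename(columns={"count": "n_subjects"}).copy()
    nodes["node"] = (
        nodes["group"] + ":" + nodes["year"].astype(str) + ":" + nodes["class"]
    )
    edges = summary.transitions.copy()
    edges["source"] = (
        edges["group"] + ":" + edges["year_from"].astype(str) + ":" + edges["class_from"]
    )
    edges["target"] = (
        edges["group"] + ":" + edges["year_to"].astype(str) + ":" + edges["class_to"]
    )
    return nodes, edges


def trajectories_frame(trajectories: list[ScreeningTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for y, entry in tr.by_year.items():
            if entry is None:
                rows.append(
                    {"subject_id": tr.subject_id, "group": tr.group, "year": y,
                     "sample_tdx": None, "probability": None, "ppv": None,
                     "class": "none"}
                )
            else:
                tdx, p, ppv, cls = entry
                rows.append(
                    {"subject_id": tr.subject_id, "group": tr.group, "year": y,
                     "sample_tdx": tdx, "probability": p, "ppv": ppv, "class": cls}
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "year", "sample_tdx", "probability", "ppv", "class"],
    )
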