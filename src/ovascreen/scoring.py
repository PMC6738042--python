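"""Baseline estimation and specificity-binned dysregulation scoring.

Each subject's pre-disease baseline per marker is the mean of the earliest up
to three samples drawn more than two years before diagnosis — the interval in
which cases behave like controls.  Every sample's absolute deviation from that
baseline (dysregulation in either direction) is converted to an ordinal score
by binning against deviation thresholds placed at fixed specificity levels of
the control deviation distribution: 80/90/95/97.5/98/99% for CA125, protein Z
and LCAT (scores 0-6) and 70/80/90/95/99/99.5/99.9% for CRP (scores 0-7),
giving the model access to CRP's wider specificity range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import MARKERS, SerumSample
from .errors import BaselineUnusableError, ValidationError
from .io import Cohort


@dataclass(frozen=True)
class BinSpec:
    """Specificity cut points for one marker; score range is 0..len(cut_points)."""

    marker: str
    cut_points: tuple[float, ...]

    def __post_init__(self):
        cps = tuple(float(c) for c in self.cut_points)
        if any(not 0.0 < c < 1.0 for c in cps):
            raise ValidationError(f"{self.marker}: cut points must lie in (0, 1)")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValidationError(f"{self.marker}: cut points must be strictly increasing")
        object.__setattr__(self, "cut_points", cps)

    @property
    def max_score(self) -> int:
        return len(self.cut_points)


#: Default bins: scores 0-6 for CA125/PROZ/LCAT, 0-7 for CRP.
DEFAULT_BINS: dict[str, BinSpec] = {
    "CA125": BinSpec("CA125", (0.80, 0.90, 0.95, 0.975, 0.98, 0.99)),
    "PROZ": BinSpec("PROZ", (0.80, 0.90, 0.95, 0.975, 0.98, 0.99)),
    "LCAT": BinSpec("LCAT", (0.80, 0.90, 0.95, 0.975, 0.98, 0.99)),
    "CRP": BinSpec("CRP", (0.70, 0.80, 0.90, 0.95, 0.99, 0.995, 0.999)),
}


@dataclass(frozen=True)
class BaselineEstimate:
    subject_id: str
    baseline: dict[str, float]
    n_used: int
    usable: bool


@dataclass(frozen=True)
class ScoreVector:
    subject_id: str
    tdx: float
    scores: dict[str, int]


@dataclass
class ThresholdTable:
    """Per marker, deviation thresholds at each specificity level (ascending)."""

    thresholds: dict[str, list[tuple[float, float]]]
    n_control_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker": m, "specificity": s, "threshold": t}
            for m, pairs in self.thresholds.items()
            for s, t in pairs
        ]
        return pd.DataFrame(rows, columns=["marker", "specificity", "threshold"])

    def to_yaml(self, path) -> None:
        payload = {
            "n_control_samples": self.n_control_samples,
            "thresholds": {
                m: [{"specificity": float(s), "threshold": float(t)} for s, t in pairs]
                for m, pairs in self.thresholds.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def estimate_baseline(
    samples_of_subject: list[SerumSample], window_tdx: float = 2.0, max_n: int = 3
) -> BaselineEstimate:
    """Per-marker mean of the up-to-``max_n`` earliest samples with tdx > window.

    "Earliest" means largest tdx (furthest before diagnosis).  If no sample
    qualifies the estimate is flagged unusable rather than raising.
    """
    if not samples_of_subject:
        raise ValidationError("estimate_baseline requires at least one sample")
    sid = samples_of_subject[0].subject_id
    eligible = [s for s in samples_of_subject if s.tdx is not None and s.tdx > window_tdx]
    if not eligible:
        return BaselineEstimate(sid, {}, 0, usable=False)
    eligible.sort(key=lambda s: -s.tdx)
    used = eligible[:max_n]
    baseline = {m: float(np.mean([s.markers[m] for s in used])) for m in MARKERS}
    return BaselineEstimate(sid, baseline, len(used), usable=True)


def compute_deviation(sample: SerumSample, baseline: BaselineEstimate) -> dict[str, float]:
    """Absolute deviation |value - baseline| per marker, in concentration units."""
    if not baseline.usable:
        raise BaselineUnusableError(baseline.subject_id)
    return {m: abs(sample.markers[m] - baseline.baseline[m]) for m in MARKERS}


def derive_thresholds(
    control_deviations: dict[str, list[float]],
    bins: dict[str, BinSpec] | None = None,
) -> ThresholdTable:
    """Place deviation thresholds at the configured specificity levels.

    For specificity s among N control deviations the threshold is the
    ceil(s*N)-th order statistic: the smallest deviation d such that the
    fraction of control deviations <= d is at least s.  Being an attained data
    value, the implied specificity guarantee is conservative.
    """
    bins = bins or DEFAULT_BINS
    out: dict[str, list[tuple[float, float]]] = {}
    n_ref = None
    for m, spec in bins.items():
        values = np.sort(np.asarray(control_deviations.get(m, []), dtype=float))
        n = len(values)
        if n == 0:
            raise ValidationError(f"no control deviations for marker {m}")
        if n < 20:
            warnings.warn(
                f"only {n} control deviations for {m}: upper quantiles are unstable",
                stacklevel=2,
            )
        n_ref = n if n_ref is None else n_ref
        out[m] = [(s, float(values[math.ceil(s * n) - 1])) for s in spec.cut_points]
    return ThresholdTable(out, n_control_samples=n_ref or 0)


def score_sample(
    deviations: dict[str, float],
    thresholds: ThresholdTable,
    bins: dict[str, BinSpec] | None = None,
) -> dict[str, int]:
    """Ordinal score per marker: how many specificity thresholds the deviation
    reaches (inclusive comparison: deviation == threshold counts as crossed)."""
    bins = bins or DEFAULT_BINS
    scores: dict[str, int] = {}
    for m, d in deviations.items():
        if m not in thresholds.thresholds:
            raise ValidationError(f"no thresholds for marker {m!r}")
        pairs = thresholds.thresholds[m]
        scores[m] = int(sum(1 for _, t in pairs if t <= d))
    return scores


def score_cohort(
    cohort: Cohort,
    bins: dict[str, BinSpec] | None = None,
    window_tdx: float = 2.0,
    max_n: int = 3,
    thresholds: ThresholdTable | None = None,
) -> tuple[list[ScoreVector], ThresholdTable, dict[str, BaselineEstimate]]:
    """Run the full scoring stage over an aligned cohort.

    Baselines are estimated per subject; thresholds (unless supplied) are
    derived from deviations of all samples of eligible controls — controls not
    flagged as later developing cancer — with usable baselines; every sample of
    every subject with a usable baseline is then scored.  Subjects without a
    usable baseline are silently excluded here and reported by callers.
    """
    if not cohort.aligned:
        raise ValidationError("cohort must be aligned before scoring")
    bins = bins or DEFAULT_BINS

    baselines: dict[str, BaselineEstimate] = {}
    for subj in cohort.subjects:
        own = cohort.samples_of(subj.subject_id)
        if own:
            baselines[subj.subject_id] = estimate_baseline(own, window_tdx, max_n)

    if thresholds is None:
        control_devs: dict[str, list[float]] = {m: [] for m in bins}
        for subj in cohort.controls:
            if subj.excluded_from_training:
                continue
            est = baselines.get(subj.subject_id)
            if est is None or not est.usable:
                continue
            for s in cohort.samples_of(subj.subject_id):
                dev = compute_deviation(s, est)
                for m in bins:
                    control_devs[m].append(dev[m])
        thresholds = derive_thresholds(control_devs, bins)

    scored: list[ScoreVector] = []
    for s in cohort.samples:
        est = baselines.get(s.subject_id)
        if est is None or not est.usable:
            continue
        dev = compute_deviation(s, est)
        scored.append(ScoreVector(s.subject_id, s.tdx, score_sample(dev, thresholds, bins)))
    return scored, thresholds, baselines


def scores_frame(scores: list[ScoreVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in scores],
            "tdx_years": [v.tdx for v in scores],
            **{
                f"score_{m.lower()}": [v.scores[m] for v in scores]
                for m in MARKERS
            },
        }
    )
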