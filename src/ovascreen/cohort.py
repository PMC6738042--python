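"""Seedable synthetic longitudinal serum cohort generator.

Emulates a nested case-control serum series: ~31 controls and ~49 epithelial
ovarian cancer cases (30 aggressive Type II, 19 Type I of which 10 borderline),
with roughly annual draws spanning up to seven years before diagnosis.  Controls
fluctuate multiplicatively about stable per-subject baselines; cases depart from
baseline — up- or down-regulated per subject and marker — only within a terminal
window (default two years) before diagnosis, ramping log-linearly to a terminal
fold-change at diagnosis.

All randomness flows from one seed; each subject draws from a deterministic
child stream, so cohorts are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Canonical marker order used throughout the package.
MARKERS = ("CA125", "PROZ", "LCAT", "CRP")

#: Lower-case CSV column names for the four markers.
MARKER_COLUMNS = tuple(m.lower() for m in MARKERS)


def _per_marker(value) -> dict[str, float]:
    """Broadcast a scalar to all four markers, or validate a mapping."""
    if isinstance(value, Mapping):
        missing = set(MARKERS) - set(value)
        if missing:
            raise ConfigError(f"per-marker mapping missing markers: {sorted(missing)}")
        return {m: float(value[m]) for m in MARKERS}
    return {m: float(value) for m in MARKERS}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Concentrations are in arbitrary assay units on a log-normal scale:
    ``baseline_location`` is the per-marker mean of log-concentration across
    subjects and ``baseline_spread`` its between-subject SD.  ``noise_cv`` is
    the within-subject coefficient of variation of repeat draws.
    ``effect_size`` is the terminal fold-change magnitude a case's expected
    level reaches at diagnosis (tDx = 0), applied upward with probability
    ``direction_prob_up`` (per subject-marker pair) and as its reciprocal
    otherwise.  Dysregulation begins ``onset_tdx`` years before diagnosis.
    """

    n_controls: int = 31
    n_type2: int = 30
    n_type1: int = 19
    n_borderline: int = 10
    followup_years: float = 7.0
    span_jitter: float = 2.0
    draw_interval_mean: float = 1.0
    draw_interval_jitter: float = 0.2
    baseline_location: dict[str, float] = field(
        default_factory=lambda: {"CA125": math.log(14.0), "PROZ": math.log(1200.0),
                                 "LCAT": math.log(5000.0), "CRP": math.log(1.5)}
    )
    baseline_spread: dict[str, float] = field(default_factory=lambda: _per_marker(0.4))
    noise_cv: dict[str, float] = field(
        default_factory=lambda: {"CA125": 0.15, "PROZ": 0.15, "LCAT": 0.15, "CRP": 0.30}
    )
    onset_tdx: float = 2.0
    effect_size: dict[str, float] = field(
        default_factory=lambda: {"CA125": 4.0, "PROZ": 2.0, "LCAT": 1.8, "CRP": 2.0}
    )
    direction_prob_up: dict[str, float] = field(
        default_factory=lambda: {"CA125": 0.9, "PROZ": 0.3, "LCAT": 0.3, "CRP": 0.8}
    )
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "baseline_location", _per_marker(self.baseline_location))
        object.__setattr__(self, "baseline_spread", _per_marker(self.baseline_spread))
        object.__setattr__(self, "noise_cv", _per_marker(self.noise_cv))
        object.__setattr__(self, "effect_size", _per_marker(self.effect_size))
        object.__setattr__(self, "direction_prob_up", _per_marker(self.direction_prob_up))
        self.validate()

    def validate(self) -> None:
        for name in ("n_controls", "n_type2", "n_type1", "n_borderline"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_borderline > self.n_type1:
            raise ConfigError(
                f"n_borderline ({self.n_borderline}) must not exceed n_type1 ({self.n_type1})"
            )
        if not self.onset_tdx > 0:
            raise ConfigError(f"onset_tdx must be > 0, got {self.onset_tdx}")
        if not self.followup_years > self.onset_tdx:
            raise ConfigError(
                f"followup_years ({self.followup_years}) must exceed onset_tdx ({self.onset_tdx})"
            )
        if self.draw_interval_mean <= 0:
            raise ConfigError(f"draw_interval_mean must be > 0, got {self.draw_interval_mean}")
        if self.draw_interval_jitter < 0:
            raise ConfigError(f"draw_interval_jitter must be >= 0, got {self.draw_interval_jitter}")
        if self.span_jitter < 0 or self.span_jitter >= self.followup_years:
            raise ConfigError(f"span_jitter must be in [0, followup_years), got {self.span_jitter}")
        for name in ("baseline_spread", "noise_cv", "effect_size"):
            for m, v in getattr(self, name).items():
                if v < 0:
                    raise ConfigError(f"{name}[{m}] must be >= 0, got {v}")
        for m, v in self.direction_prob_up.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"direction_prob_up[{m}] must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant."""

    subject_id: str
    group: str  # "control" | "type1" | "type2"
    borderline: bool = False
    stage: str = "none"  # "I" | "II" | "III" | "IV" | "none"
    matched_case_id: str | None = None
    excluded_from_training: bool = False  # controls later developing cancer

    def __post_init__(self):
        if self.group not in ("control", "type1", "type2"):
            raise ConfigError(f"group must be control/type1/type2, got {self.group!r}")
        if (self.matched_case_id is not None) != (self.group == "control"):
            raise ConfigError(
                f"subject {self.subject_id}: matched_case_id present iff group=control"
            )
        if self.borderline and self.group != "type1":
            raise ConfigError(f"subject {self.subject_id}: borderline only valid for type1")


@dataclass(frozen=True)
class SerumSample:
    """One serum draw: four marker concentrations at a time-to-diagnosis.

    ``tdx`` is in years before diagnosis (larger = earlier); for controls it is
    assigned by temporal alignment to the matched case and may be None until
    alignment.  ``draw_time`` is years since the subject's first draw, kept for
    unaligned control input.
    """

    subject_id: str
    tdx: float | None
    markers: dict[str, float]
    draw_time: float | None = None

    def __post_init__(self):
        if set(self.markers) != set(MARKERS):
            raise ConfigError(f"sample markers must be exactly {MARKERS}")
        for m, v in self.markers.items():
            if not v > 0:
                raise ConfigError(f"marker {m} concentration must be > 0, got {v}")


def _draw_schedule(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Times-to-diagnosis of one subject's draws, latest first, ascending tdx."""
    span = config.followup_years - rng.uniform(0.0, config.span_jitter)
    t = rng.uniform(0.2, 0.8)  # last draw a few months before diagnosis
    times = [t]
    while True:
        lo = max(config.draw_interval_mean - config.draw_interval_jitter, 0.05)
        hi = config.draw_interval_mean + config.draw_interval_jitter
        t = t + rng.uniform(lo, hi)
        if t > span:
            break
        times.append(t)
    return np.asarray(times)


def _simulate_levels(
    rng: np.random.Generator,
    config: CohortConfig,
    tdx: np.ndarray,
    log_baseline: dict[str, float],
    is_case: bool,
    directions: dict[str, int],
) -> list[dict[str, float]]:
    """Marker concentrations at each tdx. Noise is mean-one log-normal so the
    expected level equals the ramp exactly (continuity at onset is exact)."""
    out: list[dict[str, float]] = []
    for t in tdx:
        row = {}
        for m in MARKERS:
            mu = log_baseline[m]
            if is_case and t <= config.onset_tdx:
                frac = 1.0 - t / config.onset_tdx  # 0 at onset, 1 at diagnosis
                mu = mu + directions[m] * frac * math.log(config.effect_size[m])
            cv = config.noise_cv[m]
            sigma = math.sqrt(math.log1p(cv * cv))
            noise = rng.normal(-0.5 * sigma * sigma, sigma) if sigma > 0 else 0.0
            row[m] = math.exp(mu + noise)
        out.append(row)
    return out


def expected_case_level(config: CohortConfig, baseline: float, marker: str,
                        tdx: float, direction: int = 1) -> float:
    """Expected (noise-free) concentration of a case at a given tdx.

    Equals ``baseline`` for tdx >= onset and ramps log-linearly to
    ``baseline * effect_size**direction`` at tdx = 0.
    """
    if tdx >= config.onset_tdx:
        return baseline
    frac = 1.0 - tdx / config.onset_tdx
    return baseline * config.effect_size[marker] ** (direction * frac)


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], list[SerumSample]]:
    """Generate a synthetic cohort of subjects and serial serum samples.

    Controls are generated already aligned: each control's last draw shares the
    tdx of its matched Type II case's last draw (round-robin matching), with
    its own inter-draw spacing preserved backwards in time.
    """
    config.validate()
    n_subjects = config.n_controls + config.n_type2 + config.n_type1
    seeds = np.random.SeedSequence(config.rng_seed).spawn(n_subjects + 1)
    top = np.random.default_rng(seeds[0])

    subjects: list[SubjectRecord] = []
    samples: list[SerumSample] = []
    case_last_tdx: dict[str, float] = {}

    idx = 0
    type2_ids: list[str] = []
    specs: list[tuple[str, str, bool]] = []
    for i in range(config.n_type2):
        specs.append((f"T2-{i+1:03d}", "type2", False))
    for i in range(config.n_type1):
        specs.append((f"T1-{i+1:03d}", "type1", i < config.n_borderline))
    for i in range(config.n_controls):
        specs.append((f"C-{i+1:03d}", "control", False))

    for sid, group, borderline in specs:
        rng = np.random.default_rng(seeds[idx + 1])
        idx += 1
        log_baseline = {
            m: rng.normal(config.baseline_location[m], config.baseline_spread[m])
            for m in MARKERS
        }
        directions = {
            m: 1 if rng.random() < config.direction_prob_up[m] else -1 for m in MARKERS
        }
        tdx = _draw_schedule(rng, config)

        if group == "control":
            matched = type2_ids[len([s for s in subjects if s.group == "control"])
                                % len(type2_ids)] if type2_ids else None
            if matched is None:
                raise ConfigError("n_type2 must be > 0 when n_controls > 0 (matching)")
            # shift the schedule so the control's last draw aligns to the case's
            offset = case_last_tdx[matched] - tdx[0]
            tdx = tdx + offset
            stage = "none"
            subjects.append(SubjectRecord(sid, group, False, stage, matched))
        else:
            if group == "type2":
                stage = str(top.choice(["I", "II", "III", "IV"]))
                type2_ids.append(sid)
                case_last_tdx[sid] = float(tdx[0])
            else:
                stage = str(top.choice(["I", "II"]))
            subjects.append(SubjectRecord(sid, group, borderline, stage, None))

        levels = _simulate_levels(rng, config, tdx, log_baseline,
                                  is_case=group != "control", directions=directions)
        for t, row in zip(tdx, levels):
            samples.append(SerumSample(sid, float(t), row))

    return subjects, samples


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "borderline": [s.borderline for s in subjects],
            "stage": [s.stage for s in subjects],
            "matched_case_id": [s.matched_case_id for s in subjects],
            "excluded_from_training": [s.excluded_from_training for s in subjects],
        }
    )


def samples_frame(samples: list[SerumSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "tdx_years": [s.tdx for s in samples],
            **{
                col: [s.markers[m] for s in samples]
                for col, m in zip(MARKER_COLUMNS, MARKERS)
            },
            "draw_time_years": [s.draw_time for s in samples],
        }
    )


def write_cohort(subjects: list[SubjectRecord], samples: list[SerumSample], path) -> tuple[str, str]:
    """Write subjects.csv and samples.csv under ``path``; returns the two paths.

    UTF-8, header row, '.' decimal separator, missing values as empty fields.
    """
    import os

    os.makedirs(path, exist_ok=True)
    subjects_path = os.path.join(path, "subjects.csv")
    samples_path = os.path.join(path, "samples.csv")
    subjects_frame(subjects).to_csv(subjects_path, index=False)
    sf = samples_frame(samples)
    if sf["draw_time_years"].isna().all() and len(sf):
        sf = sf.drop(columns=["draw_time_years"])
    # repr round-trips float64 exactly; pandas' default formatter may not
    sf.to_csv(samples_path, index=False, float_format=lambda x: repr(float(x)))
    return subjects_path, samples_path
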