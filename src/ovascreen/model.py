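"""The four-marker logistic risk model.

The ordinal dysregulation scores enter as numeric covariates, one coefficient
per marker, so each odds ratio exp(beta) is the fold change in odds of cancer
per one-step increase in that marker's score.  The published coefficients are
shipped as a versioned constants file so the classification pipeline can run
without refitting; fitting on (synthetic or user) data is a separate path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import MARKERS
from .errors import FittingError, SeparationError, ValidationError
from .io import Cohort
from .scoring import DEFAULT_BINS, BinSpec, ScoreVector


@dataclass(frozen=True)
class LogitModel:
    """Fitted (or published) logit model with Wald inference."""

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float] = field(default_factory=dict)
    wald_p: dict[str, float] = field(default_factory=dict)

    @property
    def odds_ratios(self) -> dict[str, float]:
        out = {"Intercept": float(np.exp(self.intercept))}
        out.update({m: float(np.exp(c)) for m, c in self.coefficients.items()})
        return out

    def linear_predictor(self, scores: dict[str, float]) -> float:
        return self.intercept + sum(self.coefficients[m] * scores[m] for m in self.coefficients)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "std_errors": dict(self.std_errors),
            "wald_p": dict(self.wald_p),
            "odds_ratios": self.odds_ratios,
        }


def published_model() -> LogitModel:
    """Load the published coefficients from the versioned constants file."""
    text = resources.files("ovascreen").joinpath("data/published_model.yaml").read_text()
    payload = yaml.safe_load(text)
    return LogitModel(
        intercept=float(payload["intercept"]),
        coefficients={m: float(payload["coefficients"][m]) for m in MARKERS},
    )


@dataclass
class TrainingSet:
    """Design rows (one per sample) with labels and training provenance."""

    frame: pd.DataFrame  # columns: subject_id, tdx_years, label, score_<marker>...
    provenance: dict

    @property
    def n_case_rows(self) -> int:
        return int((self.frame["label"] == 1).sum())

    @property
    def n_control_rows(self) -> int:
        return int((self.frame["label"] == 0).sum())


def build_training_set(
    cohort: Cohort, scores: list[ScoreVector], tdx_window: float = 2.0
) -> TrainingSet:
    """Assemble the training design: aggressive-histotype (Type II) case samples
    within ``tdx_window`` years of diagnosis (strict inequality) versus all
    samples of eligible controls (controls flagged as later developing cancer
    are excluded)."""
    groups = {s.subject_id: s.group for s in cohort.subjects}
    excluded = {s.subject_id for s in cohort.subjects if s.excluded_from_training}
    rows = []
    for v in scores:
        g = groups.get(v.subject_id)
        if g == "type2" and v.tdx < tdx_window:
            label = 1
        elif g == "control" and v.subject_id not in excluded:
            label = 0
        else:
            continue
        rows.append(
            {
                "subject_id": v.subject_id,
                "tdx_years": v.tdx,
                "label": label,
                **{f"score_{m.lower()}": v.scores[m] for m in MARKERS},
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty or frame["label"].nunique() < 2:
        raise ValidationError(
            "training set needs both case (type2, tdx < window) and control rows"
        )
    provenance = {
        "filter": f"type2 samples with tdx < {tdx_window} vs all eligible control samples",
        "n_case_rows": int((frame["label"] == 1).sum()),
        "n_control_rows": int((frame["label"] == 0).sum()),
        "n_case_subjects": int(frame.loc[frame.label == 1, "subject_id"].nunique()),
        "n_control_subjects": int(frame.loc[frame.label == 0, "subject_id"].nunique()),
        "n_excluded_controls": len(excluded),
    }
    return TrainingSet(frame, provenance)


_SCORE_COLS = [f"score_{m.lower()}" for m in MARKERS]


def fit_logit(training: TrainingSet, tol: float = 1e-8, maxiter: int = 200) -> LogitModel:
    """Maximum-likelihood logistic regression of label on the four scores.

    Standard errors come from the observed information; Wald p-values use the
    two-sided normal reference.  Perfect separation or non-convergence raises
    rather than returning silently divergent coefficients.
    """
    frame = training.frame
    if (frame["label"] == 1).sum() < 2 or (frame["label"] == 0).sum() < 2:
        raise FittingError("need at least 2 rows per class")
    X = sm.add_constant(frame[_SCORE_COLS].astype(float), has_constant="add")
    y = frame["label"].astype(float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
        except PerfectSeparationError as e:
            raise SeparationError(f"perfect separation detected: {e}") from e
        except np.linalg.LinAlgError:
            # singular information (e.g. a constant score column): the
            # likelihood is flat along it; BFGS leaves those directions at 0
            try:
                res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=maxiter)
            except (np.linalg.LinAlgError, ValueError) as e:
                raise FittingError(f"logit fit failed: {e}") from e
        except ValueError as e:
            raise FittingError(f"logit fit failed: {e}") from e
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            raise SeparationError(f"perfect separation detected: {w.message}")
    if not res.mle_retvals.get("converged", False):
        raise FittingError(f"logit fit did not converge: {res.mle_retvals}")
    if np.any(np.abs(res.params.values) > 50):
        raise SeparationError(
            "diverging coefficients (|beta| > 50): data are (quasi-)separated"
        )
    params = res.params
    try:
        bse = res.bse
    except np.linalg.LinAlgError:
        bse = pd.Series(np.nan, index=params.index)
    coef = {m: float(params[f"score_{m.lower()}"]) for m in MARKERS}
    se = {"Intercept": float(bse["const"])}
    se.update({m: float(bse[f"score_{m.lower()}"]) for m in MARKERS})
    z = {t: (params["const"] if t == "Intercept" else coef[t]) / se[t] for t in se}
    pvals = {t: float(2 * norm.sf(abs(v))) for t, v in z.items()}
    return LogitModel(float(params["const"]), coef, se, pvals)


def predict_risk(
    scores: dict[str, float] | ScoreVector,
    model: LogitModel,
    bins: dict[str, BinSpec] | None = None,
) -> float:
    """Probability of cancer for one score vector: inverse-logit of the linear
    predictor.  Scores outside the marker's valid ordinal range are rejected."""
    bins = bins or DEFAULT_BINS
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    missing = set(model.coefficients) - set(s)
    if missing:
        raise ValidationError(f"missing scores for markers: {sorted(missing)}")
    for m, v in s.items():
        if m in bins and not 0 <= v <= bins[m].max_score:
            raise ValidationError(
                f"score {v} for {m} outside valid range 0..{bins[m].max_score}"
            )
    return float(expit(model.linear_predictor(s)))


def odds_ratio(model: LogitModel) -> dict[str, float]:
    """exp(coefficient) per term: fold change in odds per score increment."""
    return model.odds_ratios


def roc_analysis(
    probabilities, labels
) -> tuple[float, list[tuple[float, float, float]]]:
    """Empirical ROC: AUC (trapezoid / Mann-Whitney with tie averaging) and
    (threshold, sensitivity, specificity) rows over all distinct thresholds."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("roc_analysis requires both classes")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p)
    rows = [
        (float(t), float(se), float(1.0 - fp))
        for t, se, fp in zip(thr, tpr, fpr)
        if np.isfinite(t)
    ]
    rows.sort(key=lambda r: r[0])
    return auc, rows
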