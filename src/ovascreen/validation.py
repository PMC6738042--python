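"""Cross-validation of the risk model: coefficient stability and held-out ROC.

Two schemes mirror standard practice for case-control serum sets of this size:
leave-one-out by *subject* (all of a woman's samples removed together, one
refit per subject) and k-fold by *sample* (label-stratified random partition of
the training rows, default k=10).  Each scheme reports the per-term standard
deviation of coefficients across refits; the k-fold scheme additionally scores
held-out predictions by ROC within the terminal tDx strata (<1, <2, and 1-2
years before diagnosis) against all held-out controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import MARKERS
from .errors import FittingError, ValidationError
from .model import _SCORE_COLS, LogitModel, TrainingSet, fit_logit, roc_analysis

_TERMS = ["Intercept"] + list(MARKERS)

#: tDx strata for held-out ROC; each stratum's cases vs all held-out controls.
ROC_STRATA = {
    "tdx<1": lambda t: t < 1.0,
    "tdx<2": lambda t: t < 2.0,
    "1<=tdx<2": lambda t: (t >= 1.0) & (t < 2.0),
}


@dataclass
class CVReport:
    scheme: str  # "loo_subject" | "kfold_sample"
    k: int | None
    coefficients: pd.DataFrame  # one row per repetition, columns = terms
    coefficient_sd: dict[str, float]
    heldout_auc: dict[str, dict] = field(default_factory=dict)
    rng_seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme,
            "k": self.k,
            "rng_seed": self.rng_seed,
            "coefficient_sd": self.coefficient_sd,
            "heldout_auc": self.heldout_auc,
            "coefficients": self.coefficients.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _coef_row(model: LogitModel) -> dict[str, float]:
    row = {"Intercept": model.intercept}
    row.update(model.coefficients)
    return row


def _sd(frame: pd.DataFrame) -> dict[str, float]:
    # sample SD (ddof=1) across repetitions
    return {t: float(frame[t].std(ddof=1)) for t in _TERMS}


def loo_cv(training: TrainingSet) -> CVReport:
    """Leave-one-subject-out: refit once per training subject with all that
    subject's samples removed; report per-term coefficient SDs."""
    frame = training.frame
    for label in (0, 1):
        if frame.loc[frame.label == label, "subject_id"].nunique() < 3:
            raise ValidationError("loo_cv needs >= 3 subjects per class")
    rows = []
    for sid in frame["subject_id"].unique():
        reduced = TrainingSet(frame[frame.subject_id != sid].reset_index(drop=True), {})
        try:
            rows.append(_coef_row(fit_logit(reduced)))
        except FittingError as e:
            raise ValidationError(f"LOO refit failed excluding subject {sid!r}: {e}") from e
    coefs = pd.DataFrame(rows, columns=_TERMS)
    return CVReport("loo_subject", None, coefs, _sd(coefs))


def kfold_cv(training: TrainingSet, k: int = 10, seed: int = 0) -> CVReport:
    """Label-stratified k-fold over sample rows: per-fold refit, coefficient
    SDs, and held-out ROC per tDx stratum (mean AUC across folds)."""
    frame = training.frame.reset_index(drop=True)
    y = frame["label"].to_numpy()
    if k < 2 or k > len(frame):
        raise ValidationError(f"k must be in [2, n_samples], got {k}")

    # stratification requires each class to fill every fold; beyond that
    # (e.g. k = n, leave-one-sample-out) fall back to a plain shuffled split
    min_class = int(min(np.bincount(y)))
    last_err: Exception | None = None
    for attempt in range(10):
        if k <= min_class:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        rows, fold_aucs = [], {name: [] for name in ROC_STRATA}
        try:
            for train_idx, test_idx in splitter.split(frame, y):
                sub = TrainingSet(frame.iloc[train_idx].reset_index(drop=True), {})
                model = fit_logit(sub)
                rows.append(_coef_row(model))
                held = frame.iloc[test_idx]
                from .model import predict_risk

                probs = np.array(
                    [
                        predict_risk({m: r[f"score_{m.lower()}"] for m in MARKERS}, model)
                        for _, r in held.iterrows()
                    ]
                )
                for name, in_stratum in ROC_STRATA.items():
                    mask = (held["label"].to_numpy() == 0) | (
                        (held["label"].to_numpy() == 1)
                        & in_stratum(held["tdx_years"].to_numpy())
                    )
                    yy, pp = held["label"].to_numpy()[mask], probs[mask]
                    if len(np.unique(yy)) == 2:
                        fold_aucs[name].append(roc_analysis(pp, yy)[0])
            break
        except FittingError as e:
            last_err = e
    else:
        raise ValidationError(f"k-fold degenerate after 10 partition redraws: {last_err}")

    coefs = pd.DataFrame(rows, columns=_TERMS)
    heldout = {
        name: {
            "per_fold": [float(a) for a in aucs],
            "mean": float(np.mean(aucs)) if aucs else float("nan"),
            "n_folds": len(aucs),
        }
        for name, aucs in fold_aucs.items()
    }
    return CVReport("kfold_sample", k, coefs, _sd(coefs), heldout, rng_seed=seed)
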