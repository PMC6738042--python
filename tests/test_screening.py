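"""PPV mapping, N/I/E/S classification and the annual screening simulation."""

import numpy as np
import pandas as pd
import pytest

from ovascreen import (
    Cohort,
    CohortConfig,
    PPVTable,
    RiskThresholds,
    SerumSample,
    SubjectRecord,
    ValidationError,
    build_ppv_table,
    build_training_set,
    classify_probability,
    fit_logit,
    generate_cohort,
    predict_risk,
    published_model,
    render_riverplot_data,
    roc_analysis,
    score_cohort,
    simulate_screening,
)
from ovascreen.cohort import MARKERS
from ovascreen.scoring import ScoreVector


class TestPPVTable:
    def test_ideal_and_symmetric_cases(self):
        t = build_ppv_table([(0.5, 1.0, 1.0)], prevalence=0.1)
        assert t.frame["ppv"].iloc[0] == 1.0
        t = build_ppv_table([(0.5, 0.5, 0.5)], prevalence=0.5)
        assert t.frame["ppv"].iloc[0] == pytest.approx(0.5)

    def test_matches_confusion_matrix_simulation(self):
        """PPV formula agrees with counting TP/(TP+FP) in a simulated
        million-woman population."""
        sens, spec, prev = 0.8, 0.99, 0.01
        t = build_ppv_table([(0.5, sens, spec)], prevalence=prev)
        formula = t.frame["ppv"].iloc[0]
        assert formula == pytest.approx(0.008 / (0.008 + 0.0099), abs=1e-9)
        rng = np.random.default_rng(123)
        n = 1_000_000
        disease = rng.random(n) < prev
        positive = np.where(disease, rng.random(n) < sens, rng.random(n) < (1 - spec))
        tp = int((disease & positive).sum())
        fp = int((~disease & positive).sum())
        assert formula == pytest.approx(tp / (tp + fp), abs=0.015)

    def test_prevalence_bounds(self):
        with pytest.raises(ValidationError):
            build_ppv_table([(0.5, 1, 1)], prevalence=0.0)
        with pytest.raises(ValidationError):
            build_ppv_table([(0.5, 1, 1)], prevalence=1.0)


def _table(rows, prev=0.004):
    return PPVTable(
        pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "ppv"]),
        prev,
    )


class TestClassification:
    def test_below_lowest_threshold_is_normal(self):
        t = _table([[0.5, 0.9, 0.9, 0.5]])
        assert classify_probability(0.1, t) == "N"

    def test_class_ladder(self):
        t = _table(
            [[0.1, 0.9, 0.5, 0.01], [0.3, 0.8, 0.9, 0.03],
             [0.5, 0.6, 0.95, 0.10], [0.8, 0.4, 0.99, 0.45]]
        )
        assert classify_probability(0.05, t) == "N"
        assert classify_probability(0.35, t) == "I"
        assert classify_probability(0.6, t) == "E"
        assert classify_probability(0.9, t) == "S"

    def test_all_low_ppv_means_all_normal(self):
        t = _table([[0.1, 1, 0.5, 0.01], [0.9, 0.1, 0.99, 0.02]])
        for p in (0.0, 0.5, 1.0):
            assert classify_probability(p, t) == "N"

    def test_worked_example_severe(self):
        """{6,1,0,0} scores 0.87 under the published model; with a PPV table
        mapping that probability to PPV >= 30% the class is severe."""
        p = predict_risk({"CA125": 6, "PROZ": 1, "LCAT": 0, "CRP": 0}, published_model())
        assert round(p, 2) == 0.87
        t = _table([[0.5, 0.8, 0.9, 0.10], [0.85, 0.5, 0.99, 0.40]])
        assert classify_probability(p, t) == "S"

    def test_probability_out_of_range(self):
        t = _table([[0.5, 1, 1, 1]])
        with pytest.raises(ValidationError):
            classify_probability(1.5, t)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            RiskThresholds(severe=0.05, elevated=0.30, intermediate=0.025)


def _mini_cohort_with_scores(tdxs, scores_by_tdx):
    subj = SubjectRecord("T2-001", "type2", False, "III", None)
    samples = [
        SerumSample("T2-001", t, {m: 10.0 for m in MARKERS}) for t in tdxs
    ]
    cohort = Cohort([subj], samples, aligned=True)
    scores = [
        ScoreVector("T2-001", t, scores_by_tdx[t]) for t in tdxs
    ]
    return cohort, scores


class TestScreeningSimulation:
    def test_latest_sample_before_cutoff_selected(self):
        """Samples at tdx {4.5,3.5,2.5,0.5}: the year-4 screen sees tdx 4.5 and
        the year-1 screen sees tdx 2.5 (0.5 falls after the cut-off)."""
        tdxs = [4.5, 3.5, 2.5, 0.5]
        cohort, scores = _mini_cohort_with_scores(
            tdxs, {t: {m: 0 for m in MARKERS} for t in tdxs}
        )
        table = _table([[0.0, 1, 0.5, 0.5]])
        trajectories, _ = simulate_screening(cohort, scores, published_model(), table)
        by_year = trajectories[0].by_year
        assert by_year[4][0] == 4.5
        assert by_year[3][0] == 3.5
        assert by_year[2][0] == 2.5
        assert by_year[1][0] == 2.5

    def test_missing_year_yields_no_sample(self):
        cohort, scores = _mini_cohort_with_scores(
            [1.5], {1.5: {m: 0 for m in MARKERS}}
        )
        table = _table([[0.0, 1, 0.5, 0.5]])
        trajectories, summary = simulate_screening(cohort, scores, published_model(), table)
        assert trajectories[0].by_year[4] is None
        assert trajectories[0].by_year[1] is not None
        none_rows = summary.class_counts.query("`class` == 'none'")
        assert set(none_rows["year"]) == {4, 3, 2}

    def test_monotone_probabilities_give_monotone_severity(self):
        """Scores rising toward diagnosis never de-escalate the class."""
        tdxs = [4.5, 3.5, 2.5, 1.5]
        rising = {
            4.5: {m: 0 for m in MARKERS},
            3.5: {"CA125": 2, "PROZ": 0, "LCAT": 0, "CRP": 0},
            2.5: {"CA125": 4, "PROZ": 1, "LCAT": 0, "CRP": 0},
            1.5: {"CA125": 6, "PROZ": 2, "LCAT": 1, "CRP": 1},
        }
        cohort, scores = _mini_cohort_with_scores(tdxs, rising)
        table = _table(
            [[0.05, 1, 0.5, 0.02], [0.2, 0.9, 0.9, 0.03],
             [0.5, 0.7, 0.95, 0.10], [0.9, 0.4, 0.99, 0.40]]
        )
        trajectories, _ = simulate_screening(cohort, scores, published_model(), table)
        sev = {"N": 0, "I": 1, "E": 2, "S": 3}
        classes = [trajectories[0].by_year[y][3] for y in (4, 3, 2, 1)]
        assert all(sev[a] <= sev[b] for a, b in zip(classes, classes[1:]))

    def test_riverplot_edges_match_independent_recount(self, default_cohort, scored_default):
        scores, _, _ = scored_default
        model = published_model()
        groups = {s.subject_id: s.group for s in default_cohort.subjects}
        probs = [predict_risk(v, model) for v in scores]
        labels = [0 if groups[v.subject_id] == "control" else 1 for v in scores]
        _, roc_rows = roc_analysis(probs, labels)
        table = build_ppv_table(roc_rows, prevalence=0.004)
        trajectories, summary = simulate_screening(default_cohort, scores, model, table)
        nodes, edges = render_riverplot_data(summary)
        # brute-force recount from the trajectories themselves
        recount = {}
        for tr in trajectories:
            for y0, y1 in ((4, 3), (3, 2), (2, 1)):
                c0 = tr.by_year[y0][3] if tr.by_year[y0] else "none"
                c1 = tr.by_year[y1][3] if tr.by_year[y1] else "none"
                key = (tr.group, y0, c0, y1, c1)
                recount[key] = recount.get(key, 0) + 1
        for _, r in edges.iterrows():
            key = (r.group, r.year_from, r.class_from, r.year_to, r.class_to)
            assert recount[key] == r["count"]
        assert sum(recount.values()) == edges["count"].sum()
        # node marginals: per year and group, counts sum to number of subjects
        for (g, y), grp in nodes.groupby(["group", "year"]):
            assert grp["n_subjects"].sum() == sum(
                1 for s in default_cohort.subjects if s.group == g
            )

    def test_empty_cohort_yields_empty_river_tables(self):
        cohort = Cohort([], [], aligned=True)
        table = _table([[0.5, 1, 1, 1]])
        trajectories, summary = simulate_screening(cohort, [], published_model(), table)
        assert trajectories == []
        nodes, edges = render_riverplot_data(summary)
        assert nodes.empty and edges.empty

    def test_null_cohort_controls_predominantly_normal(self):
        """With no disease signal the fitted pipeline leaves control
        screen-years overwhelmingly at class N."""
        cfg = CohortConfig(
            n_controls=60, n_type2=60, n_type1=0, n_borderline=0,
            effect_size=1.0, rng_seed=21,
        )
        subjects, samples = generate_cohort(cfg)
        cohort = Cohort(subjects, samples, aligned=True)
        scores, _, _ = score_cohort(cohort)
        model = fit_logit(build_training_set(cohort, scores))
        groups = {s.subject_id: s.group for s in subjects}
        probs, labels = [], []
        for v in scores:
            if groups[v.subject_id] == "control":
                probs.append(predict_risk(v, model)); labels.append(0)
            elif v.tdx < 2:
                probs.append(predict_risk(v, model)); labels.append(1)
        _, roc_rows = roc_analysis(probs, labels)
        table = build_ppv_table(roc_rows, prevalence=0.004)
        _, summary = simulate_screening(cohort, scores, model, table)
        ctrl = summary.class_counts.query("group == 'control' and `class` != 'none'")
        n_class = ctrl["count"].sum()
        n_normal = ctrl.query("`class` == 'N'")["count"].sum()
        assert n_normal / n_class > 0.9
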