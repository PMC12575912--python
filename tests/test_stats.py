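"""Agreement, group comparison, ROC/DeLong, logistic combination, pipeline."""

import numpy as np
import pandas as pd
import pytest

import lvikit as lk


# ----------------------------------------------------------------- ICC


def test_icc_identical_readers_is_one(rng):
    x = rng.normal(5, 1, 20)
    res = lk.compute_icc(x, x.copy())
    assert res.icc == pytest.approx(1.0)
    assert res.band == "excellent"


def test_icc_independent_noise_is_near_zero(rng):
    vals = [
        lk.compute_icc(rng.normal(0, 1, 50), rng.normal(0, 1, 50)).icc
        for _ in range(200)
    ]
    assert abs(np.mean(vals)) < 0.05
    assert lk.icc_band(float(np.mean(vals))) == "poor"


@pytest.mark.parametrize(
    "icc, band",
    [(0.9, "excellent"), (0.75, "excellent"), (0.65, "good"), (0.60, "good"),
     (0.45, "fair"), (0.40, "fair"), (0.1, "poor")],
)
def test_icc_band_thresholds(icc, band):
    assert lk.icc_band(icc) == band


def test_icc_matches_independent_reference(rng):
    # dual route: compare the ANOVA implementation with pingouin's ICC(A,1)
    pingouin = pytest.importorskip("pingouin")
    x = rng.normal(10, 2, 30)
    r1 = x + rng.normal(0, 0.5, 30)
    r2 = x + rng.normal(0, 0.5, 30)
    long = pd.DataFrame(
        {
            "subj": np.repeat(np.arange(30), 2),
            "rater": np.tile([1, 2], 30),
            "y": np.column_stack([r1, r2]).ravel(),
        }
    )
    table = pingouin.intraclass_corr(long, targets="subj", raters="rater", ratings="y")
    # the two-way random absolute-agreement single-measures row is labelled
    # ICC2 or ICC(A,1) depending on the pingouin version
    row = table[table["Type"].isin(["ICC2", "ICC(A,1)"])]
    ref = float(row["ICC"].iloc[0])
    assert lk.compute_icc(r1, r2).icc == pytest.approx(ref, rel=1e-9)


def test_icc_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        lk.compute_icc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


# --------------------------------------------------- group comparison


def test_compare_identical_groups_midpoint_u(rng):
    x = rng.exponential(1.0, 40)  # non-normal, routes to Mann-Whitney
    res = lk.compare_groups(x, x.copy())
    assert res.route == "mann-whitney"
    assert res.statistic == pytest.approx(40 * 40 / 2)
    assert res.p > 0.9


def test_compare_routes_by_normality(rng):
    res_n = lk.compare_groups(rng.normal(0, 1, 40), rng.normal(0.2, 1, 50))
    assert res_n.route == "t-test" and res_n.summary_kind == "mean_sd"
    res_e = lk.compare_groups(rng.lognormal(0, 1.5, 40), rng.lognormal(0, 1.5, 50))
    assert res_e.route == "mann-whitney" and res_e.summary_kind == "median_q1_q3"


def test_compare_constant_group_routes_to_mannwhitney():
    res = lk.compare_groups([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    assert res.route == "mann-whitney"
    assert "constant" in res.note


def test_compare_detects_calibrated_location_shift():
    """Log-normal groups shifted like the D biomarker separate reliably."""
    pos_spec = lk.calibrate_quantile_distribution(0.72, 0.30, 1.28)
    neg_spec = lk.calibrate_quantile_distribution(0.96, 0.40, 1.70)
    rng = np.random.default_rng(11)
    hits = sum(
        lk.compare_groups(pos_spec.sample(26, rng), neg_spec.sample(47, rng)).p < 0.05
        for _ in range(100)
    )
    assert hits > 10  # power well above the type-I level


# ----------------------------------------------------------- ROC / AUC


def _pair_count_auc(scores, labels):
    """Exhaustive all-pairs concordance oracle."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def test_auc_equals_exhaustive_pair_counting(rng):
    for _ in range(30):
        n = int(rng.integers(6, 50))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n - 1))] = 1
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        res = lk.roc_analysis(scores, labels, direction="higher")
        assert res.auc == _pair_count_auc(scores, labels)


def test_auc_matches_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    scores = rng.normal(size=60)
    labels = (rng.random(60) < 0.4).astype(int)
    res = lk.roc_analysis(scores, labels, direction="higher")
    assert res.auc == pytest.approx(
        sklearn_metrics.roc_auc_score(labels, scores), rel=1e-12
    )


def test_roc_perfect_separation():
    scores = np.r_[np.full(5, 10.0), np.full(7, 1.0)]
    labels = np.r_[np.ones(5), np.zeros(7)].astype(int)
    res = lk.roc_analysis(scores, labels)
    assert res.auc == 1.0
    assert res.sensitivity == 100.0 and res.specificity == 100.0
    assert res.ci_low == res.ci_high == 1.0


def test_roc_null_auc_near_half(rng):
    scores = rng.normal(size=4000)
    labels = (rng.random(4000) < 0.5).astype(int)
    res = lk.roc_analysis(scores, labels, direction="higher")
    assert res.auc == pytest.approx(0.5, abs=0.03)


def test_roc_identities_and_cutoff_semantics(rng):
    for _ in range(20):
        labels = np.r_[np.ones(26), np.zeros(47)].astype(int)
        scores = rng.normal(size=73) - 0.8 * labels  # lower score = positive
        res = lk.roc_analysis(scores, labels, direction="auto")
        assert res.fpr == pytest.approx(100.0 - res.specificity)
        assert res.fnr == pytest.approx(100.0 - res.sensitivity)
        assert res.auc >= 0.5
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.direction == "lower"
        # the reported operating point reproduces its sensitivity/specificity
        called_pos = scores <= res.cutoff
        sens = 100.0 * called_pos[labels == 1].mean()
        spec = 100.0 * (~called_pos[labels == 0]).mean()
        assert sens == pytest.approx(res.sensitivity)
        assert spec == pytest.approx(res.specificity)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        lk.roc_analysis([1.0, 2.0], [1, 1])


# --------------------------------------------------------------- DeLong


def test_delong_identical_scores():
    labels = np.r_[np.ones(10), np.zeros(15)].astype(int)
    scores = np.arange(25.0)
    res = lk.delong_compare(scores, scores, labels)
    assert res.z == 0.0 and res.p == 1.0


def test_delong_rank_invariance(rng):
    labels = np.r_[np.ones(12), np.zeros(20)].astype(int)
    scores = rng.normal(size=32) + labels
    res = lk.delong_compare(scores, np.exp(scores), labels)
    assert res.z == 0.0 and res.p == 1.0


def test_delong_detects_auc_difference(rng):
    labels = np.r_[np.ones(40), np.zeros(60)].astype(int)
    strong = rng.normal(size=100) + 2.0 * labels
    weak = rng.normal(size=100)
    res = lk.delong_compare(strong, weak, labels)
    assert res.p < 0.01
    assert res.auc_a > res.auc_b


# ------------------------------------------------------------- logistic


def test_univariate_logistic_null_or_near_one(rng):
    x = rng.normal(size=3000)
    y = (rng.random(3000) < 0.4).astype(int)
    res = lk.univariate_logistic(x, y)
    assert res.table["or"].iloc[0] == pytest.approx(1.0, abs=0.15)


def test_univariate_logistic_recovers_generating_coefficient(rng):
    x = rng.normal(size=2000)
    p = 1.0 / (1.0 + np.exp(-(-1.0 + 0.8 * x)))
    y = (rng.random(2000) < p).astype(int)
    res = lk.univariate_logistic(x, y)
    coef = res.table["coef"].iloc[0]
    # within 3 standard errors of the generating slope
    se = (np.log(res.table["ci_high"].iloc[0]) - np.log(res.table["or"].iloc[0])) / 1.96
    assert abs(coef - 0.8) < 3 * se


def test_univariate_logistic_scale_equivariance(rng):
    x = rng.normal(size=500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
    a = lk.univariate_logistic(x, y)
    b = lk.univariate_logistic(10 * x, y)
    assert b.table["coef"].iloc[0] == pytest.approx(a.table["coef"].iloc[0] / 10, rel=1e-6)
    assert b.table["p"].iloc[0] == pytest.approx(a.table["p"].iloc[0], rel=1e-6)


def test_univariate_logistic_flags_separation():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = x.astype(int)
    res = lk.univariate_logistic(x, y)
    assert res.separation


def _toy_subjects(rng, n=300):
    x1 = rng.normal(size=n)
    noise = {m: rng.normal(size=n) for m in lk.BIOMARKERS if m != "mtv"}
    p = 1 / (1 + np.exp(-(-0.3 + 1.5 * x1)))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "lvi": y, "mtv": x1})
    for m, v in noise.items():
        df[m] = v
    return df


def test_multivariate_single_survivor_equals_univariate(rng):
    subjects = _toy_subjects(rng)
    multi = lk.multivariate_selection(subjects, p_enter=1e-4)
    assert multi.members == ("mtv",)
    uni = lk.univariate_logistic(subjects["mtv"], subjects["lvi"], "mtv")
    assert multi.table["coef"].iloc[0] == pytest.approx(uni.table["coef"].iloc[0], rel=1e-8)


def test_multivariate_recovers_two_generating_predictors(rng):
    n = 2000
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + 0.9 * x1 - 0.7 * x2)))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"subject_id": range(n), "lvi": y, "mtv": x1, "d": x2})
    res = lk.multivariate_selection(df, p_enter=0.1, biomarkers=("mtv", "d"))
    assert set(res.members) == {"mtv", "d"}
    assert (res.table["p"] < 0.05).all()
    coefs = dict(zip(res.table["term"], res.table["coef"]))
    assert coefs["mtv"] == pytest.approx(0.9, abs=0.2)
    assert coefs["d"] == pytest.approx(-0.7, abs=0.2)


def test_multivariate_duplicated_biomarker_flags_collinearity(rng):
    n = 400
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
    df = pd.DataFrame({"subject_id": range(n), "lvi": y, "mtv": x, "d": x})
    res = lk.multivariate_selection(df, p_enter=0.5, biomarkers=("mtv", "d"))
    assert res.collinear


def test_multivariate_empty_screen(rng):
    n = 200
    df = pd.DataFrame(
        {
            "subject_id": range(n),
            "lvi": (rng.random(n) < 0.4).astype(int),
            "mtv": rng.normal(size=n),
        }
    )
    res = lk.multivariate_selection(df, p_enter=1e-9, biomarkers=("mtv",))
    assert res.members == ()
    assert len(res.table) == 0


def test_combination_single_member_matches_raw_roc(default_cohort):
    subjects = lk.subject_table(default_cohort)
    combo = lk.combine_predictors(subjects, ["mtv"])
    raw = lk.roc_analysis(subjects["mtv"], subjects["lvi"], direction="higher")
    assert combo.roc.auc == pytest.approx(raw.auc, abs=1e-12)


def test_combination_all_not_worse_than_subsets(default_cohort):
    subjects = lk.subject_table(default_cohort)
    auc_all = lk.combine_predictors(subjects, lk.PRESET_COMBINATIONS["ALL"]).roc.auc
    for name in ("PET", "IVIM", "DKI", "MTV+D"):
        auc_sub = lk.combine_predictors(subjects, lk.PRESET_COMBINATIONS[name]).roc.auc
        assert auc_all >= auc_sub - 0.02


# ------------------------------------------------------------- pipeline


def test_pipeline_report_structure(default_cohort):
    report = lk.run_pipeline(default_cohort)
    assert list(report.icc_table.biomarker) == list(lk.BIOMARKERS)
    assert len(report.comparison_table) == 9
    assert len(report.univariate_table) == 9
    assert len(report.roc_table) == 9 + 5
    assert set(report.combinations) == {"PET", "IVIM", "DKI", "MTV+D", "ALL"}
    assert ((report.roc_table.fpr + report.roc_table.specificity - 100).abs() < 1e-9).all()
    text = report.to_text()
    assert "ICC" in text and "ROC" in text


def test_pipeline_zero_reader_noise_all_icc_one():
    cohort = lk.generate_cohort(lk.default_cohort_config(seed=6, reader_icc=1.0))
    report = lk.run_pipeline(cohort)
    assert np.allclose(report.icc_table.icc, 1.0)


def test_pipeline_deterministic_under_fixed_seed():
    a = lk.run_pipeline(lk.generate_cohort(lk.default_cohort_config(seed=12)))
    b = lk.run_pipeline(lk.generate_cohort(lk.default_cohort_config(seed=12)))
    assert a.to_text() == b.to_text()


def test_pipeline_missing_column_named():
    cohort = lk.generate_cohort(lk.default_cohort_config(seed=1)).drop(columns=["tlg"])
    with pytest.raises(ValueError, match="tlg"):
        lk.run_pipeline(cohort)


def test_subject_table_averages_readers(default_cohort):
    subjects = lk.subject_table(default_cohort)
    assert len(subjects) == 73
    one = default_cohort[default_cohort.subject_id == "S001"]
    assert subjects.loc[subjects.subject_id == "S001", "mtv"].iloc[0] == pytest.approx(
        one.mtv.mean()
    )
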