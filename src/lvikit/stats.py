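"""Biomarker statistics: agreement, group comparison, ROC, logistic models.

This layer reproduces the statistical chain of a two-group imaging-biomarker
study of lymphovascular invasion (LVI):

1. inter-reader agreement per biomarker via the intraclass correlation
   coefficient, two-way random effects, absolute agreement, single measures
   (ICC(2,1)), with the conventional qualitative bands;
2. LVI+ vs LVI- comparison routed by Shapiro-Wilk normality: Student's
   t-test with mean +/- sd summaries when both groups are consistent with
   normality, Mann-Whitney U with median (Q1, Q3) summaries otherwise;
3. per-biomarker ROC analysis: the all-pairs concordance AUC (ties count
   one half), DeLong variance for the confidence interval, and the Youden
   operating point (ties broken toward higher specificity);
4. DeLong's test for comparing two correlated AUCs measured on the same
   subjects;
5. univariate logistic screening (p < 0.1) feeding a multivariate logistic
   model, and logistic combination of preset biomarker panels whose
   predicted probability is scored by ROC.

No multiple-testing correction is applied across biomarkers, and all
models are evaluated in-sample; both choices mirror the study design this
pipeline emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic import BIOMARKERS

__all__ = [
    "ICCResult",
    "GroupComparisonResult",
    "ROCResult",
    "DeLongResult",
    "LogisticResult",
    "CombinedROC",
    "StudyReport",
    "PipelineConfig",
    "PRESET_COMBINATIONS",
    "icc_band",
    "compute_icc",
    "compare_groups",
    "roc_analysis",
    "delong_compare",
    "univariate_logistic",
    "multivariate_selection",
    "combine_predictors",
    "subject_table",
    "run_pipeline",
]

#: preset biomarker panels; ALL is the union of the three modality panels
PRESET_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "PET": ("suvmax", "mtv", "tlg"),
    "IVIM": ("adc", "d", "dstar", "f_pct"),
    "DKI": ("mk", "md"),
    "MTV+D": ("mtv", "d"),
    "ALL": ("suvmax", "mtv", "tlg", "adc", "d", "dstar", "f_pct", "mk", "md"),
}


# --------------------------------------------------------------------------
# Inter-reader agreement
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    band: str


def icc_band(icc: float) -> str:
    """Qualitative agreement band: >=0.75 excellent, 0.60-0.75 good,
    0.40-0.60 fair, <0.40 poor."""
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


def compute_icc(reader1, reader2) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("reader vectors must be 1-D and of equal length")
    n = r1.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    x = np.column_stack([r1, r2])
    if np.ptp(x) == 0:
        raise ValueError("ICC undefined: zero total variance")
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(icc=float(icc), band=icc_band(float(icc)))


# --------------------------------------------------------------------------
# Two-group comparison with normality routing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparisonResult:
    biomarker: str
    route: str  # "t-test" | "mann-whitney"
    statistic: float
    p: float
    summary_kind: str  # "mean_sd" | "median_q1_q3"
    pos_summary: tuple[float, ...]
    neg_summary: tuple[float, ...]
    shapiro_p: tuple[float, float] | None = None
    note: str = ""


def _summaries(pos: np.ndarray, neg: np.ndarray, kind: str):
    if kind == "mean_sd":
        return (
            (float(pos.mean()), float(pos.std(ddof=1))),
            (float(neg.mean()), float(neg.std(ddof=1))),
        )
    q = lambda v: tuple(float(x) for x in np.percentile(v, [50, 25, 75]))
    return q(pos), q(neg)


def compare_groups(
    pos, neg, alpha_normal: float = 0.05, biomarker: str = ""
) -> GroupComparisonResult:
    """Compare LVI+ vs LVI- values with Shapiro-Wilk routing.

    Both groups consistent with normality at ``alpha_normal`` -> pooled
    two-sample t-test, mean +/- sd summaries; otherwise Mann-Whitney U,
    median (Q1, Q3) summaries.  Constant data in a group makes the
    normality test inapplicable and routes to Mann-Whitney with a note.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise ValueError("both groups need at least 3 observations")
    note = ""
    if np.ptp(pos) == 0 or np.ptp(neg) == 0:
        shapiro_p = None
        normal = False
        note = "constant data in a group; normality test inapplicable"
    else:
        sw_pos = sps.shapiro(pos).pvalue
        sw_neg = sps.shapiro(neg).pvalue
        shapiro_p = (float(sw_pos), float(sw_neg))
        normal = sw_pos > alpha_normal and sw_neg > alpha_normal
    if normal:
        stat, p = sps.ttest_ind(pos, neg, equal_var=True)
        kind, route = "mean_sd", "t-test"
    else:
        stat, p = sps.mannwhitneyu(pos, neg, alternative="two-sided")
        kind, route = "median_q1_q3", "mann-whitney"
    pos_s, neg_s = _summaries(pos, neg, kind)
    return GroupComparisonResult(
        biomarker=biomarker,
        route=route,
        statistic=float(stat),
        p=float(p),
        summary_kind=kind,
        pos_summary=pos_s,
        neg_summary=neg_s,
        shapiro_p=shapiro_p,
        note=note,
    )


# --------------------------------------------------------------------------
# ROC analysis and DeLong machinery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong confidence interval and the Youden operating point.

    Percent-scale columns obey FPR = 100 - specificity and
    FNR = 100 - sensitivity.  ``direction`` records whether high or low
    scores indicate the positive class; the cutoff is on the original
    score scale (positive call: score >= cutoff for "higher",
    score <= cutoff for "lower").
    """

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    n_pos: int
    n_neg: int

    @property
    def fpr(self) -> float:
        return 100.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 100.0 - self.sensitivity


@dataclass(frozen=True)
class DeLongResult:
    z: float
    p: float
    auc_a: float
    auc_b: float


def _split_scores(scores: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be coded 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Placement values: v10[i] = P-hat(pos_i beats a random negative), v01
    symmetric; their means both equal the concordance AUC."""
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0) + 0.5 * (diff == 0)
    return wins.mean(axis=1), wins.mean(axis=0)


def _auc_and_var(pos: np.ndarray, neg: np.ndarray):
    v10, v01 = _placements(pos, neg)
    m, n = pos.size, neg.size
    # sum wins before dividing once: keeps the AUC bit-identical to the
    # exhaustive all-pairs count (wins are exact multiples of 1/2)
    diff = pos[:, None] - neg[None, :]
    wins = float(((diff > 0) + 0.5 * (diff == 0)).sum())
    auc = wins / (m * n)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return auc, float(var)


def roc_analysis(scores, labels, direction: str = "auto") -> ROCResult:
    """All-pairs concordance AUC, DeLong CI, Youden cutoff.

    ``direction``: "higher" / "lower" fixes which score extreme indicates
    the positive class; "auto" orients so AUC >= 0.5 and records the flip.
    The cutoff maximises Youden's J = sensitivity + specificity - 1 over
    the observed score values; ties are broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if direction not in ("auto", "higher", "lower"):
        raise ValueError("direction must be auto/higher/lower")
    pos, neg = _split_scores(scores, labels)
    if direction == "auto":
        auc_raw, _ = _auc_and_var(pos, neg)
        direction = "higher" if auc_raw >= 0.5 else "lower"
    sgn = 1.0 if direction == "higher" else -1.0
    opos, oneg = sgn * pos, sgn * neg
    auc, var = _auc_and_var(opos, oneg)
    half = 1.959963984540054 * np.sqrt(var)
    ci_low = float(np.clip(auc - half, 0.0, 1.0))
    ci_high = float(np.clip(auc + half, 0.0, 1.0))

    thresholds = np.unique(np.concatenate([opos, oneg]))
    sens = np.array([(opos >= t).mean() for t in thresholds])
    spec = np.array([(oneg < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best_j = j.max()
    cand = np.flatnonzero(np.isclose(j, best_j))
    cand = cand[np.argsort(spec[cand], kind="stable")]
    idx = int(cand[-1])  # highest specificity among the J-ties
    return ROCResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(sgn * thresholds[idx]),
        sensitivity=float(100.0 * sens[idx]),
        specificity=float(100.0 * spec[idx]),
        direction=direction,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test for two correlated AUCs on the same subjects.

    The two score vectors must be paired subject by subject.  The variance
    of the AUC difference comes from the empirical covariance of the
    placement values; Z = dAUC / se with a two-sided normal p-value.
    Identical or rank-identical scores give dAUC = 0, Z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b, labels must be equal-length")
    pa, na = _split_scores(a, labels)
    pb, nb = _split_scores(b, labels)
    v10a, v01a = _placements(pa, na)
    v10b, v01b = _placements(pb, nb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = pa.size, na.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    dauc = auc_a - auc_b
    if var <= 0:
        if abs(dauc) < 1e-12:
            return DeLongResult(z=0.0, p=1.0, auc_a=auc_a, auc_b=auc_b)
        raise ValueError("degenerate: zero variance of the AUC difference")
    z = dauc / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(z=float(z), p=float(p), auc_a=auc_a, auc_b=auc_b)


# --------------------------------------------------------------------------
# Logistic models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticResult:
    """A fitted logistic model over one or more biomarkers.

    ``table`` holds one row per non-intercept term: coefficient, odds
    ratio with Wald 95% CI, and p-value.  ``linear_predictor`` and
    ``probability`` are the in-sample fitted scores.  ``separation`` flags
    a monotone likelihood (perfectly separating predictor); ``collinear``
    flags a rank-deficient design.
    """

    members: tuple[str, ...]
    table: pd.DataFrame
    intercept: float
    linear_predictor: np.ndarray
    probability: np.ndarray
    converged: bool
    separation: bool = False
    collinear: bool = False
    screened: dict[str, float] = field(default_factory=dict)


def _fit_logistic(x: pd.DataFrame, y: np.ndarray) -> LogisticResult:
    members = tuple(x.columns)
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    collinear = np.linalg.matrix_rank(design) < design.shape[1]
    separation = False
    converged = True
    bse = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            # monotone likelihood or rank-deficient design: fall back to a
            # lightly ridge-penalized fit and flag, never report a silent OR
            if not collinear:
                separation = True
            converged = False
            glm = sm.GLM(y, design, family=sm.families.Binomial())
            res = glm.fit_regularized(alpha=1e-6, L1_wt=0.0)
            params = np.asarray(res.params, dtype=float)
            bse = np.full_like(params, np.nan)
    for w in caught:
        if "separat" in str(w.message).lower():
            separation = True
        if "converge" in str(w.message).lower():
            converged = False
    if np.any(~np.isfinite(bse)) or np.any(np.abs(params[1:]) > 1e3):
        separation = separation or not collinear
    zcrit = 1.959963984540054
    with np.errstate(over="ignore"):
        rows = []
        for j, name in enumerate(members, start=1):
            coef, se = params[j], bse[j]
            pval = 2.0 * sps.norm.sf(abs(coef / se)) if se > 0 else np.nan
            rows.append(
                {
                    "term": name,
                    "coef": coef,
                    "or": np.exp(coef),
                    "ci_low": np.exp(coef - zcrit * se),
                    "ci_high": np.exp(coef + zcrit * se),
                    "p": pval,
                }
            )
    table = pd.DataFrame(rows, columns=["term", "coef", "or", "ci_low", "ci_high", "p"])
    lp = design @ params
    return LogisticResult(
        members=members,
        table=table,
        intercept=float(params[0]),
        linear_predictor=lp,
        probability=expit(lp),
        converged=converged,
        separation=separation,
        collinear=collinear,
    )


def univariate_logistic(biomarker, labels, name: str = "x") -> LogisticResult:
    """Maximum-likelihood logistic fit of the LVI label on one biomarker."""
    x = pd.DataFrame({name: np.asarray(biomarker, dtype=float)})
    y = np.asarray(labels).astype(int)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    return _fit_logistic(x, y)


def multivariate_selection(
    subjects: pd.DataFrame,
    p_enter: float = 0.1,
    biomarkers: tuple[str, ...] = BIOMARKERS,
) -> LogisticResult:
    """Univariate screen (p < ``p_enter``) followed by one joint logistic fit.

    ``subjects`` is a subject-level table with an ``lvi`` column and one
    column per biomarker.  Biomarkers passing the screen enter a single
    multivariate model; an empty screen yields an intercept-only result.
    """
    y = subjects["lvi"].to_numpy(dtype=int)
    screened: dict[str, float] = {}
    for m in biomarkers:
        uni = univariate_logistic(subjects[m], y, name=m)
        screened[m] = float(uni.table["p"].iloc[0])
    selected = tuple(m for m in biomarkers if screened[m] < p_enter)
    if not selected:
        p1 = float(np.mean(y))
        lp = np.full(len(y), np.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0)
        return LogisticResult(
            members=(),
            table=pd.DataFrame(columns=["term", "coef", "or", "ci_low", "ci_high", "p"]),
            intercept=float(lp[0]),
            linear_predictor=lp,
            probability=expit(lp),
            converged=True,
            screened=screened,
        )
    result = _fit_logistic(subjects[list(selected)], y)
    return LogisticResult(
        members=result.members,
        table=result.table,
        intercept=result.intercept,
        linear_predictor=result.linear_predictor,
        probability=result.probability,
        converged=result.converged,
        separation=result.separation,
        collinear=result.collinear,
        screened=screened,
    )


@dataclass(frozen=True)
class CombinedROC:
    name: str
    members: tuple[str, ...]
    logistic: LogisticResult
    scores: np.ndarray
    roc: ROCResult


def combine_predictors(
    subjects: pd.DataFrame, members, name: str = "combined"
) -> CombinedROC:
    """Logistic combination of a biomarker panel, scored by ROC.

    The joint logistic model's predicted probability is the combined score
    per subject; its ROC (direction "higher": larger probability means
    LVI-positive) is returned alongside the fit.  A single-member panel
    reproduces that biomarker's own ROC, since the logistic map is
    monotone.
    """
    members = tuple(members)
    if not members:
        raise ValueError("members must be non-empty")
    y = subjects["lvi"].to_numpy(dtype=int)
    logistic = _fit_logistic(subjects[list(members)], y)
    scores = logistic.probability
    roc = roc_analysis(scores, y, direction="higher")
    return CombinedROC(name=name, members=members, logistic=logistic, scores=scores, roc=roc)


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    alpha_normal: float = 0.05
    p_enter: float = 0.1
    p_independent: float = 0.05
    biomarkers: tuple[str, ...] = BIOMARKERS


@dataclass
class StudyReport:
    """Tables of the full analysis: agreement, comparison, regression, ROC."""

    icc_table: pd.DataFrame
    comparison_table: pd.DataFrame
    univariate_table: pd.DataFrame
    multivariate: LogisticResult
    independent_predictors: tuple[str, ...]
    roc_table: pd.DataFrame
    combinations: dict[str, CombinedROC]
    config: PipelineConfig

    def to_text(self) -> str:
        lines = ["# Study report", "", "## Inter-reader agreement (ICC)"]
        lines.append(self.icc_table.to_string(index=False))
        lines += ["", "## Group comparison (LVI+ vs LVI-)"]
        lines.append(self.comparison_table.to_string(index=False))
        lines += ["", "## Univariate logistic regression"]
        lines.append(self.univariate_table.to_string(index=False))
        lines += ["", "## Multivariate logistic regression"]
        lines.append(
            self.multivariate.table.to_string(index=False)
            if len(self.multivariate.table)
            else "(no biomarker passed the univariate screen)"
        )
        lines.append(
            "independent predictors: "
            + (", ".join(self.independent_predictors) or "none")
        )
        lines += ["", "## ROC analysis"]
        lines.append(self.roc_table.to_string(index=False))
        return "\n".join(lines) + "\n"


def subject_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse the subject x reader cohort to one row per subject.

    Biomarker values are averaged over the two readers (the per-subject
    measurement entering comparison, ROC and regression); the LVI label is
    carried through.
    """
    markers = [c for c in BIOMARKERS if c in cohort.columns]
    grouped = cohort.groupby("subject_id", sort=False)
    out = grouped[markers].mean()
    out.insert(0, "lvi", grouped["lvi"].first())
    return out.reset_index()


def _reader_vectors(cohort: pd.DataFrame, marker: str):
    wide = cohort.pivot_table(
        index="subject_id", columns="reader", values=marker, sort=False
    )
    if wide.shape[1] != 2:
        raise ValueError("cohort must contain exactly two readers")
    return wide[1].to_numpy(), wide[2].to_numpy()


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> StudyReport:
    """Run the full statistics layer on a two-reader cohort table.

    Stages (failures are re-raised with the stage name): ICC per biomarker,
    normality-routed group comparison, per-biomarker ROC, univariate and
    multivariate logistic regression, and logistic combinations for the
    preset panels (PET, IVIM, DKI, MTV+D, ALL).  The whole report is a
    deterministic function of the cohort table.
    """
    config = config or PipelineConfig()
    markers = config.biomarkers
    missing = [m for m in (*markers, "lvi", "reader", "subject_id") if m not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if set(cohort["reader"].unique()) != {1, 2}:
        raise ValueError("cohort must contain readers 1 and 2")

    def _stage(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    subjects = subject_table(cohort)
    y = subjects["lvi"].to_numpy(dtype=int)

    icc_rows = []
    for m in markers:
        r1, r2 = _reader_vectors(cohort, m)
        res = _stage(f"icc:{m}", compute_icc, r1, r2)
        icc_rows.append({"biomarker": m, "icc": res.icc, "band": res.band})
    icc_table = pd.DataFrame(icc_rows)

    cmp_rows = []
    for m in markers:
        res = _stage(
            f"compare:{m}",
            compare_groups,
            subjects.loc[subjects["lvi"] == 1, m],
            subjects.loc[subjects["lvi"] == 0, m],
            config.alpha_normal,
            m,
        )
        cmp_rows.append(
            {
                "biomarker": m,
                "route": res.route,
                "statistic": res.statistic,
                "p": res.p,
                "summary_kind": res.summary_kind,
                "pos_summary": res.pos_summary,
                "neg_summary": res.neg_summary,
            }
        )
    comparison_table = pd.DataFrame(cmp_rows)

    uni_rows = []
    for m in markers:
        res = _stage(f"univariate:{m}", univariate_logistic, subjects[m], y, m)
        row = res.table.iloc[0]
        uni_rows.append(
            {
                "biomarker": m,
                "or": row["or"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "p": row["p"],
            }
        )
    univariate_table = pd.DataFrame(uni_rows)

    multivariate = _stage(
        "multivariate", multivariate_selection, subjects, config.p_enter, markers
    )
    independent = tuple(
        multivariate.table.loc[
            multivariate.table["p"] < config.p_independent, "term"
        ]
    )

    roc_rows = []
    for m in markers:
        res = _stage(f"roc:{m}", roc_analysis, subjects[m], y, "auto")
        roc_rows.append({"name": m, **_roc_row(res)})
    combinations = {}
    for name, members in PRESET_COMBINATIONS.items():
        combo = _stage(f"roc:{name}", combine_predictors, subjects, members, name)
        combinations[name] = combo
        roc_rows.append({"name": name, **_roc_row(combo.roc)})
    roc_table = pd.DataFrame(roc_rows)

    return StudyReport(
        icc_table=icc_table,
        comparison_table=comparison_table,
        univariate_table=univariate_table,
        multivariate=multivariate,
        independent_predictors=independent,
        roc_table=roc_table,
        combinations=combinations,
        config=config,
    )


def _roc_row(res: ROCResult) -> dict:
    return {
        "auc": res.auc,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "cutoff": res.cutoff,
        "specificity": res.specificity,
        "sensitivity": res.sensitivity,
        "fpr": res.fpr,
        "fnr": res.fnr,
        "direction": res.direction,
    }
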