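"""Statistical decision procedure for the two-group, two-condition trial.

The study design has one between-subject factor (group: EG vs CG) and one
within-subject factor (session or trial pair).  The procedure is:

1. check normality (Shapiro-Wilk on residuals about cell means),
   homoscedasticity (Levene), and sphericity (trivially satisfied with
   two within-subject levels);
2. if the data are homoscedastic and spherical but not normal, apply a
   natural log transform (only when all values are positive);
3. run a two-factor mixed-design ANOVA (split-plot sums of squares),
   reporting F, degrees of freedom and two-sided p for the within main
   effect, the between main effect, and the interaction;
4. for the single Training trial, compare EG vs CG with an independent
   t-test when normality and homoscedasticity hold, or a Mann-Whitney U
   test (U = min(U1, U2), midranks for ties) when the data are
   significantly non-normal.

Two-sided p < 0.05 is the significance criterion throughout, starred as
*p < 0.05, **p < 0.01, ***p < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA = 0.05


def significance_stars(p: float) -> str:
    """Star label: *p < 0.05, **p < 0.01, ***p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AssumptionReport:
    normal: bool
    normal_p: float
    homoscedastic: bool
    homoscedastic_p: float
    spherical: bool
    spherical_p: float
    transform_applied: str = "none"  # 'none' | 'natural_log'


@dataclass(frozen=True)
class StatResult:
    effect: str            # 'trial_main' | 'group_main' | 'interaction' | 'two_sample'
    statistic_kind: str    # 'F' | 't' | 'U' | 'chi2'
    statistic: float
    df: tuple[float, ...]  # (df1, df2) for F; (df,) for t; () for U
    p: float
    stars: str
    assumptions: AssumptionReport | None = None

    @classmethod
    def make(cls, effect, kind, statistic, df, p, assumptions=None):
        return cls(effect, kind, float(statistic), tuple(df), float(p),
                   significance_stars(p), assumptions)


# ---------------------------------------------------------------------------
# assumption checks and the transform rule
# ---------------------------------------------------------------------------

def check_assumptions(
    df: pd.DataFrame, alpha: float = ALPHA, value_col: str = "value"
) -> AssumptionReport:
    """Normality / homoscedasticity / sphericity checks on grouped values.

    ``df`` needs columns ``group`` and ``value``; an optional
    ``condition`` column defines the within-subject levels.  Normality is
    Shapiro-Wilk on residuals about the group x condition cell means;
    homoscedasticity is Levene across the cells; sphericity is trivially
    satisfied when there are at most two within-subject levels (the only
    design this procedure supports).

    The transform decision follows the rule: apply a natural log only
    when homoscedasticity and sphericity hold, normality fails, and all
    values are positive.  The returned report has ``transform_applied``
    still 'none'; :func:`apply_transform_rule` performs the transform.
    """
    if "group" not in df.columns or value_col not in df.columns:
        raise ValidationError("need 'group' and value columns")
    keys = ["group"] + (["condition"] if "condition" in df.columns else [])
    cells = df.groupby(keys)[value_col]
    if (cells.size() < 3).any():
        raise ValidationError("need >= 3 observations per cell")
    residuals = df[value_col] - cells.transform("mean")
    if np.allclose(residuals, residuals.iloc[0]):
        # constant residuals: Shapiro is undefined; treat as normal
        normal_p = 1.0
    else:
        normal_p = float(stats.shapiro(residuals).pvalue)
    cell_values = [v.to_numpy() for _, v in cells]
    if all(np.ptp(v) == 0 for v in cell_values):
        homo_p = 1.0
    else:
        homo_p = float(stats.levene(*cell_values).pvalue)
    n_within = df["condition"].nunique() if "condition" in df.columns else 1
    if n_within > 2:
        raise ValidationError("procedure supports at most 2 within-subject "
                              "levels; sphericity testing is out of scope")
    spherical_p = 1.0  # trivially satisfied below 3 levels
    return AssumptionReport(
        normal=normal_p >= alpha, normal_p=normal_p,
        homoscedastic=homo_p >= alpha, homoscedastic_p=homo_p,
        spherical=True, spherical_p=spherical_p,
    )


def apply_transform_rule(
    df: pd.DataFrame, report: AssumptionReport, value_col: str = "value"
) -> tuple[pd.DataFrame, AssumptionReport]:
    """Apply the natural-log rule and return (possibly transformed) data.

    The transform fires only when the data are homoscedastic and
    spherical but not normal; non-positive values make the transform
    impossible, in which case it is skipped and flagged in the log.
    Already-normal data are returned untouched (idempotence).
    """
    wants = report.homoscedastic and report.spherical and not report.normal
    if not wants:
        return df, report
    if (df[value_col] <= 0).any():
        logger.warning("log transform indicated but values are not all "
                       "positive; transform skipped")
        return df, report
    out = df.copy()
    out[value_col] = np.log(out[value_col])
    new_report = check_assumptions(out, value_col=value_col)
    return out, replace(new_report, transform_applied="natural_log")


# ---------------------------------------------------------------------------
# mixed-design (split-plot) ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(df: pd.DataFrame, alpha: float = ALPHA) -> dict[str, StatResult]:
    """Two-factor mixed ANOVA: between factor ``group``, within ``condition``.

    ``df`` needs columns subject_id, group, condition, value with one
    value per subject per condition.  Subjects missing a condition are
    excluded listwise (logged).  Returns StatResults keyed by
    'trial_main' (within), 'group_main' (between), and 'interaction',
    computed from split-plot sums of squares:

    * between-subject stratum: group tested against subjects-within-group,
    * within-subject stratum: condition and group x condition tested
      against the condition x subject residual.

    Effects with zero sum of squares report F = 0, p = 1 (constant data).
    """
    for col in ("subject_id", "group", "condition", "value"):
        if col not in df.columns:
            raise ValidationError(f"mixed_anova: missing column {col!r}")
    wide = df.pivot_table(index=["subject_id", "group"], columns="condition",
                          values="value", aggfunc="first")
    n_before = wide.shape[0]
    wide = wide.dropna()
    if wide.shape[0] < n_before:
        logger.info("mixed_anova: %d subjects excluded listwise",
                    n_before - wide.shape[0])
    conditions = list(wide.columns)
    k = len(conditions)
    if k < 2:
        raise ValidationError("need >= 2 within-subject conditions")
    groups = wide.index.get_level_values("group").to_numpy()
    uniq_groups = np.unique(groups)
    g = uniq_groups.size
    if g < 2:
        raise ValidationError("need >= 2 groups")
    y = wide.to_numpy(dtype=float)  # subjects x conditions
    n_subj = y.shape[0]
    if n_subj < g + 1:
        raise ValidationError("too few subjects for a mixed ANOVA")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for gr in uniq_groups:
        m = groups == gr
        n_g = int(m.sum())
        ss_group += k * n_g * (y[m].mean() - grand) ** 2
        cell = y[m].mean(axis=0)
        ss_cells += n_g * ((cell - grand) ** 2).sum()
    ss_subj_within = ss_subjects - ss_group
    ss_cond = n_subj * ((cond_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_cond
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_cells - ss_subj_within

    df_group, df_subj = g - 1, n_subj - g
    df_cond = k - 1
    df_inter = (g - 1) * (k - 1)
    df_error = (n_subj - g) * (k - 1)

    def f_result(effect, ss_eff, df_eff, ss_err, df_err):
        ss_eff = max(ss_eff, 0.0)
        ss_err = max(ss_err, 0.0)
        if ss_eff <= 1e-12 * max(ss_total, 1.0):
            return StatResult.make(effect, "F", 0.0, (df_eff, df_err), 1.0)
        ms_eff = ss_eff / df_eff
        if ss_err <= 0 or df_err <= 0:
            return StatResult.make(effect, "F", float("inf"),
                                   (df_eff, df_err), 0.0)
        ms_err = ss_err / df_err
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, df_eff, df_err))
        return StatResult.make(effect, "F", f, (df_eff, df_err), p)

    return {
        "trial_main": f_result("trial_main", ss_cond, df_cond,
                               ss_error, df_error),
        "group_main": f_result("group_main", ss_group, df_group,
                               ss_subj_within, df_subj),
        "interaction": f_result("interaction", ss_inter, df_inter,
                                ss_error, df_error),
    }


def run_mixed_procedure(
    df: pd.DataFrame, alpha: float = ALPHA
) -> tuple[dict[str, StatResult], AssumptionReport]:
    """Full decision procedure: assumption checks, transform rule, ANOVA."""
    report = check_assumptions(df, alpha=alpha)
    data, report = apply_transform_rule(df, report)
    results = mixed_anova(data, alpha=alpha)
    results = {k: replace(v, assumptions=report) for k, v in results.items()}
    return results, report


# ---------------------------------------------------------------------------
# training-trial two-sample comparison
# ---------------------------------------------------------------------------

def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (reported as min(U1, U2)) and two-sided p.

    U1 counts pairs (xi, yj) with xi > yj, ties counted 1/2 (midranks);
    U1 + U2 = n1 * n2 by construction.  The p-value uses the
    tie-corrected normal approximation (exact for small untied samples
    via scipy's automatic method selection).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return min(u1, u2), float(res.pvalue)


def compare_training(
    eg: np.ndarray, cg: np.ndarray, alpha: float = ALPHA
) -> StatResult:
    """EG-vs-CG comparison for the Training trial.

    Branches on the assumption checks: an independent two-sample t-test
    when normality (Shapiro-Wilk per group) and homoscedasticity (Levene)
    hold; Welch's t-test when normal but heteroscedastic; a Mann-Whitney
    U test when significantly non-normal.
    """
    eg = np.asarray(eg, dtype=float)
    cg = np.asarray(cg, dtype=float)
    if eg.size < 2 or cg.size < 2:
        raise ValidationError("need >= 2 values per group")
    pooled = np.concatenate([eg, cg])
    if np.ptp(pooled) == 0:
        raise ValidationError("all-constant data: no comparison possible")
    normal_ps = []
    for arr in (eg, cg):
        if np.ptp(arr) == 0 or arr.size < 3:
            normal_ps.append(1.0)
        else:
            normal_ps.append(float(stats.shapiro(arr).pvalue))
    normal_p = min(normal_ps)
    homo_p = float(stats.levene(eg, cg).pvalue)
    report = AssumptionReport(
        normal=normal_p >= alpha, normal_p=normal_p,
        homoscedastic=homo_p >= alpha, homoscedastic_p=homo_p,
        spherical=True, spherical_p=1.0,
    )
    if not report.normal:
        u, p = mann_whitney_u(eg, cg)
        return StatResult.make("two_sample", "U", u, (), p, report)
    t, p = stats.ttest_ind(eg, cg, equal_var=report.homoscedastic)
    if report.homoscedastic:
        dof = eg.size + cg.size - 2.0
    else:  # Welch-Satterthwaite
        v1, v2 = eg.var(ddof=1) / eg.size, cg.var(ddof=1) / cg.size
        dof = (v1 + v2) ** 2 / (v1 ** 2 / (eg.size - 1) + v2 ** 2 / (cg.size - 1))
    return StatResult.make("two_sample", "t", t, (dof,), p, report)


# ---------------------------------------------------------------------------
# baseline descriptive table
# ---------------------------------------------------------------------------

def pearson_chi2(table: np.ndarray) -> tuple[float, float, float, bool]:
    """Pearson chi-squared on a contingency table (no continuity correction).

    Returns (chi2, df, p, low_expected_flag); the flag marks any expected
    cell count below 1.
    """
    table = np.asarray(table, dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(dof), float(p), bool((expected < 1).any())


def baseline_table(
    df: pd.DataFrame, as_printed: bool = False
) -> pd.DataFrame:
    """Descriptive baseline comparison of EG vs CG (Day 1 data).

    ``df`` needs columns subject_id, group, variable, value, kind
    ('continuous' or 'categorical').  Continuous variables are reported
    as mean +/- SD per group with a two-sample t-test p-value
    (``as_printed=True`` instead pairs subjects by row order and uses a
    paired t-test — statistically questionable for independent groups but
    offered as a reporting mode); categorical variables as n (%) per
    group with a Pearson chi-squared p-value.
    """
    for col in ("subject_id", "group", "variable", "value", "kind"):
        if col not in df.columns:
            raise ValidationError(f"baseline_table: missing column {col!r}")
    if not set(df["group"]) >= {"EG", "CG"}:
        raise ValidationError("baseline_table: need both EG and CG rows")
    rows = []
    for var, sub in df.groupby("variable", sort=True):
        kind = sub["kind"].iloc[0]
        eg = sub[sub["group"] == "EG"]["value"]
        cg = sub[sub["group"] == "CG"]["value"]
        if kind == "continuous":
            eg_v, cg_v = eg.astype(float), cg.astype(float)
            if as_printed:
                n = min(eg_v.size, cg_v.size)
                t, p = stats.ttest_rel(eg_v.iloc[:n], cg_v.iloc[:n])
            else:
                t, p = stats.ttest_ind(eg_v, cg_v)
            if np.isnan(p):  # zero-variance identical samples
                t, p = 0.0, 1.0
            rows.append((var, kind,
                         f"{eg_v.mean():.2f} (±{eg_v.std(ddof=1):.2f})",
                         f"{cg_v.mean():.2f} (±{cg_v.std(ddof=1):.2f})",
                         "t", float(t), float(p), significance_stars(p), ""))
        elif kind == "categorical":
            levels = sorted(sub["value"].astype(str).unique())
            counts = np.array([
                [int((eg.astype(str) == lv).sum()) for lv in levels],
                [int((cg.astype(str) == lv).sum()) for lv in levels],
            ])
            if counts.sum(axis=0).min() == 0 or len(levels) < 2:
                chi2, p, flag = 0.0, 1.0, False
            else:
                # identical proportions give chi2 = 0 exactly
                chi2, _, p, flag = pearson_chi2(counts)
            desc = []
            for gi, grp_n in enumerate(counts):
                tot = grp_n.sum()
                desc.append("; ".join(
                    f"{lv}: {c} ({100.0 * c / tot:.0f}%)"
                    for lv, c in zip(levels, grp_n)))
            rows.append((var, kind, desc[0], desc[1], "chi2", float(chi2),
                         float(p), significance_stars(p),
                         "low_expected" if flag else ""))
        else:
            raise ValidationError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows, columns=[
        "variable", "kind", "EG", "CG", "statistic_kind", "statistic",
        "p", "stars", "flag"])


# ---------------------------------------------------------------------------
# whole-protocol analysis over summary tables
# ---------------------------------------------------------------------------

#: trial pairs analyzed with the mixed ANOVA
ANALYSIS_PAIRS = {
    "Gait": ("GaitBaseline", "GaitPost"),
    "Test": ("TestPre", "TestPost"),
}


def analyze_gait_protocol(
    summaries: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Run the full trial-statistics battery over a summary table.

    For each metric and each statistic (per-subject mean and SD): the
    mixed ANOVA on the Gait pair (GaitBaseline vs GaitPost) and the Test
    pair (TestPre vs TestPost), plus the EG-vs-CG two-sample comparison
    on the Training trial.  Returns a tidy results frame.
    """
    needed = {"subject_id", "group", "trial", "metric", "mean", "sd"}
    if not needed <= set(summaries.columns):
        raise ValidationError(f"summary table needs columns {sorted(needed)}")
    rows = []
    for metric, msub in summaries.groupby("metric", sort=True):
        for stat_name in ("mean", "sd"):
            for pair_name, (c0, c1) in ANALYSIS_PAIRS.items():
                sub = msub[msub["trial"].isin((c0, c1))]
                if sub.empty:
                    continue
                data = sub.rename(columns={"trial": "condition",
                                           stat_name: "value"})
                data = data[["subject_id", "group", "condition", "value"]].dropna()
                try:
                    results, report = run_mixed_procedure(data, alpha=alpha)
                except ValidationError as exc:
                    logger.warning("skipping %s %s %s: %s", pair_name, metric,
                                   stat_name, exc)
                    continue
                for eff, r in results.items():
                    rows.append((pair_name, metric, stat_name, eff,
                                 r.statistic_kind, r.statistic,
                                 r.df[0] if r.df else np.nan,
                                 r.df[1] if len(r.df) > 1 else np.nan,
                                 r.p, r.stars, report.transform_applied))
            training = msub[msub["trial"] == "Training"].dropna(
                subset=[stat_name])
            eg = training[training["group"] == "EG"][stat_name].to_numpy()
            cg = training[training["group"] == "CG"][stat_name].to_numpy()
            if eg.size >= 2 and cg.size >= 2:
                try:
                    r = compare_training(eg, cg, alpha=alpha)
                except ValidationError as exc:
                    logger.warning("skipping Training %s %s: %s", metric,
                                   stat_name, exc)
                else:
                    rows.append(("Training", metric, stat_name, "two_sample",
                                 r.statistic_kind, r.statistic,
                                 r.df[0] if r.df else np.nan, np.nan,
                                 r.p, r.stars, "none"))
    return pd.DataFrame(rows, columns=[
        "analysis", "metric", "statistic_of", "effect", "statistic_kind",
        "statistic", "df1", "df2", "p", "stars", "transform"])
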