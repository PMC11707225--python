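"""Inferential layer: 2x2 mixed ANOVA, effect sizes, stepwise regression.

The balance statistics are analysed in a 2 (group: CAI vs HC, between) x
2 (condition: static vs moving, within) mixed design with partial eta
squared effect sizes, Bonferroni-adjusted pairwise post hocs (group within
condition, condition within group; m = 2 per family), and a forward
stepwise multiple regression of the TTB-ML mean of minima on the 12 RMS
joint angular-velocity channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats


class DesignError(ValueError):
    pass


class UndefinedEffectError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


ETA_SQ_BANDS = ((0.01, "small"), (0.06, "moderate"), (0.14, "large"))
COHENS_D_BANDS = ((0.0, "small"), (0.40, "moderate"), (0.80, "large"))


def interpret_partial_eta_sq(value: float) -> str:
    label = "negligible"
    for lo, name in ETA_SQ_BANDS:
        if value > lo or (value == lo and name == "small"):
            label = name
    return label


def interpret_cohens_d(value: float) -> str:
    v = abs(value)
    if v > 0.80:
        return "large"
    if v >= 0.40:
        return "moderate"
    return "small"


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """Omnibus table (group, condition, interaction) plus post hocs.

    ``anova`` rows carry F, df pair, p and partial eta squared
    (SS_effect/(SS_effect + SS_error), each effect against its own error
    term). ``posthoc`` holds the Bonferroni-adjusted pairwise comparisons
    (m = 2 within each framing) with 95% CIs of the mean differences.
    """

    anova: pd.DataFrame
    posthoc: pd.DataFrame


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    between: str = "group",
    within: str = "condition",
) -> MixedAnovaResult:
    """Two-way mixed ANOVA on a balanced long-format design.

    Every subject must contribute exactly one value per within level and
    both factors must have exactly two levels. Normality is the caller's
    responsibility (see :func:`shapiro_diagnostic`).
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise DesignError("missing values in the response")
    g_levels = sorted(df[between].unique())
    c_levels = sorted(df[within].unique())
    if len(g_levels) != 2 or len(c_levels) != 2:
        raise DesignError(
            f"need exactly 2 levels per factor, got {g_levels} x {c_levels}")
    counts = df.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise DesignError("unbalanced design: every subject needs one value "
                          "per within-factor level")

    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between,
                         subject=subject)
    aov = aov.rename(columns={"Source": "effect", "DF1": "df1", "DF2": "df2",
                              "p_unc": "p", "np2": "partial_eta_sq"})
    aov["effect"] = aov["effect"].replace({"Interaction": "interaction"})
    aov["magnitude"] = aov["partial_eta_sq"].map(interpret_partial_eta_sq)
    anova = aov[["effect", "F", "df1", "df2", "p", "partial_eta_sq",
                 "magnitude"]].reset_index(drop=True)

    rows = []
    m = 2  # comparisons per family
    # group within condition: independent t
    for c in c_levels:
        sub = df[df[within] == c]
        a = sub.loc[sub[between] == g_levels[0], dv].to_numpy()
        b = sub.loc[sub[between] == g_levels[1], dv].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        dof = a.size + b.size - 2
        crit = stats.t.ppf(0.975, dof)
        rows.append(dict(
            family="group_within_condition", level=c,
            contrast=f"{g_levels[0]} - {g_levels[1]}",
            diff=diff, ci_low=diff - crit * se, ci_high=diff + crit * se,
            t=float(t), p_raw=float(p), p_bonf=min(1.0, m * float(p)),
            cohens_d=cohens_d(b, a),
        ))
    # condition within group: paired t
    for g in g_levels:
        sub = df[df[between] == g].pivot(index=subject, columns=within,
                                         values=dv)
        a = sub[c_levels[0]].to_numpy()
        b = sub[c_levels[1]].to_numpy()
        t, p = stats.ttest_rel(a, b)
        d = a - b
        diff = d.mean()
        se = d.std(ddof=1) / np.sqrt(d.size)
        crit = stats.t.ppf(0.975, d.size - 1)
        rows.append(dict(
            family="condition_within_group", level=g,
            contrast=f"{c_levels[0]} - {c_levels[1]}",
            diff=diff, ci_low=diff - crit * se, ci_high=diff + crit * se,
            t=float(t), p_raw=float(p), p_bonf=min(1.0, m * float(p)),
            cohens_d=cohens_d(b, a),
        ))
    return MixedAnovaResult(anova=anova, posthoc=pd.DataFrame(rows))


def mixed_anova_ss_decomposition(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    """From-scratch sums-of-squares decomposition of the balanced 2x2 design.

    Textbook split-plot partition: the between effect is tested against
    subjects-within-groups, the within and interaction effects against the
    within-x-subjects residual. Serves as an independent check of
    :func:`mixed_anova_2x2`.
    """
    df = data[[subject, between, within, dv]].copy()
    g_levels = sorted(df[between].unique())
    c_levels = sorted(df[within].unique())
    a, c = len(g_levels), len(c_levels)
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv,
                          observed=True)
    y = wide.to_numpy()            # subjects x conditions
    grp = wide.index.get_level_values(between).to_numpy()
    n_per = np.array([(grp == g).sum() for g in g_levels])
    if len(set(n_per)) != 1:
        # unequal group sizes are fine for the decomposition; keep going
        pass
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[grp == g].mean() for g in g_levels])
    cond_means = y.mean(axis=0)
    cell_means = np.array([[y[grp == g][:, j].mean() for j in range(c)]
                           for g in g_levels])

    ss_between_subj = c * np.sum((subj_means - grand) ** 2)
    ss_group = c * np.sum(n_per * (group_means - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_total = np.sum((y - grand) ** 2)
    ss_within_subj = ss_total - ss_between_subj
    ss_cond = y.shape[0] * np.sum((cond_means - grand) ** 2)
    ss_inter = np.sum(
        n_per[:, None] * (cell_means - group_means[:, None]
                          - cond_means[None, :] + grand) ** 2)
    ss_resid = ss_within_subj - ss_cond - ss_inter

    n_subj = y.shape[0]
    df_group, df_err_b = a - 1, n_subj - a
    df_cond = c - 1
    df_inter = (a - 1) * (c - 1)
    df_err_w = (n_subj - a) * (c - 1)
    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        ("group", ss_group, df_group, ss_subj_within, df_err_b),
        ("condition", ss_cond, df_cond, ss_resid, df_err_w),
        ("interaction", ss_inter, df_inter, ss_resid, df_err_w),
    ]:
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = stats.f.sf(F, df_eff, df_err)
        rows.append(dict(effect=name, SS=ss_eff, SS_error=ss_err,
                         df1=df_eff, df2=df_err, F=F, p=p,
                         partial_eta_sq=ss_eff / (ss_eff + ss_err)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(a, b) -> float:
    """Cohen's d, (mean_b - mean_a) / pooled SD (n-1 weights)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                 / (a.size + b.size - 2))
    if sp == 0:
        raise UndefinedEffectError("pooled SD is zero")
    return float((b.mean() - a.mean()) / sp)


def shapiro_diagnostic(values) -> dict:
    """Shapiro-Wilk normality diagnostic (never gates any computation)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return {"W": float(w), "p": float(p)}


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    """Forward-stepwise OLS selection trace and final fit.

    ``steps`` is the event log (predictor entered/removed, cumulative R^2
    after the event); ``coefficients`` the final model's slopes with 95%
    CIs and p values; ``r_squared`` the final coefficient of determination.
    """

    steps: pd.DataFrame
    selected: list
    coefficients: pd.DataFrame
    r_squared: float
    model: object  # statsmodels results of the final fit


def stepwise_regression(
    y,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseModel:
    """Forward stepwise multiple linear regression with backward pruning.

    At each step the candidate with the smallest partial-F p value enters
    if p < ``p_enter``; after each entry, any included predictor whose p
    value has risen above ``p_remove`` is dropped (worst first). Entry and
    removal thresholds are reported in the step log.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values are not allowed")
    if len(y) != len(X):
        raise ValueError("outcome and candidate matrix must be paired")
    if len(y) <= X.shape[1] and len(y) < 4:
        raise ValueError("too few observations")

    def fit(cols):
        M = sm.add_constant(X[cols].to_numpy())
        if np.linalg.matrix_rank(M) < M.shape[1]:
            corr = np.corrcoef(X[cols].to_numpy().T)
            pair = cols[:2]
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    if abs(corr[i, j]) > 1 - 1e-10:
                        pair = (cols[i], cols[j])
            raise CollinearityError(
                f"perfect collinearity among selected predictors {pair}")
        return sm.OLS(y, M).fit()

    selected: list = []
    events = []
    while True:
        remaining = [c for c in X.columns if c not in selected]
        if not remaining:
            break
        best_p, best_col = np.inf, None
        for cand in remaining:
            res = fit(selected + [cand])
            p = res.pvalues[-1]
            if p < best_p:
                best_p, best_col = p, cand
        if best_col is None or best_p >= p_enter:
            break
        selected.append(best_col)
        res = fit(selected)
        events.append(dict(event="enter", predictor=best_col,
                           p=float(best_p), r_squared=float(res.rsquared),
                           p_enter=p_enter, p_remove=p_remove))
        # backward pruning
        while len(selected) > 1:
            res = fit(selected)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] <= p_remove:
                break
            dropped = selected.pop(worst)
            res = fit(selected) if selected else None
            events.append(dict(
                event="remove", predictor=dropped, p=float(pvals[worst]),
                r_squared=float(res.rsquared) if res is not None else 0.0,
                p_enter=p_enter, p_remove=p_remove))

    if selected:
        final = fit(selected)
        ci = final.conf_int()
        coef = pd.DataFrame({
            "predictor": ["intercept"] + selected,
            "beta": final.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": final.pvalues,
        }).reset_index(drop=True)
        r2 = float(final.rsquared)
    else:
        final = None
        coef = pd.DataFrame(columns=["predictor", "beta", "ci_low",
                                     "ci_high", "p"])
        r2 = 0.0
    return StepwiseModel(
        steps=pd.DataFrame(events), selected=selected,
        coefficients=coef, r_squared=r2, model=final)
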