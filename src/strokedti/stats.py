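"""The study's statistical battery over long-format study tables.

Measures (diffusion metrics and behavior scores) live in a long table of
(subject_id, group, day, measure, value) records.  Group-by-time effects
use a split-plot repeated-measures ANOVA (subject-random-intercept model;
fitted by mixed model when the design is unbalanced), pairwise lesion
comparisons use Welch t with Holm-Sidak correction, fiber densities use
Kruskal-Wallis with Dunn post hoc and Mann-Whitney, and lesion-behavior
coupling uses Pearson/Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, IncompleteSeriesError, ParameterError

ALPHA = 0.05

STUDY_TABLE_COLUMNS = ("subject_id", "group", "day", "measure", "value")


@dataclass
class TestResult:
    test: str
    comparison: str
    statistic: float
    p_raw: float
    p_adj: float
    adjustment: str
    significant: bool

    @classmethod
    def make(cls, test, comparison, statistic, p_raw, p_adj=None,
             adjustment="none", alpha=ALPHA):
        p_adj = p_raw if p_adj is None else p_adj
        return cls(test, comparison, float(statistic), float(p_raw),
                   float(p_adj), adjustment, bool(p_adj < alpha))


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(STUDY_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise DesignError(f"study table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "day", "measure"])
    if dup.any():
        raise DesignError("study table has duplicate (subject, day, measure) rows")
    return table


# ---------------------------------------------------------------------------
# pairwise t tests with Holm-Sidak correction


def _welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def holm_sidak_ttests(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[str] | None = None,
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> list[TestResult]:
    """Two-tailed (Welch by default) t tests with Holm-Sidak step-down.

    Sorted raw p-values p_(i) get adjusted p_(i) = 1 - (1 - p_(i))^(m-i+1),
    enforced monotone nondecreasing.
    """
    if labels is None:
        labels = [f"pair_{i}" for i in range(len(pairs))]
    stats_p = [_welch_t(a, b, equal_var) for a, b in pairs]
    raw = np.array([p for _, p in stats_p])
    if len(raw) == 1:
        adj = raw.copy()
    else:
        _, adj, _, _ = multipletests(raw, alpha=alpha, method="holm-sidak")
    return [
        TestResult.make("welch_t" if not equal_var else "pooled_t", lab, t, p,
                        pa, "holm-sidak", alpha)
        for lab, (t, p), pa in zip(labels, stats_p, adj)
    ]


# ---------------------------------------------------------------------------
# group x time (split-plot / mixed) analysis


@dataclass
class SplitPlotResult:
    f_group: float
    p_group: float
    f_day: float
    p_day: float
    f_interaction: float
    p_interaction: float


def split_plot_anova(group_arrays: Sequence[np.ndarray]) -> SplitPlotResult:
    """Split-plot RM-ANOVA: group between subjects, day repeated within.

    ``group_arrays[g]`` is an (n_g, n_days) matrix of one group's values,
    complete and over a common day grid.  All-equal data returns F = 0,
    p = 1 for every effect.
    """
    ys = [np.asarray(a, float) for a in group_arrays]
    if len(ys) < 2 or any(y.ndim != 2 for y in ys):
        raise DesignError("need >= 2 groups of (subjects x days) matrices")
    t = ys[0].shape[1]
    if any(y.shape[1] != t for y in ys) or t < 2:
        raise DesignError("all groups need the same >= 2 days")
    if any(y.shape[0] < 2 for y in ys):
        raise DesignError("each group needs >= 2 subjects")
    all_y = np.concatenate(ys, axis=0)
    n_total = all_y.shape[0]
    grand = all_y.mean()
    ss_total = ((all_y - grand) ** 2).sum()
    if ss_total == 0:
        return SplitPlotResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0)
    subj_means = all_y.mean(axis=1)
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    ss_group = t * sum(y.shape[0] * (y.mean() - grand) ** 2 for y in ys)
    ss_subj_within = ss_between_subj - ss_group
    day_means = all_y.mean(axis=0)
    ss_day = n_total * ((day_means - grand) ** 2).sum()
    ss_inter = sum(
        y.shape[0] * ((y.mean(axis=0) - y.mean() - day_means + grand) ** 2).sum()
        for y in ys
    )
    ss_err = ss_total - ss_between_subj - ss_day - ss_inter
    g = len(ys)
    df_group, df_subj = g - 1, n_total - g
    df_day, df_inter = t - 1, (g - 1) * (t - 1)
    df_err = df_subj * (t - 1)

    def f_p(ss_effect, df_effect, ss_error, df_error):
        if ss_error <= 0 or df_error <= 0:
            return (0.0, 1.0) if ss_effect <= 1e-12 else (np.inf, 0.0)
        f = (ss_effect / df_effect) / (ss_error / df_error)
        return float(f), float(sps.f.sf(f, df_effect, df_error))

    fg, pg = f_p(ss_group, df_group, ss_subj_within, df_subj)
    fd, pd_ = f_p(ss_day, df_day, ss_err, df_err)
    fi, pi = f_p(ss_inter, df_inter, ss_err, df_err)
    return SplitPlotResult(fg, pg, fd, pd_, fi, pi)


def _mixed_model_tests(df: pd.DataFrame) -> SplitPlotResult:
    """Subject-random-intercept model for unbalanced/missing designs."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ C(group) * C(day)", df, groups=df["subject_id"], re_formula="1"
        )
        fit = model.fit(reml=False)
    wald = fit.wald_test_terms(scalar=True).table
    out = {}
    for key, name in (
        ("C(group)", "group"),
        ("C(day)", "day"),
        ("C(group):C(day)", "interaction"),
    ):
        row = wald.loc[key]
        out[name] = (float(row["statistic"]), float(row["pvalue"]))
    return SplitPlotResult(
        out["group"][0], out["group"][1],
        out["day"][0], out["day"][1],
        out["interaction"][0], out["interaction"][1],
    )


def group_time_test(
    table: pd.DataFrame,
    measure: str,
    groups: Sequence[str],
    days: Sequence[int],
    alpha: float = ALPHA,
    contrast_adjust: str = "bonferroni",
) -> list[TestResult]:
    """Two-factor group x day analysis of one measure.

    With complete balanced data this is a split-plot RM-ANOVA; with
    missing cells a subject-random-intercept mixed model is fitted.
    Per-day pairwise group contrasts (Bonferroni-adjusted) are emitted
    only when the interaction or a main effect is significant.
    """
    validate_study_table(table)
    df = table[
        (table["measure"] == measure)
        & table["group"].isin(groups)
        & table["day"].isin(days)
    ].copy()
    for gname in groups:
        if not (df["group"] == gname).any():
            raise DesignError(f"group {gname!r} entirely missing for {measure!r}")
    wide = df.pivot_table(index=["group", "subject_id"], columns="day",
                          values="value", aggfunc="mean")
    complete = not wide.isna().any().any() and set(wide.columns) == set(days)
    if complete:
        arrays = [wide.loc[gname].to_numpy() for gname in groups]
        res = split_plot_anova(arrays)
        method = "split-plot RM-ANOVA"
    else:
        res = _mixed_model_tests(df)
        method = "mixed-effects (random intercept)"
    results = [
        TestResult.make(method, f"{measure}: group", res.f_group, res.p_group, alpha=alpha),
        TestResult.make(method, f"{measure}: day", res.f_day, res.p_day, alpha=alpha),
        TestResult.make(method, f"{measure}: group x day", res.f_interaction,
                        res.p_interaction, alpha=alpha),
    ]
    gate = min(res.p_interaction, res.p_group, res.p_day) < alpha
    if gate:
        contrasts = []
        for d in days:
            sub = df[df["day"] == d]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    a = sub[sub["group"] == groups[i]]["value"].to_numpy()
                    b = sub[sub["group"] == groups[j]]["value"].to_numpy()
                    if len(a) < 2 or len(b) < 2:
                        continue
                    t, p = _welch_t(a, b, equal_var=False)
                    contrasts.append((f"{measure} day {d}: {groups[i]} vs {groups[j]}", t, p))
        m = len(contrasts)
        for lab, t, p in contrasts:
            results.append(
                TestResult.make("welch_t", lab, t, p, min(1.0, p * m),
                                contrast_adjust, alpha)
            )
    return results


# ---------------------------------------------------------------------------
# rank-based tests


def kruskal_dunn(
    samples: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = ALPHA,
    adjust: str = "holm",
) -> list[TestResult]:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post hoc z tests.

    The Dunn stage runs only when the omnibus H test is significant; its
    p-values are adjusted within the Holm family by default.
    """
    samples = [np.asarray(s, float) for s in samples]
    if len(samples) < 3:
        raise ParameterError("kruskal_dunn needs >= 3 groups")
    if any(len(s) < 2 for s in samples):
        raise ParameterError("each group needs n >= 2")
    if labels is None:
        labels = [f"group_{i}" for i in range(len(samples))]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return [TestResult.make("kruskal-wallis", "omnibus", 0.0, 1.0, alpha=alpha)]
    h, p_h = sps.kruskal(*samples)
    results = [TestResult.make("kruskal-wallis", "omnibus", h, p_h, alpha=alpha)]
    if p_h >= alpha:
        return results
    # Dunn z statistics on pooled mid-ranks with tie correction
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    offsets = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(samples))
    ]
    zs, ps, labs = [], [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt(var_base * (1 / len(samples[i]) + 1 / len(samples[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            zs.append(z)
            ps.append(2 * sps.norm.sf(abs(z)))
            labs.append(f"{labels[i]} vs {labels[j]}")
    _, adj, _, _ = multipletests(ps, alpha=alpha, method=adjust)
    for lab, z, p, pa in zip(labs, zs, ps, adj):
        results.append(TestResult.make("dunn", lab, z, p, pa, adjust, alpha))
    return results


def mann_whitney(a: np.ndarray, b: np.ndarray, alpha: float = ALPHA) -> TestResult:
    """Two-tailed Mann-Whitney U; exact for small tie-free samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 1 or len(b) < 1:
        raise ParameterError("each sample needs n >= 1")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult.make("mann-whitney", "a vs b", len(a) * len(b) / 2.0,
                               1.0, alpha=alpha)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult.make("mann-whitney", "a vs b", u, p, alpha=alpha)


# ---------------------------------------------------------------------------
# correlation and slope comparison


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    alpha: float = ALPHA,
    rng_seed: int = 0,
) -> tuple[float, float, float]:
    """Correlation coefficient, R^2, and two-sided p.

    The p-value uses the t transform for n >= 8 and an exact/randomized
    permutation distribution for smaller samples.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined: zero variance")
    if method == "pearson":
        stat = lambda a, b: sps.pearsonr(a, b)[0]  # noqa: E731
    elif method == "spearman":
        stat = lambda a, b: sps.spearmanr(a, b)[0]  # noqa: E731
    else:
        raise ParameterError("method must be 'pearson' or 'spearman'")
    r = float(stat(x, y))
    if len(x) < 8:
        res = sps.permutation_test(
            (x, y),
            lambda a, b: stat(a, b),
            permutation_type="pairings",
            n_resamples=40320,  # >= 7! so small samples are exact
            alternative="two-sided",
            rng=rng_seed,
        )
        p = float(res.pvalue)
    else:
        p = float(sps.pearsonr(x, y)[1] if method == "pearson"
                  else sps.spearmanr(x, y)[1])
    return r, r * r, p


def slope_compare(
    series: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = ALPHA,
) -> tuple[dict[str, float], float]:
    """Per-group OLS slope over time and a slope-equality test.

    Slopes come from per-group ordinary least squares; equality is tested
    by the day x group interaction F test in a pooled model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(series) < 2:
        raise ParameterError("need >= 2 groups")
    slopes = {}
    rows = []
    for gname, (days, values) in series.items():
        days = np.asarray(days, float)
        values = np.asarray(values, float)
        if len(np.unique(days)) < 3:
            raise IncompleteSeriesError("each group needs >= 3 timepoints")
        slopes[gname] = float(np.polyfit(days, values, 1)[0])
        rows.extend({"group": gname, "day": d, "value": v}
                    for d, v in zip(days, values))
    df = pd.DataFrame(rows)
    full = smf.ols("value ~ day * C(group)", df).fit()
    reduced = smf.ols("value ~ day + C(group)", df).fit()
    cmp_ = sm.stats.anova_lm(reduced, full)
    p = float(cmp_["Pr(>F)"].iloc[1])
    if np.isnan(p):  # identical fits (e.g. identical series)
        p = 1.0
    return slopes, p
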