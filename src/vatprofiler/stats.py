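"""Group comparisons, logistic regression, ROC and DeLong AUC tests.

Two- and three-group comparisons follow the usual clinical-table
conventions: Student's t / Mann-Whitney U (or ANOVA / Kruskal-Wallis)
chosen by a Shapiro-Wilk normality pre-check in ``auto`` mode, the chi²
test for categorical variables, and a Bonferroni-corrected significance
level of 0.05/3 = 0.0167 for the three pairwise follow-ups.

ROC analysis is implemented from first principles because the paired
comparison needs DeLong's structural components anyway: the AUC is the
tie-corrected Mann-Whitney probability that a positive outranks a
negative, its variance and confidence interval come from the DeLong
placement values, and the reported sensitivity/specificity sit at the
Youden-optimal cutoff (ties broken toward higher specificity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GroupComparison",
    "LogisticResult",
    "RocResult",
    "DeLongComparison",
    "compare_two",
    "compare_three",
    "chi_square",
    "proportion",
    "logistic_fit",
    "roc",
    "auc_mann_whitney",
    "delong_compare",
    "DiscriminationModel",
    "DiscriminationResults",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    summaries: dict[str, str]
    alpha_used: float
    significant: bool
    pairwise: dict[str, "GroupComparison"] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class LogisticResult:
    """Odds ratios with Wald 95% CIs from a maximum-likelihood logistic fit."""

    table: pd.DataFrame  # index: covariate; columns: odds_ratio, ci_low, ci_high, p_value
    converged: bool
    separation: bool = False

    def __post_init__(self) -> None:
        t = self.table
        if not self.separation:
            bad = (t["ci_low"] > t["odds_ratio"]) | (t["odds_ratio"] > t["ci_high"])
            if bad.any():
                raise ValueError(f"CI does not bracket OR for {list(t.index[bad])}")

    def odds_ratio(self, covariate: str) -> tuple[float, float, float, float]:
        row = self.table.loc[covariate]
        return (row["odds_ratio"], row["ci_low"], row["ci_high"], row["p_value"])


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity_pct: float
    specificity_pct: float
    cutoff: float
    auc_variance: float

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")
        for name in ("sensitivity_pct", "specificity_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} = {v} outside [0, 100]")


@dataclass
class DeLongComparison:
    auc_1: float
    auc_2: float
    difference: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# group comparisons


def _summaries(groups: Sequence[np.ndarray], names: Sequence[str], parametric: bool) -> dict:
    out = {}
    for g, name in zip(groups, names):
        g = np.asarray(g, dtype=float)
        if parametric:
            out[name] = f"{g.mean():.2f} ± {g.std(ddof=1):.2f}"
        else:
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            out[name] = f"{med:.2f} ({q1:.2f}, {q3:.2f})"
    return out


def _is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(values).pvalue > alpha


def _choose_parametric(groups: Sequence[np.ndarray], method: str) -> bool:
    if method == "parametric":
        return True
    if method == "nonparametric":
        return False
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    return all(_is_normal(g) for g in groups)


def compare_two(
    values_a: Sequence,
    values_b: Sequence,
    scale: str = "continuous",
    method: str = "auto",
    group_names: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-group comparison: t-test / Mann-Whitney U, or chi² for labels.

    For ``scale="categorical"`` the inputs are category labels; a 2×k
    contingency table is built and tested with :func:`chi_square`.
    """
    if scale == "categorical":
        a = pd.Series(list(values_a))
        b = pd.Series(list(values_b))
        cats = sorted(set(a) | set(b))
        table = np.array(
            [[int((a == c).sum()) for c in cats], [int((b == c).sum()) for c in cats]]
        )
        result = chi_square(table, alpha=alpha)
        result.summaries = {
            group_names[0]: ", ".join(f"{c}: {int((a == c).sum())}" for c in cats),
            group_names[1]: ", ".join(f"{c}: {int((b == c).sum())}" for c in cats),
        }
        return result
    if scale != "continuous":
        raise ValueError(f"unknown scale {scale!r}")

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    parametric = _choose_parametric([a, b], method)
    if parametric:
        stat, p = sps.ttest_ind(a, b)
        name = "t-test"
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0  # all observations tied: no evidence of difference
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
        name = "Mann-Whitney U"
    return GroupComparison(
        test_name=name,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        summaries=_summaries([a, b], group_names, parametric),
        alpha_used=alpha,
        significant=bool(p < alpha),
    )


def chi_square(table: np.ndarray, alpha: float = 0.05) -> GroupComparison:
    """Pearson chi² on a contingency table of counts.

    Yates continuity correction is applied only when some expected count
    falls below 5 (and the table is 2×2).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency table must be a 2-D array of non-negative counts")
    expected = sps.contingency.expected_freq(table)
    correction = bool(table.shape == (2, 2) and (expected < 5).any())
    res = sps.chi2_contingency(table, correction=correction)
    return GroupComparison(
        test_name="chi-square" + (" (Yates)" if correction else ""),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries={},
        alpha_used=alpha,
        significant=bool(res.pvalue < alpha),
    )


def compare_three(
    groups: Sequence[Sequence],
    method: str = "auto",
    group_names: tuple[str, str, str] = ("A", "B", "C"),
    alpha_pairwise: float = 0.0167,
) -> GroupComparison:
    """Three-group omnibus test with Bonferroni-corrected pairwise follow-ups.

    The omnibus is one-way ANOVA or Kruskal-Wallis; the three pairwise
    comparisons (P1: A vs B, P2: A vs C, P3: B vs C) are each judged at
    0.05/3 = 0.0167.
    """
    if len(groups) != 3:
        raise ValueError("compare_three requires exactly three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    parametric = _choose_parametric(arrays, method)
    if parametric:
        stat, p = sps.f_oneway(*arrays)
        name = "one-way ANOVA"
    else:
        if np.ptp(np.concatenate(arrays)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*arrays)
        name = "Kruskal-Wallis"
    sub_method = "parametric" if parametric else "nonparametric"
    pairs = {
        "P1": (0, 1),
        "P2": (0, 2),
        "P3": (1, 2),
    }
    pairwise = {
        key: compare_two(
            arrays[i],
            arrays[j],
            method=sub_method,
            group_names=(group_names[i], group_names[j]),
            alpha=alpha_pairwise,
        )
        for key, (i, j) in pairs.items()
    }
    return GroupComparison(
        test_name=name,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        summaries=_summaries(arrays, group_names, parametric),
        alpha_used=0.05,
        significant=bool(p < 0.05),
        pairwise=pairwise,
    )


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100·numerator/denominator`` reported to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# logistic regression


def logistic_fit(
    outcome: Sequence[int],
    covariates: pd.DataFrame | np.ndarray | None,
    add_intercept: bool = True,
) -> LogisticResult:
    """Maximum-likelihood binary logistic regression with Wald 95% CIs.

    Complete or quasi-complete separation is flagged and the CIs marked
    unreliable (``separation=True``); the point estimates are still
    returned when the optimizer produced any.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if covariates is None:
        X = pd.DataFrame(index=np.arange(y.size))
    else:
        X = pd.DataFrame(covariates).copy()
    constant = X.nunique() <= 1
    if constant.any():
        raise ValueError(f"constant covariate(s): {list(X.columns[constant])}")
    if not add_intercept and X.shape[1] == 0:
        raise ValueError("model needs an intercept or at least one covariate")
    if add_intercept:
        if X.shape[1] == 0:
            X = pd.DataFrame({"const": np.ones(y.size)})
        else:
            X = sm.add_constant(X, has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            fit = sm.Logit(y, X.astype(float)).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
        separation = separation or any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )

    params = np.asarray(fit.params, dtype=float)
    separation = separation or bool(np.abs(params).max() > 20)
    try:
        ci = np.asarray(fit.conf_int(), dtype=float)
        pvals = np.asarray(fit.pvalues, dtype=float)
    except Exception:
        ci = np.column_stack([params, params]) * np.nan
        pvals = np.full_like(params, np.nan)
    with np.errstate(over="ignore"):  # separated fits can have infinite CI ends
        table = pd.DataFrame(
            {
                "odds_ratio": np.exp(params),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
                "p_value": pvals,
            },
            index=list(X.columns),
        )
    converged = bool(getattr(fit, "mle_retvals", {}).get("converged", True)) and not separation
    return LogisticResult(table=table, converged=converged, separation=separation)


# ---------------------------------------------------------------------------
# ROC / DeLong


def _delong_placements(labels: np.ndarray, scores: np.ndarray):
    """AUC and DeLong placement values via midranks (O(n log n))."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r_all = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # P(pos_i beats a random negative)
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_mann_whitney(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Tie-corrected rank AUC: P(score_pos > score_neg) + ½P(equal)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    auc, _, _ = _delong_placements(labels, scores)
    return auc


def _youden_cutoff(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, cutoff) maximizing Youden's J.

    A subject is called positive when ``score >= cutoff``. Among
    J-maximizing cutoffs the one with the higher specificity wins.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cuts = np.concatenate([np.unique(scores), [np.inf]])
    best = (-np.inf, -np.inf, np.nan)  # (J, specificity, cutoff)
    best_sens = best_spec = 0.0
    for c in cuts:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, c)
            best_sens, best_spec = sens, spec
    return best_sens, best_spec, float(best[2])


def roc(labels: Sequence[int], scores: Sequence[float]) -> RocResult:
    """ROC analysis: rank AUC, DeLong 95% CI, Youden operating point.

    For a binary score the AUC reduces to (sensitivity + specificity)/2.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be paired")
    auc, v10, v01 = _delong_placements(labels, scores)
    m, n = v10.size, v01.size
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    sens, spec, cut = _youden_cutoff(labels, scores)
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
        cutoff=cut,
        auc_variance=float(var),
    )


def delong_compare(
    labels: Sequence[int],
    scores_1: Sequence[float],
    scores_2: Sequence[float],
) -> DeLongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    labels = np.asarray(labels).astype(int)
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if not labels.shape == s1.shape == s2.shape:
        raise ValueError("scores must be paired on identical subjects")
    a1, v10_1, v01_1 = _delong_placements(labels, s1)
    a2, v10_2, v01_2 = _delong_placements(labels, s2)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = a1 - a2
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        half = 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))
        half = 1.959963984540054 * np.sqrt(var_diff)
    return DeLongComparison(
        auc_1=a1,
        auc_2=a2,
        difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        z=float(z),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# model/results facade for the cohort discrimination analysis

#: covariates of the adjusted ("clinical + CV") discrimination model
DEFAULT_COVARIATES = ("age_years", "perianal_disease", "crp_mg_l", "esr_mm_hr")


class DiscriminationModel:
    """Case-control discrimination of two cohort groups.

    Wraps the full battery applied to a cohort table: a multivariable
    logistic model of group membership on clinical covariates plus the
    lumbar CV biomarker, and ROC analyses of the individual and combined
    predictors. The CV enters the linear predictor as a fraction
    (``cv_pct / 100``) by default so its odds ratio is per unit CV;
    ``cv_scale="percent"`` keeps the percent scale.
    """

    def __init__(
        self,
        outcome: np.ndarray,
        covariates: pd.DataFrame,
        cv_column: str | None = "cv_pct",
        cv_scale: str = "fraction",
    ) -> None:
        self.outcome = np.asarray(outcome).astype(int)
        X = pd.DataFrame(covariates).astype(float).copy()
        self.cv_column = None
        if cv_column is not None and cv_column in X.columns:
            if cv_scale == "fraction":
                X[cv_column] = X[cv_column] / 100.0
            elif cv_scale != "percent":
                raise ValueError(f"unknown cv_scale {cv_scale!r}")
            self.cv_column = cv_column
        self.covariates = X

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        group_column: str = "group",
        positive: str = "CD",
        negative: str | None = "UC",
        covariates: Sequence[str] | None = None,
        cv_column: str | None = "cv_pct",
        cv_scale: str = "fraction",
    ) -> "DiscriminationModel":
        """Build the model from a cohort table, dropping incomplete rows."""
        if negative is not None:
            cohort = cohort[cohort[group_column].isin([positive, negative])]
        if covariates is None:
            covariates = [c for c in DEFAULT_COVARIATES if c in cohort.columns]
        cols = list(covariates)
        if cv_column is not None and cv_column in cohort.columns and cv_column not in cols:
            cols.append(cv_column)
        sub = cohort.dropna(subset=cols)
        outcome = (sub[group_column] == positive).astype(int).to_numpy()
        return cls(outcome, sub[cols], cv_column=cv_column, cv_scale=cv_scale)

    def fit(self) -> "DiscriminationResults":
        logistic = logistic_fit(self.outcome, self.covariates)
        X = sm.add_constant(self.covariates.astype(float), has_constant="add")
        eta = X.to_numpy() @ np.log(logistic.table["odds_ratio"].to_numpy())
        combined = roc(self.outcome, eta)
        per_covariate = {}
        for col in self.covariates.columns:
            scores = self.covariates[col].to_numpy()
            r = roc(self.outcome, scores)
            # flip covariates that protect rather than predict
            if r.auc < 0.5:
                r = roc(self.outcome, -scores)
            per_covariate[col] = r
        return DiscriminationResults(
            model=self,
            logistic=logistic,
            roc_combined=combined,
            roc_per_covariate=per_covariate,
            combined_scores=np.asarray(eta, dtype=float),
        )


@dataclass
class DiscriminationResults:
    """Fitted discrimination analysis: odds ratios, AUCs, comparisons."""

    model: DiscriminationModel
    logistic: LogisticResult
    roc_combined: RocResult
    roc_per_covariate: dict[str, RocResult]
    combined_scores: np.ndarray

    def compare_with(self, other_scores: Sequence[float]) -> DeLongComparison:
        """DeLong comparison of the combined model against other paired scores."""
        return delong_compare(self.model.outcome, self.combined_scores, other_scores)

    def summary(self) -> str:
        lines = [
            "Cohort discrimination analysis",
            "=" * 62,
            f"subjects: {len(self.model.outcome)}  "
            f"(positive: {int(self.model.outcome.sum())})",
            "",
            "Logistic regression (odds ratios, Wald 95% CI)",
            "-" * 62,
        ]
        for name, row in self.logistic.table.iterrows():
            lines.append(
                f"  {name:<18} OR {row['odds_ratio']:>8.2f} "
                f"({row['ci_low']:.2f}, {row['ci_high']:.2f})  p = {row['p_value']:.3f}"
            )
        if not self.logistic.converged:
            lines.append("  [warning] fit did not converge cleanly")
        if self.logistic.separation:
            lines.append("  [warning] separation detected; CIs unreliable")
        lines += ["", "ROC analysis", "-" * 62]
        for name, r in {**self.roc_per_covariate, "combined": self.roc_combined}.items():
            lines.append(
                f"  {name:<18} AUC {r.auc:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}]  "
                f"sens {r.sensitivity_pct:.2f}%  spec {r.specificity_pct:.2f}%"
            )
        return "\n".join(lines)
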