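"""Group statistics: percent differences/increases, Cohen's d with CI,
Mann-Whitney-Wilcoxon rank-sum tests, Benjamini-Hochberg adjustment, linear
mixed-effects sex x load interaction tests, and empirical CDFs.

Conventions recovered from the published worked values: a between-group
percent difference uses the mean of the two group means as denominator; a
within-group percent increase uses the no-load group mean as denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Between-group percent difference: 100*|a-b| / mean(a, b).

    Symmetric in its arguments and invariant to common rescaling.
    """
    denom = 0.5 * (mean_a + mean_b)
    if denom == 0:
        raise ZeroDivisionError("mean of the two group means is zero")
    return 100.0 * abs(mean_a - mean_b) / denom


def percent_increase(baseline: float, loaded: float) -> float:
    """Within-group percent increase over the baseline (no-load) mean."""
    if baseline == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return 100.0 * (loaded - baseline) / baseline


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float


def cohens_d(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    confidence: float = 0.95,
) -> EffectSize:
    """Cohen's d (absolute standardized mean difference, pooled SD) with a
    normal-approximation confidence interval.

    s_pooled = sqrt(((n_a-1)sd_a^2 + (n_b-1)sd_b^2)/(n_a+n_b-2));
    SE(d) = sqrt((n_a+n_b)/(n_a n_b) + d^2/(2(n_a+n_b))).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if pooled_var == 0:
        if mean_a != mean_b:
            raise ZeroDivisionError("zero pooled SD with unequal means")
        return EffectSize(0.0, 0.0, 0.0)
    d = abs(mean_a - mean_b) / np.sqrt(pooled_var)
    se = np.sqrt((n_a + n_b) / (n_a * n_b) + d**2 / (2 * (n_a + n_b)))
    z = sps.norm.ppf(0.5 + confidence / 2)
    return EffectSize(d=d, ci_low=d - z * se, ci_high=d + z * se)


def cohens_d_from_samples(a, b, confidence: float = 0.95) -> EffectSize:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), confidence
    )


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value: exact enumeration for
    combined n <= 12 without ties, otherwise the normal approximation with
    tie and continuity correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class InteractionResult:
    variable: str
    f_statistic: float
    df_num: int
    df_den: float
    p_value: float
    df_method: str
    converged: bool


def mixed_model_interaction(
    table: pd.DataFrame, value_col: str, variable_name: str | None = None
) -> InteractionResult:
    """Sex x load interaction test from a linear mixed-effects model.

    Fits value ~ sex * load (both categorical) with a random intercept per
    subject (REML), then a Wald F-test of the interaction terms.  The
    denominator degrees of freedom use the between-within (split-plot) rule
    (N_subjects - sex levels) * (load levels - 1), which coincides with the
    Kenward-Roger value for this balanced repeated-measures design; the rule
    used is recorded in the result.
    """
    required = {"subject_id", "sex", "load", value_col}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    data = table.dropna(subset=[value_col])
    counts = data.groupby(["sex", "load"], observed=True).size()
    n_sex = data["sex"].nunique()
    n_load = data["load"].nunique()
    if n_sex < 2 or n_load < 3 or (counts < 2).any():
        raise ValueError(
            "need >= 2 subjects per sex and all three load conditions present"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"{value_col} ~ C(sex) * C(load)", data, groups=data["subject_id"]
        )
        fit = model.fit(reml=True)
    interaction_terms = [name for name in fit.params.index if ":" in name]
    df_num = len(interaction_terms)
    hypothesis = ", ".join(f"{t} = 0" for t in interaction_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wald = fit.wald_test(hypothesis, scalar=True)
    f_stat = float(wald.statistic) / df_num
    n_subjects = data["subject_id"].nunique()
    df_den = (n_subjects - n_sex) * (n_load - 1)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return InteractionResult(
        variable=variable_name or value_col,
        f_statistic=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        df_method="between-within (split-plot)",
        converged=bool(fit.converged),
    )


@dataclass
class ECDF:
    """Right-continuous empirical CDF; query(x) = fraction of values <= x."""

    sorted_values: np.ndarray

    def __call__(self, x) -> np.ndarray | float:
        q = np.searchsorted(self.sorted_values, np.asarray(x), side="right") / len(
            self.sorted_values
        )
        return q if q.ndim else float(q)

    @property
    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.sorted_values)
        return self.sorted_values, np.arange(1, n + 1) / n


def ecdf(values) -> ECDF:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    return ECDF(sorted_values=np.sort(values))


def compare_groups(
    table: pd.DataFrame, value_col: str, variable_name: str | None = None
) -> pd.DataFrame:
    """Women-vs-men comparison per load: group means/SDs, percent difference,
    Cohen's d with CI, raw rank-sum p (BH adjustment is applied across the
    full report, not per variable)."""
    rows = []
    for load, sub in table.groupby("load"):
        women = sub.loc[sub["sex"] == "female", value_col].to_numpy()
        men = sub.loc[sub["sex"] == "male", value_col].to_numpy()
        es = cohens_d_from_samples(women, men)
        rows.append(
            {
                "variable": variable_name or value_col,
                "load": load,
                "mean_f": women.mean(),
                "sd_f": women.std(ddof=1),
                "n_f": len(women),
                "mean_m": men.mean(),
                "sd_m": men.std(ddof=1),
                "n_m": len(men),
                "percent_difference": percent_difference(women.mean(), men.mean()),
                "cohens_d": es.d,
                "d_ci_low": es.ci_low,
                "d_ci_high": es.ci_high,
                "p_raw": rank_sum_test(women, men),
            }
        )
    return pd.DataFrame(rows)
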