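"""Group and covariate statistics for brain-PAD analyses.

Two-sample comparisons use the pooled-variance (Student) t-test — from raw
samples or directly from published (n, mean, SD) summaries, with identical
formulas so the two routes agree to machine precision — plus Mann-Whitney U,
Pearson chi-squared (no continuity correction by default) and Pearson
correlation. Covariate adjustment is ordinary least squares of brain-PAD on
an intercept, a group indicator and the covariates; interaction tests add the
group x covariate product term. No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class SummaryStats:
    """(n, mean, sd) of one measure in one group."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2 for variance-based tests, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def of(cls, x: Sequence[float], label: str = "") -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)), label=label)


@dataclass(frozen=True)
class GroupComparison:
    """Effect (group1 - group2), its SE, 95% CI, test statistic, df, p."""

    effect: float
    se: float
    ci95: tuple[float, float]
    t: float
    df: float
    p: float
    test_name: str = "pooled t-test"


def t_test_from_summary(g1: SummaryStats, g2: SummaryStats) -> GroupComparison:
    """Student's pooled-variance two-sample t-test from summary statistics.

    effect = mean1 - mean2; SE uses the pooled SD; two-sided p on
    n1 + n2 - 2 df; CI = effect +/- t_crit(df, 0.975) * SE.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    if sp2 <= 0:
        raise ValueError(
            f"zero pooled variance for {g1.label or 'group1'} vs {g2.label or 'group2'}"
        )
    se = float(np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n)))
    effect = g1.mean - g2.mean
    t = effect / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tc = float(sps.t.ppf(0.975, df))
    return GroupComparison(effect, se, (effect - tc * se, effect + tc * se),
                           float(t), float(df), p)


def t_test_pooled(x1: Sequence[float], x2: Sequence[float]) -> GroupComparison:
    """Student's pooled-variance two-sample t-test on raw samples.

    Equivalent to :func:`t_test_from_summary` applied to the samples' own
    (n, mean, sd) triples.
    """
    return t_test_from_summary(SummaryStats.of(x1), SummaryStats.of(x2))


def mann_whitney_u(
    x1: Sequence[float], x2: Sequence[float], exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and no ties; otherwise the normal approximation with tie correction.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    has_ties = np.unique(np.concatenate([x1, x2])).size < x1.size + x2.size
    method = "exact" if (max(x1.size, x2.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared_2x2(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table (1 df), continuity correction off.

    The correction default mirrors the published sex-ratio comparison; pass
    ``correction=True`` for Yates' correction.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared is undefined with a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input to pearson_r")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Covariate-adjusted group effects (OLS)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermStats:
    beta: float
    se: float
    ci95: tuple[float, float]
    t: float
    p: float


@dataclass
class RegressionFit:
    terms: dict[str, TermStats]
    adjusted_r2: float
    n: int
    formula_label: str = ""

    def group_comparison(self, term: str = "group") -> GroupComparison:
        ts = self.terms[term]
        df = self.n - len(self.terms)
        return GroupComparison(ts.beta, ts.se, ts.ci95, ts.t, df, ts.p,
                               test_name="OLS adjusted group effect")


def _group_indicator(group: Sequence, patient_label: str | None) -> tuple[np.ndarray, str]:
    labels = pd.unique(pd.Series(list(group)))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {list(labels)}")
    if patient_label is None:
        non_control = [l for l in labels if str(l).lower() != "control"]
        patient_label = non_control[0] if len(non_control) == 1 else labels[0]
    if patient_label not in set(labels):
        raise ValueError(f"patient_label {patient_label!r} not among {list(labels)}")
    ind = np.asarray([1.0 if g == patient_label else 0.0 for g in group])
    return ind, str(patient_label)


def _ols_fit(y: np.ndarray, X: pd.DataFrame, label: str) -> RegressionFit:
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"check collinear terms among {list(X.columns[1:])}"
        )
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = {
        name: TermStats(
            beta=float(res.params[name]),
            se=float(res.bse[name]),
            ci95=(float(ci.loc[name, 0]), float(ci.loc[name, 1])),
            t=float(res.tvalues[name]),
            p=float(res.pvalues[name]),
        )
        for name in X.columns
    }
    return RegressionFit(terms=terms, adjusted_r2=float(res.rsquared_adj),
                         n=int(res.nobs), formula_label=label)


def adjusted_group_effect(
    y: Sequence[float],
    group: Sequence,
    covariates: Mapping[str, Sequence[float]] | None = None,
    patient_label: str | None = None,
) -> RegressionFit:
    """OLS of brain-PAD on intercept + group indicator + covariates.

    The ``group`` coefficient is the covariate-adjusted patient-minus-control
    effect. When ``patient_label`` is not given, the label that is not
    "control" (case-insensitive) is coded 1.
    """
    y = np.asarray(y, dtype=float)
    ind, plabel = _group_indicator(group, patient_label)
    X = pd.DataFrame({"const": np.ones(y.size), "group": ind})
    for name, vals in (covariates or {}).items():
        X[name] = np.asarray(vals, dtype=float)
    label = f"brain_pad ~ group[{plabel}] + " + " + ".join((covariates or {}).keys())
    return _ols_fit(y, X, label.rstrip("+ "))


def interaction_test(
    y: Sequence[float],
    group: Sequence,
    covariate: Sequence[float],
    patient_label: str | None = None,
) -> float:
    """Two-sided p of the group x covariate interaction in the OLS model."""
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    ind, plabel = _group_indicator(group, patient_label)
    X = pd.DataFrame(
        {
            "const": np.ones(y.size),
            "group": ind,
            "covariate": cov,
            "group_x_covariate": ind * cov,
        }
    )
    fit = _ols_fit(y, X, f"brain_pad ~ group[{plabel}] * covariate")
    return fit.terms["group_x_covariate"].p


# ---------------------------------------------------------------------------
# BMI-matched subcohort and single-subject comparison
# ---------------------------------------------------------------------------


def bmi_match_filter(
    cohort: pd.DataFrame,
    group_col: str = "group",
    bmi_col: str = "bmi",
    patient_label: str | None = None,
) -> pd.DataFrame:
    """BMI-overlap subcohort: keep patients with BMI <= max(control BMI) and
    controls with BMI >= min(patient BMI).

    Boundary convention: subjects whose BMI equals the extreme of the other
    group are *retained* (<=/>=), matching the published retained ranges.
    """
    ind, plabel = _group_indicator(cohort[group_col], patient_label)
    is_patient = ind.astype(bool)
    bmi = cohort[bmi_col].to_numpy(dtype=float)
    max_control = bmi[~is_patient].max()
    min_patient = bmi[is_patient].min()
    keep = np.where(is_patient, bmi <= max_control, bmi >= min_patient)
    out = cohort.loc[keep].copy()
    for lbl, grp_mask in ((plabel, is_patient), ("control", ~is_patient)):
        if not np.any(keep & grp_mask):
            warnings.warn(f"BMI matching removed every {lbl} subject")
    return out


def single_subject_vs_norm(
    subject_brain_pad: float, norms: Sequence[float]
) -> tuple[float, float]:
    """Compare one subject's brain-PAD against a normative sample.

    Returns (z, percentile): z uses the norms' mean and sample SD; the
    percentile is the empirical position within the norms (mean rank of
    <= and < counts, in percent).
    """
    norms = np.asarray(norms, dtype=float)
    if norms.size < 2:
        raise ValueError("need at least 2 normative values")
    sd = float(norms.std(ddof=1))
    if sd == 0:
        raise ValueError("normative sample has zero standard deviation")
    z = (float(subject_brain_pad) - float(norms.mean())) / sd
    pct = float(sps.percentileofscore(norms, subject_brain_pad, kind="mean"))
    return z, pct


def single_subject_z_from_summary(subject_brain_pad: float, norm: SummaryStats) -> float:
    """z-score against a published normative (n, mean, sd) summary."""
    if norm.sd == 0:
        raise ValueError("normative SD is zero")
    return (float(subject_brain_pad) - norm.mean) / norm.sd
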