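"""Group statistics for the levodopa-challenge analysis.

Covers every downstream comparison the pipeline reports: covariate-adjusted
group comparisons (general linear model with age, gender and education),
paired OFF-ON tests with a normality gate (paired t vs Wilcoxon signed-rank),
demographic-table tests (two-sample t / Mann-Whitney / Kruskal-Wallis /
Pearson chi-square), the group x medication-status interaction from a linear
mixed-effects model with a per-subject random intercept, partial correlation
with covariates regressed out, Bonferroni thresholds, and network-level
summaries versus normal controls.

Normality gates use the Kolmogorov-Smirnov test with estimated parameters
(Lilliefors critical values) at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TestResult",
    "adjusted_group_comparison",
    "paired_comparison",
    "demographic_comparison",
    "mixed_interaction",
    "partial_correlation",
    "bonferroni_threshold",
    "network_summary_report",
]

ALPHA = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: float | None = None
    threshold: float = ALPHA
    branch: str | None = None
    estimate: float | None = None
    notes: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.threshold

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p": self.p,
            "df": self.df,
            "threshold": self.threshold,
            "significant": self.significant,
            "branch": self.branch,
            "estimate": self.estimate,
            "notes": self.notes,
        }


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Lilliefors-style KS normality gate; tiny samples count as non-normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p >= alpha


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Covariates as a float design block; gender coded as a 0/1 indicator."""
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        cols = list(covariates.columns)
        mat = np.column_stack([
            pd.factorize(covariates[c])[0].astype(float)
            if covariates[c].dtype == object else covariates[c].to_numpy(float)
            for c in cols])
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        cols = [f"cov{i}" for i in range(mat.shape[1])]
    if mat.shape[0] != n:
        raise ValueError("covariate rows do not match outcome length")
    keep = mat.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"zero-variance covariate(s) removed: {dropped}", stacklevel=3)
        mat = mat[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
    return mat, cols


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) == design.shape[1]:
        return
    for j in range(1, design.shape[1]):   # find the first aliased column
        if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
            raise ValueError(f"collinear design: column {names[j]!r} is aliased")
    raise ValueError("collinear design")


def adjusted_group_comparison(outcome, group, covariates=None, *,
                              threshold: float = ALPHA,
                              name: str = "glm_group") -> TestResult:
    """Two-sided test of the group effect in a linear model with covariates.

    Fits ``outcome ~ intercept + group + age + gender + education`` (or
    whatever covariates are supplied) by ordinary least squares and returns
    the t test of the group coefficient.  With no covariates this is exactly
    the pooled-variance two-sample t test.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    gind = (g == levels[1]).astype(float)
    cov, cov_names = _covariate_matrix(covariates, len(y))
    design = np.column_stack([np.ones(len(y)), gind, cov])
    names = ["intercept", "group"] + cov_names
    if len(y) < design.shape[1] + 2:
        raise ValueError("too few subjects for the model")
    _check_rank(design, names)
    fit = sm.OLS(y, design).fit()
    return TestResult(
        name=name, statistic=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
        df=float(fit.df_resid), threshold=threshold,
        estimate=float(fit.params[1]),
        branch="glm", notes={"group_levels": [str(l) for l in levels],
                             "covariates": cov_names})


def paired_comparison(off, on, *, threshold: float = ALPHA,
                      name: str = "paired_off_on") -> TestResult:
    """Paired OFF-ON comparison; the normality of the differences picks the test.

    Normal differences (Lilliefors KS, alpha 0.05) -> paired t test;
    otherwise Wilcoxon signed-rank.  All-zero differences are degenerate and
    reported as p = 1.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape:
        raise ValueError("off/on must be paired (equal length)")
    d = on - off
    if np.all(d == 0):
        return TestResult(name=name, statistic=0.0, p=1.0, threshold=threshold,
                          branch="degenerate")
    if _is_normal(d):
        stat, p = sps.ttest_rel(on, off)
        return TestResult(name=name, statistic=float(stat), p=float(p),
                          df=float(len(d) - 1), threshold=threshold,
                          branch="paired_t", estimate=float(d.mean()))
    res = sps.wilcoxon(d)
    return TestResult(name=name, statistic=float(res.statistic),
                      p=float(res.pvalue), threshold=threshold,
                      branch="wilcoxon", estimate=float(np.median(d)))


def demographic_comparison(values, groups, kind: str, *,
                           threshold: float = ALPHA,
                           name: str = "demographic") -> TestResult:
    """Demographic-table test.

    Continuous, 2 groups: two-sample t if both groups pass the normality
    gate, else Mann-Whitney U.  Continuous, 3+ groups: Kruskal-Wallis.
    Categorical: Pearson chi-square without continuity correction.
    """
    groups = np.asarray(groups)
    levels = [l for l in pd.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if any((groups == l).sum() == 0 for l in levels):
        raise ValueError("empty group")
    if kind == "categorical":
        table = pd.crosstab(pd.Series(groups), pd.Series(np.asarray(values)))
        res = sps.chi2_contingency(table.to_numpy(), correction=False)
        return TestResult(name=name, statistic=float(res.statistic),
                          p=float(res.pvalue), df=float(res.dof),
                          threshold=threshold, branch="chi_square")
    if kind != "continuous":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    values = np.asarray(values, dtype=float)
    samples = [values[groups == l] for l in levels]
    if len(levels) > 2:
        stat, p = sps.kruskal(*samples)
        return TestResult(name=name, statistic=float(stat), p=float(p),
                          df=float(len(levels) - 1), threshold=threshold,
                          branch="kruskal_wallis")
    a, b = samples
    if _is_normal(a) and _is_normal(b):
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return TestResult(name=name, statistic=float(stat), p=float(p),
                          df=float(len(a) + len(b) - 2), threshold=threshold,
                          branch="t_test")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(name=name, statistic=float(res.statistic),
                      p=float(res.pvalue), threshold=threshold,
                      branch="mann_whitney")


def _residualize(y: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), cov])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def mixed_interaction(fc_off, fc_on, group, covariates=None, *,
                      threshold: float = ALPHA,
                      name: str = "group_x_status") -> TestResult:
    """Group x medication-status interaction from a linear mixed model.

    The outcome (per subject, OFF and ON) is first residualized against the
    covariates, then modelled with fixed effects for group, status and their
    interaction plus a per-subject random intercept (REML).  The interaction
    is tested with a Wald test under the normal approximation.  A singular
    random-effects fit falls back to a two-sample t test on the per-subject
    ON-OFF differences, flagged in ``branch``.
    """
    off = np.asarray(fc_off, dtype=float)
    on = np.asarray(fc_on, dtype=float)
    g = np.asarray(group)
    if not (off.shape == on.shape == g.shape):
        raise ValueError("fc_off, fc_on and group must align per subject")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    n = len(off)
    y = np.concatenate([off, on])
    gind = np.tile((g == levels[1]).astype(float), 2)
    status = np.repeat([0.0, 1.0], n)
    subject = np.tile(np.arange(n), 2)
    cov, _ = _covariate_matrix(covariates, n)
    if cov.shape[1]:
        y = _residualize(y, np.vstack([cov, cov]))
    exog = np.column_stack([np.ones(2 * n), gind, status, gind * status])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.MixedLM(y, exog, groups=subject).fit(reml=True)
        if not np.isfinite(fit.bse[3]) or fit.bse[3] == 0:
            raise np.linalg.LinAlgError("singular interaction covariance")
        z = float(fit.params[3] / fit.bse[3])
        return TestResult(
            name=name, statistic=z, p=float(2 * sps.norm.sf(abs(z))),
            threshold=threshold, branch="mixed_model",
            estimate=float(fit.params[3]),
            notes={"random_intercept_var": float(np.asarray(fit.cov_re)[0, 0]),
                   "residual_var": float(fit.scale)})
    except (np.linalg.LinAlgError, ValueError):
        d = on - off
        res = adjusted_group_comparison(d, g, None, threshold=threshold,
                                        name=name)
        res.branch = "fallback_t_on_differences"
        return res


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates by least squares; the
    correlation of the residuals is returned with a p-value from the t
    distribution on ``n - 2 - k`` degrees of freedom.  With no covariates
    this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov, _ = _covariate_matrix(covariates, len(x))
    k = cov.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ValueError("need n > k + 3 observations")
    if k:
        x = _residualize(x, cov)
        y = _residualize(y, cov)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2 * sps.t.sf(abs(t), df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def network_summary_report(patient_means: Mapping[str, pd.DataFrame] | pd.DataFrame,
                           control_means: pd.DataFrame | None,
                           covariates_patients=None, covariates_controls=None,
                           ) -> dict[str, TestResult]:
    """Patient-versus-control comparisons of network-level summaries.

    Expects per-subject data frames with columns ``da``, ``ach`` and
    ``session`` (mean Fisher-z per network) for patients and controls.
    Compares, per session: mean DA-FC and mean ACh-FC (Bonferroni m = 2) and
    the ACh - DA difference (raw alpha), each adjusted for the supplied
    covariates.  Controls carry a single measurement structure; their OFF
    rows are used for both sessions' references.
    """
    if control_means is None:
        warnings.warn("no controls available; network summaries skipped",
                      stacklevel=2)
        return {}
    pat = patient_means
    out: dict[str, TestResult] = {}
    thr2 = bonferroni_threshold(ALPHA, 2)
    nc = control_means[control_means["session"] == "OFF"]
    for session in ("OFF", "ON"):
        ps = pat[pat["session"] == session]
        for measure, thr in (("da", thr2), ("ach", thr2), ("difference", ALPHA)):
            if measure == "difference":
                pvals = ps["ach"].to_numpy(float) - ps["da"].to_numpy(float)
                cvals = nc["ach"].to_numpy(float) - nc["da"].to_numpy(float)
            else:
                pvals = ps[measure].to_numpy(float)
                cvals = nc[measure].to_numpy(float)
            outcome = np.concatenate([pvals, cvals])
            grp = np.array(["patient"] * len(pvals) + ["control"] * len(cvals))
            if covariates_patients is not None and covariates_controls is not None:
                cov = pd.concat([covariates_patients, covariates_controls],
                                ignore_index=True)
            else:
                cov = None
            out[f"{measure}_{session}"] = adjusted_group_comparison(
                outcome, grp, cov, threshold=thr,
                name=f"network_{measure}_{session}")
    return out


def selected_edge_vs_controls(edge_values_patients: Sequence[float],
                              edge_values_controls: Sequence[float],
                              covariates_patients=None,
                              covariates_controls=None, *,
                              m: int = 2,
                              name: str = "edge_vs_nc") -> TestResult:
    """One PD-subgroup-versus-controls comparison of a selected edge's FC."""
    pvals = np.asarray(edge_values_patients, dtype=float)
    cvals = np.asarray(edge_values_controls, dtype=float)
    outcome = np.concatenate([pvals, cvals])
    grp = np.array(["patient"] * len(pvals) + ["control"] * len(cvals))
    cov = None
    if covariates_patients is not None and covariates_controls is not None:
        cov = pd.concat([covariates_patients, covariates_controls],
                        ignore_index=True)
    return adjusted_group_comparison(outcome, grp, cov,
                                     threshold=bonferroni_threshold(ALPHA, m),
                                     name=name)
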