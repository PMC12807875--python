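"""Differential allelic imbalance: per-gene binomial GLM Wald tests.

The inactive-X read count k of a gene is modelled as binomial given the total
allelic count n, with a logistic model logit(p) = b0 + b1 * treated. The Wald
statistic b1 / se(b1) tests whether treatment shifts the allelic ratio.

With a single binary covariate the group totals (sum k, sum n per condition)
are sufficient statistics, so the replicate-level fit and the pooled fit have
identical maximum-likelihood estimates and observed-information standard
errors; the closed form is used here:

    b1 = logit(k_t / n_t) - logit(k_c / n_c)
    se(b1)^2 = 1/k_c + 1/(n_c - k_c) + 1/k_t + 1/(n_t - k_t)

Genes with a boundary MLE (zero or full Xi counts in a group) are reported
with ``estimable = False`` and undefined p, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError

TEST_COLUMNS = [
    "gene_id", "condition_control", "condition_treated", "xi_control",
    "total_control", "xi_treated", "total_treated", "beta_treatment",
    "std_error", "wald_statistic", "p_value", "estimable",
]


def _wald_two_group(k_c: int, n_c: int, k_t: int, n_t: int):
    """Closed-form two-group binomial-logistic MLE and Wald test."""
    if n_c == 0 or n_t == 0 or k_c in (0, n_c) or k_t in (0, n_t):
        return np.nan, np.nan, np.nan, np.nan, False
    logit_c = np.log(k_c / (n_c - k_c))
    logit_t = np.log(k_t / (n_t - k_t))
    beta = logit_t - logit_c
    se = np.sqrt(1 / k_c + 1 / (n_c - k_c) + 1 / k_t + 1 / (n_t - k_t))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, z, p, True


class AllelicImbalanceModel:
    """Per-gene binomial GLM of allelic imbalance between two conditions.

    Parameters
    ----------
    ratios
        Per-sample allelic ratio table (from
        :func:`xiescape.ratios.compute_allelic_ratios`).
    sheet
        Validated sample sheet.
    contrast
        ``(control_condition, treated_condition)`` labels.
    pool_replicates
        Accepted for interface stability; for this design pooled and
        replicate-level observations yield the same fit (see module note).
    """

    def __init__(self, ratios: pd.DataFrame, sheet: pd.DataFrame,
                 contrast: tuple[str, str], pool_replicates: bool = False):
        condition = sheet.set_index("sample_id")["condition_label"]
        present = set(condition)
        for label in contrast:
            if label not in present:
                raise ConfigurationError(
                    f"contrast condition {label!r} absent from sample sheet"
                )
        self.contrast = tuple(contrast)
        self.pool_replicates = pool_replicates
        work = ratios.copy()
        work["condition_label"] = work["sample_id"].map(condition)
        self._data = work[work["condition_label"].isin(contrast)]

    def fit(self) -> "ImbalanceResults":
        control, treated = self.contrast
        sums = (
            self._data.groupby(["gene_id", "condition_label"], sort=False)[
                ["xi_count", "total"]
            ].sum().unstack("condition_label", fill_value=0)
        )
        rows = []
        for gene_id, row in sums.iterrows():
            k_c = int(row.get(("xi_count", control), 0))
            n_c = int(row.get(("total", control), 0))
            k_t = int(row.get(("xi_count", treated), 0))
            n_t = int(row.get(("total", treated), 0))
            beta, se, z, p, ok = _wald_two_group(k_c, n_c, k_t, n_t)
            rows.append((gene_id, control, treated, k_c, n_c, k_t, n_t,
                         beta, se, z, p, ok))
        table = pd.DataFrame(rows, columns=TEST_COLUMNS)
        return ImbalanceResults(table, self.contrast)


class ImbalanceResults:
    """Fitted per-gene Wald tests with multiple-testing adjustment."""

    def __init__(self, table: pd.DataFrame, contrast: tuple[str, str]):
        self.table = table
        self.contrast = contrast

    def adjusted(self, method: str = "holm") -> pd.DataFrame:
        out = self.table.copy()
        out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(), method)
        return out

    def summary(self, alpha: float = 0.05, method: str = "holm") -> str:
        adj = self.adjusted(method)
        n = len(adj)
        n_est = int(adj["estimable"].sum())
        n_sig = int((adj["p_adjusted"] < alpha).sum())
        lines = [
            "Allelic imbalance (binomial GLM, Wald test)",
            f"contrast: {self.contrast[0]} vs {self.contrast[1]}",
            f"genes tested:        {n}",
            f"estimable fits:      {n_est}",
            f"significant (adj p < {alpha:g}, {method}): {n_sig}",
        ]
        return "\n".join(lines)


def fit_binomial_glm(ratios: pd.DataFrame, sheet: pd.DataFrame,
                     contrast: tuple[str, str],
                     pool_replicates: bool = False) -> pd.DataFrame:
    """Functional wrapper: fit the per-gene model, return the test table."""
    return AllelicImbalanceModel(ratios, sheet, contrast,
                                 pool_replicates).fit().table


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Holm (step-down) or Benjamini-Hochberg (step-up) adjustment.

    NaN entries are propagated and excluded from the family size m.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    methods = {"holm": "holm", "benjamini_hochberg": "fdr_bh"}
    if method not in methods:
        raise ConfigurationError(f"unknown adjustment method: {method!r}")
    out = np.full_like(p, np.nan)
    if valid.any():
        out[valid] = multipletests(p[valid], method=methods[method])[1]
    return out


def call_silencing(
    tests: pd.DataFrame,
    condition_means: pd.DataFrame,
    alpha: float = 0.05,
    reduction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Call Dox-induced silencing: significant >= 50% ratio reduction.

    ``tests`` must carry ``p_adjusted`` (see :meth:`ImbalanceResults.adjusted`);
    ``condition_means`` is the aggregated (gene, condition) ratio matrix. The
    reduction fraction is 1 - treated mean / control mean; a gene is
    silenced_by_dox when the adjusted p is below alpha, the fit is estimable
    and the reduction reaches the threshold. A zero control mean leaves the
    reduction undefined and the call False.
    """
    means = condition_means.set_index(["gene_id", "condition_label"])["mean_ratio"]
    rows = []
    for rec in tests.itertuples(index=False):
        control = means.get((rec.gene_id, rec.condition_control), np.nan)
        treated = means.get((rec.gene_id, rec.condition_treated), np.nan)
        if not np.isfinite(control) or control == 0 or not np.isfinite(treated):
            reduction = np.nan
        else:
            reduction = 1.0 - treated / control
        significant = bool(
            rec.estimable and np.isfinite(rec.p_adjusted)
            and rec.p_adjusted < alpha
        )
        silenced = bool(
            significant and np.isfinite(reduction)
            and reduction >= reduction_threshold
        )
        rows.append((rec.gene_id, reduction, significant, silenced))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "reduction_fraction", "significant", "silenced_by_dox"],
    )


def compare_categories(values: pd.DataFrame, value_col: str = "value",
                       group_col: str = "group",
                       paired: bool = False) -> pd.DataFrame:
    """Pairwise Wilcoxon comparisons between groups, BH-adjusted.

    Unpaired groups use the rank-sum (Mann-Whitney U) test; ``paired`` uses
    the signed-rank test and requires equal group lengths (values matched by
    order within group).
    """
    groups = {name: sub[value_col].to_numpy(dtype=float)
              for name, sub in values.groupby(group_col, sort=False)}
    if len(groups) < 2:
        raise InsufficientDataError("compare_categories needs >= 2 groups")
    rows = []
    for name_a, name_b in combinations(groups, 2):
        a, b = groups[name_a], groups[name_b]
        if paired:
            if len(a) != len(b):
                raise ValueError("paired comparison requires equal lengths")
            if np.allclose(a, b):
                statistic, p = 0.0, 1.0
            else:
                statistic, p = stats.wilcoxon(a, b)
        else:
            statistic, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((name_a, name_b, len(a), len(b), statistic, p))
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p_value"]
    )
    out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(),
                                       "benjamini_hochberg")
    return out


@dataclass
class CorrelationRecord:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate_escape_xist(mean_escape, xist_level) -> CorrelationRecord:
    """Pearson correlation between per-sample mean escape and Xist level."""
    x = np.asarray(xist_level, dtype=float)
    y = np.asarray(mean_escape, dtype=float)
    if len(x) != len(y):
        raise ValueError("mean_escape and xist_level must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("correlation requires >= 3 samples")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, deg=1)
    return CorrelationRecord(r=float(r), p_value=float(p), slope=float(slope),
                             intercept=float(intercept), n=len(x))
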