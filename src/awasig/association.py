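"""Subtype-phenotype association statistics.

A molecular-subtype call crossed with case/control status yields a 2x2
table (tp = subtype-positive cases, fp = subtype-positive controls,
fn = subtype-negative cases, tn = subtype-negative controls).  From it we
report the odds ratio with a Wald 95% CI, sensitivity/specificity,
chi-square or Fisher p-values, and a covariate-adjusted logistic
regression (case status ~ subtype + covariates), whose exponentiated
subtype coefficient is the adjusted odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "crosstab",
    "odds_ratio",
    "sens_spec",
    "chi_square",
    "adjusted_logistic",
    "subgroup_association",
    "counts_from_percent",
]


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("contingency counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_array(self) -> np.ndarray:
        """Rows: subtype +/-; columns: case/control."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float | None
    specificity: float | None
    method: str
    statistic: float | None = None


def crosstab(assignment, labels) -> ContingencyTable:
    """Cross-tabulate a binary subtype call against case/control labels.

    ``assignment`` may be the DataFrame produced by
    :func:`awasig.subtype.assign_subtypes` (its ``awa`` column is used) or
    any binary vector aligned with ``labels``.
    """
    if isinstance(assignment, pd.DataFrame):
        assignment = assignment["awa"]
    a = np.asarray(assignment, dtype=int)
    y = np.asarray(labels, dtype=int)
    if a.shape != y.shape:
        raise ValueError("assignment and labels have different lengths")
    return ContingencyTable(
        tp=int(((a == 1) & (y == 1)).sum()),
        fp=int(((a == 1) & (y == 0)).sum()),
        fn=int(((a == 0) & (y == 1)).sum()),
        tn=int(((a == 0) & (y == 0)).sum()),
    )


def _p_for_table(table: ContingencyTable) -> tuple[float, float | None, str]:
    """Default 2x2 p-value: Pearson chi-square, Fisher exact if sparse."""
    arr = table.to_array()
    if arr.sum() == 0:
        return 1.0, None, "none"
    expected = stats.contingency.expected_freq(arr)
    if (expected < 5).any():
        _, p = stats.fisher_exact(arr)
        return float(p), None, "fisher"
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p), float(chi2), "chi2"


def odds_ratio(
    table: ContingencyTable,
    correction: str = "none",
    conf_level: float = 0.95,
) -> AssociationResult:
    """Cross-product odds ratio with a Wald confidence interval.

    ``correction="haldane"`` adds 0.5 to every cell whenever any cell is
    zero; with ``correction="none"`` a zero cell is an error.
    """
    cells = [table.tp, table.fp, table.fn, table.tn]
    if correction == "haldane":
        if any(c == 0 for c in cells):
            cells = [c + 0.5 for c in cells]
    elif correction == "none":
        if any(c == 0 for c in cells):
            raise ValueError(
                "zero cell in 2x2 table; use correction='haldane'"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    tp, fp, fn, tn = cells
    or_ = (tp * tn) / (fp * fn)
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    ci_low = math.exp(math.log(or_) - z * se)
    ci_high = math.exp(math.log(or_) + z * se)
    p, statistic, method = _p_for_table(table)
    sens, spec = sens_spec(table)
    return AssociationResult(
        odds_ratio=float(or_), ci_low=ci_low, ci_high=ci_high,
        p_value=p, sensitivity=sens, specificity=spec,
        method=f"wald+{method}", statistic=statistic,
    )


def sens_spec(table: ContingencyTable) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) of the call."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise ValueError("empty margin: sensitivity/specificity undefined")
    return table.tp / (table.tp + table.fn), table.tn / (table.tn + table.fp)


def chi_square(table: ContingencyTable, yates: bool = False) -> AssociationResult:
    """Pearson chi-square test of the 2x2 table (optional Yates correction)."""
    arr = table.to_array()
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    try:
        sens, spec = sens_spec(table)
    except ValueError:
        sens = spec = None
    return AssociationResult(
        odds_ratio=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        p_value=float(p), sensitivity=sens, specificity=spec,
        method="chi2_yates" if yates else "chi2", statistic=float(chi2),
    )


def adjusted_logistic(
    assignment, labels, covariates, conf_level: float = 0.95
) -> AssociationResult:
    """Logistic regression of case status on the subtype call + covariates.

    Reports exp(beta_subtype) with its Wald CI and p.  Constant covariate
    columns are dropped (they are collinear with the intercept), so a
    degenerate covariate matrix reproduces the crude odds ratio exactly.
    Quasi-separation is reported as an error rather than silently
    returning a diverging estimate.
    """
    if isinstance(assignment, pd.DataFrame):
        assignment = assignment["awa"]
    a = np.asarray(assignment, dtype=float)
    y = np.asarray(labels, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(y):
        cov = cov.T
    if cov.shape[0] != len(y):
        raise ValueError("covariate matrix does not align with samples")
    if np.isnan(cov).any():
        raise ValueError("missing covariate values; impute or drop samples first")
    keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
    if len(keep) < cov.shape[1]:
        logger.warning("dropping %d constant covariate column(s)",
                       cov.shape[1] - len(keep))
    X = np.column_stack([np.ones_like(a), a] + [cov[:, j] for j in keep])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ValueError(
            f"logistic fit failed ({exc}); consider a penalized fallback"
        ) from exc
    beta = fit.params[1]
    if abs(beta) > 15 or not np.isfinite(fit.bse[1]):
        raise ValueError(
            "separation detected (diverging subtype coefficient); "
            "consider a penalized fallback"
        )
    z = stats.norm.ppf(0.5 + conf_level / 2)
    return AssociationResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * fit.bse[1])),
        ci_high=float(np.exp(beta + z * fit.bse[1])),
        p_value=float(fit.pvalues[1]),
        sensitivity=None, specificity=None,
        method="logistic", statistic=float(fit.tvalues[1]),
    )


def subgroup_association(
    assignment, labels, mask, correction: str = "none"
) -> AssociationResult:
    """Recompute the 2x2 association on the samples selected by ``mask``."""
    if isinstance(assignment, pd.DataFrame):
        assignment = assignment["awa"]
    a = np.asarray(assignment, dtype=int)
    y = np.asarray(labels, dtype=int)
    m = np.asarray(mask, dtype=bool)
    if not (len(a) == len(y) == len(m)):
        raise ValueError("assignment, labels and mask must align")
    ys = y[m]
    if ys.sum() == 0 or (1 - ys).sum() == 0:
        raise ValueError("subgroup lacks one phenotype class")
    return odds_ratio(crosstab(a[m], ys), correction=correction)


def counts_from_percent(percent: float, n: int) -> int:
    """Reconstruct a count from a printed percentage (nearest integer)."""
    if not (0 <= percent <= 100):
        raise ValueError("percent must lie in [0, 100]")
    return int(round(percent / 100 * n))
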