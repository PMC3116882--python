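"""Per-probe two-group differential expression and FDR estimation.

Three complementary views of the same comparison:

* plain two-sample t tests (Welch by default, pooled optionally) with the
  log2 fold change taken as case mean minus control mean;
* the q-value machinery: pi0 (the proportion of truly null probes) is
  estimated from the tail behaviour of pi0(lambda) = #{p > lambda} /
  (m (1 - lambda)) smoothed by a natural cubic spline and read off at the
  largest lambda, and q-values are the pi0-scaled step-up FDR;
* a permutation procedure built on the variance-stabilized d statistic
  d_i = (mean difference) / (pooled SE + s0), where the fudge factor s0
  is chosen among percentiles of the SE distribution to make the spread
  of d as uniform as possible across expression-variability bins.

``1 - pi0`` is the estimated fraction of differentially expressed probes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix

__all__ = [
    "DEResult",
    "Pi0Estimate",
    "SamResult",
    "welch_t",
    "t_from_summary",
    "storey_qvalue",
    "estimate_de_fraction",
    "sam_permutation",
    "pvalue_histogram",
    "differential_expression",
]

_VAR_FLOOR = 1e-12


@dataclass
class Pi0Estimate:
    """Estimated proportion of non-differentially-expressed features."""

    pi0: float
    lambda_grid: np.ndarray
    raw: np.ndarray  # pi0(lambda) before smoothing
    method: str  # "spline" or "fixed_lambda"


@dataclass
class DEResult:
    """Per-probe statistics; ``table`` has columns t, p, q, log2_fc [, sam_d]."""

    table: pd.DataFrame
    pi0: Pi0Estimate | None = None


@dataclass
class SamResult:
    """Permutation-FDR summary around the d statistic."""

    d: pd.Series  # per-probe observed d
    s0: float
    n_permutations: int
    pi0: float
    table: pd.DataFrame  # columns: cutoff, called, median_false, fdr
    perm_p: pd.Series  # add-one permutation p-values, (b+1)/(B+1)

    def significant_probes(self, fdr_threshold: float) -> list[str]:
        """Probes with |d| at or above the loosest cutoff meeting the FDR."""
        ok = self.table[self.table["fdr"] < fdr_threshold]
        if ok.empty:
            return []
        cutoff = ok["cutoff"].min()
        return list(self.d.index[np.abs(self.d.to_numpy()) >= cutoff])


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _group_moments(x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    sub = x[:, mask]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), sub.shape[1]


def two_group_t(
    x: np.ndarray, labels: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rowwise two-sample t test.

    Returns (t, p, log2_fc, floored) where log2_fc is group-1 mean minus
    group-0 mean and ``floored`` flags rows whose variance fell below the
    numerical floor in both groups.
    """
    labels = np.asarray(labels)
    m1, v1, n1 = _group_moments(x, labels == 1)
    m0, v0, n0 = _group_moments(x, labels == 0)
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")
    floored = (v1 < _VAR_FLOOR) & (v0 < _VAR_FLOOR)
    v1 = np.maximum(v1, _VAR_FLOOR)
    v0 = np.maximum(v0, _VAR_FLOOR)
    diff = m1 - m0
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
        df = np.full(x.shape[0], n1 + n0 - 2, dtype=float)
    else:
        se = np.sqrt(v1 / n1 + v0 / n0)
        df = (v1 / n1 + v0 / n0) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, diff, floored


def welch_t(
    matrix: ExpressionMatrix, labels, equal_var: bool = False
) -> DEResult:
    """Per-probe two-sample t test of group 1 vs group 0 samples.

    ``labels`` is a binary vector aligned with the matrix's samples.
    Zero-variance probes are tested with a variance floor and flagged.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise ValueError("labels length does not match sample count")
    t, p, fc, floored = two_group_t(
        matrix.values.to_numpy(dtype=float), labels, equal_var=equal_var
    )
    table = pd.DataFrame(
        {"t": t, "p": p, "log2_fc": fc, "zero_variance": floored},
        index=matrix.values.index,
    )
    return DEResult(table=table)


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t test from printed summary statistics (mean +/- SD, n).

    Lets tabulated cohort characteristics be re-tested without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both standard deviations are zero")
    v1, v2 = sd1**2, sd2**2
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def _natural_spline_smooth(x: np.ndarray, y: np.ndarray, df: float) -> np.ndarray:
    """Natural cubic smoothing spline with a target effective df.

    Solves (I + alpha * K) f = y where K = Q R^-1 Q' is the usual
    second-derivative penalty on the knots x, with alpha chosen by
    bisection so that trace[(I + alpha K)^-1] equals ``df``.
    """
    n = len(x)
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    eye = np.eye(n)

    def trace_df(log_alpha: float) -> float:
        return float(np.trace(np.linalg.inv(eye + 10.0**log_alpha * K)))

    lo, hi = -12.0, 12.0
    # trace decreases monotonically from n (alpha->0) to 2 (alpha->inf)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if trace_df(mid) > df:
            lo = mid
        else:
            hi = mid
    alpha = 10.0 ** (0.5 * (lo + hi))
    return np.linalg.solve(eye + alpha * K, y)


def storey_qvalue(
    p_values,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, Pi0Estimate]:
    """q-values with spline-smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on
    ``lambda_grid`` (default 0, 0.05, ..., 0.90), smoothed by a natural
    cubic spline with 3 effective degrees of freedom, and read off at the
    largest lambda; the result is clipped to (0, 1].  For fewer than 10
    p-values the fixed-lambda estimate at lambda = 0.5 is used instead.
    Passing ``pi0`` explicitly (e.g. 1.0) bypasses estimation, in which
    case the q-values reduce to Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    raw = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid])

    if pi0 is not None:
        if not (0 < pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")
        est = Pi0Estimate(float(pi0), lambda_grid, raw, "fixed")
    elif m < 10:
        lam = 0.5
        val = min(1.0, (p > lam).sum() / (m * (1 - lam)))
        est = Pi0Estimate(max(val, 1.0 / m), np.array([lam]),
                          np.array([val]), "fixed_lambda")
    else:
        smoothed = _natural_spline_smooth(lambda_grid, raw, df=3.0)
        val = float(smoothed[-1])
        val = min(val, 1.0)
        if val <= 0:
            val = min(1.0, max(raw[-1], 1.0 / m))
        est = Pi0Estimate(val, lambda_grid, raw, "spline")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = est.pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, est


def estimate_de_fraction(pi0_estimate: Pi0Estimate) -> float:
    """Fraction of features estimated to be differentially expressed."""
    return 1.0 - pi0_estimate.pi0


# ---------------------------------------------------------------------------
# permutation FDR (SAM-style)
# ---------------------------------------------------------------------------

def _d_statistic(x: np.ndarray, labels: np.ndarray, s0: float) -> np.ndarray:
    m1, v1, n1 = _group_moments(x, labels == 1)
    m0, v0, n0 = _group_moments(x, labels == 0)
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    se = np.sqrt(pooled * (1 / n1 + 1 / n0))
    return (m1 - m0) / (se + s0)


def _pooled_se(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    m1, v1, n1 = _group_moments(x, labels == 1)
    m0, v0, n0 = _group_moments(x, labels == 0)
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    return np.sqrt(pooled * (1 / n1 + 1 / n0))


def _choose_s0(x: np.ndarray, labels: np.ndarray) -> float:
    """Fudge factor: the SE percentile minimizing the CV of the spread of d.

    Probes are binned into up to 100 equal-occupancy bins of the SE; for
    each candidate s0 the median absolute deviation of d within each bin
    is computed and the candidate with the smallest coefficient of
    variation of those MADs wins.
    """
    se = _pooled_se(x, labels)
    diff_over = _d_statistic(x, labels, 0.0) * se  # mean difference
    candidates = np.percentile(se, np.arange(0, 101, 5))
    n_bins = min(100, max(2, len(se) // 20))
    edges = np.quantile(se, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = diff_over / (se + s0)
        mads = np.array([
            stats.median_abs_deviation(d[bins == b], scale=1 / 1.4826)
            for b in range(n_bins) if (bins == b).sum() >= 2
        ])
        mads = mads[mads > 0]
        if len(mads) < 2:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_labelings(
    labels: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Label permutations: full enumeration when feasible, else sampled."""
    n = len(labels)
    n1 = int(labels.sum())
    if math.comb(n, n1) <= n_permutations:
        perms = []
        for idx in itertools.combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(idx)] = 1
            perms.append(lab)
        return np.array(perms)
    perms = np.empty((n_permutations, n), dtype=int)
    for b in range(n_permutations):
        perms[b] = rng.permutation(labels)
    return perms


def sam_permutation(
    matrix: ExpressionMatrix,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """Permutation-based FDR around the fudged d statistic.

    For every observed |d| used as a cutoff, the expected number of false
    calls is the median across label permutations of the null exceedance
    count, scaled by the permutation pi0 estimate (fraction of observed d
    falling between the null quartiles, capped at 1).
    """
    labels = np.asarray(labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both groups must be non-empty")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    x = matrix.values.to_numpy(dtype=float)
    if s0 is None:
        s0 = _choose_s0(x, labels)
    d_obs = _d_statistic(x, labels, s0)
    rng = np.random.default_rng(seed)
    perms = _permutation_labelings(labels, n_permutations, rng)
    B = perms.shape[0]
    m = x.shape[0]

    cutoffs = np.sort(np.abs(d_obs))  # ascending
    called = m - np.arange(m)  # #|d_obs| >= cutoffs[i]
    false_counts = np.empty((B, m))
    null_all = np.empty((B, m))
    for b in range(B):
        d_null = _d_statistic(x, perms[b], s0)
        null_all[b] = d_null
        abs_sorted = np.sort(np.abs(d_null))
        false_counts[b] = m - np.searchsorted(abs_sorted, cutoffs, side="left")
    median_false = np.median(false_counts, axis=0)

    q25, q75 = np.percentile(null_all, [25, 75])
    pi0 = min(1.0, ((d_obs > q25) & (d_obs < q75)).sum() / (0.5 * m))
    fdr = np.minimum(1.0, pi0 * median_false / np.maximum(called, 1))

    exceed = (np.abs(null_all) >= np.abs(d_obs)[None, :]).sum(axis=0)
    perm_p = (exceed + 1) / (B + 1)

    table = pd.DataFrame(
        {"cutoff": cutoffs, "called": called, "median_false": median_false, "fdr": fdr}
    )
    return SamResult(
        d=pd.Series(d_obs, index=matrix.values.index, name="sam_d"),
        s0=float(s0),
        n_permutations=B,
        pi0=float(pi0),
        table=table,
        perm_p=pd.Series(perm_p, index=matrix.values.index, name="perm_p"),
    )


# ---------------------------------------------------------------------------
# diagnostics and drivers
# ---------------------------------------------------------------------------

def pvalue_histogram(p_values, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of p-values with the flat reference height m / n_bins."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "expected_uniform": p.size / n_bins,
        }
    )


def differential_expression(
    matrix: ExpressionMatrix,
    labels,
    equal_var: bool = False,
    sam: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DEResult:
    """t tests + q-values (+ optionally the permutation d statistic)."""
    res = welch_t(matrix, labels, equal_var=equal_var)
    q, pi0 = storey_qvalue(res.table["p"].to_numpy())
    res.table["q"] = q
    res.pi0 = pi0
    if sam:
        sam_res = sam_permutation(matrix, labels, n_permutations, seed)
        res.table["sam_d"] = sam_res.d
    return res
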