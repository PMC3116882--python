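"""Cross-study fold-change concordance.

Compares the subtype contrast of one study with a paired
baseline/post-stimulus contrast from another platform: probes are joined
across platforms by gene symbol (multi-probe genes collapsed to one probe
per platform), per-gene log2 fold changes are computed in each study, and
agreement is summarized by the overlap of significant genes (with a
hypergeometric enrichment p) and the Pearson correlation of the two
fold-change vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix

__all__ = [
    "ProbeMap",
    "ConcordanceResult",
    "map_by_symbol",
    "paired_fold_changes",
    "concordance",
]


@dataclass
class ProbeMap:
    """One probe per platform per retained gene symbol."""

    table: pd.DataFrame  # columns: gene_symbol, probe_a, probe_b

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass
class ConcordanceResult:
    n_mapped: int
    n_overlap: int  # genes with p < alpha in both studies
    r: float | None  # Pearson r of fold changes (None if undefined)
    r_p: float | None
    overlap_p: float  # hypergeometric tail p for the overlap
    per_gene: pd.DataFrame  # fc_a, fc_b, p_a, p_b, significant_both


def _collapse(annot: pd.DataFrame, expr: ExpressionMatrix | None,
              collapse: str, probe_col: str) -> pd.DataFrame:
    if collapse == "first":
        return annot.drop_duplicates("gene_symbol", keep="first")
    if collapse == "max_mean_expression":
        if not annot["gene_symbol"].duplicated().any():
            return annot
        if expr is None:
            raise ValueError(
                "collapse='max_mean_expression' needs the expression matrix"
            )
        means = expr.values.mean(axis=1)
        annot = annot.assign(_mean=annot[probe_col].map(means))
        if annot["_mean"].isna().any():
            missing = annot.loc[annot["_mean"].isna(), probe_col].tolist()
            raise ValueError(f"probes absent from expression matrix: {missing[:5]}")
        annot = annot.sort_values("_mean", ascending=False)
        return annot.drop_duplicates("gene_symbol", keep="first").drop(columns="_mean")
    raise ValueError(f"unknown collapse rule {collapse!r}")


def map_by_symbol(
    annot_a: pd.DataFrame,
    annot_b: pd.DataFrame,
    collapse: str = "max_mean_expression",
    expr_a: ExpressionMatrix | None = None,
    expr_b: ExpressionMatrix | None = None,
) -> ProbeMap:
    """Join two probe -> gene-symbol tables on their shared symbols.

    Each annotation table has columns ``probe_id`` and ``gene_symbol``.
    Genes measured by several probes on a platform are collapsed to one
    probe per the rule (default: the probe with the highest mean
    expression, requiring the matching expression matrix).
    """
    for name, annot in (("annot_a", annot_a), ("annot_b", annot_b)):
        if annot.empty:
            raise ValueError(f"{name} is empty")
        missing = {"probe_id", "gene_symbol"} - set(annot.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {sorted(missing)}")
        if (annot["gene_symbol"].astype(str).str.strip() == "").any():
            raise ValueError(f"{name} contains empty gene symbols")
    a = _collapse(annot_a, expr_a, collapse, "probe_id")
    b = _collapse(annot_b, expr_b, collapse, "probe_id")
    merged = a.merge(b, on="gene_symbol", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no gene symbols shared between the two platforms")
    table = merged.rename(
        columns={"probe_id_a": "probe_a", "probe_id_b": "probe_b"}
    )[["gene_symbol", "probe_a", "probe_b"]].reset_index(drop=True)
    return ProbeMap(table=table)


def paired_fold_changes(
    baseline: ExpressionMatrix, post: ExpressionMatrix
) -> pd.DataFrame:
    """Per-probe within-subject log2 change and paired t-test p.

    Subjects are paired by sample id; the two matrices must cover the
    same subjects and probes.
    """
    if set(baseline.sample_ids) != set(post.sample_ids):
        extra = set(baseline.sample_ids) ^ set(post.sample_ids)
        raise ValueError(f"unpaired subjects: {sorted(extra)[:10]}")
    if list(baseline.probe_ids) != list(post.probe_ids):
        raise ValueError("baseline and post matrices must share the probe axis")
    post_aligned = post.values[baseline.sample_ids]
    diff = post_aligned.to_numpy(dtype=float) - baseline.values.to_numpy(dtype=float)
    n = diff.shape[1]
    if n < 2:
        raise ValueError("paired test needs at least 2 subjects")
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    se = np.maximum(sd, 1e-12) / np.sqrt(n)
    t = mean / se
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(sd < 1e-12, 1.0, p)  # no within-subject change at all
    return pd.DataFrame(
        {"log2_fc": mean, "p": p}, index=baseline.values.index
    )


def concordance(
    de_a: pd.DataFrame,
    fc_b: pd.DataFrame,
    probe_map: ProbeMap,
    alpha: float = 0.05,
    restrict: bool = True,
) -> ConcordanceResult:
    """Fold-change agreement between two studies over the mapped genes.

    ``de_a`` needs columns ``log2_fc`` and ``p`` indexed by study-A probe
    id (a :class:`~awasig.diffexpr.DEResult` table qualifies); ``fc_b``
    likewise for study B.  With ``restrict=True`` (default) the Pearson r
    is computed over genes significant at ``alpha`` in both studies;
    otherwise over all mapped genes.  The overlap p-value is the
    hypergeometric tail probability of seeing at least the observed
    number of dual-significant genes given each study's significant-call
    count.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    t = probe_map.table
    missing_a = set(t["probe_a"]) - set(de_a.index)
    missing_b = set(t["probe_b"]) - set(fc_b.index)
    if missing_a or missing_b:
        raise ValueError(
            f"mapped probes absent from results: A={sorted(missing_a)[:5]} "
            f"B={sorted(missing_b)[:5]}"
        )
    per_gene = pd.DataFrame(
        {
            "gene_symbol": t["gene_symbol"].to_numpy(),
            "fc_a": de_a.loc[t["probe_a"], "log2_fc"].to_numpy(),
            "p_a": de_a.loc[t["probe_a"], "p"].to_numpy(),
            "fc_b": fc_b.loc[t["probe_b"], "log2_fc"].to_numpy(),
            "p_b": fc_b.loc[t["probe_b"], "p"].to_numpy(),
        }
    ).set_index("gene_symbol")
    sig_a = per_gene["p_a"] < alpha
    sig_b = per_gene["p_b"] < alpha
    both = sig_a & sig_b
    per_gene["significant_both"] = both
    n_mapped = len(per_gene)
    n_overlap = int(both.sum())

    M, nA, nB, k = n_mapped, int(sig_a.sum()), int(sig_b.sum()), n_overlap
    overlap_p = float(stats.hypergeom.sf(k - 1, M, nA, nB)) if nA and nB else 1.0

    subset = per_gene[both] if restrict else per_gene
    if len(subset) >= 3 and subset["fc_a"].std() > 0 and subset["fc_b"].std() > 0:
        r, r_p = stats.pearsonr(subset["fc_a"], subset["fc_b"])
        r, r_p = float(r), float(r_p)
    else:
        r = r_p = None
    return ConcordanceResult(
        n_mapped=n_mapped, n_overlap=n_overlap, r=r, r_p=r_p,
        overlap_p=overlap_p, per_gene=per_gene,
    )
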