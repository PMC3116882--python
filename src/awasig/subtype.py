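"""Multiple-random-validation subtype discovery.

The procedure that turns a noisy case/control contrast into a robust
molecular subtype: the cohort is repeatedly split into stratified folds;
within each training set the probes are ranked by |t| and the top k feed
a support vector machine that classifies the held-out fold; each sample
therefore receives one atherosclerosis-like/not vote per repeat, and the
final subtype ("AWA", associated-with-atherosclerosis) is the strict
majority vote across repeats.  Feature selection and standardization are
re-done inside every training set, so no information from a test fold
ever reaches the classifier that judges it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import association
from .diffexpr import two_group_t
from .io_core import AnalysisConfig, ExpressionMatrix

__all__ = [
    "VoteMatrix",
    "stratified_partition",
    "rank_genes_by_t",
    "fit_and_classify",
    "multiple_random_validation",
    "assign_subtypes",
    "sweep_k",
]


@dataclass
class VoteMatrix:
    """One binary vote per sample per repeat (1 = classified as case-like)."""

    votes: np.ndarray  # (n_samples, n_repeats)
    sample_ids: list[str]

    @property
    def n_repeats(self) -> int:
        return self.votes.shape[1]

    def __post_init__(self) -> None:
        if self.votes.ndim != 2:
            raise ValueError("votes must be a 2-d sample x repeat matrix")
        if self.votes.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids do not match vote matrix rows")
        if not np.isin(self.votes, [0, 1]).all():
            raise ValueError("votes must be binary")


def _repeat_seed(rng_seed: int, repeat: int) -> np.random.Generator:
    """Stable per-repeat stream: SeedSequence keyed on (rng_seed, repeat)."""
    return np.random.default_rng(np.random.SeedSequence([rng_seed, repeat]))


def stratified_partition(labels, n_folds: int, seed) -> np.ndarray:
    """Random stratified fold assignment (fold ids 0..n_folds-1).

    Cases and controls are shuffled separately and dealt round-robin with
    a continuing pointer, so fold sizes differ by at most one and per-fold
    case counts differ by at most one.  Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    pointer = int(rng.integers(n_folds))  # randomize which folds get extras
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for i in idx:
            folds[i] = pointer % n_folds
            pointer += 1
    return folds


def rank_genes_by_t(train_values: np.ndarray, train_labels, probe_ids) -> np.ndarray:
    """Row indices sorted by decreasing |t| (case vs control in training).

    Ties are broken by lexicographic probe id so the ranking is fully
    deterministic.
    """
    train_labels = np.asarray(train_labels)
    if train_labels.sum() == 0 or train_labels.sum() == len(train_labels):
        raise ValueError("training set contains a single class")
    t, _, _, _ = two_group_t(train_values, train_labels)
    probe_ids = np.asarray(probe_ids)
    return np.lexsort((probe_ids, -np.abs(t)))


def fit_and_classify(
    train_values: np.ndarray,
    train_labels,
    test_values: np.ndarray,
    k_genes: int,
    config: AnalysisConfig,
    probe_ids=None,
) -> np.ndarray:
    """Train a top-k-gene SVM on the training columns, classify the test ones.

    ``train_values`` and ``test_values`` are probe x sample arrays sharing
    the probe axis.  Gene ranking and per-probe standardization parameters
    come from the training data only.
    """
    if k_genes > train_values.shape[0]:
        raise ValueError("k_genes exceeds the number of available probes")
    if probe_ids is None:
        probe_ids = np.arange(train_values.shape[0])
    order = rank_genes_by_t(train_values, train_labels, probe_ids)
    top = order[:k_genes]
    Xtr = train_values[top].T  # samples x features
    Xte = test_values[top].T
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    gamma = config.svm_gamma
    if gamma == "auto":
        gamma = 1.0 / k_genes
    clf = SVC(kernel=config.svm_kernel, C=config.svm_cost, gamma=gamma)
    clf.fit(Xtr, np.asarray(train_labels, dtype=int))
    return clf.predict(Xte).astype(int)


def multiple_random_validation(
    matrix: ExpressionMatrix,
    labels,
    config: AnalysisConfig,
    n_repeats: int | None = None,
    k_genes: int | None = None,
) -> VoteMatrix:
    """Repeated stratified cross-validation voting.

    Every repeat draws a fresh stratified fold plan (its random stream is
    derived deterministically from ``config.rng_seed`` and the repeat
    index), trains on n_folds - 1 folds and classifies the held-out fold,
    so each sample receives exactly one vote per repeat.
    """
    labels = np.asarray(labels, dtype=int)
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[1] != len(labels):
        raise ValueError("labels do not align with matrix samples")
    R = config.n_repeats if n_repeats is None else n_repeats
    k = config.k_genes if k_genes is None else k_genes
    probe_ids = np.asarray(matrix.probe_ids)
    votes = np.empty((x.shape[1], R), dtype=np.int8)
    for r in range(R):
        rng = _repeat_seed(config.rng_seed, r)
        folds = stratified_partition(labels, config.n_folds, rng)
        for f in range(config.n_folds):
            test = folds == f
            train = ~test
            try:
                pred = fit_and_classify(
                    x[:, train], labels[train], x[:, test], k, config, probe_ids
                )
            except Exception as exc:
                raise RuntimeError(f"repeat {r}, fold {f}: {exc}") from exc
            votes[test, r] = pred
    return VoteMatrix(votes=votes.astype(int), sample_ids=matrix.sample_ids)


def assign_subtypes(votes: VoteMatrix, config: AnalysisConfig) -> pd.DataFrame:
    """Strict-majority subtype call from the vote matrix.

    A sample is AWA iff its vote count strictly exceeds the threshold
    (default n_repeats / 2); a count exactly at the threshold is not AWA.
    """
    threshold = (
        votes.n_repeats / 2 if config.vote_threshold is None else config.vote_threshold
    )
    count = votes.votes.sum(axis=1)
    return pd.DataFrame(
        {
            "vote_count": count,
            "vote_fraction": count / votes.n_repeats,
            "awa": (count > threshold).astype(int),
        },
        index=pd.Index(votes.sample_ids, name="sample_id"),
    )


def sweep_k(
    matrix: ExpressionMatrix,
    labels,
    config: AnalysisConfig,
    ks=None,
    n_repeats: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Signature-size sweep: association strength of the assignment per k.

    For each candidate k the voting procedure is run (with a reduced
    repeat count by default) and the odds ratio of the resulting subtype
    against the true labels recorded; returns the per-k table and the k
    with the largest odds ratio.
    """
    if ks is None:
        lo, hi = config.k_genes_sweep
        ks = range(lo, hi + 1)
    labels = np.asarray(labels, dtype=int)
    rows = []
    for k in ks:
        vm = multiple_random_validation(
            matrix, labels, config, n_repeats=n_repeats, k_genes=int(k)
        )
        assignment = assign_subtypes(vm, config)
        table = association.crosstab(assignment, labels)
        res = association.odds_ratio(table, correction="haldane")
        rows.append({"k": int(k), "odds_ratio": res.odds_ratio,
                     "n_awa": int(assignment["awa"].sum())})
    out = pd.DataFrame(rows).set_index("k")
    best_k = int(out["odds_ratio"].idxmax())
    return out, best_k
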