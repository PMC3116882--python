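"""Synthetic cohorts with the structure the pipeline assumes.

The generator emulates a case-control blood-transcriptome study: a latent
binary molecular subtype Z linked to case status through a fixed
(sensitivity, specificity) pair, a fraction of probes shifted between the
Z strata, block-correlated probe groups driven by shared latent factors,
per-probe detection-call p-values, and covariates (Framingham risk score,
age) drawn per group from normal models.  Defaults mirror the study
regime this package targets: 48 cases / 71 controls, 2,057 probes, 20%
differentially expressed probes, subtype-case linkage at sensitivity 0.60
and specificity 0.76 (implying a crude odds ratio of
(0.60/0.40)/(0.24/0.76) = 4.75), four correlated probe blocks.

A null variant severs every dependence, and a paired baseline/post
variant emulates a second study whose per-probe shifts correlate with the
cohort's subtype effects at a chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "expected_crude_odds_ratio",
    "generate_cohort",
    "generate_null_cohort",
    "generate_paired_stimulus",
    "identity_annotation",
]


@dataclass
class CohortSpec:
    n_cases: int = 48
    n_controls: int = 71
    n_probes: int = 2057
    frac_de: float = 0.20          # fraction of probes shifted between subtypes
    effect_size_sd: float = 0.5    # log2 units; effects truncated away from 0 at 0.1
    sensitivity: float = 0.60      # P(Z = 1 | case)
    specificity: float = 0.76      # P(Z = 0 | control)
    n_blocks: int = 4              # correlated probe blocks (latent factors)
    within_block_corr: float = 0.6
    noise_sd: float = 0.7          # per-measurement log2 noise
    baseline_mean: float = 8.0     # mean log2 intensity of expressed probes
    baseline_sd: float = 1.0
    detection_fail_rate: float = 0.05  # probe/sample pairs below array background
    frs_case: tuple[float, float] = (5.8, 4.5)      # mean, SD (percent)
    frs_control: tuple[float, float] = (2.6, 2.9)
    age_case: tuple[float, float] = (69.4, 6.8)     # years
    age_control: tuple[float, float] = (64.3, 7.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_de <= 1):
            raise ValueError("frac_de must lie in [0, 1]")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_blocks > self.n_probes:
            raise ValueError("n_blocks cannot exceed n_probes")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    subtype: pd.Series        # per-sample latent Z
    probes: pd.DataFrame      # per-probe: de (bool), effect (log2), block


def expected_crude_odds_ratio(sensitivity: float, specificity: float) -> float:
    """Closed-form odds ratio implied by the subtype-case linkage."""
    return (sensitivity / (1 - sensitivity)) / ((1 - specificity) / specificity)


def _truncated_effects(rng: np.random.Generator, n: int, sd: float,
                       min_abs: float = 0.1) -> np.ndarray:
    """N(0, sd^2) draws resampled until |effect| >= min_abs."""
    out = rng.normal(0.0, sd, n)
    bad = np.abs(out) < min_abs
    while bad.any():
        out[bad] = rng.normal(0.0, sd, bad.sum())
        bad = np.abs(out) < min_abs
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, lower: float = 0.0) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _block_structure(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(block id, factor index, loading sign) per probe.

    Blocks are contiguous, equal-sized groups.  When there are at least
    three blocks the third reuses the first block's factor with negative
    loadings, emulating a pair of anticorrelated gene clusters.
    """
    block = np.repeat(np.arange(spec.n_blocks),
                      int(np.ceil(spec.n_probes / spec.n_blocks)))[: spec.n_probes]
    factor = block.copy()
    sign = np.ones(spec.n_probes)
    if spec.n_blocks >= 3:
        anti = block == 2
        factor[anti] = 0
        sign[anti] = -1.0
    return block, factor, sign


def _expression(
    spec: CohortSpec,
    rng: np.random.Generator,
    z: np.ndarray,
    effects: np.ndarray,
) -> np.ndarray:
    n_p, n_s = spec.n_probes, spec.n_samples
    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, n_p)
    _, factor_idx, sign = _block_structure(spec)
    factors = rng.normal(0.0, 1.0, (spec.n_blocks, n_s))
    load = spec.noise_sd * np.sqrt(spec.within_block_corr)
    idio = spec.noise_sd * np.sqrt(1 - spec.within_block_corr)
    x = (
        mu[:, None]
        + effects[:, None] * z[None, :]
        + load * sign[:, None] * factors[factor_idx]
        + rng.normal(0.0, idio, (n_p, n_s))
    )
    return x


def _detection(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    unexpressed = rng.random((spec.n_probes, spec.n_samples)) < spec.detection_fail_rate
    p = rng.uniform(0.0, 0.001, (spec.n_probes, spec.n_samples))
    p[unexpressed] = rng.uniform(0.0, 1.0, int(unexpressed.sum()))
    return p


def _covariates(spec: CohortSpec, rng: np.random.Generator,
                case: np.ndarray) -> pd.DataFrame:
    n = spec.n_samples
    frs = np.empty(n)
    age = np.empty(n)
    is_case = case == 1
    frs[is_case] = _truncated_normal(rng, *spec.frs_case, int(is_case.sum()))
    frs[~is_case] = _truncated_normal(rng, *spec.frs_control, int((~is_case).sum()))
    age[is_case] = rng.normal(*spec.age_case, int(is_case.sum()))
    age[~is_case] = rng.normal(*spec.age_control, int((~is_case).sum()))
    return pd.DataFrame({"case_status": case, "frs": frs, "age": age})


def _ids(spec: CohortSpec) -> tuple[list[str], list[str]]:
    probes = [f"P{i:06d}" for i in range(spec.n_probes)]
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    return probes, samples


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Draw one cohort: expression + detection, annotation, ground truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    case = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    z = np.where(
        case == 1,
        (rng.random(spec.n_samples) < spec.sensitivity).astype(int),
        (rng.random(spec.n_samples) < 1 - spec.specificity).astype(int),
    )
    n_de = int(round(spec.frac_de * spec.n_probes))
    de = np.zeros(spec.n_probes, dtype=bool)
    de[rng.choice(spec.n_probes, n_de, replace=False)] = True
    effects = np.zeros(spec.n_probes)
    if n_de:
        effects[de] = _truncated_effects(rng, n_de, spec.effect_size_sd)

    x = _expression(spec, rng, z, effects)
    det = _detection(spec, rng)
    probes, samples = _ids(spec)
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=probes, columns=samples),
        pd.DataFrame(det, index=probes, columns=samples),
    )
    annotation = _covariates(spec, rng, case)
    annotation.index = pd.Index(samples, name="sample_id")
    block, _, _ = _block_structure(spec)
    truth = CohortTruth(
        subtype=pd.Series(z, index=samples, name="subtype"),
        probes=pd.DataFrame(
            {"de": de, "effect": effects, "block": block}, index=probes
        ),
    )
    return matrix, annotation, truth


def generate_null_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """A cohort with no subtype-probe and no subtype-phenotype dependence.

    All structure is severed: subtype effects are zero, the latent factor
    loadings are dropped so probes are mutually exchangeable pure noise,
    and the latent subtype is a fair coin independent of case status.
    Case labels are therefore exchangeable with respect to expression and
    per-probe p-values are independently uniform.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    case = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    z = (rng.random(spec.n_samples) < 0.5).astype(int)
    effects = np.zeros(spec.n_probes)
    iid = replace(spec, within_block_corr=0.0)
    x = _expression(iid, rng, z, effects)
    det = _detection(spec, rng)
    probes, samples = _ids(spec)
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=probes, columns=samples),
        pd.DataFrame(det, index=probes, columns=samples),
    )
    annotation = _covariates(spec, rng, case)
    annotation.index = pd.Index(samples, name="sample_id")
    block, _, _ = _block_structure(spec)
    truth = CohortTruth(
        subtype=pd.Series(z, index=samples, name="subtype"),
        probes=pd.DataFrame(
            {"de": np.zeros(spec.n_probes, dtype=bool), "effect": effects,
             "block": block},
            index=probes,
        ),
    )
    return matrix, annotation, truth


def generate_paired_stimulus(
    spec: CohortSpec,
    shared_effect_fraction: float = 1.0,
    cross_corr: float = 0.6,
    n_subjects: int = 8,
    noise_sd: float = 0.2,
    subject_sd: float = 0.3,
    effects: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """A paired baseline/post-stimulus study correlated with the cohort.

    For the shared fraction of probes the post-stimulus shift is drawn so
    its population correlation with the cohort's subtype effects equals
    ``cross_corr``; the remaining probes get independent shifts with the
    same marginal mixture.  ``effects`` may pass in the effect vector of
    an actual generated cohort (``truth.probes["effect"]``); by default a
    fresh cohort-style effect vector is drawn.

    Returns (baseline, post, truth) where truth holds per-probe
    ``effect_a``, ``effect_b`` and the ``shared`` flag.
    """
    if not (-1 <= cross_corr <= 1):
        raise ValueError("cross_corr must lie in [-1, 1]")
    if not (0 <= shared_effect_fraction <= 1):
        raise ValueError("shared_effect_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_p = spec.n_probes

    def mixture_effects() -> np.ndarray:
        out = np.zeros(n_p)
        n_de = int(round(spec.frac_de * n_p))
        idx = rng.choice(n_p, n_de, replace=False)
        if n_de:
            out[idx] = _truncated_effects(rng, n_de, spec.effect_size_sd)
        return out

    eff_a = mixture_effects() if effects is None else np.asarray(effects, float)
    if eff_a.shape != (n_p,):
        raise ValueError("effects vector does not match n_probes")
    sigma_a = eff_a.std()
    shared = rng.random(n_p) < shared_effect_fraction
    eff_b = mixture_effects()  # independent draws for the non-shared part
    correlated = (
        cross_corr * eff_a
        + np.sqrt(max(0.0, 1 - cross_corr**2)) * sigma_a * rng.normal(0, 1, n_p)
    )
    eff_b[shared] = correlated[shared]

    probes = [f"P{i:06d}" for i in range(n_p)]
    subjects = [f"SUBJ{i:02d}" for i in range(n_subjects)]
    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, n_p)
    subj = rng.normal(0.0, subject_sd, n_subjects)
    base = mu[:, None] + subj[None, :] + rng.normal(0, noise_sd, (n_p, n_subjects))
    post = (
        mu[:, None] + subj[None, :] + eff_b[:, None]
        + rng.normal(0, noise_sd, (n_p, n_subjects))
    )
    baseline_m = ExpressionMatrix(pd.DataFrame(base, index=probes, columns=subjects))
    post_m = ExpressionMatrix(pd.DataFrame(post, index=probes, columns=subjects))
    truth = pd.DataFrame(
        {"effect_a": eff_a, "effect_b": eff_b, "shared": shared}, index=probes
    )
    return baseline_m, post_m, truth


def identity_annotation(probe_ids, prefix: str = "GENE") -> pd.DataFrame:
    """A one-probe-per-gene annotation table for same-platform comparisons."""
    return pd.DataFrame(
        {"probe_id": list(probe_ids),
         "gene_symbol": [f"{prefix}_{p}" for p in probe_ids]}
    )
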