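"""Core domain containers and file I/O.

The pipeline's native interchange format is plain TSV: an expression matrix
with probes as rows (first column ``probe_id``, header row of sample ids),
an optional detection-p-value matrix with identical axes, and a CSV/TSV
sample-annotation table with at least ``sample_id`` and ``case_status``
columns.  GEO Series-Matrix files are supported as an alternative
expression input (``!Sample_geo_accession`` supplies the sample ids).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "AnalysisConfig",
    "read_expression",
    "write_expression",
    "read_detection",
    "read_annotation",
    "write_annotation",
    "align_samples",
]

REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "case_status")


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """A probe x sample matrix of log2 intensities.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
    detection_p
        Optional DataFrame of detection-call p-values (the per-probe,
        per-sample evidence that a transcript is expressed above array
        background), shape-matched to ``values`` with entries in [0, 1].
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate probe ids: {dups[:10]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups[:10]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite expression value at probe "
                f"{v.index[bad[0]]!r}, sample {v.columns[bad[1]]!r}"
            )
        d = self.detection_p
        if d is not None:
            if list(d.index) != list(v.index) or list(d.columns) != list(v.columns):
                raise ParseError("detection matrix axes do not match expression axes")
            darr = d.to_numpy()
            if np.nanmin(darr) < 0 or np.nanmax(darr) > 1:
                raise ParseError("detection p-values must lie in [0, 1]")

    # -- convenience accessors -------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given probes/samples."""
        v = self.values
        d = self.detection_p
        if probes is not None:
            v = v.loc[list(probes)]
            d = d.loc[list(probes)] if d is not None else None
        if samples is not None:
            v = v[list(samples)]
            d = d[list(samples)] if d is not None else None
        return ExpressionMatrix(v, d)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Defaults reproduce the study design this package emulates: a
    119-sample cohort filtered to ~2,000 probes, ten-fold stratified
    splits repeated 1,000 times with top-50 |t| gene selection and an
    RBF support vector machine, majority vote with a strict >R/2 rule.
    """

    # probe filtering
    cv_exclude_below: float = 0.03
    detection_alpha: float = 0.01
    min_detected_samples: int = 61
    cv_on_log_scale: bool = False
    # subtype discovery
    k_genes: int = 50
    k_genes_sweep: tuple[int, int] = (1, 100)
    n_folds: int = 10
    n_repeats: int = 1000
    vote_threshold: int | None = None  # None -> n_repeats / 2, strict majority
    svm_kernel: str = "rbf"
    svm_cost: float = 1.0
    svm_gamma: float | str = "auto"  # "auto" -> 1 / n_features
    # differential expression
    n_permutations: int = 1000
    equal_var: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        lo, hi = self.k_genes_sweep
        if not (1 <= lo <= hi):
            raise ValueError("k_genes_sweep must be an increasing positive range")
        if not (lo <= self.k_genes <= hi):
            raise ValueError("k_genes must lie within k_genes_sweep")
        if not (0 < self.detection_alpha < 1):
            raise ValueError("detection_alpha must lie in (0, 1)")
        if self.cv_exclude_below < 0:
            raise ValueError("cv_exclude_below must be >= 0")
        if self.min_detected_samples < 0:
            raise ValueError("min_detected_samples must be >= 0")
        if self.vote_threshold is not None and not (
            0 <= self.vote_threshold <= self.n_repeats
        ):
            raise ValueError("vote_threshold must lie in [0, n_repeats]")

    def effective_vote_threshold(self) -> float:
        return self.n_repeats / 2 if self.vote_threshold is None else self.vote_threshold

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_genes_sweep" in raw:
            raw["k_genes_sweep"] = tuple(raw["k_genes_sweep"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["k_genes_sweep"] = list(self.k_genes_sweep)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    format: str = "tsv",
    detection_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO Series-Matrix file.

    The TSV dialect expects the first column to hold probe ids and the
    header row to hold sample ids.  ``detection_path`` optionally attaches
    a detection-p-value matrix with identical axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        values = _read_matrix_tsv(path)
    elif format == "geo_series_matrix":
        values = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    detection = None
    if detection_path is not None:
        detection = _read_matrix_tsv(Path(detection_path))
        detection = detection.reindex(index=values.index, columns=values.columns)
        if detection.isna().any().any():
            raise ParseError("detection matrix does not cover all probes/samples")
    return ExpressionMatrix(values, detection)


def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    try:
        # round_trip parsing: bitwise-exact write -> read for repr floats
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate probe ids {dups[:10]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in columns {non_numeric[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def _read_series_matrix(path: Path) -> pd.DataFrame:
    """Parse the data table of a GEO Series-Matrix text file.

    Only the ``!series_matrix_table_begin`` .. ``table_end`` block is read;
    ``!Sample_geo_accession`` (when present) supplies the sample ids.
    """
    accessions: list[str] | None = None
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!Sample_geo_accession"):
                accessions = [t.strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!series_matrix_table_begin"):
                in_table = True
            elif line.startswith("!series_matrix_table_end"):
                in_table = False
            elif in_table and line:
                table_lines.append(line)
    if not table_lines:
        raise ParseError(f"{path}: no series-matrix table found")
    rows = [l.split("\t") for l in table_lines]
    header = [t.strip('"') for t in rows[0]]
    body = rows[1:]
    probe_ids = [r[0].strip('"') for r in body]
    try:
        data = np.array([[float(x) for x in r[1:]] for r in body])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in table: {exc}") from exc
    columns = accessions if accessions is not None else header[1:]
    if len(columns) != data.shape[1]:
        raise ParseError(f"{path}: header width does not match table width")
    return pd.DataFrame(data, index=probe_ids, columns=columns)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     detection_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally its detection matrix) as TSV.

    Uses repr-precision floats so a write -> read round trip is exact.
    """
    matrix.values.to_csv(path, sep="\t", index_label="probe_id",
                         float_format=None)
    if detection_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix has no detection p-values to write")
        matrix.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_detection(path: str | Path) -> pd.DataFrame:
    """Read a standalone detection-p-value matrix (TSV, same dialect)."""
    df = _read_matrix_tsv(Path(path))
    if df.to_numpy().min() < 0 or df.to_numpy().max() > 1:
        raise ParseError(f"{path}: detection p-values must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation table (CSV or TSV, sniffed by extension).

    Returns a DataFrame indexed by ``sample_id`` with an integer
    ``case_status`` column (1 = case) plus whatever covariate columns are
    present (``frs`` in percent, ``age`` in years, medication flags...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty annotation file") from exc
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: annotation table has no rows")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:10]}")
    status = pd.to_numeric(df["case_status"], errors="coerce")
    if status.isna().any() or not status.isin([0, 1]).all():
        bad = df.loc[~status.isin([0, 1]), "case_status"].tolist()
        raise ParseError(f"{path}: case_status must be 0/1, got {bad[:10]}")
    df["case_status"] = status.astype(int)
    if "frs" in df.columns:
        frs = pd.to_numeric(df["frs"], errors="coerce")
        if (frs.dropna() < 0).any():
            raise ParseError(f"{path}: frs must be >= 0")
        df["frs"] = frs
    return df.set_index("sample_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    annotation.to_csv(path, sep=sep, index_label="sample_id")


def align_samples(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict matrix and annotation to their common samples, same order.

    The intersection keeps the matrix's column order.  Dropped ids are
    logged as a warning; an empty intersection is an error.
    """
    common = [s for s in matrix.sample_ids if s in annotation.index]
    if not common:
        raise ValueError("expression matrix and annotation share no sample ids")
    dropped = sorted(
        (set(matrix.sample_ids) | set(annotation.index)) - set(common)
    )
    if dropped:
        logger.warning("align_samples dropped %d sample(s): %s",
                       len(dropped), dropped[:20])
    return matrix.subset(samples=common), annotation.loc[common]
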