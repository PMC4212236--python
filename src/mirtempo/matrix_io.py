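"""Parsing and writing of the tab-delimited count-matrix dialect.

The input is a TSV file whose first column is the feature (miRNA) name and
whose remaining ``n_timepoints * n_replicates`` columns are non-negative
counts, laid out time-point-major: all replicates of time point 1, then all
replicates of time point 2, and so on.  A header line is optional and is
detected by a non-numeric second field.

All tabular outputs (results tables, heatmap text matrices) are plain TSV,
UTF-8, ``\\n`` line endings, ``.`` decimal point.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CardinalityError,
    DimensionMismatchError,
    DuplicateFeatureNameError,
    MatrixFormatError,
    MissingFileError,
    NegativeCountError,
    NonNumericCountError,
    RaggedRowError,
    UnwritablePathError,
)

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 2
MAX_TIMEPOINTS = 20
MIN_REPLICATES = 1
MAX_REPLICATES = 3

#: significant digits used for all numeric TSV output; round-trips doubles
#: losslessly at the precision the results-table contract requires
_FLOAT_FMT = "%.12g"


@dataclass
class AnalysisConfig:
    """Run-level parameters shared by every stage.

    Parameters
    ----------
    n_replicates, n_timepoints
        Expected layout of the input matrix; parsing fails on mismatch.
    corr_threshold
        Pearson-r gate for replicate retention, in (0, 1]. Default 0.70.
    alpha
        Significance level for both the linear and non-linear stages.
    nqt_mode
        ``"deterministic"`` uses the expected-order-statistic approximation
        of the sorted normal sample; ``"random_draw"`` draws and sorts
        pseudo-random normals (requires ``seed``).
    seed
        Seed for ``random_draw`` mode; ignored in deterministic mode.
    linkage
        Agglomerative linkage for heatmap row clustering.
    anova_split
        Grouping rule for the >3-time-point ANOVA stage; only the
        deterministic half split is defined.
    multiple_testing
        ``"none"`` (raw p-values, the default) or ``"benjamini_hochberg"``.
    cdf_two_sided
        If True the CDF stage uses the two-sided p = 2(1 - Phi(|d|));
        the default is the one-sided form p = Phi(tpn - tp1).
    """

    n_replicates: int
    n_timepoints: int
    corr_threshold: float = 0.70
    alpha: float = 0.05
    nqt_mode: str = "deterministic"
    seed: int | None = None
    linkage: str = "complete"
    anova_split: str = "half_split"
    multiple_testing: str = "none"
    cdf_two_sided: bool = False

    def __post_init__(self):
        if not (MIN_TIMEPOINTS <= self.n_timepoints <= MAX_TIMEPOINTS):
            raise CardinalityError(
                f"n_timepoints must be in [{MIN_TIMEPOINTS}, {MAX_TIMEPOINTS}], "
                f"got {self.n_timepoints}"
            )
        if not (MIN_REPLICATES <= self.n_replicates <= MAX_REPLICATES):
            raise CardinalityError(
                f"n_replicates must be in [{MIN_REPLICATES}, {MAX_REPLICATES}], "
                f"got {self.n_replicates}"
            )
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.nqt_mode not in ("deterministic", "random_draw"):
            raise ValueError(f"unknown nqt_mode {self.nqt_mode!r}")
        if self.nqt_mode == "random_draw" and self.seed is None:
            raise ValueError("random_draw mode requires a seed")
        if self.linkage not in ("complete", "average", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.anova_split != "half_split":
            raise ValueError(f"unknown anova_split {self.anova_split!r}")
        if self.multiple_testing not in ("none", "benjamini_hochberg"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")


@dataclass
class CountMatrix:
    """Raw parsed input: features x time points x replicates, counts >= 0."""

    feature_names: list[str]
    counts: np.ndarray  # shape (n_features, n_timepoints, n_replicates)
    n_timepoints: int
    n_replicates: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (
            len(self.feature_names),
            self.n_timepoints,
            self.n_replicates,
        ):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.feature_names)}, {self.n_timepoints}, {self.n_replicates})"
            )
        if not (MIN_TIMEPOINTS <= self.n_timepoints <= MAX_TIMEPOINTS):
            raise CardinalityError(f"n_timepoints={self.n_timepoints} outside [2, 20]")
        if not (MIN_REPLICATES <= self.n_replicates <= MAX_REPLICATES):
            raise CardinalityError(f"n_replicates={self.n_replicates} outside [1, 3]")
        if any(not name for name in self.feature_names):
            raise ValueError("feature names must be non-empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DuplicateFeatureNameError("feature names must be unique")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise NegativeCountError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _parse_cell(token: str, line_no: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise NonNumericCountError(f"count {token!r} is not numeric", line=line_no)
    if math.isnan(value) or math.isinf(value):
        raise NonNumericCountError(f"count {token!r} is not finite", line=line_no)
    if value < 0:
        raise NegativeCountError(f"count {value} is negative", line=line_no)
    return value


def _is_number(token: str) -> bool:
    try:
        return math.isfinite(float(token))
    except ValueError:
        return False


def parse_count_matrix(path: str | Path, config: AnalysisConfig) -> CountMatrix:
    """Parse a tab-delimited count matrix, validating against *config*.

    Columns must be time-point-major (t1r1 t1r2 ... t2r1 ...).  An optional
    header line is skipped when its second field is non-numeric.  Row order
    of the file is preserved.

    Raises
    ------
    MissingFileError, RaggedRowError, NonNumericCountError,
    NegativeCountError, DuplicateFeatureNameError, CardinalityError
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"input file not found: {path}")

    expected = config.n_timepoints * config.n_replicates
    names: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line_no, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank line
            if line_no == 1 and len(fields) >= 2 and not _is_number(fields[1]):
                continue  # header line
            if len(fields) != 1 + expected:
                raise RaggedRowError(
                    f"expected {1 + expected} tab-separated fields "
                    f"(1 name + {config.n_timepoints} time points x "
                    f"{config.n_replicates} replicates), got {len(fields)}",
                    line=line_no,
                )
            name = fields[0].strip()
            if not name:
                raise MatrixFormatError("feature name is empty", line=line_no)
            if name in seen:
                raise DuplicateFeatureNameError(
                    f"duplicate feature name {name!r}", line=line_no
                )
            seen.add(name)
            names.append(name)
            rows.append([_parse_cell(tok, line_no) for tok in fields[1:]])

    if not names:
        raise RaggedRowError("input file contains no data rows", line=None)

    counts = np.asarray(rows, dtype=float).reshape(
        len(names), config.n_timepoints, config.n_replicates
    )
    return CountMatrix(
        feature_names=names,
        counts=counts,
        n_timepoints=config.n_timepoints,
        n_replicates=config.n_replicates,
    )


def write_count_matrix(m: CountMatrix, path: str | Path, header: bool = True) -> Path:
    """Write a CountMatrix in the exact dialect :func:`parse_count_matrix` reads."""
    path = Path(path)
    cols = [
        f"t{t + 1}r{r + 1}"
        for t in range(m.n_timepoints)
        for r in range(m.n_replicates)
    ]
    flat = m.counts.reshape(m.n_features, -1)
    df = pd.DataFrame(flat, index=m.feature_names, columns=cols)
    try:
        df.to_csv(
            path, sep="\t", header=header, index=True, index_label="miRNA",
            float_format=_FLOAT_FMT, lineterminator="\n",
        )
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {path}: {exc}") from exc
    return path


def write_results_table(results: Sequence, path: str | Path) -> Path:
    """Write per-feature test results as TSV.

    One row per feature: name, method label, p-value, intercept, slope.
    Intercept/slope are blank for features that only have a non-linear
    result.  Numbers survive a round-trip at 12 significant digits.
    """
    path = Path(path)
    rows = []
    for res in results:
        if res.linear is not None:
            p = res.linear.p_value
            intercept: float | str = res.linear.intercept
            slope: float | str = res.linear.slope
            method = "linear"
            if res.classification == "nonlinear_significant" and res.nonlinear is not None:
                method = res.nonlinear.method.lower()
                p = res.nonlinear.min_p_value()
        else:
            method = res.nonlinear.method.lower() if res.nonlinear else "none"
            p = res.nonlinear.min_p_value() if res.nonlinear else float("nan")
            intercept = ""
            slope = ""
        rows.append(
            {
                "miRNA": res.feature_name,
                "method": method,
                "classification": res.classification,
                "p_value": p,
                "intercept": intercept,
                "slope": slope,
            }
        )
    df = pd.DataFrame(
        rows, columns=["miRNA", "method", "classification", "p_value", "intercept", "slope"]
    )
    if df.empty:
        logger.warning("results table %s written with header only (no features)", path)
    try:
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {path}: {exc}") from exc
    return path


def write_heatmap_text(
    feature_names: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    column_labels: Sequence[str] | None = None,
) -> Path | None:
    """Write a feature x time-point matrix as a TSV heatmap file.

    The dialect (row labels in the first column, time-point labels in the
    header) is loadable by generic matrix viewers.  An empty subset writes
    nothing and logs a warning.
    """
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if len(feature_names) == 0:
        logger.warning("heatmap %s skipped: empty feature subset", path)
        return None
    if values.ndim != 2 or values.shape[0] != len(feature_names):
        raise DimensionMismatchError(
            f"values shape {values.shape} does not match "
            f"{len(feature_names)} feature names"
        )
    if column_labels is None:
        column_labels = [f"t{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=list(feature_names), columns=list(column_labels))
    try:
        df.to_csv(path, sep="\t", index=True, index_label="miRNA",
                  float_format=_FLOAT_FMT, lineterminator="\n")
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {path}: {exc}") from exc
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Re-read a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def read_heatmap_text(path: str | Path) -> pd.DataFrame:
    """Re-read a heatmap TSV written by :func:`write_heatmap_text`."""
    return pd.read_csv(path, sep="\t", index_col=0)
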