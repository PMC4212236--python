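"""Replicate gating by Pearson correlation and collapse to one value per
feature per time point.

Within each time point, replicate 1 is the anchor and is always retained.
Replicate 2 is retained iff its Pearson correlation with replicate 1
(computed across all features) meets the threshold.  Replicate 3 is gated
incrementally: it is compared against the mean of the replicates retained
so far.  Retained replicates are averaged with equal weights; excluded
replicates contribute nothing.  A replicate whose vector is constant has an
undefined correlation and is excluded with a warning rather than crashing
the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ZeroVarianceError
from .matrix_io import CountMatrix

logger = logging.getLogger(__name__)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`ZeroVarianceError` when either vector is constant
    (the coefficient is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson_r needs two equal-length 1-D vectors of size >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("pearson_r inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(a, b).statistic)
    # numerical guard: the coefficient is a cosine, clamp rounding spill
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class ReplicateDecision:
    """Outcome of gating one replicate at one time point."""

    timepoint: int  # 1-based
    replicate: int  # 1-based
    retained: bool
    r: float | None  # correlation driving the decision; None for the anchor
    reason: str


@dataclass
class CollapsedMatrix:
    """One value per feature per time point, with QC provenance."""

    feature_names: list[str]
    values: np.ndarray  # shape (n_features, n_timepoints)
    replicate_report: list[list[ReplicateDecision]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def collapse_replicates(m: CountMatrix, threshold: float) -> CollapsedMatrix:
    """Gate replicates per time point and average the retained ones.

    Replicate 1 anchors each time point. Each further replicate k is
    retained iff its correlation with the mean of the already-retained
    replicates is >= *threshold*; undefined correlations (constant vectors)
    exclude the replicate with a logged warning.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    n_feat, n_tp, n_rep = m.counts.shape
    values = np.empty((n_feat, n_tp), dtype=float)
    report: list[list[ReplicateDecision]] = []

    for t in range(n_tp):
        decisions = [
            ReplicateDecision(
                timepoint=t + 1, replicate=1, retained=True, r=None,
                reason="anchor replicate, always retained",
            )
        ]
        retained = [m.counts[:, t, 0]]
        for k in range(1, n_rep):
            candidate = m.counts[:, t, k]
            anchor = np.mean(retained, axis=0)
            try:
                r = pearson_r(anchor, candidate)
            except ZeroVarianceError:
                logger.warning(
                    "time point %d replicate %d excluded: correlation undefined "
                    "(constant vector)", t + 1, k + 1,
                )
                decisions.append(
                    ReplicateDecision(
                        timepoint=t + 1, replicate=k + 1, retained=False, r=None,
                        reason="zero variance: correlation undefined",
                    )
                )
                continue
            keep = r >= threshold
            if not keep:
                logger.warning(
                    "time point %d replicate %d excluded: r=%.4f < threshold %.2f",
                    t + 1, k + 1, r, threshold,
                )
            decisions.append(
                ReplicateDecision(
                    timepoint=t + 1, replicate=k + 1, retained=keep, r=r,
                    reason=(
                        f"r={r:.6f} {'>=' if keep else '<'} threshold {threshold}"
                    ),
                )
            )
            if keep:
                retained.append(candidate)
        values[:, t] = np.mean(retained, axis=0)
        report.append(decisions)

    return CollapsedMatrix(
        feature_names=list(m.feature_names), values=values, replicate_report=report
    )
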