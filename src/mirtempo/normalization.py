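"""Normal quantile transformation (NQT) of the collapsed matrix.

Each time-point column is transformed independently: a sorted reference
vector of n standard-normal values is built (n = number of features), the
column's values are ranked with a stable first-occurrence tie-break, and
each value is replaced by the reference value at its rank.  The column's
empirical distribution becomes (exactly, up to the reference construction)
standard normal while the ordering of features is preserved.

Two reference constructions are offered.  ``deterministic`` (the default)
uses the expected-order-statistic approximation Phi^-1((i - 0.5) / n),
which is reproducible run to run.  ``random_draw`` draws n pseudo-random
standard normals from a seed and sorts them, reproducing the original
randomized construction; the seed is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NonPositiveNError
from .matrix_io import AnalysisConfig
from .replicate_qc import CollapsedMatrix


def reference_normals(
    n: int,
    mode: str = "deterministic",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sorted vector of n standard-normal reference values.

    deterministic mode returns Phi^-1((i - 0.5)/n) for i = 1..n; random_draw
    mode sorts n pseudo-random N(0,1) deviates drawn from *rng* or *seed*.
    """
    if n < 1:
        raise NonPositiveNError(f"need n >= 1, got {n}")
    if mode == "deterministic":
        probs = (np.arange(1, n + 1) - 0.5) / n
        return stats.norm.ppf(probs)
    if mode == "random_draw":
        if rng is None:
            if seed is None:
                raise ValueError("random_draw mode requires a seed or rng")
            rng = np.random.default_rng(seed)
        return np.sort(rng.standard_normal(n))
    raise ValueError(f"unknown mode {mode!r}")


def rank_with_ties(x: np.ndarray) -> np.ndarray:
    """Integer ranks 1..n; ties broken by original position (stable)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_with_ties expects a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("rank_with_ties requires finite values")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=int)
    ranks[order] = np.arange(1, x.size + 1)
    return ranks


@dataclass
class NormalizedMatrix:
    """NQT scores plus the per-column reference and rank vectors."""

    feature_names: list[str]
    nqt: np.ndarray  # shape (n_features, n_timepoints)
    rn: list[np.ndarray]  # per column: sorted reference normals
    qt: list[np.ndarray]  # per column: integer ranks 1..n
    mode: str
    seed: int | None = None

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_timepoints(self) -> int:
        return self.nqt.shape[1]


def nqt_transform(m: CollapsedMatrix, config: AnalysisConfig) -> NormalizedMatrix:
    """Apply the NQT independently to each time-point column of *m*.

    In random_draw mode one generator seeded by ``config.seed`` supplies a
    fresh reference draw per column; in deterministic mode every column
    shares the same expected-order-statistic reference.
    """
    n = m.n_features
    if n < 1:
        raise NonPositiveNError("matrix has no features")
    rng = (
        np.random.default_rng(config.seed)
        if config.nqt_mode == "random_draw"
        else None
    )
    nqt = np.empty_like(m.values)
    rn_cols: list[np.ndarray] = []
    qt_cols: list[np.ndarray] = []
    for t in range(m.n_timepoints):
        rn = reference_normals(n, mode=config.nqt_mode, rng=rng)
        ranks = rank_with_ties(m.values[:, t])
        nqt[:, t] = rn[ranks - 1]
        rn_cols.append(rn)
        qt_cols.append(ranks)
    return NormalizedMatrix(
        feature_names=list(m.feature_names),
        nqt=nqt,
        rn=rn_cols,
        qt=qt_cols,
        mode=config.nqt_mode,
        seed=config.seed,
    )
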