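"""Synthetic count matrices with known ground truth.

The generator emulates a miRNA-seq time course: baseline abundances are
log-uniform across features (spanning roughly 8 to 1000 counts by
default), counts are negative-binomial with a quadratic mean-variance
relationship (var = mu + dispersion * mu^2), and replicates are
independent re-draws around a per-replicate log2-mean perturbed by
Gaussian noise, which controls the inter-replicate Pearson correlation.

Three feature classes are planted: ``linear`` features ramp their
log2-mean up or down by ``effect_size`` per time step, ``transient``
features pulse a single interior time point by ``effect_size`` log2
units, and the remainder are ``null`` (constant mean).  The returned
labels allow exact confusion-matrix computation for any pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidSpecError, UnreachableTargetError
from .matrix_io import CountMatrix
from .replicate_qc import pearson_r


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic time-course dataset.

    effect_size is in log2-mean units per time step; dispersion is the
    negative-binomial overdispersion (var = mu + dispersion * mu^2);
    replicate_noise is the standard deviation of the per-replicate
    log2-mean perturbation.
    """

    n_features: int = 500
    n_timepoints: int = 6
    n_replicates: int = 2
    frac_linear: float = 0.1
    frac_transient: float = 0.1
    effect_size: float = 1.0
    dispersion: float = 0.1
    replicate_noise: float = 0.05
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1:
            raise InvalidSpecError("n_features must be >= 1")
        if not (2 <= self.n_timepoints <= 20):
            raise InvalidSpecError("n_timepoints must be in [2, 20]")
        if not (1 <= self.n_replicates <= 3):
            raise InvalidSpecError("n_replicates must be in [1, 3]")
        for name in ("frac_linear", "frac_transient"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidSpecError(f"{name} must be in [0, 1]")
        if self.frac_linear + self.frac_transient > 1.0:
            raise InvalidSpecError("class fractions must sum to <= 1")
        if self.dispersion < 0 or self.replicate_noise < 0:
            raise InvalidSpecError("dispersion and replicate_noise must be >= 0")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean mu, var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def generate_dataset(spec: SyntheticSpec) -> tuple[CountMatrix, list[str]]:
    """Generate a count matrix and its per-feature ground-truth labels.

    Labels are ``"linear"``, ``"transient"`` or ``"null"``, in feature
    order.  The same spec (including seed) always yields the same matrix.
    """
    rng = np.random.default_rng(spec.seed)
    F, T, R = spec.n_features, spec.n_timepoints, spec.n_replicates

    n_linear = round(spec.frac_linear * F)
    n_transient = round(spec.frac_transient * F)
    labels = (
        ["linear"] * n_linear
        + ["transient"] * n_transient
        + ["null"] * (F - n_linear - n_transient)
    )

    lo, hi = spec.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=F)

    # per-feature log2-mean trajectory over time
    log2_mean = np.tile(baseline[:, None], (1, T)).astype(float)
    t_idx = np.arange(T, dtype=float)
    # trend sign is headroom-aware: a rank-based normalization cannot express
    # a trend for a feature already at the extreme of the abundance range, so
    # features in the upper half ramp down and those in the lower half ramp up
    mid = 0.5 * (lo + hi)
    signs = np.where(baseline[:n_linear] >= mid, -1.0, 1.0)
    for i in range(n_linear):
        log2_mean[i] += signs[i] * spec.effect_size * t_idx
    pulse_signs = rng.choice([-1.0, 1.0], size=n_transient)
    pulse_tps = rng.integers(1, max(T - 1, 1), size=n_transient)  # interior tp
    for j in range(n_transient):
        i = n_linear + j
        log2_mean[i, pulse_tps[j]] += pulse_signs[j] * 2.0 * spec.effect_size

    counts = np.empty((F, T, R), dtype=float)
    if spec.replicate_noise == 0 and R > 1:
        # degenerate knob setting: replicates are exact duplicates
        for t in range(T):
            col = _nb_draw(rng, 2.0 ** log2_mean[:, t], spec.dispersion)
            counts[:, t, :] = col[:, None]
    else:
        for t in range(T):
            for r in range(R):
                mu = 2.0 ** (
                    log2_mean[:, t]
                    + rng.normal(0.0, spec.replicate_noise, size=F)
                )
                counts[:, t, r] = _nb_draw(rng, mu, spec.dispersion)

    names = [f"miR-syn-{i + 1:04d}" for i in range(F)]
    matrix = CountMatrix(
        feature_names=names, counts=counts, n_timepoints=T, n_replicates=R
    )
    return matrix, labels


def measure_replicate_r(
    spec: SyntheticSpec, measure_seed: int = 12345, n_draws: int = 10
) -> float:
    """Empirical Pearson r between replicates 1 and 2.

    Averaged over all time points of *n_draws* independently generated
    datasets: raw counts are heavy-tailed, so a single pair's r is noisy
    and the calibration loop needs a lower-variance estimate.
    """
    if spec.n_replicates < 2:
        raise InvalidSpecError("need >= 2 replicates to measure correlation")
    rs = []
    for j in range(n_draws):
        m, _ = generate_dataset(replace(spec, seed=measure_seed + j))
        rs += [
            pearson_r(m.counts[:, t, 0], m.counts[:, t, 1])
            for t in range(spec.n_timepoints)
        ]
    return float(np.mean(rs))


def replicate_correlation_knob(
    spec: SyntheticSpec,
    target_r: float,
    tol: float = 0.01,
    max_iter: int = 40,
) -> SyntheticSpec:
    """Calibrate ``replicate_noise`` so replicate pairs reach *target_r*.

    Bisects replicate_noise until the empirical replicate correlation
    (measured on >= 500 features) is within *tol* of the target.
    ``target_r = 1.0`` returns the degenerate duplicated-column spec.
    Raises :class:`UnreachableTargetError` when the target exceeds the
    correlation floor set by counting noise alone.
    """
    if not (0.0 < target_r <= 1.0):
        raise ValueError("target_r must be in (0, 1]")
    if spec.n_features < 500:
        spec = replace(spec, n_features=500)
    if target_r == 1.0:
        return replace(spec, replicate_noise=0.0)

    lo, hi = 1e-4, 4.0
    r_at_lo = measure_replicate_r(replace(spec, replicate_noise=lo))
    if target_r > r_at_lo + tol:
        raise UnreachableTargetError(
            f"target r={target_r} above the achievable ceiling "
            f"{r_at_lo:.3f} set by counting noise"
        )
    r_at_hi = measure_replicate_r(replace(spec, replicate_noise=hi))
    if target_r < r_at_hi - tol:
        raise UnreachableTargetError(
            f"target r={target_r} below the floor {r_at_hi:.3f} "
            f"at maximum replicate noise"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = measure_replicate_r(replace(spec, replicate_noise=mid))
        if abs(r_mid - target_r) <= tol:
            return replace(spec, replicate_noise=mid)
        if r_mid > target_r:  # correlation too high -> more noise
            lo = mid
        else:
            hi = mid
    raise UnreachableTargetError(
        f"calibration did not converge to r={target_r} within {max_iter} steps"
    )
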