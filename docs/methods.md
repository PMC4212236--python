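# Methods

## Input model and replicate gating

The input is a features × (time point, replicate) count matrix,
time-point-major column order (t1r1 t1r2 … t2r1 …), 2–20 time points and
1–3 replicates, counts accepted as any non-negative finite reals so that
pre-scaled array or RT-PCR data work unchanged. An optional header line
is detected by a non-numeric second field.

Replicate quality control computes one Pearson r per time point, across
all features: replicate 1 anchors the time point, replicate 2 is kept
iff r(rep1, rep2) ≥ *c*, and replicate 3 is gated *incrementally*
against the mean of the replicates kept so far. Kept replicates are
averaged with equal weights. Design choices made here, where the gate's
fine print was genuinely open:

* the correlation unit is the replicate column (one r per time point),
  not the feature, because the vectors being compared are the full
  abundance profiles of two library preparations;
* a constant replicate vector has no defined r and is excluded with a
  logged warning — the conservative reading of the gate;
* the default threshold is c = 0.70; values below that are accepted but
  not recommended.

Raising *c* can never un-exclude replicate 2; for replicate 3 the
incremental rule makes strict threshold-monotonicity unprovable in
pathological cases (excluding replicate 2 changes the basis replicate 3
is correlated against). The property is tested at 2 replicates and holds
in practice at 3.

## Normal quantile transformation

Each time-point column is independently mapped onto a standard-normal
reference: build a sorted length-*n* reference vector, rank the column,
index the reference by the ranks. Two reference constructions:

* `deterministic` (default): Φ⁻¹((i − ½)/n), the expected-order-statistic
  grid. Reproducible run to run, and the n → ∞ limit of the random
  construction; the KS distance of a transformed column from N(0, 1) is
  ≈ 1/(2n) by construction.
* `random_draw`: n sorted pseudo-random standard normals from a
  mandatory seed, reproducing the randomized construction exactly; the
  reference is re-drawn per column from one seeded generator.

Ranks are integers 1..n with ties broken by first occurrence (stable
sort). Midranks are deliberately not used: the transform indexes a
vector, which requires integer ranks, and the stable tie-break makes the
output a permutation of the reference in every case.

## The testing cascade

With T time points and design x = 1..T (a numeric-times override is
accepted):

**Linear stage (T ≥ 3).** Per feature, OLS of the NQT profile on x;
F = SS_reg/(SS_res/(T−2)) on (1, T−2) df; significant iff p < α
(default 0.05, raw p-values). A zero residual sum of squares (relative
tolerance 1e−12) is a *perfect fit*: p is reported as 0 with a flag; a
constant profile reports F = 0, p = 1. T = 2 is saturated (zero residual
df), so the linear stage is skipped entirely.

**CDF stage (T ≤ 3).** p = Φ(tpₙ − tp₁) for each later time point; with
T = 3 both comparisons are reported and the minimum gates significance.
The test is one-sided exactly as the formula composes — small p only for
decreases — because fidelity to the published formula comes first; a
documented two-sided option p = 2(1 − Φ(|d|)) is available
(`cdf_two_sided`).

**ANOVA stage (T > 3).** Welch's unequal-variances one-way test between
two pooled groups: early = {1..⌊T/2⌋}, late = the rest — the
deterministic half split, since no grouping was prescribed. The k-group
Welch statistic is implemented directly (weights wᵢ = nᵢ/sᵢ²,
Welch–Satterthwaite denominator df); for two groups it reduces exactly
to the squared Welch t statistic, which the tests exploit as an
independent oracle. Zero within-group variance makes the weights
undefined; by convention p = 0 when the group means differ and 1 when
they are equal, logged per feature. With one NQT value per time point,
identical values (same rank at two time points) do occur, so this branch
is exercised in practice.

Multiple testing defaults to raw p < α; Benjamini–Hochberg is an opt-in
flag (`--adjust benjamini_hochberg`), applied within each test family
(linear; each CDF comparison; ANOVA). Every feature receives exactly one
classification; per-feature failures are contained and labeled
`not_significant` with a reason rather than aborting the run.

## Reporting

Heatmap rows are ordered by agglomerative hierarchical clustering
(complete linkage by default; average and single available) on the
Euclidean distance matrix of NQT profiles. The clusterer is implemented
in-package with Lance–Williams distance updates so that tie-breaking is
fully specified: the minimum-distance pair merges, ties resolved by the
smallest (older) cluster ids, and the leaf order is the preorder
traversal visiting the older child first. Heatmaps display NQT scores
(the clustered quantities) on a diverging colormap centered at 0; each
PNG has a TSV companion in a dialect loadable by generic matrix viewers.
The entry page is written to `output_files/mirnata.html`; images and
tables are linked relatively, missing artifacts render as placeholder
notes, and the page echoes α, the correlation threshold, the NQT mode
and the seed for provenance. Rendering failures never abort the
statistical pipeline; they are collected and surfaced in the exit status
and the run manifest.

## Synthetic data

`SyntheticSpec` emulates a miRNA-seq time course: baseline log2-means
uniform on [3, 10] (≈ 8–1000 counts, the dynamic range of a typical
mature-miRNA profile), negative-binomial counts with
var = μ + dispersion·μ² (dispersion 0.1 by default, sequencing-like
overdispersion), and replicates drawn independently around a
per-replicate log2-mean perturbed by N(0, replicate_noise)
(0.05 default ⇒ replicate r ≈ 0.85, i.e. replicates that pass the 0.70
gate). Planted classes: `linear` ramps of ±effect_size log2 per step,
`transient` single-interior-time-point pulses of 2·effect_size, rest
`null`.

Two generator details matter for interpreting recovery numbers:

* **Trend signs are headroom-aware.** A rank-based transform cannot
  express a trend in a feature already at the extreme of the abundance
  distribution: a top-ranked feature that keeps growing keeps rank ~n
  and its NQT profile is constant. Planting up-trends on upper-half
  baselines would therefore create labels that are unrecoverable by
  construction. The generator plants down-ramps on upper-half baselines
  and up-ramps on lower-half ones, deterministically.
* **Recall is non-monotone in effect size.** Very large per-step effects
  saturate ranks mid-course (and down-ramps hit the zero-count floor),
  flattening the NQT profile and *lowering* linear-stage recall. The
  "strong trend" regime used for recovery measurements is
  effect_size = 0.7 log2/step over 6 time points — half the 7-log2
  baseline range traversed over the 5 steps, the largest trend that does
  not saturate — with dispersion 0.05. Recall is ≈ 1.0 across effect
  sizes 0.5–1.4 under these conditions, so the measurement does not sit
  on a knife edge.

`replicate_correlation_knob` calibrates replicate_noise to a target
empirical r by bisection. Raw counts are heavy-tailed, so the empirical
r estimator averages over all time points of 10 independently generated
datasets; a target of exactly 1.0 returns the degenerate
duplicated-column spec, and targets above the ceiling set by counting
noise alone raise `UnreachableTargetError`.

What the generator does **not** emulate: library-size differences
between columns (no size factors; the NQT absorbs them anyway),
correlated features (miRNA families co-regulated in real data), batch
effects, and zero-inflation beyond what the negative binomial produces.
Passing recovery/type-I tests on this generator shows the cascade is
calibrated and sensitive under clean overdispersed counts, not that it
is robust to those real-data complications.

## Calibration measurements and problem sizes

* Type-I error of the linear stage: all-null data, 500 features ×
  4 time points × 2 replicates, 50 seeds, pooled fraction of
  linear-significant features at raw α = 0.05; measured ≈ 0.050, band
  checked [0.03, 0.07]. Under all-null generation the columns are
  exchangeable and a null feature's NQT profile is approximately iid
  N(0, 1), so the F-test is essentially exact; extreme-abundance
  features whose ranks pin at 1 or n give constant profiles and p = 1,
  a slightly conservative edge.
* Recovery: 5 seeds × 500 features at the strong-trend regime above,
  recall of planted linear features ≥ 0.9 (measured 1.0).
* Oracle agreement: OLS triples vs the normal equations, F survival
  probabilities vs numeric integration of the density, Welch p vs the
  Welch t-test and a hand-coded formula, Pearson vs the covariance
  formula, distances vs a double loop, cluster merge heights and
  mid-cut partitions vs scipy's linkage — all at 1e−10 on ~1000 random
  small instances each.
* End-to-end determinism: identical seeded runs produce byte-identical
  TSVs; numeric TSV output uses 12-significant-digit formatting, which
  round-trips the reported statistics losslessly.

## Known limitations

* The CDF stage is one-sided by default: monotone *increases* between
  two time points get p near 1 and can only be caught by the two-sided
  option (or by the linear stage when T = 3).
* One value per (feature, time point) after collapsing means the linear
  F-test at T = 4 has 2 residual df — low power by design; the cascade
  compensates with the ANOVA/CDF stages.
* The ANOVA half split tests early-vs-late mean shifts only; a pulse
  confined to one half can cancel within its group.
* Welch's test with groups of size 2–3 is approximate; its
  Satterthwaite df can drop below 2, making the p-value conservative.
* NQT discards all magnitude information: fold changes are not
  estimable from the transformed scale, and features at the rank
  extremes are blind spots (see the generator notes above).
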