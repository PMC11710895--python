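# Methods

This note documents the models, conventions and numerical choices behind
`sednet`, in the order the pipeline runs them.

## Behavioral change scores and the median split

The change score is exactly `month6 − baseline` per measure (min/day of
sitting for `st`, steps/day for `ns`). Subjects are ranked by the improvement
score `s_i = improvement_sign × change_i` with `improvement_sign = −1` for
sitting time (a decrease is an improvement) and `+1` for steps. Scores
strictly above the cohort median are "high" (more improvement), strictly
below "low". The median is the midpoint of the two central order statistics
for even cohorts. Ties at the median are deterministic: tied subjects start
in "low" and are promoted to "high" in ascending subject-id order until the
split is balanced (exact for even cohorts, within one for odd). Whether the
original study split on raw or improvement-signed change is constrained only
by its group means; the signed convention reproduces their direction (the
high-change group's sitting change is negative, its step change positive).

## Sliding-window correlation networks

* **Window**: 61 TRs (122 s at TR = 2 s), shift 1 TR, giving T = T′ − W + 1
  windows. Weights are uniform (rectangular) by default; a Tukey taper
  (`shape="tapered"`, parameter α, renormalized to sum 1) is available as an
  extension point. The tapered variant is optional because the precise taper
  used in the motivating work is not specified there.
* **Weighted Pearson correlation**: with weights w summing to one,
  m_j = Σ_t w_t x_tj, cov_jk = Σ_t w_t (x_tj − m_j)(x_tk − m_k),
  r_jk = cov_jk/√(cov_jj cov_kk). Uniform weights reduce this to plain
  Pearson (tested against `np.corrcoef` at 1e−12). A window in which a
  region's weighted variance falls below a relative floor of 1e−24·max(1, m²)
  raises a degenerate-signal error naming the region.
* **f_min guard**: windows shorter than 1/f_min seconds can produce spurious
  connectivity fluctuations. At the canonical parameters (61 TRs × 2 s =
  122 s, f_min = 0.008 → 125 s) the guard is marginally violated, so it
  warns by default; `enforce_fmin=True` upgrades it to an error.
* **Proportional threshold**: K = round(density·N(N−1)/2) upper-triangle
  entries of largest *signed* value are retained with their weights
  (`rank_by="absolute"` and `binarize=True` are available); ties break by
  ascending (row, col); rounding is half-away-from-zero, making K
  deterministic (3578 at N = 268, density 0.10). The diagonal is zeroed and
  symmetry restored by mirroring.

## HOSVD reduction

Training tensors stack into C ∈ ℝ^{N×N×T×M}. Only the connectivity modes are
reduced; because every slice is symmetric the mode-2 factor equals the
mode-1 factor, and the time/subject factors never enter any downstream
quantity, so none of the three is computed. The mode-1 factor comes from the
N×N Gram matrix G = Σ_{t,m} C_tm C_tmᵀ (equal to A Aᵀ for the mode-1
unfolding A) via `numpy.linalg.eigh`; eigenvalues are the squared singular
values. This avoids materializing the N×(N·T·M) unfolding at study scale and
is tested to agree with an explicit-unfolding SVD at 1e−8. Sign
indeterminacy is fixed by making each column's largest-magnitude entry
positive.

The reduced rank R is the smallest r whose cumulative squared-singular-value
fraction reaches the variance threshold (0.85 default). When the repeated-CV
driver selects rank automatically, it uses the *maximum* over splits of each
split's minimal rank so that feature length is constant and weight matrices
can be averaged across splits; `PipelineConfig(rank=K)` reproduces a
fixed-rank run.

Subject features are the time-averaged reduced slices, flattened row-major
to R². Averaging commutes with projection
(mean_t Uᵀ C_t U = Uᵀ (mean_t C_t) U), so the CV engine precomputes each
subject's time-mean matrix and Gram once; `project_subject` +
`time_average_features` remain the reference path and the two are tested to
agree exactly.

## Prediction

* **Splits**: 100 balanced random subsamplings; per split 14 low + 14 high
  train, 4 + 4 test, drawn uniformly and reproducibly from a seed. The same
  scheme object serves the `st` analysis, the `ns` analysis and both nulls.
* **Classifier**: soft-margin linear SVM, C = 1, no feature scaling, no
  hyperparameter search (28 training subjects leave no room for tuning),
  implemented by `sklearn.svm.SVC(kernel="linear")`. Low-change is the
  positive class, so specificity measures the high-change group.
* **Metrics**: accuracy, per-class recalls (percent), and a logistic
  cross-entropy −mean[y·ln p + (1−y)·ln(1−p)] with p = σ(decision) clipped
  to [1e−12, 1−1e−12]; no Platt scaling is fitted, again because of the
  sample size. Aggregates are mean ± sample (n−1) std over splits.
* **Leakage**: every fitted quantity (basis, SVM) is a function of that
  split's training subjects only; this is asserted bit-wise in the tests.
* **Permutation null**: per split a balanced random relabeling of the whole
  cohort is drawn, then the split proceeds unchanged
  (`per_split_permutation=False` draws one relabeling per run). Test sets
  that lose a class under relabeling (rare) report NaN recalls, which the
  aggregation skips; accuracy is always defined.

A subtlety worth knowing: repeated-subsampling permutation nulls center
slightly *below* 50% because the train and test class compositions are
anti-correlated when a balanced relabeling of a finite cohort is subsampled.
At the study geometry (36 subjects, 8-subject test sets) the measured center
is ≈48% with ≈2 points of spread across 100-split runs; at very small
cohorts (12 subjects) it drops to ≈40%. This is a property of the protocol,
not a defect of the implementation.

## Component maps

Component i is the rank-1 edge matrix u_i u_iᵀ of basis column i. Across the
100 split bases, columns are sign-aligned to the first basis (non-negative
dot product) before averaging and renormalizing — averaging sign-ambiguous
singular vectors is meaningless otherwise; the attached normalized variance
is the mean across bases. Normalized variance is defined as σ_i²/σ₁²
(ratio-to-first on the variance scale), which is what the drop-below-0.25
ranking refers to. Edge maps keep the round(0.01·N(N−1)/2) largest-|weight|
edges (358 at N = 268); node degree counts retained incident edges.

## Synthetic cohort generator

The generator emulates *preprocessed* ROI signals (no hemodynamics, motion
or scanner noise): everything is band-limited to 0.009–0.08 Hz at TR = 2 s
by frequency-domain masking of white Gaussian noise, which gives exact
spectral control and seedable determinism. Each subject's signal is

    X(t) = background + Σ_k amp_k · a_k(t) · s_k(t) · u_kᵀ + noise,

* **Background**: regions belong round-robin to the eight canonical
  subnetworks; regions of a subnetwork share a subject-specific latent
  signal scaled by `background_strength` (default 1.5 × noise SD). This
  reproduces the modular community structure of real connectomes — without
  it the top-10% thresholded edges are unstructured noise, the connectivity
  spectrum is nearly flat, and the variance-based rank selection returns
  most of the spectrum, which no real cohort shows. The background is
  identical in law for both groups.
* **Planted components**: `n_components` (default 3) unit patterns with
  equal positive loadings on disjoint random supports of ~N/(3·n_components)
  regions. Positive loadings make each component a coherent positive
  correlation block; signed thresholding would discard half the edges of a
  mixed-sign pattern. Per-support-region signal SD is
  `component_snr` (default 2) × noise SD.
* **Group effect**: only the envelopes differ. For component k, one group
  (alternating with k) has constant envelope 1 while the other's is
  max(0, 1 + effect_size · sin(2π f_k t + φ)), f_k ∈ [0.01, 0.02] Hz with a
  per-subject random phase — its connectivity through the component waxes
  and wanes over the scan. `effect_size` = 0 makes every envelope constant,
  and the generated data is bit-independent of the group assignment
  (exchangeability). The assembled signal is band-pass masked once more
  because amplitude modulation leaks small sidebands outside the band.
* **Behavior**: change scores are Gaussian around the motivating cohort's
  group means (st: +63.14 low / −68.83 high min/day; ns: −709.1 low /
  +2953.7 high steps/day) with jitter SD = gap/`behavior_gap` (default 4),
  so the median split recovers the planted groups for all but ~2% of
  subjects; baselines are Gaussian (st 570 ± 115 min/day,
  ns 6700 ± 2600 steps/day) floored so no behavioral value goes negative.

What passing tests on this cohort do *not* show: real BOLD autocorrelation
and hemodynamic smoothing, inter-subject anatomical variability, overlapping
or anti-correlated networks, non-stationary noise, or any particular true
effect size — the planted-effect scale is chosen for testability, not
realism.

## Problem sizes and defaults used in the shipped analyses

The analysis drivers and the acceptance script run 36 subjects × 80 regions
× 197 TRs with 100 subsamplings — the cohort geometry of the motivating
study with a reduced region count, which preserves every structural property
of the pipeline (window count 137, balanced 28/8 splits, per-split refits)
while keeping a full run in the tens of seconds. The full 268-region
geometry is exercised where exactness matters cheaply (edge-count contracts:
3578 kept edges at 10%, 358 at 1%).

## Known limitations

* The Tukey option stands in for the unspecified "modulated rectangular"
  taper of the motivating work; results here use rectangular weights.
* Rank selection on synthetic cohorts lands near R ≈ 30 at the 85% threshold
  (vs 17 on the real cohort) — the synthetic spectrum's tail is heavier than
  real data's; fix the rank explicitly to mirror a fixed-R analysis.
* The permutation null's small negative bias (above) is inherent to
  subsampled nulls on finite cohorts and should be kept in mind when reading
  "chance level" numbers.
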