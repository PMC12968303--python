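# Methods

This note records the models behind `breathvoc`, the choices made where
the analysis was genuinely open, and what the synthetic benchmarks do and
do not establish.

## Signal model and preprocessing

A raw micro-GC trace is modeled as a sum of Gaussian peaks on a smooth
drifting baseline, plus white detector noise, occasional 1–2-point impulse
spikes, and (optionally) hard clipping at a detector saturation level.
The preprocessing chain inverts those nuisances one at a time:

* **Spike removal.** A 5-point running median tracks any chromatographic
  peak wider than about three grid steps but not an impulse, so the
  residual against it isolates spikes even on steep peak flanks — the
  regime where a plain windowed Hampel filter fails, because the local MAD
  there is dominated by the slope.  A point is replaced when its residual
  exceeds `hampel_nsigma` (default 6) times the local MAD of the residual,
  floored at 1% of the local intensity so that noiseless traces (zero MAD)
  are never altered.  Peaks narrower than ~3 grid steps are below the
  filter's resolution; at the default 5 Hz sampling that means widths
  σ ≳ 0.6 s, comfortably below real column peak widths.
* **Baseline.** Asymmetric penalized least squares: minimize
  Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with w = p above the fit and 1−p below
  (defaults λ = 3·10⁷ at 5 Hz, p = 0.001).  Linear drifts lie in the
  penalty's null space and are removed exactly; with these defaults a
  baseline-free peak of width σ = 2 s loses < 0.2% of its area.  λ scales
  with (sampling rate)⁴ if the grid changes.
* **Overload.** Runs of ≥ 3 points at ≥ 99% of the saturation level are
  replaced by a Gaussian fitted to the unsaturated flanks of the enclosing
  window.  A noiseless peak clipped at 60% of its true height is restored
  to within a fraction of a percent; the documented contract is 10%.
* **Smoothing.** Truncated, edge-renormalized Gaussian kernel (default
  sd 0.8 s, support 5 s).  Convolution preserves peak areas exactly and
  inflates a σ = 2 s width by 8%; areas, not widths, are the quantitative
  output.  The kernel sd trades second-derivative noise against width
  resolution: at SNR 50 the default keeps the d² noise floor far below the
  curvature of peaks up to σ ≈ 3 s.
* **Detection.** Apexes are local minima of the discrete second
  derivative below −`detect_nsigma` × (MAD noise scale of d² over the
  lowest-intensity half of the trace), with an equal prominence
  requirement — without it, noise ripple inside a strong peak's curvature
  basin double-counts apexes.  On peak-free noise traces the false-positive
  rate is ≈ 0 per trace at the default 5σ.
* **Clustering and deconvolution.** Adjacent apexes merge when closer
  than 3 estimated widths or when the valley between them stays above 30%
  of the smaller apex.  Each cluster is fit by nonlinear least squares as a
  sum of Gaussians plus a constant offset.  Components of one cluster
  **share a single width** by default (`cluster_shared_width`): compounds
  that co-elute leave the column with near-identical band broadening, and
  the constraint is what makes strongly overlapped doublets identifiable —
  with free widths, a 1.5σ-separated 2:1 doublet at SNR 50 cannot be
  apportioned to 5% area accuracy (the parameters trade off along a ridge),
  while the shared-width fit recovers both areas within 5% in ≈ 95% of
  runs.  Second-derivative detection itself resolves doublets only from
  ≈ 1.75σ separation upward (below that the summed curvature has a single
  minimum), so closer overlaps must be seeded with an externally known
  component count.

## Matrix construction and normalization

Peaks are pooled across samples, sorted by retention time, and split into
features at single-linkage gaps larger than `rt_tolerance_s` (default
2 s — no number is standard; the value must exceed the instrument's RT
jitter and stay below the closest true compound spacing).  Features keep
the consensus (median) RT in their id (`VOC@510.013`, seconds).  A feature
is retained when detected in ≥ 80% of all samples or ≥ 80% of any single
clinical group; a sample is retained when ≥ 80% of retained features were
quantified in it; both boundaries are inclusive.  κ is pooled per
acquisition date over all samples and all six anchors observed that date
("daily correction factor" read as per-date pooling); V′ = 100·V/κ then
cancels any whole-day multiplicative drift exactly, which the synthetic
day-effect model makes testable.  Missing values are imputed as half the
feature's minimum observed value — a standard limit-of-detection
convention; the screening statistics are robust to it because they are
rank-based.

## Screening

Mann–Whitney U uses the exact permutation null when n₁+n₂ ≤ 12 and the
pooled sample is tie-free (the enumeration is cheap there), otherwise the
tie-corrected normal approximation with continuity correction.  The
single-marker AUC is U/(n₁n₂) with ties half-weighted; fold change is the
ratio of group medians, disease over control (medians, not means: raw
areas are right-skewed).  Benjamini–Hochberg q-values are used in the
pass rule — q < 0.05 AND VIP > 1 — rather than raw p: adjusted
significance is the stated analysis convention and the stricter of the
two readings.  All screening runs on the training split only.

## OPLS-DA and VIP

One predictive component (binary y admits exactly one discriminative
dimension) and one orthogonal component by default, fit by NIPALS-style
deflation on autoscaled (unit-variance) data.  VIP is computed on the
predictive component only — screening targets class-discriminative
importance, not total variance — which for a single component with a
unit-norm weight vector w reduces to VIPⱼ = √p·|wⱼ|, automatically
satisfying mean(VIP²) = 1.  With `n_ortho=0` the model coincides with
one-component PLS-DA, which is cross-checked against an independent PLS
implementation in the tests.

## Classification

Pairwise binary comparisons only.  The split is stratified, 75/25 by
default, at seed 42; screening, imputation statistics (training-split
minima), the log-transform floor, and hyperparameter tuning all derive
from the training rows alone.  Features enter the models on the log scale
(abundances are lognormal-like; log-then-autoscale is the metabolomics
standard) with per-feature standardization inside the scale-sensitive
pipelines.  Grids are deliberately small (logistic C, SVC C, k-NN k,
forest depth, boosting depth/learning-rate) and tuned by seeded 5-fold
stratified CV on ROC-AUC.  Point estimates come from the single declared
split; 95% percentile bootstrap intervals over 1000 test-set resamples
(single-class resamples redrawn) qualify their stability.  PPV/NPV are
reported as undefined — not zero — when no positive/negative call exists.

## Synthetic cohorts

Feature log-abundances are equicorrelated Gaussians (one correlation
parameter; no covariance information exists to justify more structure),
so raw abundances are lognormal — an assumption, chosen because areas are
positive and right-skewed and medians are the natural summary.  A target
single-marker AUC is planted through the binormal calibration
δ = √2·Φ⁻¹(AUC) (shift in units of the log-SD); a target fold change
through the lognormal median ratio (log shift = ln FC).  When both are
given, the fold change fixes the shift and the AUC then fixes the log-SD,
so both are honored simultaneously.  A per-day lognormal factor multiplies
every feature of a sample (anchors included), emulating instrument drift;
independent per-cell dropout exercises the detection filters.  The
six-feature pneumonia-vs-healthy configuration uses the per-VOC AUCs
{0.82, 0.823, 0.723, 0.712, 0.706, 0.711} as independent features, for
which the analytic binormal combination Φ(‖δ‖/√2) ≈ 0.957 bounds the
achievable test AUC.

What the generator does **not** emulate: retention-time drift between
runs, correlated (structured) covariance between compounds, heteroscedastic
detector noise, non-Gaussian peak shapes (tailing/fronting), and
concentration-dependent detection limits.  Passing benchmarks therefore
demonstrate the correctness of the estimators under the stated model, not
instrument-grade robustness.

## Problem sizes

The validation suite uses 50 five-peak traces at SNR 50 for recovery, 100
seeds for deconvolution and VIP ranking, 200 simulations for FDR control
and bootstrap coverage, 10,000 samples per group for effect-size recovery,
and 10 cohort seeds for the classifier benchmark — sizes at which the
Monte-Carlo error is comfortably below each stated tolerance.

## Known limitations

* The overload restorer assumes one Gaussian per saturated run; two peaks
  clipping into a single plateau are restored as one.
* `align_peaks` is single-linkage on RT gaps: a slow monotone RT drift
  across many samples could chain distinct compounds; RT drift correction
  is out of scope.
* The exact Mann–Whitney branch is capped at n₁+n₂ ≤ 12; for tied or
  larger samples the normal approximation is used even when an exact tie
  permutation null would be feasible.
* κ requires at least one anchor observation per date; a date losing all
  six anchors is an error rather than an interpolation.
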