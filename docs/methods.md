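# Methods

`hrvbalance` analyses beat-to-beat (RR) interval recordings collected
around an acute public-speaking stressor: a 5-minute seated baseline
("pre"), a 10-minute live interview ("interview"), and a 5-minute recovery
("post"). This note documents the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## RR preprocessing

**Artifact detection.** Chest-strap RR exports contain ectopic beats
(premature beat with a compensatory pause), missed beats (two true
intervals merged), extra beats (one interval split by a spurious trigger),
and small timing misalignments. Detection uses adaptive thresholds scaled
by the local quartile deviation (QD = inter-quartile range / 2): beat *i*
is suspect when its successive difference dRR_i or its deviation from an
11-beat local median (mRR_i) exceeds 5.2 x the QD of that series in a
sliding 91-beat window (windows truncated, not mirrored, at the edges; all
constants configurable via `ArtifactRuleConfig`). Two refinements suppress
false alarms without touching those constants:

* *echo skip* — the large dRR step immediately after a handled artifact is
  not itself an artifact when the beat's own interval is locally
  unremarkable;
* *smoothness veto* — a deviation shared in sign and comparable magnitude
  by both neighbouring beats is oscillatory physiology (a strong
  low-frequency excursion that the short median cannot track), not an
  impulsive beat error. Without it, segments with LF amplitude above
  ~55 ms have several percent of clean beats flagged.

Suspects are classified by pattern: interval/median ratio in [1.7, 2.3] ->
missed (split in two); pair sum within 30 % of the median -> extra (merge);
antisymmetric short/long pair -> ectopic; a lone median-only outlier with
ratio outside [0.7, 1.3] -> long/short; anything else -> misaligned.
Corrections only merge, split, or redistribute time inside adjacent
interval pairs (redistribution sets the first interval to a cubic-spline
estimate from surrounding good beats and gives the remainder to the
second), so total elapsed time is conserved exactly. When >= 5 % of beats
are corrected the segment is flagged and excluded from group statistics
(never silently dropped: every excluded segment appears in the run
manifest with a machine-readable reason).

On simulated series with 3 % injected artifacts the detector reaches
~0.96 sensitivity at a false-positive rate of ~3 x 10^-4. The misaligned
category (+-20-50 ms antisymmetric jitter) is only partially detectable in
principle: its dRR signature (~2 x jitter) often sits below 5.2 x QD of
normal variability. It is kept rare in the default artifact mix (0.2 % of
beats vs 1.2/0.8/0.8 % for ectopic/missed/extra), which reflects a
chest-strap error profile dominated by detection dropouts and ectopy.

**Resampling.** The corrected intervals, stamped at the time of the beat
closing each interval, are cubic-spline interpolated and evaluated on an
even 4 Hz grid spanning the observed beats (no extrapolation). Note the
tachogram reflects the underlying modulator roughly half a mean RR earlier
(midpoint rule); this pure delay is irrelevant to spectra.

**Detrending.** Slow non-stationary trends are removed with the
smoothness-priors operator: trend = (I + lambda^2 D2' D2)^{-1} y, with D2
the second-difference matrix and lambda = 500 at 4 Hz. Straight lines lie
in the null space of D2 and are removed exactly; the residual is a
high-pass signal whose cutoff (~0.03 Hz) leaves the LF and HF bands
essentially intact (a 0.25 Hz component retains > 99 % of its variance;
a 0.005 Hz component retains < 5 %). The solve uses a banded Cholesky
factorization (O(n)) and matches a dense inverse to < 1e-8 on 2000-sample
problems. Detrending is applied after resampling: a second-difference
penalty is only well defined on an even grid, so the operator order
resolves the ambiguity in favour of a numerically well-defined pipeline.

**Segmentation.** Analysis windows of 300 s (180 s fallback for phases
shorter than 300 s; below 180 s the segment is unavailable) are centered
on each phase; centering minimizes boundary transients from the phase
transitions.

## Spectral features and balance indices

Welch's method (Hann taper, 300 s windows, 50 % overlap, density
normalization; a single full-length window when the segment is shorter) is
applied to the detrended tachogram. The binding calibration contract is
Parseval: the integrated density reproduces the signal variance within
10 %, and a sinusoid of amplitude *a* ms integrates to a^2/2 ms^2 in its
band. Band powers are trapezoidal integrals over VLF 0.003-0.04 Hz
(short-term convention for the lower edge; configurable), LF 0.04-0.15 Hz
and HF 0.15-0.40 Hz.

Beyond the classical indices (total power, normalized units
LFnu = 100 LF/(LF+HF), LF/HF ratio, SDNN with the n-1 denominator), the
package centres on two coordinates of the HF-LF plane:

* **LHFP = LF + HF** — combined oscillatory power (ms^2), a radius-like
  coordinate;
* **LHFND = (LF - HF)/(LF + HF)** — a bounded (-1 to +1), symmetric
  balance index, identically (LFnu - HFnu)/100, i.e. a normalized 45
  degree rotation of the plane. Unlike the LF/HF ratio it is robust to
  near-zero denominators and treats the two bands symmetrically.

Normalized units are defined as power/(LF+HF) x 100, which makes the two
published formulations of the balance index (difference of normalized
units; normalized difference of powers) algebraically identical.

The transform (LF, HF) <-> (LHFP, LHFND) is a bijection between
{LF >= 0, HF >= 0, LF+HF > 0} and {LHFP > 0, |LHFND| <= 1}; LF+HF = 0
raises an explicit undefined-index error instead of silently producing 0.

"HR range" is reported as max - min instantaneous heart rate; published
tables in this literature sometimes label mean-HR-like values as "HR
range", so the analysis layer emits both mean HR and the literal range and
leaves the mapping to the caller.

When aggregating across subjects, the group LHFND is the mean of
per-subject LHFND values, not the LHFND of mean powers — group tables in
this field average the individual indices, and the two differ whenever
power varies across subjects.

**State labels.** Relative to a personal baseline, each band is rated
high/neutral/low with a +-20 % dead zone (configurable; published plane
figures shade regions only qualitatively, so a concrete rule is required).
(high LF, low HF) -> physical stress; (low, low) -> emotional stress;
(high, high) -> recovery/rebound onset; balanced neutral -> rest; LF
neutral with a moderate HF decrease (ratio in [0.5, 0.8)) -> engaged
"flow"; LF neutral with HF collapsed below half baseline -> mental stress
(the literature on LF under mental stress is inconsistent, so this last
mapping is a package decision, not an empirical claim). Labels are
scale-invariant and are interpretive vocabulary only — no claim is made
that they measure true sympathetic/parasympathetic drive.

## Statistics

**Repeated-measures ANOVA.** The phase factor (k = 3) is transformed into
k-1 orthonormal Helmert contrasts regressed on the between-subject design:
intercept, sum-to-zero (effect) coded factors with their full factorial
interactions, and mean-centered covariates (age, natural-log publication
count). Per term the package reports:

* the multivariate test — Pillai's trace V = tr(H (H+E)^{-1}) with the
  standard F approximation (for a rank-1 hypothesis this is exact);
* the averaged univariate test with Greenhouse-Geisser correction,
  epsilon = (tr S)^2 / ((k-1) tr S^2) from the contrast-transformed
  residual covariance S, applied unconditionally (no sphericity
  pre-test);
* the between-subjects F on subject means;
* partial eta^2 = F df1 / (F df1 + df2) for univariate effects and V/s for
  multivariate ones.

Estimated marginal means evaluate each phase at the covariate means with
balanced (unweighted) factor weights — the intercept of the per-phase
regression under this coding — and pairwise phase contrasts come from the
same regression on difference scores (so each mean difference equals the
difference of adjusted means exactly), with Bonferroni adjustment (the
conventional default; the source analyses do not state their adjustment).
Exactly constant within-subject data are snapped to zero contrast scores
so the phase test reports F = 0, p = 1 rather than amplified rounding
noise. Under the null the multivariate phase test's type-I error is
calibrated (0.052 over 500 simulations at n = 20).

**PCA with varimax.** Judgment PCA runs on the correlation matrix of
communicator-level mean ratings; components with eigenvalue > 1 (strict)
are retained, or a fixed count via `n_components`. Varimax rotation uses
Kaiser normalization (rows scaled to unit communality before rotating,
rescaled after) and reports variance proportions before and after
rotation; the retained variance is invariant under rotation to 1e-6.
Component signs follow the dominant-loading-positive convention.

**Other tests.** Paired t, Pearson correlations (two-sided p via the t
transform with n-2 df), and the Pearson chi-square for 2x2 tables (no
continuity correction) use their textbook closed forms; the chi-square p
value is exact by full enumeration of tables with fixed margins
(hypergeometric weights) for N <= 200. Binary performance clustering uses
the exact one-dimensional two-cluster solution — the sorted split
minimizing within-cluster sum of squares, which contains the global
K-means optimum in 1-D and is deterministic — with a separation F on
(1, n-2) df.

A note on degrees of freedom: with two crossed two-level factors (gender,
performance cluster), their interaction, and two covariates over n = 25
subjects, the design has 6 columns, giving multivariate within tests on
(2, 18) df, between tests on (1, 19) df, and averaged univariate error df
of 38 — matching the published table layout this layer mirrors.

## Synthetic data

**RR recordings.** An integral pulse frequency modulation (IPFM) model
emits a beat each time the running integral of the instantaneous rate
1000/(mean_rr + m(t)) crosses an integer threshold (threshold 1.0,
crossing times by linear interpolation on a 0.125 s integration grid), so
beat placement is grid-free and the RR series tracks the modulator m(t) to
first order. m(t) is the sum of an LF sinusoid (0.10 Hz), an HF sinusoid
(0.25 Hz) and broadband noise, white on the modulator (sampled at 4 Hz and
interpolated, default SD 5 ms) rather than on the intervals, which keeps
the spectrum interpretable. Sinusoid amplitudes are set as sqrt(2 x target
band power).

Default phase targets are calibrated to published whole-group values for
this protocol: mean RR 680/586/708 ms, LF 643/449/1088 ms^2, HF
295/232/373 ms^2 for pre/interview/post. The cohort generator splits
subjects into a low-Authority (LA) cluster showing the full
stress/recovery excursion — LF 900 -> 208 -> 1552 ms^2, matching the
published adjusted mean differences of -692 (pre to interview) and +1344
(interview to post) — and a high-Authority (HA) cluster nearly flat in LF
(550/550/560 ms^2). The published group-level table and the cluster-level
mean differences cannot both hold exactly for a 50/50 split; the cluster
trajectories take precedence and the implied group means stay inside the
published confidence intervals. Per-subject heterogeneity uses a lognormal
trait amplitude factor (SD 0.15), a per-phase lognormal state factor
(SD 0.20) and a normal mean-RR offset (SD 25 ms); covariates are drawn as
age ~ N(52.64, 9), log publications ~ N(3.9231, 0.8), 56 % female. The
source study reports group means but no per-subject variance components,
so these dispersions are calibrated choices, not estimates.

**Jury ratings.** 26 raters x 30 communicators x 6 Likert dimensions
(Interest, Agreement, Engagement, Authoritativeness, Learning, Clarity) on
a continuous 1-5 scale (communicator means, the analyzed quantity, are
continuous; integer rounding is optional). Ratings follow a two-factor
model — a "Content" factor carried by Interest/Agreement and a
"Performance" factor by Authoritativeness/Learning/Clarity, Engagement
split across both — with rating r,c,d = clip(mean_d + 0.25 (L_d . F_c +
sqrt(1-h^2_d) u_cd) + bias_r + eps, 1, 5), bias SD 0.3, residual SD 0.5.
The implied communicator-mean SD (~0.27) matches the published standard
errors (0.036-0.080 x sqrt(30)). Loadings implying communality > 1 are
rejected (non-positive-definite implied correlation).

**What the generator does not emulate.** Sinusoidal modulators have
line spectra, unlike the broadband LF/HF peaks of real HRV; there is no
respiratory frequency drift, no slow circadian trend beyond the phase
structure, no missing data, and artifact positions are non-adjacent by
construction. Passing tests therefore demonstrate correctness of the
pipeline's numerics and its behaviour under the study's design, not
robustness to every pathology of field recordings.

## Problem sizes

Test and validation runs use the protocol's native sizes: 300/600/300 s
phases, 24-subject cohorts, 200-run pattern-recovery batches, 500-run null
calibrations, and 50-seed fidelity checks; a full cohort analysis takes
well under a second per run on one core thanks to the banded detrend solve
and vectorized IPFM integration.

## Known limitations

* The fixed 11-beat median tracks strong LF oscillation poorly; the
  smoothness veto compensates, but extremely high-amplitude recordings may
  still see inflated correction percentages.
* The misaligned-beat category is defined here (antisymmetric +-20-50 ms
  jitter) because the field taxonomy names it without printing a
  definition; its detectability is intrinsically partial.
* The exact chi-square enumeration is limited to N <= 200 (asymptotic tail
  beyond); the 1-D clustering F assumes the usual normal-theory reference.
* Likert clipping at the 1-5 bounds slightly attenuates the jury factor
  structure relative to the unclipped model; at default noise this is
  negligible for recovery.
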