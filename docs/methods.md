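# Methods

This note documents the models, algorithms and numerical choices behind
`sparsegate`, in enough detail to reproduce or audit any stage.

## The measurement model

Somatic calcium imaging of dentate granule cells reports action-potential
firing: suprathreshold depolarization opens high-threshold calcium
channels, and a bulk-loaded indicator converts the resulting calcium influx
into a fluorescence transient with a fast rise and a slow, roughly
exponential decay. Subthreshold activity produces no somatic transient, so
"did this ROI produce a stimulus-locked transient" is a per-cell proxy for
"did this cell fire". Traces are mean ROI intensities per frame at 55
frames/s, normalized as ΔF/F₀ (%) against a pre-stimulus baseline.

## Transient detection

`detect()` composes deterministic stages; identical `(trace, params)` give
identical events.

1. **ΔF/F₀.** F₀ is the mean of the pre-stimulus baseline window (default:
   the first 1 s, truncated at the first stimulus; at least 5 frames).
   `dff = 100·(F − F₀)/F₀`.
2. **Smoothing.** Savitzky-Golay, default window 11 frames (~200 ms) and
   order 3. SG is zero-phase and reproduces polynomials up to its order
   exactly; its side effects on a fast-rise transient — backward spread of
   roughly half a window and a small (~3%) overshoot at the peak corner —
   are accounted for below.
3. **Derivative.** `np.gradient` on the uniform frame grid (central
   differences, one-sided at the ends), in % ΔF/F₀ per second.
4. **Initial threshold.** Candidate maxima of the derivative must exceed
   `deriv_threshold_k × σ_deriv`. Inside `detect()`, σ_deriv is derived
   from the raw-trace noise SD — estimated as the robust SD (1.4826·MAD)
   of the raw-minus-smoothed residual, divided by the residual filter's L2
   gain — propagated through the exact L2 gain of the smoothing+derivative
   filter chain (`filter_noise_gains`). This estimate is immune to
   contamination by the transients themselves, which matters once several
   events occupy a trace (a plain MAD of the derivative quadruples on a
   three-event sweep and silently destroys sensitivity). The standalone
   `estimate_initial_threshold` falls back to 1.4826·MAD of the derivative
   when no noise estimate is supplied. The default `deriv_threshold_k` is
   4.5, set so that a flat noisy trace (1% noise) yields a false event on
   ≤ 1% of sweeps while transients ≥ 5% ΔF/F₀ are kept with recall > 0.95;
   k = 3 admits false events on ~19% of flat sweeps.
5. **Candidates.** Local maxima of the derivative above threshold, with
   non-maximum suppression over `min_event_separation` (default 150 ms,
   keeping the larger maximum). Each maximum is bracketed by its preceding
   zero crossing (ties to the earlier frame; the onset boundary) and its
   following zero crossing (end of the rising phase).
6. **AUC gate.** The event window runs from the onset zero crossing to the
   first return of ΔF/F to its onset level, capped at the next candidate's
   onset or the trace end. A candidate is accepted iff its trapezoidal AUC
   above onset level ≥ `auc_threshold_k × σ_smoothed × median window
   duration` (k default 2.0), with σ_smoothed the smoothed-trace noise SD
   from the same residual-based estimate.
7. **Characterization.** `peak_dff` is the maximum ΔF/F in the event
   window (smoothed trace by default; `characterize_on_smoothed=False`
   switches to the raw trace, appropriate for noise-free or low-noise
   data where smoothing distortion dominates). The 90%-decay time is the
   first time after the peak at which ΔF/F falls to onset level + 10% of
   the peak-to-onset height — for a pure exponential decay this interval
   is τ·ln 10. The decay constant is a least-squares single-exponential
   fit from the peak to the 90%-decay point; when the trace ends first,
   both decay fields are NaN and the event is flagged unresolved.
   The reported onset is refined on the **raw** trace: the last pre-rise
   frame at or below onset level + max(5% of peak height, 2× the raw noise
   SD). The derivative zero crossing itself is biased early by about half
   the smoothing window and would violate frame-level onset accuracy.
8. **Stimulus assignment.** An event belongs to stimulus j iff its onset
   lies in (t_j − slack, t_j + response_window]; nearest preceding stimulus
   wins on overlap; unassigned events are spontaneous. The bare
   `classify_stimulus_responses` defaults to slack 0 (the strict interval
   rule); `detect()` passes `pre_stimulus_slack` = 50 ms because true AP
   latencies (~5–7 ms) are sub-frame at 55 Hz while onset estimates are
   frame-quantized with ~1-frame jitter — without slack, roughly half of
   genuine responses would be mislabeled spontaneous.

The interactive curation step used with such detectors in practice is
replaced by deterministic parameters plus an optional exclusion list; there
is no GUI.

## Population analysis

Viability follows the saturating-PTX logic: with GABA_A receptors blocked
and strong stimulation, nearly all healthy, afferented cells fire, so a
cell inactive in *every* condition including PTX is excluded as dead or
deafferented, and a slice in which ≥ 70% of ROIs are PTX-inactive is
excluded wholesale (the ≥ boundary is strict-at-70% and config-exposed;
69/100 inactive retains the slice). Proportional activation is
100 × responding / viable per slice, and per-slice percentages — not pooled
cells — are the unit of analysis for group comparisons. Positions within
the granule cell layer are expressed as % distance from the inner (hilar)
to the outer border; the inner/outer contingency splits at 50%.

## Juxtacellular latency

The pre-stimulus segment of each sweep sets a robust noise scale; after
blanking 1 ms past the stimulus (artifact), the AP time is the first sample
exceeding `threshold_k × scale` (k default 5). Latency is read to AP
*onset* (threshold crossing at a small fraction of spike height), not to
the spike peak. Effect sizes from printed summaries use
percent change = 100·(ref − new)/ref (rounded half-up to integers in
paper-comparison mode), fold change = new/ref, and the Welch t from SEMs;
the Welch–Satterthwaite df is emitted only when both n are known.

## Statistical battery

Standard tests are delegated to scipy (`kruskal`, `f_oneway`,
`levene(center="median")` for Brown-Forsythe, `kstest`, `ks_2samp`
(asymptotic p), `tukey_hsd`, `dunnett`); implemented here are:

- **Dunn's post hoc**: rank-mean z with the Σ(t³−t)/(12(N−1)) tie
  correction, two-sided normal p, Bonferroni family adjustment by default
  (the common commercial-software convention; `adjust="none"` disables).
- **Dunnett's comparisons** go through scipy's implementation, which
  integrates the multivariate-t null by randomized QMC with a fixed
  internal seed here, so post hoc p-values are reproducible.
- **Fisher's exact**: two-sided p as the sum of hypergeometric
  probabilities of margin-fixed tables no more probable than the observed,
  with the conventional (1+1e-7) tie slack; verified against exact integer
  enumeration for every table with N ≤ 40.
- **ROUT (one-group case)**: residuals from the median, scaled by the
  robust SD of residuals (68.27th percentile of |residual| with an n/(n−1)
  correction); residual t-tail probabilities (df = n−1) are compared,
  largest first, against the Benjamini-Hochberg boundary q·i/n, and the
  maximal extreme prefix passing is flagged. n < 5 warns and removes
  nothing. The full robust-regression variant is out of scope.
- **auto_compare_groups**: KS-screen each group for normality (against a
  normal with the sample's own mean/SD — anticonservative in the classical
  Lilliefors sense, which here only routes borderline data to the
  nonparametric branch); non-normal → Kruskal-Wallis + Dunn; otherwise
  Brown-Forsythe, with a log(x+1) transform (non-negative data only) on
  variance inequality, then one-way ANOVA with the configured post hoc.
  Under a 5-group normal null the driver's type-I error is ~0.05.

## Synthetic data: what it emulates, and what it does not

Traces are `F₀·(1 + drift·t)·(1 + Σ kernels) + N(0, noise_sd·F₀)`. The
transient kernel is a difference of exponentials normalized so its
continuous-time maximum equals the drawn amplitude; defaults τ_rise 20 ms,
τ_decay 500 ms (typical somatic kinetics for this indicator class; the
source experiments report none). Amplitudes are log-normal around the
group median (dispersion 0.4 log-units, matching right-skewed observed
distributions); responding flags are independent Bernoulli draws per cell
and stimulus with the group's per-intensity probability (p ≥ 0.95 under
PTX); onsets are stimulus time + a normal latency draw (ms, truncated).
Noise is white Gaussian at 1% of F₀ by default and drift defaults to 0 —
the simplest models that exercise the thresholds. GCL positions are
uniform on [0, 100]%. Multi-AP responses are modeled purely as larger
amplitude draws, since amplitude cannot cleanly be decomposed into spike
count versus buffering changes. Latency SDs per group are derived from the
printed SEM × √n; the >6 mo group reuses the 2–3 mo latency parameters
(not measured separately).

Deliberately **not** modeled: calcium buffering kinetics, dentate network
dynamics, correlated noise, photobleaching nonlinearity, movement
artifacts, overlapping ROIs. Passing round-trip tests therefore
demonstrates correctness of the pipeline's logic and calibration of its
thresholds under the stated noise model — not robustness to every
pathology of real recordings.

## Problem sizes and tolerances

Round-trip suites use 500 transients (noise SD 1% of F₀, amplitudes
conditioned ≥ 5% ΔF/F₀), cohorts of 6 slices × 60 cells per group, 2000
null replicates for type-I calibration, and 500 clean samples of 20 for
ROUT calibration; these sizes put binomial/CLT error well inside the
asserted bands while keeping the whole suite fast. Event matching uses a
±0.2 s onset window; noise-free assertions use one-frame (18.2 ms)
tolerances; amplitude medians are required within 10%, decay-constant fits
within 5%. The decay fit needs ≥ 3 frames past the peak and initializes τ
from the observed 90%-decay interval / ln 10.

## Known limitations

- Detector-based activation estimates are biased low for groups whose
  amplitude distribution has substantial mass below ~5% ΔF/F₀ at 1% noise
  (sensitivity floor of the thresholds); ground-truth flags in
  `SyntheticDataset.cell_metadata` allow separating this detector effect
  from population-statistics behavior.
- `welch_t_from_summary` cannot produce a df when a source omits n.
- The one-sample KS normality screen uses estimated parameters (see above).
- ROUT is the constant-fit (single-group) variant only.
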