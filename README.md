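# sparsegate

Analysis pipeline for population ("multicellular") calcium imaging of
hippocampal dentate granule cells (DGCs), the sparsely firing principal
neurons that gate cortical input into the hippocampus. In slice experiments,
perforant-path stimulation evokes somatic calcium transients (reported as
% ΔF/F₀ from an OGB-type indicator at 55 frames/s) only in the small
fraction of DGCs that fire action potentials; the fraction of responsive
cells — *proportional activation* — and the transient amplitudes are the
core readouts of dentate circuit excitability, e.g. across epilepsy
development.

`sparsegate` provides, as a tested and reusable library plus CLI:

- **Transient detection** (`sparsegate.detection`): ΔF/F₀ conversion,
  Savitzky-Golay smoothing, a derivative-threshold event caller with a
  robust (noise-calibrated) initial threshold, an area-under-the-curve
  second threshold, and per-event characterization — onset, peak % ΔF/F₀,
  AUC, 90%-decay time, single-exponential decay constant — with support for
  multiple peaks per trace and spontaneous events.
- **Population analysis** (`sparsegate.population`): viability filtering
  against a saturating-picrotoxin (PTX) condition (cells inactive in every
  condition including PTX are excluded; slices with ≥ 70% PTX-inactive ROIs
  are dropped), per-slice proportional activation, amplitude median/IQR and
  ECDFs, granule-cell-layer position statistics (two-sample KS, inner/outer
  Fisher contingency).
- **Juxtacellular analysis** (`sparsegate.ephys`): AP latency from
  loose-patch sweeps (artifact blanking + robust threshold crossing) and
  summary-statistic effect sizes — percent change, fold change, and the
  Welch *t* computed directly from (mean, SEM, n) triples,
  t = |m₁ − m₂| / √(SEM₁² + SEM₂²).
- **Statistics** (`sparsegate.stats`): KS normality screening,
  Brown-Forsythe variance test, log(x+1) variance-stabilizing transform,
  Kruskal-Wallis + Dunn's post hoc, one-way ANOVA + Dunnett's/Tukey's,
  Fisher's exact test, two-sample KS, and ROUT robust outlier elimination
  at a configurable false-discovery rate, wrapped in an `auto_compare_groups`
  decision driver.
- **Synthetic data** (`sparsegate.synthetic`): a fully seeded generator of
  ROI trace tables, cohorts and juxtacellular sweeps with known ground
  truth. `STUDY_GROUPS` carries generative profiles for a control group and
  four post-status-epilepticus time points (activation probabilities
  4/21, 57/82, 13/43, 54/81, 54/91 % at the two stimulus intensities;
  amplitude medians 5.2–19.7 % ΔF/F₀; AP latencies 5.65–7.28 ms).

## Worked example

```python
import numpy as np
from sparsegate import STUDY_GROUPS, AcquisitionConfig, detect, generate_trace

profile = STUDY_GROUPS["control"]                  # median amplitude 5.2% dF/F0
acq = AcquisitionConfig(noise_sd=0.01)             # 55 Hz, 1% noise, stim at 1 s
trace, truth = generate_trace(profile, acq, respond=[True],
                              rng=np.random.default_rng(0))
for ev in detect(trace):
    print(f"onset {ev.onset_time:.3f}s  peak {ev.peak_dff:.2f}%dF/F0 "
          f"auc {ev.auc:.2f}  stim {ev.evoking_stimulus_index}")
print(f"truth: onset {truth[0].true_onset:.3f}s  amp {truth[0].true_amplitude:.2f}")
```

prints

```
onset 1.018s  peak 5.28%dF/F0 auc 3.12  stim 0
truth: onset 1.008s  amp 4.93
```

i.e. the detector recovers the injected transient's onset to within one
frame (18 ms) and its amplitude to within the smoothing/noise error, and
assigns it to the stimulus delivered at 1 s.

The same flow scales to cohorts: `generate_population` builds multi-slice,
multi-condition datasets with consistent ROI identities, and
`sparsegate.io.run_pipeline` chains simulate → detect → viability filtering
→ per-slice activation → group statistics into a JSON report embedding the
resolved configuration and seed.

From the shell:

```bash
sparsegate simulate --group 3-7d --seed 1 --out runs/sim
sparsegate detect runs/sim/traces_400uA.csv --out runs/events.csv
sparsegate analyze runs/sim/metadata.csv --out runs/slices.csv
sparsegate report --seed 1 --out runs/report.json
```

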