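"""Synthetic OGB-loaded granule-cell imaging data with known ground truth.

Every downstream stage of the pipeline (transient detection, viability
filtering, population statistics, latency analysis) is exercised against
datasets produced here: baseline fluorescence with Gaussian noise and an
optional slow linear bleach, stimulus-locked transients with fast rise and
exponential decay, per-group activation probabilities and log-normal
amplitude distributions, picrotoxin (PTX) conditions with near-universal
activation, and juxtacellular voltage traces with group-specific action
potential latencies.

``STUDY_GROUPS`` holds the generative profiles for the five experimental
groups (control and four post-status-epilepticus time points) parameterized
from the study's reported per-group activation fractions, amplitude medians
and AP latencies.  Identical seeds and configs yield bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detection import RoiTrace
from .population import CellRecord

__all__ = [
    "AcquisitionConfig",
    "GroupProfile",
    "GroundTruthEvent",
    "SyntheticDataset",
    "STUDY_GROUPS",
    "PTX_CONDITION",
    "transient_kernel",
    "generate_trace",
    "generate_population",
    "generate_juxtacellular",
]

PTX_CONDITION = "PTX"


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging acquisition settings.

    frame_rate : Hz (55 by default, the confocal system's frame rate)
    n_frames : frames per sweep
    stimulus_times : afferent stimulus onsets, seconds
    baseline_f0 : resting fluorescence, arbitrary camera units
    noise_sd : additive Gaussian noise SD as a fraction of F₀
    drift_rate : linear bleach, fraction of F₀ per second (negative = decay)
    """

    frame_rate: float = 55.0
    n_frames: int = 330
    stimulus_times: tuple[float, ...] = (1.0,)
    baseline_f0: float = 1000.0
    noise_sd: float = 0.01
    drift_rate: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        duration = self.n_frames / self.frame_rate
        if any(not (0 <= s < duration) for s in self.stimulus_times):
            raise ConfigError("stimulus_times must lie within the sweep")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one experimental group.

    ``p_active`` and ``amplitude_median`` map a stimulus-intensity label
    (e.g. "100uA", "400uA") to the per-cell activation probability and the
    median transient amplitude (% ΔF/F₀).  Amplitudes are drawn log-normal
    around the median with ``amplitude_dispersion`` log-units of spread.
    Latencies are in ms; ``p_active_ptx`` is the activation probability
    under saturating GABA_A blockade (≥ 0.9 — near-universal activation).
    """

    name: str
    p_active: Mapping[str, float]
    amplitude_median: Mapping[str, float]
    amplitude_dispersion: float = 0.4
    tau_rise: float = 0.020
    tau_decay: float = 0.500
    latency_mean: float = 7.28
    latency_sd: float = 2.00
    p_active_ptx: float = 0.95

    def __post_init__(self) -> None:
        for p in list(self.p_active.values()) + [self.p_active_ptx]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError("activation probabilities must lie in [0,1]")
        if any(a <= 0 for a in self.amplitude_median.values()):
            raise ConfigError("amplitude medians must be positive")
        if not self.tau_decay > self.tau_rise > 0:
            raise ConfigError("need tau_decay > tau_rise > 0")

    def median_for(self, condition: str) -> float:
        if condition in self.amplitude_median:
            return self.amplitude_median[condition]
        # PTX sweeps use a strong tetanic stimulus: reuse the largest median
        return max(self.amplitude_median.values())


@dataclass(frozen=True)
class GroundTruthEvent:
    """Oracle record for one injected transient."""

    roi_id: str
    true_onset: float
    true_amplitude: float
    evoking_stimulus_index: int | None = None

    def __post_init__(self) -> None:
        if self.true_amplitude <= 0 or self.true_onset < 0:
            raise ConfigError("ground-truth events need positive amplitude, onset ≥ 0")


@dataclass
class SyntheticDataset:
    """Traces plus their oracle: ground-truth events and cell metadata.

    ``cell_metadata`` carries CellRecord skeletons whose ``responded`` maps
    hold the generator's true responding flags, so population statistics can
    be validated both against the oracle and against detector output.
    """

    traces: list[RoiTrace]
    ground_truth: list[GroundTruthEvent]
    cell_metadata: list[CellRecord]
    profile_used: GroupProfile

    def __post_init__(self) -> None:
        roi_ids = {(tr.roi_id, tr.condition) for tr in self.traces}
        if any((ev.roi_id.rsplit("/", 1)[0], ev.roi_id.rsplit("/", 1)[1]) not in roi_ids
               for ev in self.ground_truth if "/" in ev.roi_id):
            raise ConfigError("ground-truth event references a missing ROI")


# Per-group generative settings: activation fractions at moderate (100 µA)
# and supramaximal (400 µA) perforant-path stimulation, amplitude medians
# (% ΔF/F₀) per intensity, and juxtacellular AP latency (mean ms, SD ms).
# Latency was not measured for the >6 mo group; it reuses the 2–3 mo values.
STUDY_GROUPS: dict[str, GroupProfile] = {
    "control": GroupProfile(
        "control", {"100uA": 0.04, "400uA": 0.21}, {"100uA": 5.2, "400uA": 6.6},
        latency_mean=7.28, latency_sd=2.00),
    "3-7d": GroupProfile(
        "3-7d", {"100uA": 0.57, "400uA": 0.82}, {"100uA": 9.8, "400uA": 13.6},
        latency_mean=5.82, latency_sd=1.10),
    "14d": GroupProfile(
        "14d", {"100uA": 0.13, "400uA": 0.43}, {"100uA": 6.43, "400uA": 10.4},
        latency_mean=6.94, latency_sd=2.01),
    "2-3mo": GroupProfile(
        "2-3mo", {"100uA": 0.54, "400uA": 0.81}, {"100uA": 12.33, "400uA": 12.68},
        latency_mean=5.65, latency_sd=1.44),
    ">6mo": GroupProfile(
        ">6mo", {"100uA": 0.54, "400uA": 0.91}, {"100uA": 10.2, "400uA": 19.7},
        latency_mean=5.65, latency_sd=1.44),
}


def transient_kernel(
    amplitude: float, tau_rise: float, tau_decay: float, t: np.ndarray, onset: float = 0.0
) -> np.ndarray:
    """Difference-of-exponentials transient normalized to peak ``amplitude``.

    Zero before ``onset``; rises with time constant ``tau_rise``, decays with
    ``tau_decay``; the continuous-time maximum equals ``amplitude`` exactly.
    """
    if not tau_decay > tau_rise > 0:
        raise ConfigError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    s = t - onset
    out = np.zeros_like(s)
    pos = s > 0
    out[pos] = np.exp(-s[pos] / tau_decay) - np.exp(-s[pos] / tau_rise)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return amplitude * out / norm


def generate_trace(
    profile: GroupProfile,
    acq: AcquisitionConfig,
    respond: Sequence[bool],
    rng: np.random.Generator,
    roi_id: str = "roi000",
    condition: str = "100uA",
) -> tuple[RoiTrace, list[GroundTruthEvent]]:
    """One ROI trace with a ground-truth transient per responding stimulus.

    Raw fluorescence = F₀ · (1 + drift·t) · (1 + Σ kernels) + Gaussian noise.
    Each responding stimulus contributes a transient whose amplitude is a
    log-normal draw around the profile's median for ``condition`` and whose
    onset is the stimulus time plus a latency draw (ms, truncated at 0).
    """
    if len(respond) != len(acq.stimulus_times):
        raise ConfigError("respond flags must match the number of stimuli")
    t = acq.times
    dff_frac = np.zeros_like(t)
    events: list[GroundTruthEvent] = []
    median = profile.median_for(condition)
    for j, (flag, stim) in enumerate(zip(respond, acq.stimulus_times)):
        if not flag:
            continue
        latency_s = max(rng.normal(profile.latency_mean, profile.latency_sd), 0.0) / 1000.0
        onset = stim + latency_s
        amp = float(np.exp(rng.normal(np.log(median), profile.amplitude_dispersion)))
        dff_frac += transient_kernel(amp, profile.tau_rise, profile.tau_decay, t, onset) / 100.0
        events.append(GroundTruthEvent(roi_id, onset, amp, j))
    f = acq.baseline_f0 * (1.0 + acq.drift_rate * t) * (1.0 + dff_frac)
    if acq.noise_sd > 0:
        f = f + rng.normal(0.0, acq.noise_sd * acq.baseline_f0, size=len(t))
    trace = RoiTrace(
        roi_id=roi_id, t=t, f_raw=f,
        stimulus_times=tuple(acq.stimulus_times), condition=condition,
    )
    return trace, events


def generate_population(
    profile: GroupProfile,
    n_slices: int,
    n_cells_per_slice: int,
    conditions: Sequence[str] = ("100uA", "400uA", PTX_CONDITION),
    seed: int = 0,
    acq: AcquisitionConfig | None = None,
    position_dist: str = "uniform",
    position_median_pct: float = 50.0,
) -> SyntheticDataset:
    """A multi-slice, multi-condition cohort with consistent ROI identities.

    Per cell and stimulus, responding flags are independent Bernoulli draws
    with probability p_active[condition] (p_active_ptx under PTX).  Cells
    keep the same ROI id across conditions.  Positions within the granule
    cell layer (% of the inner→outer distance) are drawn uniform on
    [0, 100] by default; ``position_dist="beta"`` draws a Beta(2, b) shape
    whose median matches ``position_median_pct`` (e.g. the ~41% control or
    ~47-49% epileptic empirical medians), for position-analysis studies.
    Traces carry roi ids; ground-truth event ids are "<roi>/<condition>".
    """
    acq = acq or AcquisitionConfig()
    if position_dist not in ("uniform", "beta"):
        raise ConfigError(f"unknown position distribution: {position_dist!r}")
    if not 0 < position_median_pct < 100:
        raise ConfigError("position_median_pct must lie in (0, 100)")
    # Beta(a, b) median ≈ (a − 1/3)/(a + b − 2/3) for a, b > 1
    m = position_median_pct / 100.0
    beta_b = (2.0 - 1.0 / 3.0) / m - 2.0 + 2.0 / 3.0
    for cond in conditions:
        if cond != PTX_CONDITION and cond not in profile.p_active:
            raise ConfigError(f"unknown condition label: {cond!r}")
    rng = np.random.default_rng(seed)
    traces: list[RoiTrace] = []
    truth: list[GroundTruthEvent] = []
    cells: list[CellRecord] = []
    n_stim = len(acq.stimulus_times)
    for s in range(n_slices):
        slice_id = f"slice{s:02d}"
        for c in range(n_cells_per_slice):
            roi_id = f"{slice_id}-roi{c:03d}"
            if position_dist == "uniform":
                position = float(rng.uniform(0.0, 100.0))
            else:
                position = float(100.0 * rng.beta(2.0, beta_b))
            responded: dict[str, bool] = {}
            peak: dict[str, float | None] = {}
            for cond in conditions:
                p = profile.p_active_ptx if cond == PTX_CONDITION else profile.p_active[cond]
                flags = rng.random(n_stim) < p
                trace, evts = generate_trace(
                    profile, acq, flags, rng, roi_id=roi_id, condition=cond
                )
                trace = RoiTrace(
                    roi_id=roi_id, t=trace.t, f_raw=trace.f_raw,
                    stimulus_times=trace.stimulus_times,
                    slice_id=slice_id, condition=cond,
                )
                traces.append(trace)
                truth.extend(
                    GroundTruthEvent(f"{roi_id}/{cond}", e.true_onset,
                                     e.true_amplitude, e.evoking_stimulus_index)
                    for e in evts
                )
                responded[cond] = bool(flags.any())
                peak[cond] = max((e.true_amplitude for e in evts), default=None)
            cells.append(CellRecord(
                slice_id=slice_id, roi_id=roi_id, position_pct=position,
                responded=responded, peak_dff=peak,
            ))
    return SyntheticDataset(traces=traces, ground_truth=truth,
                            cell_metadata=cells, profile_used=profile)


def generate_juxtacellular(
    latency_mean: float,
    latency_sd: float,
    n_traces: int,
    seed: int = 0,
    sampling_rate: float = 20000.0,
    duration: float = 0.060,
    stimulus_time: float = 0.010,
    noise_sd: float = 0.02,
    ap_amplitude: float = 1.0,
) -> list[tuple["VoltageTrace", float]]:
    """Loose-patch voltage sweeps: stimulus artifact plus one AP per trace.

    Each sweep holds a brief biphasic stimulus artifact at ``stimulus_time``
    and a stereotyped action-potential waveform starting at
    stimulus_time + latency, with the latency drawn N(mean, sd) in ms
    (truncated at 0.1 ms).  Returns (trace, true_latency_ms) pairs.
    """
    from .ephys import VoltageTrace  # deferred: ephys imports nothing from here

    if latency_mean <= 0:
        raise ConfigError("latency_mean must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    dt = 1.0 / sampling_rate
    out: list[tuple[VoltageTrace, float]] = []
    for _ in range(n_traces):
        latency_ms = max(rng.normal(latency_mean, latency_sd), 0.1) if latency_sd > 0 else latency_mean
        v = np.zeros(n)
        if noise_sd > 0:
            v += rng.normal(0.0, noise_sd, size=n)
        # biphasic stimulus artifact, 0.2 ms total
        a0 = int(round(stimulus_time / dt))
        half = max(1, int(round(0.0001 / dt)))
        v[a0: a0 + half] += 5.0 * ap_amplitude
        v[a0 + half: a0 + 2 * half] -= 5.0 * ap_amplitude
        # AP: fast linear rise (0.15 ms), exponential repolarization with
        # a brief afterhyperpolarization
        ap0 = int(round((stimulus_time + latency_ms / 1000.0) / dt))
        rise = max(2, int(round(0.00015 / dt)))
        fall = int(round(0.001 / dt))
        for k in range(rise):
            if ap0 + k < n:
                v[ap0 + k] += ap_amplitude * (k + 1) / rise
        for k in range(fall):
            idx = ap0 + rise + k
            if idx < n:
                v[idx] += ap_amplitude * (1.25 * np.exp(-k * dt / 0.0003) - 0.25)
        out.append((
            VoltageTrace(t=t, v=v, stimulus_time=stimulus_time,
                         sampling_rate=sampling_rate),
            float(latency_ms),
        ))
    return out
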