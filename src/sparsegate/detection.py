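"""Calcium-transient detection on ROI fluorescence traces.

Implements a derivative-threshold event caller for somatic calcium imaging:
the raw ROI trace is converted to % ΔF/F₀, smoothed with a Savitzky-Golay
filter, and differentiated.  Local maxima of the derivative exceeding a
robust noise-scaled threshold nominate candidate transients, whose rising
phase is bracketed by the surrounding derivative zero crossings.  A second,
area-under-the-curve threshold discriminates genuine stimulus responses
from noise, and each accepted event is characterized by its onset, peak
amplitude, 90%-decay time and a single-exponential decay fit.  The number
of events per trace is unlimited, so multiple peaks under slow (~1 Hz)
stimulation and spontaneous transients are both detectable.

Detection is deterministic: identical (trace, params) give identical events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "RoiTrace",
    "DffTrace",
    "DetectionParams",
    "CandidateEvent",
    "CalciumEvent",
    "compute_dff",
    "smooth",
    "derivative",
    "estimate_initial_threshold",
    "estimate_noise_sd",
    "filter_noise_gains",
    "find_candidate_events",
    "apply_auc_threshold",
    "characterize_event",
    "detect",
    "classify_stimulus_responses",
    "robust_sd",
]


class DataError(ValueError):
    """Raised when an input trace violates the data contract."""


class ParameterError(ValueError):
    """Raised when detection parameters are inconsistent."""


def robust_sd(x: np.ndarray) -> float:
    """MAD-based robust standard deviation (consistent for a Gaussian)."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


@dataclass(frozen=True)
class RoiTrace:
    """One ROI's raw somatic fluorescence time series.

    ``t`` is the frame timestamp in seconds (frame i at i/frame_rate,
    0-based); ``f_raw`` is the mean fluorescence inside the ROI in
    arbitrary camera units.
    """

    roi_id: str
    t: np.ndarray
    f_raw: np.ndarray
    stimulus_times: tuple[float, ...] = ()
    slice_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "f_raw", np.asarray(self.f_raw, dtype=float))
        if self.t.shape != self.f_raw.shape:
            raise DataError("t and f_raw must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
                raise DataError("t must be strictly increasing and uniform")
        if np.any(self.f_raw <= 0):
            raise DataError("raw fluorescence must be positive")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class DffTrace:
    """% ΔF/F₀ trace derived from a RoiTrace; ``f0`` is the baseline used."""

    roi_id: str
    t: np.ndarray
    dff: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "dff", np.asarray(self.dff, dtype=float))
        if self.t.shape != self.dff.shape:
            raise DataError("t and dff must have equal length")
        if self.f0 <= 0:
            raise DataError("baseline f0 must be positive")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the transient detector.

    sg_window/sg_order
        Savitzky-Golay smoothing window (frames, odd) and polynomial order.
        Defaults 11 frames (~200 ms at 55 Hz) and order 3.
    deriv_threshold_k
        Initial threshold = k × robust SD of the whole-trace derivative.
    auc_threshold_k
        Second threshold: accept a candidate iff its AUC ≥ k × (robust SD
        of the ΔF/F trace × median candidate duration).
    min_event_separation
        Non-maximum-suppression window for derivative local maxima (s).
    response_window
        Post-stimulus window for stimulus-response assignment (s).
    pre_stimulus_slack
        Tolerance (s) by which a measured onset may precede a stimulus and
        still be assigned to it.  Onset estimates are frame-quantized while
        true AP latencies are sub-frame at 55 Hz, so a strict post-stimulus
        rule would mislabel genuine responses as spontaneous.
    baseline_window
        F₀ window in seconds from trace start; the effective window never
        extends past the first stimulus.
    characterize_on_smoothed
        Measure peak/AUC/decay on the smoothed (True, default) or raw ΔF/F.
    """

    sg_window: int = 11
    sg_order: int = 3
    deriv_threshold_k: float = 4.5
    auc_threshold_k: float = 2.0
    min_event_separation: float = 0.150
    response_window: float = 0.500
    pre_stimulus_slack: float = 0.050
    baseline_window: float = 1.0
    characterize_on_smoothed: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ParameterError("sg_window must be odd and exceed sg_order")
        if self.deriv_threshold_k <= 0 or self.auc_threshold_k <= 0:
            raise ParameterError("threshold multipliers must be positive")
        if self.response_window <= 0:
            raise ParameterError("response_window must be positive")


@dataclass(frozen=True)
class CandidateEvent:
    """Derivative local maximum bracketed by its zero crossings (indices)."""

    onset_idx: int
    deriv_peak_idx: int
    rise_end_idx: int
    deriv_peak_value: float


@dataclass
class CalciumEvent:
    """A detected calcium transient and its measured properties.

    Times in seconds, amplitudes in % ΔF/F₀, ``auc`` in %·s.  ``decay90_time``
    and ``decay_tau`` are NaN when the trace ends before the transient has
    decayed 90% back toward its onset level (``decay_resolved`` False).
    """

    roi_id: str
    peak_id: int
    onset_time: float
    peak_time: float
    peak_dff: float
    auc: float
    decay90_time: float
    decay_tau: float
    decay_resolved: bool = True
    evoking_stimulus_index: int | None = None


# ---------------------------------------------------------------------------
# pipeline stages


def compute_dff(trace: RoiTrace, baseline_window: float | tuple[int, int] = 1.0) -> DffTrace:
    """Convert raw fluorescence to % ΔF/F₀.

    F₀ is the mean of a pre-stimulus baseline window: either the first
    ``baseline_window`` seconds (truncated at the first stimulus) or an
    explicit (start, stop) frame range.
    """
    if isinstance(baseline_window, tuple):
        lo, hi = baseline_window
        idx = np.arange(lo, hi)
        if any(lo / trace.frame_rate <= s < hi / trace.frame_rate for s in trace.stimulus_times):
            warnings.warn("baseline window overlaps a stimulus", stacklevel=2)
    else:
        t_end = float(baseline_window)
        if trace.stimulus_times:
            t_end = min(t_end, min(trace.stimulus_times))
        idx = np.flatnonzero(trace.t < t_end)
    if len(idx) < 5:
        raise DataError("baseline window must contain at least 5 frames")
    f0 = float(np.mean(trace.f_raw[idx]))
    if f0 <= 0:
        raise DataError("non-positive baseline fluorescence")
    dff = 100.0 * (trace.f_raw - f0) / f0
    return DffTrace(roi_id=trace.roi_id, t=trace.t, dff=dff, f0=f0)


def smooth(dff: DffTrace, params: DetectionParams) -> DffTrace:
    """Savitzky-Golay smoothing; length-preserving, exact on low-order polynomials."""
    if params.sg_window >= len(dff.dff):
        raise ParameterError("sg_window must be shorter than the trace")
    sm = savgol_filter(dff.dff, params.sg_window, params.sg_order)
    return replace(dff, dff=sm)


def derivative(dff: DffTrace) -> np.ndarray:
    """First time derivative (% ΔF/F₀ per second): central differences, one-sided ends."""
    if len(dff.dff) < 3:
        raise DataError("derivative needs at least 3 frames")
    return np.gradient(dff.dff, dff.t)


def filter_noise_gains(n: int, sg_window: int, sg_order: int, dt: float) -> tuple[float, float, float]:
    """L2 gains of the smoothing/derivative filter chain for white noise.

    Returns (g_resid, g_smooth, g_deriv): the factors by which the raw noise
    SD maps to the SD of (raw − smoothed) residuals, of the smoothed trace,
    and of the derivative of the smoothed trace.  Computed from the impulse
    response of the actual filters, so noise scales derived from the
    baseline residual stay uncontaminated by the transients themselves.
    """
    n = max(n, 4 * sg_window)
    imp = np.zeros(n)
    imp[n // 2] = 1.0
    sg = savgol_filter(imp, sg_window, sg_order)
    g_smooth = float(np.sqrt(np.sum(sg**2)))
    g_resid = float(np.sqrt(np.sum((imp - sg) ** 2)))
    dsg = np.gradient(sg, dt)
    g_deriv = float(np.sqrt(np.sum(dsg**2)))
    return g_resid, g_smooth, g_deriv


def estimate_noise_sd(raw: np.ndarray, smoothed: np.ndarray, g_resid: float) -> float:
    """Raw-trace noise SD from the robust scale of the smoothing residual."""
    if g_resid <= 0:
        return 0.0
    return robust_sd(np.asarray(raw) - np.asarray(smoothed)) / g_resid


def estimate_initial_threshold(
    deriv: np.ndarray,
    k: float = 4.5,
    noise_sd: float | None = None,
    deriv_gain: float | None = None,
) -> float:
    """Initial derivative threshold estimated from the entire trace.

    With ``noise_sd`` (raw-trace noise SD) and ``deriv_gain`` given, the
    derivative's noise scale is noise_sd × deriv_gain — immune to
    contamination by the transients.  Otherwise the scale falls back to
    1.4826 × the median absolute deviation of the derivative itself, which
    is adequate when events occupy a minority of frames.
    """
    deriv = np.asarray(deriv, dtype=float)
    if len(deriv) < 20:
        raise DataError("need at least 20 frames to estimate a threshold")
    if noise_sd is not None and deriv_gain is not None:
        scale = noise_sd * deriv_gain
    else:
        scale = robust_sd(deriv)
    if scale == 0.0:
        warnings.warn("zero-variance derivative; threshold set to 0", stacklevel=2)
    return k * scale


def find_candidate_events(
    deriv: np.ndarray,
    threshold: float,
    min_event_separation: float = 0.150,
    frame_rate: float = 55.0,
) -> list[CandidateEvent]:
    """Locate suprathreshold derivative maxima and their bracketing zero crossings.

    The sliding-window step is realized as non-maximum suppression: maxima
    closer than ``min_event_separation`` are merged keeping the larger one.
    The preceding zero crossing (last frame with derivative ≤ 0; ties to the
    earlier frame) marks the onset; the following one ends the rising phase.
    """
    if threshold < 0:
        raise ParameterError("threshold must be non-negative")
    deriv = np.asarray(deriv, dtype=float)
    min_dist = max(1, int(round(min_event_separation * frame_rate)))
    peaks, _ = find_peaks(deriv, height=threshold if threshold > 0 else 1e-300,
                          distance=min_dist)
    out: list[CandidateEvent] = []
    for p in peaks:
        before = np.flatnonzero(deriv[: p] <= 0.0)
        onset = int(before[-1]) if len(before) else 0
        after = np.flatnonzero(deriv[p + 1:] <= 0.0)
        rise_end = int(p + 1 + after[0]) if len(after) else len(deriv) - 1
        out.append(CandidateEvent(onset, int(p), rise_end, float(deriv[p])))
    return out


def _event_window(dff_vals: np.ndarray, cand: CandidateEvent, hard_end: int) -> tuple[int, float]:
    """End index of a candidate's event window and its onset-level baseline.

    The window runs from the onset zero crossing to the first frame where
    ΔF/F returns to the onset level, capped at ``hard_end`` (next event's
    onset, or trace end).
    """
    onset_level = float(dff_vals[cand.onset_idx])
    seg = dff_vals[cand.rise_end_idx: hard_end + 1]
    below = np.flatnonzero(seg <= onset_level)
    end = int(cand.rise_end_idx + below[0]) if len(below) else hard_end
    return end, onset_level


def apply_auc_threshold(
    candidates: Sequence[CandidateEvent],
    dff: DffTrace,
    params: DetectionParams,
    noise_sd_smoothed: float | None = None,
) -> list[tuple[CandidateEvent, int]]:
    """Second-stage gate: keep candidates whose AUC clears the noise floor.

    AUC is the trapezoidal integral of ΔF/F above its onset level from the
    onset zero crossing to the return-to-onset point (or trace end).  The
    acceptance bound is auc_threshold_k × (robust SD of the ΔF/F trace ×
    median candidate duration), so the bound scales with both the trace's
    noise and the typical event span.  Returns (candidate, window_end_idx)
    pairs; raising auc_threshold_k can only shrink the accepted set.
    """
    if not candidates:
        return []
    vals = dff.dff
    n = len(vals)
    ends: list[int] = []
    aucs: list[float] = []
    for i, cand in enumerate(candidates):
        hard_end = candidates[i + 1].onset_idx if i + 1 < len(candidates) else n - 1
        end, onset_level = _event_window(vals, cand, hard_end)
        seg = vals[cand.onset_idx: end + 1] - onset_level
        auc = float(np.trapezoid(seg, dff.t[cand.onset_idx: end + 1]))
        ends.append(end)
        aucs.append(auc)
    durations = [dff.t[e] - dff.t[c.onset_idx] for c, e in zip(candidates, ends)]
    noise = robust_sd(vals) if noise_sd_smoothed is None else noise_sd_smoothed
    bound = params.auc_threshold_k * noise * float(np.median(durations))
    accepted = [
        (cand, end)
        for cand, end, auc in zip(candidates, ends, aucs)
        if auc > 0 and auc >= bound
    ]
    return accepted


def _refine_onset(
    raw_vals: np.ndarray,
    smooth_vals: np.ndarray,
    candidate: CandidateEvent,
    t: np.ndarray,
) -> float:
    """Onset refinement on the raw ΔF/F trace.

    The derivative zero crossing is biased early by roughly half the
    smoothing window, so the reported onset is the last pre-rise frame at
    which the raw trace still sits at baseline: at or below onset level +
    max(5% of peak height, 2 × the raw-minus-smoothed noise scale).
    """
    m = candidate.deriv_peak_idx
    hi = min(len(smooth_vals), candidate.rise_end_idx + 30)
    peak = float(smooth_vals[candidate.onset_idx: hi].max())
    base = float(smooth_vals[candidate.onset_idx])
    sigma = robust_sd(raw_vals - smooth_vals)
    level = base + max(0.05 * (peak - base), 2.0 * sigma)
    below = np.flatnonzero(raw_vals[: m + 1] <= level)
    idx = int(below[-1]) if len(below) else candidate.onset_idx
    return float(t[max(idx, 0)])


def characterize_event(
    dff: DffTrace,
    candidate: CandidateEvent,
    window_end_idx: int,
    roi_id: str | None = None,
    raw_dff: DffTrace | None = None,
) -> CalciumEvent:
    """Measure an accepted transient: peak, onset, 90%-decay point, decay fit.

    ``peak_dff`` is the maximum ΔF/F in the event window.  The 90%-decay
    time is the first time after the peak at which ΔF/F has fallen to onset
    level + 10% of the peak-to-onset height; the decay constant is a
    least-squares single-exponential fit from the peak to that point.  When
    the trace ends first, both are returned NaN with ``decay_resolved``
    False.  When ``raw_dff`` is given, the reported onset time is refined
    on the raw trace to undo the smoothing filter's backward spread.
    """
    vals = dff.dff
    t = dff.t
    lo = candidate.onset_idx
    hi = window_end_idx
    onset_level = float(vals[lo])
    seg = vals[lo: hi + 1]
    peak_rel = int(np.argmax(seg))
    peak_idx = lo + peak_rel
    peak = float(vals[peak_idx])
    target = onset_level + 0.1 * (peak - onset_level)

    decay = vals[peak_idx:]
    reached = np.flatnonzero(decay <= target)
    if len(reached):
        d90_idx = peak_idx + int(reached[0])
        decay90_time = float(t[d90_idx])
        resolved = True
    else:
        d90_idx = len(vals) - 1
        decay90_time = float("nan")
        resolved = False

    tau = float("nan")
    fit_lo, fit_hi = peak_idx, d90_idx
    if fit_hi - fit_lo >= 3 and peak > onset_level:
        ts = t[fit_lo: fit_hi + 1] - t[peak_idx]
        ys = vals[fit_lo: fit_hi + 1] - onset_level
        amp0 = peak - onset_level

        def _decay(x, tau_):
            return amp0 * np.exp(-x / tau_)

        tau0 = max((t[fit_hi] - t[peak_idx]) / np.log(10.0), 2.0 * (t[1] - t[0]))
        try:
            popt, _ = curve_fit(_decay, ts, ys, p0=[tau0], maxfev=2000)
            tau = float(popt[0])
        except RuntimeError:
            tau = float("nan")

    onset_time = float(t[lo])
    if raw_dff is not None:
        onset_time = _refine_onset(raw_dff.dff, vals, candidate, t)
        onset_time = min(onset_time, float(t[peak_idx]) - float(t[1] - t[0]))

    return CalciumEvent(
        roi_id=roi_id if roi_id is not None else dff.roi_id,
        peak_id=-1,
        onset_time=onset_time,
        peak_time=float(t[peak_idx]),
        peak_dff=peak,
        auc=float(np.trapezoid(vals[lo: hi + 1] - onset_level, t[lo: hi + 1])),
        decay90_time=decay90_time,
        decay_tau=tau if resolved else float("nan"),
        decay_resolved=resolved,
    )


def detect(trace: RoiTrace, params: DetectionParams | None = None) -> list[CalciumEvent]:
    """Full detection pipeline on one ROI trace.

    ΔF/F₀ → SG smoothing → derivative → initial threshold → candidate
    maxima with zero crossings → AUC gate → event characterization.
    Events are sorted by onset and given ordinal peak ids, then assigned
    to stimuli (within ``response_window``) or labeled spontaneous.
    """
    params = params or DetectionParams()
    dff = compute_dff(trace, params.baseline_window)
    sm = smooth(dff, params)
    deriv = derivative(sm)
    dt = float(trace.t[1] - trace.t[0])
    g_resid, g_smooth, g_deriv = filter_noise_gains(
        len(trace.t), params.sg_window, params.sg_order, dt)
    noise_sd = estimate_noise_sd(dff.dff, sm.dff, g_resid)
    threshold = estimate_initial_threshold(
        deriv, params.deriv_threshold_k, noise_sd=noise_sd, deriv_gain=g_deriv)
    candidates = find_candidate_events(
        deriv, threshold, params.min_event_separation, trace.frame_rate
    )
    char_trace = sm if params.characterize_on_smoothed else dff
    accepted = apply_auc_threshold(
        candidates, sm, params, noise_sd_smoothed=noise_sd * g_smooth)
    events = [
        characterize_event(char_trace, cand, end, roi_id=trace.roi_id, raw_dff=dff)
        for cand, end in accepted
    ]
    events.sort(key=lambda e: e.onset_time)
    for i, ev in enumerate(events):
        ev.peak_id = i
    if trace.stimulus_times:
        classify_stimulus_responses(
            events, trace.stimulus_times, params.response_window,
            onset_slack=params.pre_stimulus_slack,
        )
    return events


def classify_stimulus_responses(
    events: Sequence[CalciumEvent],
    stimulus_times: Sequence[float],
    response_window: float = 0.500,
    onset_slack: float = 0.0,
) -> np.ndarray:
    """Assign events to stimuli and flag which stimuli evoked a response.

    An event belongs to stimulus j iff its onset lies in (t_j, t_j + window];
    with overlapping windows the nearest preceding stimulus wins.  Events
    matching no stimulus are spontaneous (``evoking_stimulus_index`` None).
    ``onset_slack`` widens the interval to (t_j − slack, t_j + window] to
    absorb frame quantization of the onset estimate (0 = strict contract).
    Mutates the events in place and returns the per-stimulus responded flags.
    """
    stims = np.asarray(sorted(stimulus_times), dtype=float)
    responded = np.zeros(len(stims), dtype=bool)
    for ev in events:
        shifted = ev.onset_time + onset_slack
        j = int(np.searchsorted(stims, shifted, side="left")) - 1
        if j >= 0 and shifted > stims[j] and ev.onset_time - stims[j] <= response_window:
            ev.evoking_stimulus_index = j
            responded[j] = True
        else:
            ev.evoking_stimulus_index = None
    return responded
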