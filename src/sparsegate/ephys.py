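"""Juxtacellular recording analysis and summary-statistic effect sizes.

AP latency is read from loose-patch voltage sweeps as the first
suprathreshold excursion after the stimulus artifact is blanked; effect
sizes (percent change, fold change, Welch t from printed mean ± SEM
summaries) reproduce the arithmetic used for published group comparisons
where raw per-cell data are summarized only as (mean, SEM, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .detection import robust_sd

__all__ = [
    "VoltageTrace",
    "LatencyResult",
    "SummaryStats",
    "detect_ap_latency",
    "percent_change",
    "fold_change",
    "welch_t_from_summary",
]


@dataclass(frozen=True)
class VoltageTrace:
    """One loose-patch current-clamp sweep (high-pass character, a.u.)."""

    t: np.ndarray
    v: np.ndarray
    stimulus_time: float
    sampling_rate: float = 20000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if not (self.t[0] <= self.stimulus_time <= self.t[-1]):
            raise ValueError("stimulus_time must lie within the trace")


@dataclass(frozen=True)
class LatencyResult:
    latency_ms: float
    ap_time: float
    detected: bool


@dataclass(frozen=True)
class SummaryStats:
    """(mean, SEM, n) triple; n optional when a source does not print it."""

    mean: float
    sem: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n is not None and self.n < 2:
            raise ValueError("n must be ≥ 2 when given")


def detect_ap_latency(
    trace: VoltageTrace, artifact_blank_ms: float = 1.0, threshold_k: float = 5.0
) -> LatencyResult:
    """Stimulus→AP-onset latency from one sweep.

    The pre-stimulus segment sets a robust noise scale; after blanking
    ``artifact_blank_ms`` past the stimulus, the AP time is the first sample
    exceeding threshold_k × that scale.  Translation of the stimulus time
    shifts the detected AP time but not the latency.
    """
    if artifact_blank_ms < 0:
        raise ValueError("artifact_blank_ms must be non-negative")
    pre = trace.v[trace.t < trace.stimulus_time]
    if len(pre) < 5:
        raise ValueError("too few pre-stimulus samples for a noise estimate")
    threshold = threshold_k * robust_sd(pre)
    start = trace.stimulus_time + artifact_blank_ms / 1000.0
    search = np.flatnonzero((trace.t >= start) & (trace.v > threshold))
    if len(search) == 0:
        return LatencyResult(float("nan"), float("nan"), detected=False)
    ap_time = float(trace.t[search[0]])
    return LatencyResult((ap_time - trace.stimulus_time) * 1000.0, ap_time, True)


def percent_change(
    ref: SummaryStats, new: SummaryStats, rounded: bool = False
) -> float:
    """Signed percent reduction of the mean relative to ``ref``.

    100·(ref − new)/ref; positive when the new mean is smaller.  With
    ``rounded`` the result is rounded half-up to an integer, the convention
    used when quoting printed percentages.
    """
    if ref.mean == 0:
        raise ValueError("reference mean must be non-zero")
    change = 100.0 * (ref.mean - new.mean) / ref.mean
    if rounded:
        return float(Decimal(change).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return change


def fold_change(base: SummaryStats, new: SummaryStats) -> float:
    """new.mean / base.mean; fold_change(a,b)·fold_change(b,a) = 1."""
    if base.mean <= 0:
        raise ValueError("base mean must be positive")
    return new.mean / base.mean


def welch_t_from_summary(
    a: SummaryStats, b: SummaryStats
) -> tuple[float, float | None]:
    """Welch t statistic from two (mean, SEM[, n]) summaries.

    t = |mean_a − mean_b| / sqrt(sem_a² + sem_b²); the Welch–Satterthwaite
    df is returned only when both n are given (df = None otherwise).
    """
    if a.sem <= 0 or b.sem <= 0:
        raise ValueError("both SEMs must be positive")
    pooled = a.sem**2 + b.sem**2
    t = abs(a.mean - b.mean) / np.sqrt(pooled)
    df: float | None = None
    if a.n is not None and b.n is not None:
        df = pooled**2 / (a.sem**4 / (a.n - 1) + b.sem**4 / (b.n - 1))
    return float(t), df
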