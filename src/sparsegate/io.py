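"""File formats and the end-to-end pipeline.

Tables travel as plain CSV: trace tables (first column time in seconds, one
column per ROI, stimulus times in a ``#`` header comment), cell metadata
(slice_id, roi_id, position_pct, condition, responded), and event tables
with the exported event columns (roi_id, peak_id, onset_time, max_dff,
peak_time, decay90_time, decay_fit_param) plus auc and
evoking_stimulus_index.  An optional image mode extracts ROI-mean traces
from a multi-frame TIFF stack and a label-image ROI mask.

``run_pipeline`` chains simulate → detect → analyze → stats and returns a
JSON-serializable report embedding the resolved configuration and seed, so
every run is reproducible from its report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import population as pop
from . import stats as _stats
from .detection import CalciumEvent, DetectionParams, RoiTrace, detect
from .ephys import SummaryStats, fold_change, percent_change, welch_t_from_summary
from .population import CellRecord
from .synthetic import (
    STUDY_GROUPS,
    AcquisitionConfig,
    GroupProfile,
    generate_population,
)

log = logging.getLogger("sparsegate")

__all__ = [
    "PipelineConfig",
    "read_trace_table",
    "write_trace_table",
    "read_event_table",
    "write_event_table",
    "read_metadata",
    "write_metadata",
    "read_tiff_stack_with_rois",
    "run_pipeline",
    "load_config",
    "DEFAULT_WORKED_EXAMPLES",
]


class FormatError(ValueError):
    pass


EVENT_COLUMNS = [
    "roi_id", "peak_id", "onset_time", "max_dff", "peak_time",
    "decay90_time", "decay_fit_param", "auc", "evoking_stimulus_index",
]


def write_trace_table(traces: Sequence[RoiTrace], path) -> None:
    """CSV with a shared time column and one fluorescence column per ROI."""
    if not traces:
        raise FormatError("no traces to write")
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise FormatError("all traces must share one time grid")
    df = pd.DataFrame({"time_s": t0})
    for tr in traces:
        df[tr.roi_id] = tr.f_raw
    stim = ",".join(repr(s) for s in traces[0].stimulus_times)
    with open(path, "w") as fh:
        fh.write(f"# stimulus_times: {stim}\n")
        df.to_csv(fh, index=False)


def read_trace_table(path, condition: str = "", slice_id: str = "") -> list[RoiTrace]:
    stim: tuple[float, ...] = ()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# stimulus_times:"):
            payload = first.split(":", 1)[1].strip()
            stim = tuple(float(x) for x in payload.split(",") if x)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be time_s")
    t = df["time_s"].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        out.append(RoiTrace(roi_id=str(col), t=t,
                            f_raw=df[col].to_numpy(dtype=float),
                            stimulus_times=stim, condition=condition,
                            slice_id=slice_id))
    return out


def write_event_table(events: Sequence[CalciumEvent], path) -> None:
    rows = [{
        "roi_id": e.roi_id,
        "peak_id": e.peak_id,
        "onset_time": e.onset_time,
        "max_dff": e.peak_dff,
        "peak_time": e.peak_time,
        "decay90_time": e.decay90_time,
        "decay_fit_param": e.decay_tau,
        "auc": e.auc,
        "evoking_stimulus_index": (
            -1 if e.evoking_stimulus_index is None else e.evoking_stimulus_index),
    } for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_event_table(path) -> list[CalciumEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        idx = int(r["evoking_stimulus_index"])
        out.append(CalciumEvent(
            roi_id=str(r["roi_id"]), peak_id=int(r["peak_id"]),
            onset_time=float(r["onset_time"]), peak_time=float(r["peak_time"]),
            peak_dff=float(r["max_dff"]), auc=float(r["auc"]),
            decay90_time=float(r["decay90_time"]),
            decay_tau=float(r["decay_fit_param"]),
            decay_resolved=not np.isnan(float(r["decay90_time"])),
            evoking_stimulus_index=None if idx < 0 else idx,
        ))
    return out


def write_metadata(cells: Sequence[CellRecord], path) -> None:
    """Long-format metadata: one row per (cell, condition)."""
    rows = []
    for c in cells:
        for cond, flag in c.responded.items():
            rows.append({
                "slice_id": c.slice_id, "roi_id": c.roi_id,
                "position_pct": c.position_pct, "condition": cond,
                "responded": int(flag),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> list[CellRecord]:
    df = pd.read_csv(path)
    needed = {"slice_id", "roi_id", "position_pct", "condition", "responded"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(needed)}")
    cells: dict[tuple[str, str], CellRecord] = {}
    for _, r in df.iterrows():
        key = (str(r["slice_id"]), str(r["roi_id"]))
        if key not in cells:
            cells[key] = CellRecord(slice_id=key[0], roi_id=key[1],
                                    position_pct=float(r["position_pct"]),
                                    responded={})
        cells[key].responded[str(r["condition"])] = bool(int(r["responded"]))
    return list(cells.values())


def read_exclusion_list(path) -> set[tuple[str, int | None]]:
    """Deterministic replacement for interactive event curation.

    One entry per line: ``roi_id`` rejects every event of that ROI,
    ``roi_id,peak_id`` rejects a single event.  Blank lines and ``#``
    comments are ignored.
    """
    out: set[tuple[str, int | None]] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "," in line:
            roi, peak = line.split(",", 1)
            out.add((roi.strip(), int(peak)))
        else:
            out.add((line, None))
    return out


def filter_events(events: Sequence[CalciumEvent],
                  exclusions: set[tuple[str, int | None]]) -> list[CalciumEvent]:
    """Drop events named by an exclusion list (whole ROI or single peak)."""
    return [e for e in events
            if (e.roi_id, None) not in exclusions
            and (e.roi_id, e.peak_id) not in exclusions]


def read_tiff_stack_with_rois(stack_path, mask_path,
                              frame_rate: float = 55.0,
                              stimulus_times: Sequence[float] = ()) -> list[RoiTrace]:
    """ROI-mean fluorescence traces from a TIFF stack and a label mask.

    The mask is a single-frame label image: 0 = background, each positive
    integer one ROI.  Each frame's mean intensity inside a label forms one
    sample of that ROI's trace.
    """
    import tifffile

    stack = tifffile.imread(stack_path)
    mask = tifffile.imread(mask_path)
    if stack.ndim != 3:
        raise FormatError(f"{stack_path}: expected a multi-frame (T, Y, X) stack")
    if mask.shape != stack.shape[1:]:
        raise FormatError("mask shape must match the stack's frame shape")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    t = np.arange(stack.shape[0]) / frame_rate
    out = []
    for lab in labels:
        sel = mask == lab
        trace = stack[:, sel].mean(axis=1).astype(float)
        out.append(RoiTrace(roi_id=f"roi{int(lab):03d}", t=t, f_raw=trace,
                            stimulus_times=tuple(stimulus_times)))
    return out


# ---------------------------------------------------------------------------
# pipeline

# Printed group summaries used by the worked-example effect sizes: AP latency
# under GABA_A blockade, mIPSC amplitude early post-SE, activation under
# partial disinhibition / chloride-extrusion blockade, and the single-AP
# calcium transient amplitude comparison (control vs chronically epileptic).
DEFAULT_WORKED_EXAMPLES: list[dict[str, Any]] = [
    {"name": "ap_latency_ptx_reduction_pct", "kind": "percent_change",
     "ref": {"mean": 7.28, "sem": 0.50}, "new": {"mean": 5.18, "sem": 0.83}},
    {"name": "mipsc_amplitude_reduction_3_7d_pct", "kind": "percent_change",
     "ref": {"mean": 31.6, "sem": 1.03}, "new": {"mean": 22.58, "sem": 1.39}},
    {"name": "activation_fold_change_ptx5", "kind": "fold_change",
     "ref": {"mean": 13.0, "sem": 3.0}, "new": {"mean": 52.0, "sem": 9.8}},
    {"name": "activation_fold_change_dioa", "kind": "fold_change",
     "ref": {"mean": 13.0, "sem": 3.1}, "new": {"mean": 39.0, "sem": 5.6}},
    {"name": "single_ap_amplitude_welch_t", "kind": "welch_t",
     "ref": {"mean": 6.6, "sem": 0.5, "n": 13},
     "new": {"mean": 10.93, "sem": 1.23}},
]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, resolvable to JSON."""

    groups: tuple[str, ...] = ("control", "3-7d")
    n_slices: int = 3
    n_cells_per_slice: int = 12
    conditions: tuple[str, ...] = ("100uA", "400uA", "PTX")
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    stats: _stats.StatsParams = field(default_factory=_stats.StatsParams)
    worked_examples: list[dict[str, Any]] = field(
        default_factory=lambda: [dict(w) for w in DEFAULT_WORKED_EXAMPLES])
    seed: int = 0
    profiles: dict[str, GroupProfile] = field(default_factory=dict)

    def profile_for(self, name: str) -> GroupProfile:
        if name in self.profiles:
            return self.profiles[name]
        if name in STUDY_GROUPS:
            return STUDY_GROUPS[name]
        raise FormatError(f"unknown group: {name!r}")


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a TOML file.

    Recognized tables: [pipeline] (groups, n_slices, n_cells_per_slice,
    conditions, seed), [acquisition], [detection], [stats], and
    [profiles.<name>] blocks overriding the built-in group profiles.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    pipe = raw.get("pipeline", {})
    cfg = PipelineConfig(
        groups=tuple(pipe.get("groups", ("control", "3-7d"))),
        n_slices=int(pipe.get("n_slices", 3)),
        n_cells_per_slice=int(pipe.get("n_cells_per_slice", 12)),
        conditions=tuple(pipe.get("conditions", ("100uA", "400uA", "PTX"))),
        seed=int(pipe.get("seed", 0)),
        acquisition=AcquisitionConfig(**{
            k: (tuple(v) if k == "stimulus_times" else v)
            for k, v in raw.get("acquisition", {}).items()}),
        detection=DetectionParams(**raw.get("detection", {})),
        stats=_stats.StatsParams(**raw.get("stats", {})),
    )
    for name, block in raw.get("profiles", {}).items():
        cfg.profiles[name] = GroupProfile(name=name, **block)
    if "worked_examples" in raw:
        cfg.worked_examples = list(raw["worked_examples"])
    return cfg


def _worked_example(spec: Mapping[str, Any]) -> float:
    ref = SummaryStats(**spec["ref"])
    new = SummaryStats(**spec["new"])
    kind = spec["kind"]
    if kind == "percent_change":
        return percent_change(ref, new, rounded=True)
    if kind == "fold_change":
        return fold_change(ref, new)
    if kind == "welch_t":
        return welch_t_from_summary(ref, new)[0]
    raise FormatError(f"unknown worked-example kind: {kind!r}")


def _config_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    for name, prof in d.get("profiles", {}).items():
        d["profiles"][name] = {k: (dict(v) if isinstance(v, Mapping) else v)
                               for k, v in prof.items()}
    return d


def run_pipeline(cfg: PipelineConfig | None = None, use_detector: bool = True) -> dict[str, Any]:
    """simulate → detect → analyze → stats → report.

    Simulates each configured group, runs the transient detector on every
    trace (optionally skipped to analyze ground-truth flags directly),
    applies the viability/exclusion cascade, and compares per-slice
    activation across groups.  The returned report is JSON-serializable and
    embeds the full resolved config and seed.
    """
    cfg = cfg or PipelineConfig()
    report: dict[str, Any] = {"config": _config_dict(cfg), "groups": {}}
    group_activation: dict[str, list[float]] = {}
    rng_seed = cfg.seed
    for gi, gname in enumerate(cfg.groups):
        profile = cfg.profile_for(gname)
        ds = generate_population(
            profile, cfg.n_slices, cfg.n_cells_per_slice,
            conditions=cfg.conditions, seed=rng_seed + 1000 * gi,
            acq=cfg.acquisition,
        )
        n_in = len(ds.cell_metadata)
        if use_detector:
            cells = _cells_from_detection(ds, cfg)
        else:
            cells = ds.cell_metadata
        summaries = pop.summarize_slices(cells, cfg.conditions)
        kept = [s for s in summaries if not s.excluded]
        log.info("%s: %d cells in, %d slices kept of %d", gname, n_in,
                 len(kept), len(summaries))
        amps: dict[str, list[float]] = {}
        if use_detector:
            for cond in cfg.conditions:
                vals = [c.peak_dff.get(cond) for c in cells
                        if c.peak_dff.get(cond) is not None]
                amps[cond] = [float(v) for v in vals]
        per_cond = {
            cond: [s.pct_active[cond] for s in kept if cond in s.pct_active]
            for cond in cfg.conditions
        }
        report["groups"][gname] = {
            "n_cells": n_in,
            "n_slices_kept": len(kept),
            "pct_active_per_slice": per_cond,
            "amplitude_median": {
                c: float(np.median(v)) for c, v in amps.items() if v},
        }
        if per_cond.get(cfg.conditions[0]):
            group_activation[gname] = per_cond[cfg.conditions[0]]
    if len(group_activation) >= 2:
        res = _stats.auto_compare_groups(list(group_activation.values()), cfg.stats)
        report["group_comparison"] = {
            "condition": cfg.conditions[0],
            "method": res.method,
            "statistic": res.statistic,
            "p": res.p,
        }
    report["worked_examples"] = {
        w["name"]: _worked_example(w) for w in cfg.worked_examples
    }
    return report


def _cells_from_detection(ds, cfg: PipelineConfig) -> list[CellRecord]:
    """Rebuild CellRecords from detector output instead of ground truth."""
    by_cell: dict[str, CellRecord] = {
        c.roi_id: CellRecord(slice_id=c.slice_id, roi_id=c.roi_id,
                             position_pct=c.position_pct, responded={},
                             peak_dff={})
        for c in ds.cell_metadata
    }
    for trace in ds.traces:
        events = detect(trace, cfg.detection)
        evoked = [e for e in events if e.evoking_stimulus_index is not None]
        rec = by_cell[trace.roi_id]
        rec.responded[trace.condition] = bool(evoked)
        rec.peak_dff[trace.condition] = (
            max(e.peak_dff for e in evoked) if evoked else None)
    return list(by_cell.values())


def write_report(report: Mapping[str, Any], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
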