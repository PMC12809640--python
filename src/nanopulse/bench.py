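"""Benchmark sweeps: detector accuracy versus ground truth.

Shared by the CLI ``bench`` command and the acceptance harness. Detected
events are matched to ground-truth pulses by interval overlap; per dwell (or
modulation) level we report the median relative dwell error, the relative
precision (IQR of measured dwell over the true dwell) and the detection
rates. Both detectors can be run on the *same* simulated trace per level so
their comparison is paired.

The event rate matters for the threshold-searching (TS) comparator: its
moving-average baseline and global RMS threshold degrade when pulses occupy
a non-negligible duty cycle. ``event_rate=None`` packs pulses compactly
(fast, fine for TSW-only sweeps); pass a sparse rate (e.g. 1-2 Hz) to
reproduce the dilute-analyte recording conditions the TS algorithm assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detector import EventRecord, TSWConfig, TSWDetector
from .simulate import SquarePulseSpec, simulate_square_trace
from .threshold import TSConfig, ts_detect


def match_events(
    truth: Sequence[Tuple[int, int]],
    events: Sequence[EventRecord],
) -> List[Optional[int]]:
    """For each truth interval, the index of the overlapping detected event
    with the largest overlap (None if no event overlaps). Each detected event
    is matched at most once, greedily in truth order."""
    used = set()
    out: List[Optional[int]] = []
    starts = np.array([ev.start_index for ev in events])
    ends = np.array([ev.end_index for ev in events])
    for ts, te in truth:
        best, best_ov = None, 0
        if len(events):
            ov = np.minimum(ends, te) - np.maximum(starts, ts)
            for j in np.flatnonzero(ov > 0):
                if j in used:
                    continue
                if ov[j] > best_ov:
                    best, best_ov = int(j), int(ov[j])
        out.append(best)
        if best is not None:
            used.add(best)
    return out


@dataclass
class LevelResult:
    level: float  # dwell in seconds, or modulation sd in pA
    n_truth: int
    n_detected: int
    n_matched: int
    detection_rate: float  # matched / truth
    false_event_rate: float  # unmatched detections / truth
    median_dwell_s: float
    median_rel_error: float  # (median measured - true) / true
    rel_precision: float  # IQR(measured dwell) / true dwell
    dwell_values: np.ndarray


def _summarize(
    level: float,
    true_dwell_s: float,
    truth: Sequence[Tuple[int, int]],
    events: Sequence[EventRecord],
) -> LevelResult:
    matches = match_events(truth, events)
    matched = [events[j] for j in matches if j is not None]
    dwells = np.array([ev.dwell_s for ev in matched])
    if dwells.size:
        med = float(np.median(dwells))
        q75, q25 = np.percentile(dwells, [75, 25])
        iqr = float(q75 - q25)
    else:
        med, iqr = float("nan"), float("nan")
    n_matched = len(matched)
    return LevelResult(
        level=level,
        n_truth=len(truth),
        n_detected=len(events),
        n_matched=n_matched,
        detection_rate=n_matched / len(truth) if truth else float("nan"),
        false_event_rate=(len(events) - n_matched) / len(truth) if truth else float("nan"),
        median_dwell_s=med,
        median_rel_error=(med - true_dwell_s) / true_dwell_s,
        rel_precision=iqr / true_dwell_s,
        dwell_values=dwells,
    )


def _detect(
    trace: np.ndarray, fs: float, algo: str, ts_nominal_noise_sd: float = 0.0
) -> List[EventRecord]:
    if algo == "tsw":
        return TSWDetector(TSWConfig(fs=fs)).detect(trace)
    if algo == "ts":
        return ts_detect(trace, TSConfig(fs=fs, nominal_noise_sd=ts_nominal_noise_sd))
    raise ValueError(f"unknown algo: {algo!r}")


def _level_spec(
    dwell_s: float,
    intraevent_sd: float,
    events_per_level: int,
    event_rate: Optional[float],
    fs: float,
    fc: float,
    amplitude: float,
    noise_sd: float,
    seed: int,
) -> SquarePulseSpec:
    if event_rate is None:
        gap = max(10.0 * dwell_s, 0.004)
        rate = 1.0 / (dwell_s + gap)
    else:
        rate = event_rate
    duration = (events_per_level + 1) / rate + 0.1
    return SquarePulseSpec(
        fs=fs,
        fc=fc,
        amplitude=amplitude,
        baseline_noise_sd=noise_sd,
        event_rate=rate,
        dwell_s=dwell_s,
        intraevent_sd=intraevent_sd,
        duration_s=duration,
        seed=seed,
    )


def _child_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sweep(
    levels: Sequence[float],
    vary: str,
    algos: Sequence[str],
    events_per_level: int,
    event_rate: Optional[float],
    dwell_s: float,
    fs: float,
    fc: float,
    amplitude: float,
    noise_sd: float,
    seed: int,
    ts_nominal_noise_sd: float = 0.0,
) -> Dict[str, List[LevelResult]]:
    out: Dict[str, List[LevelResult]] = {a: [] for a in algos}
    for level, s in zip(levels, _child_seeds(seed, len(levels))):
        if vary == "dwell":
            d, mod = level, 0.0
        else:
            d, mod = dwell_s, level
        spec = _level_spec(d, mod, events_per_level, event_rate,
                           fs, fc, amplitude, noise_sd, s)
        trace, truth = simulate_square_trace(spec)
        for algo in algos:
            events = _detect(trace, fs, algo, ts_nominal_noise_sd)
            out[algo].append(_summarize(level, d, truth, events))
        del trace
    return out


def dwell_sweep(
    dwells_s: Sequence[float],
    algo: str = "tsw",
    events_per_level: int = 100,
    event_rate: Optional[float] = None,
    fs: float = 500_000.0,
    fc: float = 50_000.0,
    amplitude: float = 500.0,
    noise_sd: float = 50.0,
    seed: int = 0,
    ts_nominal_noise_sd: float = 0.0,
) -> List[LevelResult]:
    """Dwell-accuracy sweep on square pulses: one simulated trace per level
    (generated, analyzed, discarded), ground truth retained for matching."""
    return _sweep(dwells_s, "dwell", [algo], events_per_level, event_rate,
                  0.0, fs, fc, amplitude, noise_sd, seed,
                  ts_nominal_noise_sd)[algo]


def paired_dwell_sweep(
    dwells_s: Sequence[float],
    algos: Sequence[str] = ("tsw", "ts"),
    events_per_level: int = 50,
    event_rate: Optional[float] = None,
    fs: float = 500_000.0,
    fc: float = 50_000.0,
    amplitude: float = 500.0,
    noise_sd: float = 50.0,
    seed: int = 0,
    ts_nominal_noise_sd: float = 0.0,
) -> Dict[str, List[LevelResult]]:
    """Run several detectors on the same trace per dwell level."""
    return _sweep(dwells_s, "dwell", algos, events_per_level, event_rate,
                  0.0, fs, fc, amplitude, noise_sd, seed, ts_nominal_noise_sd)


def modulation_sweep(
    intraevent_sds: Sequence[float],
    algo: str = "tsw",
    events_per_level: int = 100,
    event_rate: Optional[float] = None,
    dwell_s: float = 100e-6,
    fs: float = 500_000.0,
    fc: float = 50_000.0,
    amplitude: float = 500.0,
    noise_sd: float = 50.0,
    seed: int = 0,
    ts_nominal_noise_sd: float = 0.0,
) -> List[LevelResult]:
    """Robustness sweep over intraevent modulation at a fixed dwell."""
    return _sweep(intraevent_sds, "mod", [algo], events_per_level, event_rate,
                  dwell_s, fs, fc, amplitude, noise_sd, seed,
                  ts_nominal_noise_sd)[algo]


def paired_modulation_sweep(
    intraevent_sds: Sequence[float],
    algos: Sequence[str] = ("tsw", "ts"),
    events_per_level: int = 100,
    event_rate: Optional[float] = None,
    dwell_s: float = 100e-6,
    fs: float = 500_000.0,
    fc: float = 50_000.0,
    amplitude: float = 500.0,
    noise_sd: float = 50.0,
    seed: int = 0,
    ts_nominal_noise_sd: float = 0.0,
) -> Dict[str, List[LevelResult]]:
    """Run several detectors on the same trace per modulation level."""
    return _sweep(intraevent_sds, "mod", algos, events_per_level, event_rate,
                  dwell_s, fs, fc, amplitude, noise_sd, seed,
                  ts_nominal_noise_sd)


def results_table(results: Sequence[LevelResult], level_name: str = "level") -> str:
    lines = [
        f"{level_name:>12} {'n_truth':>8} {'n_det':>6} {'matched':>8} "
        f"{'det_rate':>9} {'med_dwell_us':>13} {'rel_err_%':>10} {'rel_iqr_%':>10}"
    ]
    for r in results:
        lines.append(
            f"{r.level:>12.6g} {r.n_truth:>8d} {r.n_detected:>6d} {r.n_matched:>8d} "
            f"{r.detection_rate:>9.3f} {r.median_dwell_s * 1e6:>13.2f} "
            f"{r.median_rel_error * 100:>10.2f} {r.rel_precision * 100:>10.2f}"
        )
    return "\n".join(lines)
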