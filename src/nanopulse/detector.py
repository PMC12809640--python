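"""Streaming two-sliding-window (TSW) resistive-pulse detector.

The detector keeps a variable-length baseline window ``w1`` (grows to
``n1_init`` samples, then slides; frozen while a pulse is in progress) and a
fixed-length recent-sample window ``w2`` (``n2`` samples). A pulse starts when
the sigma level ``|I - I0| / sigma1`` of a single sample exceeds
``sigma_start`` (default 5), where ``I0`` is the moving median (or mean) of
``w1`` and ``sigma1`` its moving standard deviation. The pulse ends when the
two-sample z statistic

    z = (mean1 - mean2) / sqrt(sd1^2 / N1 + sd2^2 / N2)

comparing ``w1`` (frozen) with ``w2`` falls below ``z_end`` (default 1.96).
Samples entering ``w2`` are clamped to ``I0 +/- 5 sigma1`` so that deep or
strongly modulated blockades cannot corrupt the end-test statistics.

Reported edges are refined at the half-amplitude crossings between the
baseline and the robust blockade level (median of the deep samples). The
half-amplitude convention is invariant under the acquisition low-pass --
Gaussian smoothing of a step leaves the 50% crossing at the step position --
so the dwell time stays unbiased down to pulses only a few filter rise times
long, and anchoring the amplitude at the robust level keeps the rule stable
under heavy intraevent modulation. Crossings are linearly interpolated
between samples, so ``dwell_s`` is fractional-sample accurate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np

from . import _kernels as K


@dataclass
class TSWConfig:
    """Detector configuration.

    Parameters
    ----------
    fs : sampling rate, Hz.
    n1_init : maximum baseline-window length N1 (samples). Recommended range
        fs/1000 .. fs/10; default fs/100.
    n2 : pulse-window length N2 (samples), recommended 10..100; default 50.
    sigma_start : start threshold on the sigma level (default 5).
    z_end : end threshold on the z statistic (default 1.96).
    baseline_mode : "median" (robust, default) or "mean".
    polarity : "both" (default; blockade polarity follows the bias sign),
        "negative" or "positive".
    clamp_w2 : clamp samples entering w2 to I0 +/- 5 sigma1 (default True).
    max_event_samples : guard against runaway events (pore clogs); default
        0.5 s worth of samples.
    end_band_sigma : multiple of sigma1 above which a sample counts as part of
        the blockade plateau when refining edges (default 2.5).
    edge_pad : samples trimmed from each end of the intraevent segment when
        summarizing blockade amplitudes (default 3, about two filter rise
        times at fc = fs/10).
    """

    fs: float
    n1_init: int = 0
    n2: int = 50
    sigma_start: float = 5.0
    z_end: float = 1.96
    baseline_mode: str = "median"
    polarity: str = "both"
    clamp_w2: bool = True
    max_event_samples: int = 0
    end_band_sigma: float = 2.5
    edge_pad: int = 3

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n1_init == 0:
            self.n1_init = max(4, int(self.fs / 100))
        if self.max_event_samples == 0:
            self.max_event_samples = int(0.5 * self.fs)
        if self.n1_init < 2:
            raise ValueError("n1_init must be >= 2")
        if self.n2 < 2:
            raise ValueError("n2 must be >= 2")
        if self.sigma_start <= 0 or self.z_end <= 0:
            raise ValueError("thresholds must be positive")
        if self.baseline_mode not in ("median", "mean"):
            raise ValueError("baseline_mode must be 'median' or 'mean'")
        if self.polarity not in ("both", "negative", "positive"):
            raise ValueError("polarity must be 'both', 'negative' or 'positive'")


@dataclass
class EventRecord:
    """A detected resistive pulse.

    ``start_index`` is the start of the rising edge, ``end_index`` the start
    of the falling edge (0-based sample offsets from trace start; the
    intraevent segment is ``trace[start_index:end_index]``). ``i_min`` and
    ``i_max`` are the smallest- and largest-magnitude current blockades
    (signed, relative to the baseline) within the plateau.
    """

    start_index: int
    end_index: int
    dwell_s: float
    baseline_pA: float
    sigma_pA: float
    delta_i_mean: float
    i_min: float
    i_max: float
    samples: np.ndarray = field(repr=False)
    clog: bool = False
    delta_ref: Optional[float] = None

    def to_dict(self, with_samples: bool = False) -> dict:
        d = {
            "start_index": int(self.start_index),
            "end_index": int(self.end_index),
            "dwell_s": float(self.dwell_s),
            "baseline_pA": float(self.baseline_pA),
            "sigma_pA": float(self.sigma_pA),
            "delta_i_mean": float(self.delta_i_mean),
            "i_min": float(self.i_min),
            "i_max": float(self.i_max),
            "clog": bool(self.clog),
        }
        if self.delta_ref is not None:
            d["delta_ref"] = float(self.delta_ref)
        if with_samples:
            d["samples"] = [float(v) for v in self.samples]
        return d


def compute_nsigma(i: float, i0: float, sigma: float) -> float:
    """Sigma level of a sample: ``|i - i0| / sigma``."""
    if sigma <= 0:
        raise ValueError("degenerate baseline: sigma must be positive")
    return abs(i - i0) / sigma


def compute_z(
    mean1: float, mean2: float, sd1: float, sd2: float, n1: int, n2: int
) -> float:
    """Two-sample z statistic between the baseline and pulse windows."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both windows need at least two samples")
    denom = math.sqrt(sd1 * sd1 / n1 + sd2 * sd2 / n2)
    if denom == 0.0:
        raise ValueError("degenerate windows: zero variance in both")
    return (mean1 - mean2) / denom


def clamp_w2(x: float, i0: float, sigma1: float) -> float:
    """Clamp a sample to the band ``I0 +/- 5 sigma1`` before it enters w2."""
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    lo = i0 - 5.0 * sigma1
    hi = i0 + 5.0 * sigma1
    return min(max(x, lo), hi)


class TSWDetector:
    """Single-pass streaming detector; feed samples in chunks of any size.

    The event list is invariant to how the trace is chunked (1, 100 or 10,000
    samples per call) because all state is carried across calls.
    """

    def __init__(self, config: TSWConfig) -> None:
        self.config = config
        c = config
        self._istate = np.zeros(K.ISTATE_LEN, dtype=np.int64)
        self._fstate = np.zeros(K.FSTATE_LEN, dtype=np.float64)
        self._w1_ring = np.zeros(c.n1_init, dtype=np.float64)
        cap = 4 * c.n1_init + 64
        self._low_v = np.zeros(cap, dtype=np.float64)
        self._low_s = np.zeros(cap, dtype=np.int64)
        self._high_v = np.zeros(cap, dtype=np.float64)
        self._high_s = np.zeros(cap, dtype=np.int64)
        self._w2_ring = np.zeros(c.n2, dtype=np.float64)
        self._pol = {"both": 0, "negative": -1, "positive": 1}[c.polarity]
        self._bmode = 0 if c.baseline_mode == "median" else 1
        # rolling raw-sample history for edge refinement
        self._hist_keep = c.max_event_samples + 8 * c.n2 + 64
        self._hist = np.empty(0, dtype=np.float64)
        self._hist_start = 0  # absolute index of self._hist[0]
        self.i_ref: Optional[float] = None
        self.n_samples_seen = 0

    # -- state inspection ---------------------------------------------------

    @property
    def in_event(self) -> bool:
        return bool(self._istate[K.MODE] == 1)

    @property
    def baseline(self) -> float:
        """Current baseline estimate I0 (frozen value while in an event)."""
        if self.in_event:
            return float(self._fstate[K.I0_FROZEN])
        if self._istate[K.W1_COUNT] < 2:
            raise ValueError("baseline undefined: w1 holds fewer than 2 samples")
        if self._bmode == 0:
            return float(
                K._w1_median(
                    self._istate, self._low_v, self._low_s, self._high_v, self._high_s
                )
            )
        return float(self._fstate[K.W1_MEAN])

    @property
    def sigma1(self) -> float:
        if self.in_event:
            return float(self._fstate[K.SIG_FROZEN])
        n = self._istate[K.W1_COUNT]
        if n < 2:
            raise ValueError("sigma undefined: w1 holds fewer than 2 samples")
        return float(np.sqrt(self._fstate[K.W1_M2] / (n - 1)))

    # -- control ------------------------------------------------------------

    def flush_baseline(self) -> "TSWDetector":
        """Reset both windows (manual artifact removal); any pending event is
        discarded, and emission is suppressed until the windows re-warm. The
        reference current persists (it is configuration, not window state)."""
        K._reset_windows(self._istate, self._fstate)
        return self

    def set_reference_current(self, i_ref: float) -> "TSWDetector":
        if not math.isfinite(i_ref):
            raise ValueError("reference current must be finite")
        self.i_ref = float(i_ref)
        return self

    # -- processing ---------------------------------------------------------

    def process(self, chunk: np.ndarray) -> List[EventRecord]:
        chunk = np.ascontiguousarray(chunk, dtype=np.float64)
        if chunk.size == 0:
            return []
        if not np.all(np.isfinite(chunk)):
            raise ValueError("non-finite sample in input")
        # extend history before running so refinement can see this chunk
        self._hist = np.concatenate([self._hist, chunk])
        cap = chunk.size // 2 + 8
        ev_cross = np.zeros(cap, dtype=np.int64)
        ev_fire = np.zeros(cap, dtype=np.int64)
        ev_i0 = np.zeros(cap, dtype=np.float64)
        ev_sigma = np.zeros(cap, dtype=np.float64)
        ev_flag = np.zeros(cap, dtype=np.int64)
        dummy = np.empty(0, dtype=np.float64)
        n_ev = K.run_chunk(
            chunk,
            self._istate,
            self._fstate,
            self._w1_ring,
            self._low_v,
            self._low_s,
            self._high_v,
            self._high_s,
            self._w2_ring,
            self.config.n1_init,
            self.config.n2,
            self.config.sigma_start,
            self.config.z_end,
            self._bmode,
            self._pol,
            1 if self.config.clamp_w2 else 0,
            self.config.max_event_samples,
            ev_cross,
            ev_fire,
            ev_i0,
            ev_sigma,
            ev_flag,
            dummy,
            0,
        )
        self.n_samples_seen += chunk.size
        events = [
            self._refine(ev_cross[i], ev_fire[i], ev_i0[i], ev_sigma[i], ev_flag[i])
            for i in range(n_ev)
        ]
        # trim history
        if self._hist.size > self._hist_keep:
            drop = self._hist.size - self._hist_keep
            self._hist = self._hist[drop:]
            self._hist_start += drop
        return events

    def process_sample(self, x: float) -> Optional[EventRecord]:
        events = self.process(np.asarray([x], dtype=np.float64))
        return events[0] if events else None

    def detect(self, trace: np.ndarray, chunk_size: int = 1_000_000) -> List[EventRecord]:
        """Convenience: stream a whole trace and collect its events."""
        trace = np.asarray(trace, dtype=np.float64)
        out: List[EventRecord] = []
        for i in range(0, trace.size, chunk_size):
            out.extend(self.process(trace[i : i + chunk_size]))
        return out

    def baseline_trace(self, chunk: np.ndarray) -> np.ndarray:
        """Process a chunk and return the per-sample baseline estimate
        (NaN while the windows warm up). Events are discarded; use
        :meth:`process` when the events matter."""
        chunk = np.ascontiguousarray(chunk, dtype=np.float64)
        self._hist = np.concatenate([self._hist, chunk])
        cap = chunk.size // 2 + 8
        i0_out = np.full(chunk.size, np.nan)
        K.run_chunk(
            chunk,
            self._istate,
            self._fstate,
            self._w1_ring,
            self._low_v,
            self._low_s,
            self._high_v,
            self._high_s,
            self._w2_ring,
            self.config.n1_init,
            self.config.n2,
            self.config.sigma_start,
            self.config.z_end,
            self._bmode,
            self._pol,
            1 if self.config.clamp_w2 else 0,
            self.config.max_event_samples,
            np.zeros(cap, dtype=np.int64),
            np.zeros(cap, dtype=np.int64),
            np.zeros(cap, dtype=np.float64),
            np.zeros(cap, dtype=np.float64),
            np.zeros(cap, dtype=np.int64),
            i0_out,
            1,
        )
        self.n_samples_seen += chunk.size
        if self._hist.size > self._hist_keep:
            drop = self._hist.size - self._hist_keep
            self._hist = self._hist[drop:]
            self._hist_start += drop
        return i0_out

    # -- edge refinement ----------------------------------------------------

    def _get(self, a: int, b: int) -> np.ndarray:
        """History samples for absolute indices [a, b)."""
        a = max(a, self._hist_start)
        return self._hist[a - self._hist_start : b - self._hist_start]

    def _refine(
        self, cross: int, fire: int, i0: float, sigma1: float, flag: int
    ) -> EventRecord:
        c = self.config
        # Edges are refined at the half-amplitude crossings relative to the
        # robust blockade level. Half-amplitude is the width convention that
        # survives the acquisition low-pass: Gaussian smoothing of a step
        # leaves the 50% crossing at the step position, so dwell stays
        # unbiased even when the pulse is only a few kernel widths long.
        # Anchoring the amplitude at the robust level (median of the deep
        # samples) rather than at the extremum keeps the rule stable under
        # heavy intraevent modulation.
        seg = self._get(cross, fire + 1)
        dev = np.abs(seg - i0)
        plateau = seg[dev > c.end_band_sigma * sigma1]
        level = float(np.median(plateau)) if plateau.size else float(
            seg[int(np.argmax(dev))]
        )
        half = 0.5 * (i0 + level)
        sign = 1.0 if level < i0 else -1.0  # blockade side = sign*(x - half) < 0

        def blockade_side(j: int) -> bool:
            return sign * (self._hist[j - self._hist_start] - half) < 0.0

        def crossing(j_before: int, j_after: int) -> float:
            a = self._hist[j_before - self._hist_start]
            b = self._hist[j_after - self._hist_start]
            frac = (half - a) / (b - a) if b != a else 0.5
            return j_before + min(max(frac, 0.0), 1.0)

        # start: last baseline-side sample before the edge, searched back at
        # most n2 samples from the trigger crossing
        lo_idx = max(cross - c.n2, self._hist_start)
        j = cross if blockade_side(cross) else cross - 1
        while j > lo_idx and blockade_side(j):
            j -= 1
        t_start = crossing(j, j + 1) if not blockade_side(j) else float(j)
        start = int(math.floor(t_start))
        # end: last blockade-side sample before the z-test fired
        j = fire
        while j > start and not blockade_side(j):
            j -= 1
        if j > start:
            t_end = crossing(j, min(j + 1, fire))
        else:
            t_end = t_start + 1.0
        end = int(math.ceil(t_end))
        if end <= start:
            end = start + 1
        dwell_s = max(t_end - t_start, 1.0) / c.fs
        samples = self._get(start, end).copy()
        interior = samples[c.edge_pad : samples.size - c.edge_pad]
        if interior.size == 0:
            interior = samples
        deltas = interior - i0
        mags = np.abs(deltas)
        band = mags > c.end_band_sigma * sigma1
        core = deltas[band] if np.any(band) else deltas
        i_min = float(core[np.argmin(np.abs(core))])
        i_max = float(core[np.argmax(np.abs(core))])
        delta_i_mean = float(np.mean(samples) - i0)
        rec = EventRecord(
            start_index=int(start),
            end_index=int(end),
            dwell_s=dwell_s,
            baseline_pA=float(i0),
            sigma_pA=float(sigma1),
            delta_i_mean=delta_i_mean,
            i_min=i_min,
            i_max=i_max,
            samples=samples,
            clog=bool(flag == K.FLAG_CLOG),
        )
        if self.i_ref is not None:
            rec.delta_ref = float(np.mean(samples) - self.i_ref)
        return rec


def detect_tsw(trace: np.ndarray, config: TSWConfig) -> List[EventRecord]:
    """One-shot TSW detection over a full trace."""
    return TSWDetector(config).detect(trace)
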